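"""Statistical classification of per-cell responses to flash stimulation.

Three component tests drive the taxonomy, each a paired comparison of
per-trial spike counts in stimulus-relative windows, gated by a
Shapiro-Wilk normality test on the paired differences (paired Student t if
normal, paired Wilcoxon signed-rank otherwise):

* inhibition — decrease in [0, w) vs [-w, 0) for w in {100, 200} ms, at
  least 30 trials; both windows are evaluated and the smaller p retained;
* slow (muscarinic) excitation — increase in [+1, +2) s vs [-1, 0) s, at
  least 10 trials;
* fast excitation — increase in [0, 0.5) s vs [-0.5, 0) s, at least 10
  trials; positives are subtyped early/delayed by the mean first-spike
  latency (100 ms boundary).

The tests are one-sided in the direction named by each rule, so each runs
at its nominal size alpha under the null.  Alpha is 0.05 with no
multiple-comparison correction across the three component tests.

Labels: nonresponsive, inhibition, brief_excitation,
biphasic_inhibition_muscarinic, muscarinic_only (plus inconclusive when a
component test lacks trials).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .recording import ParameterError, Recording, stim_sample_index
from .spikes import SpikeTrainSet, detect_spikes, rate_in_window

logger = logging.getLogger(__name__)

LABELS = (
    "nonresponsive",
    "inhibition",
    "brief_excitation",
    "biphasic_inhibition_muscarinic",
    "muscarinic_only",
    "inconclusive",
)


@dataclasses.dataclass
class TestResult:
    """Outcome of one normality-gated paired comparison."""

    statistic: float
    p_value: float
    test: str                   # paired-t | wilcoxon | degenerate | none
    shapiro_p: float
    n: int
    direction: str              # increase | decrease | none
    alpha: float = 0.05
    significant: bool = False
    conclusive: bool = True
    reason: str = ""
    window: tuple | None = None

    @property
    def positive(self) -> bool:
        return self.conclusive and self.significant


def _inconclusive(reason: str) -> TestResult:
    return TestResult(statistic=np.nan, p_value=np.nan, test="none",
                      shapiro_p=np.nan, n=0, direction="none",
                      significant=False, conclusive=False, reason=reason)


def paired_gated_test(pre, post, alpha: float = 0.05,
                      alpha_norm: float = 0.05,
                      alternative: str = "two-sided") -> TestResult:
    """Shapiro-Wilk gated paired comparison of post vs pre.

    The gate runs on the paired differences: normal (p >= alpha_norm) ->
    paired Student t; otherwise paired Wilcoxon signed-rank.
    ``alternative`` refers to post relative to pre ('greater' = post > pre).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ParameterError("pre and post must have equal length")
    n = len(pre)
    if n < 5:
        raise ParameterError("paired test requires at least 5 trials")
    diffs = post - pre
    mean_d = float(diffs.mean())
    direction = "increase" if mean_d > 0 else ("decrease" if mean_d < 0
                                               else "none")
    if np.all(diffs == 0):
        return TestResult(statistic=0.0, p_value=1.0, test="degenerate",
                          shapiro_p=np.nan, n=n, direction="none",
                          alpha=alpha, significant=False)
    try:
        sw_p = float(stats.shapiro(diffs).pvalue)
    except ValueError:
        sw_p = 0.0  # constant or otherwise untestable -> treat as non-normal
    if sw_p >= alpha_norm:
        res = stats.ttest_rel(post, pre, alternative=alternative)
        test = "paired-t"
    else:
        try:
            res = stats.wilcoxon(post, pre, alternative=alternative,
                                 zero_method="wilcox")
            test = "wilcoxon"
        except ValueError:
            return TestResult(statistic=0.0, p_value=1.0, test="degenerate",
                              shapiro_p=sw_p, n=n, direction=direction,
                              alpha=alpha, significant=False)
    p = float(res.pvalue)
    return TestResult(statistic=float(res.statistic), p_value=p, test=test,
                      shapiro_p=sw_p, n=n, direction=direction, alpha=alpha,
                      significant=p < alpha)


# ---------------------------------------------------------------------------
# component tests
# ---------------------------------------------------------------------------

def test_inhibition(spikes: SpikeTrainSet, stim_times,
                    windows=(0.1, 0.2), min_trials: int = 30,
                    alpha: float = 0.05, alpha_norm: float = 0.05
                    ) -> TestResult:
    """Post-stimulus spiking inhibition: rate decrease in a 100- or 200-ms
    window immediately after the flash vs the same window before it.

    Both windows are evaluated and the most significant retained; the
    reported p-value is Bonferroni-adjusted for the number of windows
    actually tested, so the test keeps its nominal size alpha under the
    null despite the window search.
    """
    best = None
    n_tested = 0
    for w in windows:
        try:
            pre, _ = rate_in_window(spikes, stim_times, (-w, 0.0))
            post, _ = rate_in_window(spikes, stim_times, (0.0, w))
        except ParameterError:
            continue
        if len(pre) < min_trials or len(post) < min_trials:
            continue
        res = paired_gated_test(pre, post, alpha=alpha, alpha_norm=alpha_norm,
                                alternative="less")
        res.window = (-w, w)
        n_tested += 1
        if best is None or (res.p_value < best.p_value
                            if np.isfinite(res.p_value) else False):
            best = res
    if best is None:
        return _inconclusive(f"fewer than {min_trials} usable trials")
    if n_tested > 1:
        best.p_value = min(1.0, n_tested * best.p_value)
        best.significant = best.p_value < best.alpha
    return best


def test_slow_excitation(spikes: SpikeTrainSet, stim_times,
                         min_trials: int = 10, alpha: float = 0.05,
                         alpha_norm: float = 0.05) -> TestResult:
    """Muscarinic excitation: spike-count increase in [+1, +2) s vs
    [-1, 0) s around the flash."""
    try:
        pre, _ = rate_in_window(spikes, stim_times, (-1.0, 0.0))
        post, _ = rate_in_window(spikes, stim_times, (1.0, 2.0))
    except ParameterError:
        return _inconclusive("episodes too short for the [-1, +2] s windows")
    if len(pre) < min_trials or len(post) < min_trials or len(pre) != len(post):
        return _inconclusive(f"fewer than {min_trials} usable trials")
    res = paired_gated_test(pre, post, alpha=alpha, alpha_norm=alpha_norm,
                            alternative="greater")
    res.window = (-1.0, 2.0)
    return res


def test_fast_excitation(spikes: SpikeTrainSet, stim_times,
                         search_window: float = 0.5, min_trials: int = 10,
                         alpha: float = 0.05, alpha_norm: float = 0.05,
                         early_boundary: float = 0.1):
    """Short-latency evoked spiking: count increase in [0, 0.5) s vs
    [-0.5, 0) s.

    Returns ``(TestResult, mean_latency_s | None, latency_class)`` with
    latency_class in {early, delayed, none}; positives are early when the
    mean first-spike latency is below ``early_boundary``.
    """
    w = search_window
    try:
        pre, _ = rate_in_window(spikes, stim_times, (-w, 0.0))
        post, _ = rate_in_window(spikes, stim_times, (0.0, w))
    except ParameterError:
        return _inconclusive("episodes too short for the fast windows"), None, "none"
    if len(pre) < min_trials or len(post) < min_trials:
        return _inconclusive(f"fewer than {min_trials} usable trials"), None, "none"
    res = paired_gated_test(pre, post, alpha=alpha, alpha_norm=alpha_norm,
                            alternative="greater")
    res.window = (-w, w)
    if not res.positive:
        return res, None, "none"
    lats = []
    for train in spikes.trains:
        for s in stim_times:
            rel = train - s
            rel = rel[(rel >= 0) & (rel < w)]
            if len(rel):
                lats.append(rel[0])
    if not lats:
        raise RuntimeError("internal consistency error: fast excitation "
                           "positive with zero post-flash spikes")
    mean_lat = float(np.mean(lats))
    return res, mean_lat, ("early" if mean_lat < early_boundary else "delayed")


def inhibition_duration(spikes: SpikeTrainSet, stim_times,
                        inhibition_positive: bool = True):
    """Mean and SD over trials of (first post-flash spike time - flash time).

    Trials without a post-flash spike (before the next flash or episode
    end) are excluded; their count is returned.  Returns
    ``(mean_s, sd_s, n_trials, n_excluded)`` or None when no trial has a
    post-flash spike.
    """
    if not inhibition_positive:
        logger.warning("inhibition_duration called without a positive "
                       "inhibition test")
    stims = sorted(stim_times)
    lats, excluded = [], 0
    for train in spikes.trains:
        for i, s in enumerate(stims):
            horizon = stims[i + 1] if i + 1 < len(stims) \
                else spikes.episode_duration
            rel = train - s
            rel = rel[(rel >= 0) & (rel < horizon - s)]
            if len(rel):
                lats.append(rel[0])
            else:
                excluded += 1
    if not lats:
        return None
    lats = np.asarray(lats)
    sd = float(lats.std(ddof=1)) if len(lats) > 1 else 0.0
    return float(lats.mean()), sd, len(lats), excluded


def evoked_current_polarity(rec: Recording, stim_times=None,
                            window: tuple = (0.0, 0.05),
                            spikes: SpikeTrainSet | None = None,
                            mask_halfwidth: float = 0.003,
                            baseline_s: float = 0.01,
                            k_se: float = 3.0) -> str:
    """Sign of the small stimulus-locked capacitive current.

    Spike waveforms are removed (samples within +-3 ms of detected spikes
    masked), trials averaged, the 10-ms pre-stimulus baseline subtracted,
    and the mean over ``window`` compared with ``k_se`` x the baseline
    standard error.  Returns 'inward' (negative), 'outward' (positive),
    'none', or 'absent' when everything is masked.
    """
    stim_times = rec.stim_times if stim_times is None else stim_times
    if spikes is None:
        spikes = detect_spikes(rec)
    fs = rec.sampling_rate
    traces = rec.traces.astype(float).copy()
    half = int(round(mask_halfwidth * fs))
    for ep, train in enumerate(spikes.trains):
        for t in train:
            i = int(round(t * fs))
            traces[ep, max(i - half, 0): i + half + 1] = np.nan
    n_pre = int(round(baseline_s * fs))
    lo, hi = window
    pre_vals, post_vals = [], []
    for s in stim_times:
        i0 = stim_sample_index(s, fs)
        j0, j1 = i0 + int(round(lo * fs)), i0 + int(round(hi * fs))
        if i0 - n_pre < 0 or j1 > rec.n_samples:
            continue
        pre_vals.append(traces[:, i0 - n_pre:i0])
        post_vals.append(traces[:, j0:j1])
    if not pre_vals:
        raise ParameterError("no usable trials for polarity measurement")
    with np.errstate(invalid="ignore"):
        pre_avg = np.nanmean(np.concatenate(pre_vals, axis=0), axis=0)
        post_avg = np.nanmean(np.concatenate(post_vals, axis=0), axis=0)
    if np.all(np.isnan(post_avg)):
        return "absent"
    base = np.nanmean(pre_avg)
    base_sd = np.nanstd(pre_avg, ddof=1)
    m = np.nanmean(post_avg) - base
    n_post = np.sum(~np.isnan(post_avg))
    n_pre = np.sum(~np.isnan(pre_avg))
    # both the window mean and the subtracted baseline carry sampling error
    se = base_sd * np.sqrt(1.0 / n_post + 1.0 / n_pre)
    if abs(m) > k_se * se:
        return "inward" if m < 0 else "outward"
    return "none"


# ---------------------------------------------------------------------------
# model-style front end
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClassificationResult:
    """Per-cell label with component statistics and derived measures."""

    label: str
    inhibition: TestResult
    slow: TestResult
    fast: TestResult
    inhibition_duration_s: float | None = None
    inhibition_duration_sd_s: float | None = None
    mean_latency_s: float | None = None
    latency_class: str = "none"
    polarity: str = "none"
    cell_id: str = "cell"
    n_trials: int = 0
    reasons: list = dataclasses.field(default_factory=list)

    def summary(self) -> str:
        def fmt_p(r):
            return "n/a" if not r.conclusive else f"{r.p_value:.4g} ({r.test})"
        lines = [
            f"Response classification -- {self.cell_id}",
            "=" * 48,
            f"label                 {self.label}",
            f"inhibition p          {fmt_p(self.inhibition)}",
            f"slow excitation p     {fmt_p(self.slow)}",
            f"fast excitation p     {fmt_p(self.fast)}",
        ]
        if self.inhibition_duration_s is not None:
            lines.append(
                "inhibition duration   "
                f"{self.inhibition_duration_s * 1e3:.0f} +/- "
                f"{self.inhibition_duration_sd_s * 1e3:.0f} ms")
        if self.mean_latency_s is not None:
            lines.append(
                f"evoked-spike latency  {self.mean_latency_s * 1e3:.1f} ms "
                f"({self.latency_class})")
        lines.append(f"evoked polarity       {self.polarity}")
        if self.reasons:
            lines.append("notes: " + "; ".join(self.reasons))
        return "\n".join(lines)


class ResponseClassifier:
    """Classifier for one cell's flash-aligned recording.

    Build from a loose cell-attached :class:`Recording` (spikes are
    detected automatically) or directly from a :class:`SpikeTrainSet`;
    ``fit()`` runs the three component tests and the decision table and
    returns a :class:`ClassificationResult`.
    """

    def __init__(self, recording: Recording | None = None,
                 spikes: SpikeTrainSet | None = None,
                 stim_times=None, spike_threshold="auto",
                 refractory: float = 0.002, alpha: float = 0.05,
                 alpha_norm: float = 0.05, min_trials_inhibition: int = 30,
                 min_trials_slow: int = 10, min_trials_fast: int = 10,
                 measure_polarity: bool | None = None):
        if recording is None and spikes is None:
            raise ParameterError("provide a recording or spike trains")
        self.recording = recording
        if spikes is None:
            spikes = detect_spikes(recording, threshold=spike_threshold,
                                   refractory=refractory)
        self.spikes = spikes
        if stim_times is None:
            if recording is None or not recording.stim_times:
                raise ParameterError("stimulus times required")
            stim_times = recording.stim_times
        self.stim_times = list(stim_times)
        self.alpha = alpha
        self.alpha_norm = alpha_norm
        self.min_trials = (min_trials_inhibition, min_trials_slow,
                           min_trials_fast)
        self.measure_polarity = (recording is not None
                                 if measure_polarity is None
                                 else measure_polarity)

    def fit(self) -> ClassificationResult:
        mi, ms, mf = self.min_trials
        inhib = test_inhibition(self.spikes, self.stim_times, min_trials=mi,
                                alpha=self.alpha, alpha_norm=self.alpha_norm)
        slow = test_slow_excitation(self.spikes, self.stim_times,
                                    min_trials=ms, alpha=self.alpha,
                                    alpha_norm=self.alpha_norm)
        fast, mean_lat, lat_class = test_fast_excitation(
            self.spikes, self.stim_times, min_trials=mf, alpha=self.alpha,
            alpha_norm=self.alpha_norm)

        reasons = [f"{name}: {r.reason}"
                   for name, r in (("inhibition", inhib), ("slow", slow),
                                   ("fast", fast)) if not r.conclusive]
        if reasons:
            label = "inconclusive"
        elif inhib.positive:
            label = ("biphasic_inhibition_muscarinic" if slow.positive
                     else "inhibition")
        elif slow.positive:
            label = "muscarinic_only"
        elif fast.positive:
            label = "brief_excitation"
        else:
            label = "nonresponsive"

        dur = sd = None
        if inhib.positive:
            est = inhibition_duration(self.spikes, self.stim_times)
            if est is not None:
                dur, sd = est[0], est[1]
        polarity = "none"
        if self.measure_polarity and self.recording is not None:
            try:
                polarity = evoked_current_polarity(
                    self.recording, self.stim_times, spikes=self.spikes)
            except ParameterError as exc:
                logger.warning("polarity measurement skipped: %s", exc)
        n_trials = self.spikes.n_episodes * len(self.stim_times)
        return ClassificationResult(
            label=label, inhibition=inhib, slow=slow, fast=fast,
            inhibition_duration_s=dur, inhibition_duration_sd_s=sd,
            mean_latency_s=mean_lat, latency_class=lat_class,
            polarity=polarity, cell_id=self.spikes.cell_id,
            n_trials=n_trials, reasons=reasons)


def classify_cell(rec: Recording, **params) -> ClassificationResult:
    """One-call classification of a loose cell-attached recording."""
    if rec.mode != "LCA":
        logger.warning("classify_cell on %s-mode recording (expected LCA)",
                       rec.mode)
    if not rec.stim_times:
        raise ParameterError("recording has no stimuli to classify against")
    return ResponseClassifier(recording=rec, **params).fit()
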