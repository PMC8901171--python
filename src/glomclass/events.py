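"""Sliding-template detection of postsynaptic currents and derived timing.

The detector is the classical template-matching scheme: at every offset the
template is optimally scaled and offset against the trace by least squares
and the detection criterion is scale / (standard error of the fit),
``SE = sqrt(SSE / (N - 1))``.  Local maxima of the criterion above a
threshold become events.  Also provided: the 5 %-of-peak onset measure,
response latency, and the evoked-barrage duration rule (return of the event
frequency to baseline + 2 SD for at least five consecutive 20-ms bins).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal

from .recording import ParameterError, Recording, Segment
from .synth import psc_kernel

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EventList:
    """Detected PSC events, per episode."""

    times: list                 # per-episode arrays of onset times (s)
    amplitudes: list            # per-episode signed fitted amplitudes (pA)
    criteria: list              # per-episode detection criterion values
    polarity: str = "inward"
    template: dict | None = None
    threshold: float | None = None
    episode_duration: float | None = None
    cell_id: str = "cell"

    @property
    def n_episodes(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(sum(len(t) for t in self.times))


@dataclasses.dataclass
class BarrageStats:
    """Evoked-barrage duration statistics from a cumulative event PSTH."""

    baseline_rate: float        # Hz
    baseline_sd: float          # Hz
    threshold_rate: float       # Hz (= baseline + k_sd * SD)
    duration: float             # s from stimulus to start of qualifying run
    first_event_latency: float | None
    run_start_bin: int | None
    censored: bool = False
    n_trials: int = 0


def make_template(rise: float, decay: float, length: float,
                  sampling_rate: float, polarity: str = "inward") -> np.ndarray:
    """Unit-peak single-exponential-decay PSC template, signed by polarity."""
    if length < 3.0 * decay:
        logger.warning("template length %.3g s < 3x decay %.3g s", length, decay)
    n = int(round(length * sampling_rate))
    if n < 4:
        raise ParameterError("template too short")
    t = np.arange(n) / sampling_rate
    kern = psc_kernel(t, rise, decay, decay, 1.0)
    return -kern if polarity == "inward" else kern


def sliding_criterion(trace: np.ndarray, template: np.ndarray):
    """Vectorised optimal scale + offset fit at every template offset.

    Returns (scale, criterion) arrays of length ``len(trace) - len(template)
    + 1``.  Adding a constant to the trace leaves the criterion unchanged
    (the offset term absorbs it) and scaling the trace leaves the criterion
    unchanged while the fitted scale is linear in the trace.
    """
    y = np.asarray(trace, dtype=float)
    T = np.asarray(template, dtype=float)
    L = len(T)
    if L > len(y):
        raise ParameterError("template longer than episode")
    ones = np.ones(L)
    Sy = np.convolve(y, ones, mode="valid")
    Syy = np.convolve(y * y, ones, mode="valid")
    Syt = np.correlate(y, T, mode="valid")
    St, Stt = T.sum(), (T * T).sum()
    denom = Stt - St * St / L
    s = (Syt - Sy * St / L) / denom
    c = (Sy - s * St) / L
    sse = (Syy + s * s * Stt + L * c * c
           - 2.0 * s * Syt - 2.0 * c * Sy + 2.0 * s * c * St)
    # guard against catastrophic cancellation on (near-)perfect fits
    floor = (1e-12 * max(1.0, np.abs(y).max())) ** 2 * L
    sse = np.clip(sse, floor, None)
    crit = s / np.sqrt(sse / (L - 1))
    return s, crit


def detect_events(rec: Recording, rise: float = 0.0005, decay: float = 0.005,
                  length: float | None = None, polarity: str = "inward",
                  criterion_threshold: float = 3.5) -> EventList:
    """Detect PSCs by sliding-template matching.

    Events are local maxima of the detection criterion above
    ``criterion_threshold``; detections within one rise time keep only the
    larger criterion.  A small prominence requirement (threshold / 2)
    rejects the flat criterion shoulder that trails each event on
    noise-free data.  Event time is the template (event) onset; amplitude
    is the signed fitted scale.
    """
    if rec.mode != "VC":
        logger.warning("detect_events on %s-mode recording (expected VC)",
                       rec.mode)
    fs = rec.sampling_rate
    length = 3.5 * decay + rise if length is None else length
    T = make_template(rise, decay, length, fs, polarity)
    sign = -1.0 if polarity == "inward" else 1.0
    dist = max(1, int(round(rise * fs)))
    times, amps, crits = [], [], []
    for ep in range(rec.n_episodes):
        s, crit = sliding_criterion(rec.traces[ep], T)
        idx, _ = signal.find_peaks(crit, height=criterion_threshold,
                                   distance=dist,
                                   prominence=criterion_threshold / 2.0)
        times.append(idx / fs)
        amps.append(sign * s[idx])
        crits.append(crit[idx])
    return EventList(times=times, amplitudes=amps, criteria=crits,
                     polarity=polarity,
                     template={"rise_s": rise, "decay_s": decay,
                               "length_s": length},
                     threshold=criterion_threshold,
                     episode_duration=rec.episode_duration,
                     cell_id=rec.cell_id)


# ---------------------------------------------------------------------------
# onset / latency
# ---------------------------------------------------------------------------

def onset_at_5pct(avg: Segment, baseline_window: float = 0.01,
                  search_window: tuple | None = None) -> float | None:
    """Onset of an averaged evoked response at 5 % of its first peak.

    Baseline is the mean of the ``baseline_window`` seconds preceding the
    stimulus.  The first post-stimulus local extremum with
    |value - baseline| > 5x baseline SD is the peak; the onset is the last
    time before it at which |response - baseline| crosses 5 % of the peak
    deflection, linearly interpolated between samples.  Returns None when no
    peak is detectable.
    """
    t, y = avg.times, avg.trace
    pre = (t >= -baseline_window) & (t < 0)
    if not pre.any():
        raise ParameterError("segment lacks pre-stimulus baseline")
    base = y[pre].mean()
    sd = y[pre].std(ddof=1) if pre.sum() > 1 else 0.0
    lo, hi = search_window if search_window is not None else (0.0, t[-1])
    post = (t >= lo) & (t <= hi)
    dev = np.abs(y - base)
    post_idx = np.nonzero(post)[0]
    if len(post_idx) < 3:
        return None
    rel = dev[post_idx]
    peaks, _ = signal.find_peaks(rel, height=5.0 * sd if sd > 0 else 0.0)
    if len(peaks) == 0:
        # monotone within the window: accept the end extremum if clearly
        # above noise, otherwise undetectable
        j = int(np.argmax(rel))
        if rel[j] <= 5.0 * sd or rel[j] == 0.0:
            return None
        peaks = np.array([j])
    p = post_idx[peaks[0]]
    thr = 0.05 * dev[p]
    j = p
    while j > 0 and dev[j - 1] >= thr and t[j - 1] >= 0:
        j -= 1
    lo_i = max(j - 1, 0)
    if dev[lo_i] >= thr:  # crossing not bracketed (e.g. starts above 5 %)
        return float(t[lo_i])
    frac = (thr - dev[lo_i]) / (dev[lo_i + 1] - dev[lo_i])
    return float(t[lo_i] + frac * (t[lo_i + 1] - t[lo_i]))


def response_latency(stim_artifact_time: float, onset: float) -> float:
    """Latency = onset - artifact time; onset must not precede the artifact."""
    if onset < stim_artifact_time - 1e-12:
        raise ParameterError("onset earlier than stimulation artifact "
                             "(alignment bug)")
    return onset - stim_artifact_time


# ---------------------------------------------------------------------------
# barrage duration
# ---------------------------------------------------------------------------

def barrage_duration(events, stim_times, episode_duration: float | None = None,
                     bin_size: float = 0.02, n_baseline_bins: int = 25,
                     k_sd: float = 2.0, run_length: int = 5) -> BarrageStats:
    """Duration of an evoked event barrage from a cumulative PSTH.

    Event frequencies per ``bin_size`` bin are accumulated across all
    (episode x stimulus) trials.  Baseline mean and SD (n-1 denominator)
    come from the ``n_baseline_bins`` pre-stimulus bins; the duration is the
    time from the stimulus to the start of the first run of at least
    ``run_length`` consecutive post-stimulus bins whose frequency is
    <= baseline + ``k_sd`` * SD.  If no run qualifies the duration is the
    full post-stimulus window, flagged censored.

    ``events`` may be an :class:`EventList` or a plain list of per-episode
    event-time arrays (then ``episode_duration`` is required).
    """
    if isinstance(events, EventList):
        trains = events.times
        episode_duration = events.episode_duration
    else:
        trains = [np.asarray(t, dtype=float) for t in events]
        if episode_duration is None:
            raise ParameterError("episode_duration required for raw trains")
    pre_span = n_baseline_bins * bin_size
    post_bins = min(int(np.floor((episode_duration - s) / bin_size + 1e-9))
                    for s in stim_times)
    for s in stim_times:
        if s < pre_span - 1e-9:
            raise ParameterError(
                f"stimulus at {s} s leaves fewer than {n_baseline_bins} "
                "pre-stimulus bins")
    if post_bins < 1:
        raise ParameterError("no post-stimulus bins available")
    n_bins = n_baseline_bins + post_bins
    counts = np.zeros(n_bins, dtype=int)
    n_trials = 0
    first_lat = []
    for train in trains:
        for s in stim_times:
            rel = train - s
            idx = np.floor(rel / bin_size + 1e-9).astype(int) + n_baseline_bins
            ok = (idx >= 0) & (idx < n_bins)
            np.add.at(counts, idx[ok], 1)
            post = rel[rel >= 0]
            if len(post):
                first_lat.append(post.min())
            n_trials += 1
    freq = counts / (n_trials * bin_size)
    base = freq[:n_baseline_bins]
    base_mean = float(base.mean())
    base_sd = float(base.std(ddof=1))
    thr = base_mean + k_sd * base_sd
    if np.isnan(thr):  # k_sd = inf with SD exactly 0
        thr = np.inf if np.isposinf(k_sd) else thr
    below = freq[n_baseline_bins:] <= thr + 1e-12
    run_start = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= run_length:
            run_start = i - run_length + 1
            break
    if run_start is None:
        censored = True
        duration = post_bins * bin_size
    else:
        censored = False
        duration = run_start * bin_size
    return BarrageStats(
        baseline_rate=base_mean, baseline_sd=base_sd, threshold_rate=thr,
        duration=float(duration),
        first_event_latency=float(np.mean(first_lat)) if first_lat else None,
        run_start_bin=run_start, censored=censored, n_trials=n_trials)
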