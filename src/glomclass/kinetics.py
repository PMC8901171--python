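"""Evoked-current averaging and exponential decay kinetics.

The decay of an averaged evoked postsynaptic current is fitted, with time
t = 0 at the peak of the current, by

    I(t) = A1 exp(-t / tau1)                       (one component), or
    I(t) = A1 exp(-t / tau1) + A2 exp(-t / tau2)   (two components),

and summarised by the amplitude-weighted decay time constant

    tau_w = (tau1 A1 + tau2 A2) / (A1 + A2).

:class:`ExponentialDecayModel` follows the model/results idiom: build the
model from an averaged response (or any decay trace), call ``fit()``, and
read estimates, diagnostics and ``summary()`` off the returned
:class:`DecayFit`.  Mono- vs bi-exponential selection uses the small-sample
corrected Akaike information criterion.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import optimize

from .recording import ParameterError, Recording, Segment, segment_by_stimulus

logger = logging.getLogger(__name__)

TAU_BOUNDS = (1e-4, 10.0)  # s


class FitError(RuntimeError):
    """Decay fit failed to converge from every start."""


@dataclasses.dataclass
class AveragedResponse:
    """Baseline-subtracted pointwise mean of stimulus-aligned sweeps."""

    times: np.ndarray           # s, t = 0 at stimulus onset
    values: np.ndarray          # pA
    n_trials: int
    baseline_sd: float = 0.0    # SD of the pre-stimulus averaged trace

    def as_segment(self) -> Segment:
        return Segment(trace=self.values, times=self.times, episode=-1,
                       stim_time=0.0)


def average_evoked(rec: Recording, stim_times=None, pre_s: float = 0.01,
                   post_s: float = 1.0) -> AveragedResponse:
    """Average aligned sweeps and subtract the 10-ms pre-stimulus baseline."""
    if stim_times is not None and list(stim_times) != list(rec.stim_times):
        rec = Recording(rec.traces, rec.sampling_rate, rec.mode,
                        stim_times=list(stim_times), cell_id=rec.cell_id,
                        provenance=rec.provenance, seed=rec.seed)
    segs = segment_by_stimulus(rec, pre_s, post_s)
    if len(segs) < 2:
        raise ParameterError("average_evoked needs at least 2 trials")
    mean = np.mean([s.trace for s in segs], axis=0)
    times = segs[0].times
    pre = times < 0
    base = mean[pre].mean() if pre.any() else 0.0
    sd = mean[pre].std(ddof=1) if pre.sum() > 1 else 0.0
    return AveragedResponse(times=times, values=mean - base,
                            n_trials=len(segs), baseline_sd=sd)


def peak_amplitude(avg: AveragedResponse, polarity: str = "auto",
                   window: tuple | None = None):
    """Signed extremum of the averaged response in the post-stimulus window.

    Returns ``(amplitude_pA, t0_s, detectable)``; ``detectable`` is False
    when the extremum does not exceed 5x the baseline SD of the average.
    """
    lo, hi = window if window is not None else (0.0, avg.times[-1])
    sel = (avg.times >= lo) & (avg.times <= hi)
    if not sel.any():
        raise ParameterError("empty peak-search window")
    t, y = avg.times[sel], avg.values[sel]
    if polarity == "inward":
        i = int(np.argmin(y))
    elif polarity == "outward":
        i = int(np.argmax(y))
    elif polarity == "auto":
        i = int(np.argmax(np.abs(y)))
    else:
        raise ParameterError("polarity must be inward, outward or auto")
    amp = float(y[i])
    detectable = abs(amp) > 5.0 * avg.baseline_sd and amp != 0.0
    if not detectable:
        logger.warning("peak amplitude %.3g pA not detectable above baseline",
                       amp)
        amp = amp if abs(amp) > 5.0 * avg.baseline_sd else 0.0
    return amp, float(t[i]), detectable


@dataclasses.dataclass
class DecayFit:
    """Results of an exponential decay fit (amplitudes pA, taus s)."""

    n_components: int
    A1: float
    tau1: float
    A2: float
    tau2: float
    t0: float                   # peak time, s (stimulus-relative)
    rss: float
    aicc: float
    n_obs: int
    sign: float                 # polarity of the fitted current
    converged: bool = True
    at_bounds: bool = False

    @property
    def tau_w(self) -> float:
        """Amplitude-weighted decay time constant (s)."""
        return weighted_tau(self.A1, self.tau1, self.A2, self.tau2)

    def predict(self, t) -> np.ndarray:
        """Fitted decay (signed, pA) at times t relative to the peak."""
        t = np.asarray(t, dtype=float)
        y = self.A1 * np.exp(-t / self.tau1)
        if self.n_components == 2:
            y = y + self.A2 * np.exp(-t / self.tau2)
        return self.sign * y

    def summary(self) -> str:
        lines = [
            "Exponential decay fit",
            "=" * 42,
            f"components        {self.n_components}",
            f"A1                {self.sign * self.A1:10.3f} pA",
            f"tau1              {self.tau1 * 1e3:10.3f} ms",
        ]
        if self.n_components == 2:
            lines += [
                f"A2                {self.sign * self.A2:10.3f} pA",
                f"tau2              {self.tau2 * 1e3:10.3f} ms",
            ]
        lines += [
            f"tau_w             {self.tau_w * 1e3:10.3f} ms",
            f"RSS               {self.rss:10.4g} pA^2",
            f"AICc              {self.aicc:10.2f}",
            f"n_obs             {self.n_obs:10d}",
        ]
        return "\n".join(lines)


def weighted_tau(A1: float, tau1: float, A2: float = 0.0,
                 tau2: float = 0.0) -> float:
    """tau_w = (tau1 A1 + tau2 A2) / (A1 + A2); mono limit is tau1."""
    if A1 < 0 or A2 < 0:
        raise ParameterError("amplitude weights must be >= 0")
    if A1 + A2 == 0:
        raise ParameterError("A1 + A2 must be > 0")
    return (tau1 * A1 + tau2 * A2) / (A1 + A2)


def _aicc(rss: float, n: int, k: int) -> float:
    # k counts the mean-model parameters + 1 for the residual variance
    k = k + 1
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class ExponentialDecayModel:
    """Mono- or bi-exponential decay model for an averaged evoked current.

    Parameters
    ----------
    avg : AveragedResponse | Segment | (times, values)
        Stimulus-aligned averaged trace.
    t0 : float, optional
        Peak time (s).  Defaults to the extremum of the post-stimulus trace.
    n_components : {1, 2}
    polarity : {"auto", "inward", "outward"}

    ``fit()`` performs bounded least squares from multiple starts (tau
    starts at {0.2, 1, 5}x a crude 1/e estimate, tau in [0.1 ms, 10 s]).
    """

    def __init__(self, avg, t0: float | None = None, n_components: int = 2,
                 polarity: str = "auto", peak_smooth: float = 0.0):
        if isinstance(avg, AveragedResponse):
            times, values = avg.times, avg.values
        elif isinstance(avg, Segment):
            times, values = avg.times, avg.trace
        else:
            times, values = avg
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if n_components not in (1, 2):
            raise ParameterError("n_components must be 1 or 2")
        if t0 is None:
            post = times >= 0
            if not post.any():
                raise ParameterError("no post-stimulus samples")
            loc = values
            if peak_smooth > 0:
                # locate the peak on a lightly smoothed copy (noise robust);
                # the fit itself always runs on the raw samples
                dt = float(np.median(np.diff(times)))
                w = max(int(round(peak_smooth / dt)), 1)
                loc = np.convolve(values, np.ones(w) / w, mode="same")
            t0 = float(times[post][np.argmax(np.abs(loc[post]))])
        sel = times >= t0
        self.t = times[sel] - t0
        y = values[sel]
        if len(y) < 5:
            raise ParameterError("too few samples after the peak")
        if np.max(np.abs(y)) == 0:
            raise ParameterError("degenerate all-zero decay")
        if polarity == "auto":
            self.sign = 1.0 if y[0] >= 0 else -1.0
        else:
            self.sign = -1.0 if polarity == "inward" else 1.0
        self.y = self.sign * y
        self.t0 = t0
        self.n_components = n_components

    # -- initialisation ---------------------------------------------------
    def _crude_tau(self) -> float:
        a0 = self.y[0]
        below = np.nonzero(self.y < a0 / np.e)[0]
        tau = self.t[below[0]] if len(below) else self.t[-1] / 2.0
        return float(np.clip(tau, *TAU_BOUNDS))

    def _starts(self):
        a0 = max(self.y[0], 1e-12)
        tau = self._crude_tau()
        if self.n_components == 1:
            for f in (0.2, 1.0, 5.0):
                yield [a0, np.clip(f * tau, *TAU_BOUNDS)]
        else:
            for fa, fb in ((0.2, 1.0), (0.2, 5.0), (1.0, 5.0), (0.5, 10.0)):
                yield [0.5 * a0, np.clip(fa * tau, *TAU_BOUNDS),
                       0.5 * a0, np.clip(fb * tau, *TAU_BOUNDS)]

    def _model(self, t, *p):
        if self.n_components == 1:
            return p[0] * np.exp(-t / p[1])
        return p[0] * np.exp(-t / p[1]) + p[2] * np.exp(-t / p[3])

    def fit(self, duration: float | None = None,
            delay: float = 0.0) -> DecayFit:
        """Fit the decay.

        ``duration`` limits the fit window after the peak; ``delay``
        excludes the first ``delay`` seconds after the peak from the fit
        (the rising phase still contaminates samples right at the peak)
        while keeping t = 0 at the peak, so amplitudes remain
        peak-referenced.
        """
        t, y = self.t, self.y
        if duration is not None or delay > 0:
            sel = (t >= delay) & (t <= (duration if duration is not None
                                        else np.inf))
            t, y = t[sel], y[sel]
            if len(t) < 5:
                raise ParameterError("fit window too short")
        if t[-1] < 5.0 * self._crude_tau():
            logger.warning("fit window %.3g s < 5x initial tau estimate",
                           t[-1])
        if self.n_components == 1:
            lo = [0.0, TAU_BOUNDS[0]]
            hi = [np.inf, TAU_BOUNDS[1]]
        else:
            lo = [0.0, TAU_BOUNDS[0]] * 2
            hi = [np.inf, TAU_BOUNDS[1]] * 2
        best, best_rss = None, np.inf
        diagnostics = []
        for p0 in self._starts():
            try:
                popt, _ = optimize.curve_fit(
                    self._model, t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
            except (RuntimeError, ValueError) as exc:
                diagnostics.append(str(exc))
                continue
            rss = float(np.sum((y - self._model(t, *popt)) ** 2))
            if rss < best_rss:
                best, best_rss = popt, rss
        if best is None:
            raise FitError("no start converged: " + "; ".join(diagnostics))
        if self.n_components == 1:
            a1, tau1, a2, tau2 = float(best[0]), float(best[1]), 0.0, 0.0
        else:
            a1, tau1, a2, tau2 = map(float, best)
            if tau1 > tau2:  # order components fast -> slow
                a1, tau1, a2, tau2 = a2, tau2, a1, tau1
        taus = [tau1] + ([tau2] if self.n_components == 2 else [])
        at_bounds = any(
            np.isclose(x, TAU_BOUNDS[0]) or np.isclose(x, TAU_BOUNDS[1])
            for x in taus)
        if at_bounds:
            logger.warning("fitted tau at parameter bound: %s", taus)
        k = 2 * self.n_components
        return DecayFit(n_components=self.n_components, A1=a1, tau1=tau1,
                        A2=a2, tau2=tau2, t0=self.t0, rss=best_rss,
                        aicc=_aicc(best_rss, len(t), k), n_obs=len(t),
                        sign=self.sign, at_bounds=at_bounds)


def fit_decay(avg, t0: float | None = None, n_components: int | None = None,
              polarity: str = "auto", duration: float | None = None,
              peak_smooth: float = 0.0, delay: float = 0.0) -> DecayFit:
    """Fit the decay of an averaged response.

    ``n_components=None`` fits both a mono- and a bi-exponential model and
    returns the one preferred by :func:`select_decay_model`.
    """
    kw = dict(t0=t0, polarity=polarity, peak_smooth=peak_smooth)
    if n_components in (1, 2):
        return ExponentialDecayModel(avg, n_components=n_components,
                                     **kw).fit(duration, delay=delay)
    f1 = ExponentialDecayModel(avg, n_components=1, **kw).fit(duration,
                                                              delay=delay)
    try:
        f2 = ExponentialDecayModel(avg, n_components=2, **kw).fit(duration,
                                                                  delay=delay)
    except FitError:
        return f1
    return select_decay_model(f1, f2)


def select_decay_model(fit1: DecayFit, fit2: DecayFit) -> DecayFit:
    """Pick the fit with the lower AICc; ties go to fewer components."""
    d = fit2.aicc - fit1.aicc
    chosen = fit2 if d < 0 else fit1
    logger.debug("model selection: delta AICc (bi - mono) = %.3f -> %d "
                 "component(s)", d, chosen.n_components)
    return chosen
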