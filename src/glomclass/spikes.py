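"""Spike detection on loose cell-attached traces and stimulus-aligned PSTHs.

In loose cell-attached (LCA) mode action potentials appear as fast biphasic
capacitive current deflections whose sign depends on seal geometry, so
detection is polarity-agnostic: a spike is a local extremum of |trace| above
an amplitude threshold, with an absolute refractory period enforced
earlier-wins.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal

from .recording import ParameterError, Recording

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SpikeTrainSet:
    """Per-episode ordered spike times (s, relative to episode start)."""

    trains: list
    episode_duration: float
    threshold: float | None = None
    refractory: float = 0.002
    cell_id: str = "cell"

    def __post_init__(self):
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for ep, t in enumerate(self.trains):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ParameterError(f"episode {ep}: spike times not increasing")
            if len(t) and (t[0] < 0 or t[-1] >= self.episode_duration + 1e-12):
                raise ParameterError(f"episode {ep}: spike outside episode")

    @property
    def n_episodes(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains))


@dataclasses.dataclass
class Psth:
    """Peri-stimulus time histogram: counts per bin summed over trials."""

    bin_size: float
    window: tuple
    counts: np.ndarray
    n_trials: int

    @property
    def edges(self) -> np.ndarray:
        lo, hi = self.window
        return lo + self.bin_size * np.arange(len(self.counts) + 1)

    @property
    def rate(self) -> np.ndarray:
        """Mean firing rate per bin in Hz (counts / (n_trials * bin))."""
        return self.counts / (self.n_trials * self.bin_size)

    def plot(self, ax=None):  # pragma: no cover - thin display helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.edges[:-1], self.rate, width=self.bin_size, align="edge",
               color="0.3")
        ax.axvline(0.0, color="tab:blue", lw=1)
        ax.set_xlabel("time from stimulus (s)")
        ax.set_ylabel("rate (Hz)")
        return ax


def noise_sigma(trace: np.ndarray) -> float:
    """Robust noise SD via the scaled median absolute deviation."""
    med = np.median(trace)
    return 1.4826 * np.median(np.abs(trace - med))


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Drop events closer than ``refractory`` to the last accepted one."""
    if len(times) < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def detect_spikes(rec: Recording, threshold="auto", refractory: float = 0.002
                  ) -> SpikeTrainSet:
    """Amplitude-threshold spike detection.

    A spike is recorded at each local extremum of |trace| with amplitude
    >= threshold; extrema closer than ``refractory`` to the previously
    accepted spike are discarded (earlier wins).  ``threshold='auto'`` uses
    6x a median-absolute-deviation noise estimate per episode.
    """
    if rec.mode != "LCA":
        logger.warning("detect_spikes on %s-mode recording (expected LCA)",
                       rec.mode)
    fs = rec.sampling_rate
    trains = []
    thr_used = None
    for ep in range(rec.n_episodes):
        tr = rec.traces[ep]
        sigma = noise_sigma(tr)
        thr = 6.0 * sigma if threshold == "auto" else float(threshold)
        if thr <= 0:
            raise ParameterError("threshold must be > 0")
        if thr <= 3.0 * sigma:
            logger.warning(
                "episode %d: threshold %.3g pA <= 3x noise SD (%.3g pA); "
                "likely false positives", ep, thr, 3.0 * sigma)
        idx, _ = signal.find_peaks(np.abs(tr), height=thr)
        times = _enforce_refractory(idx / fs, refractory)
        trains.append(times)
        thr_used = thr
    return SpikeTrainSet(trains=trains, episode_duration=rec.episode_duration,
                         threshold=thr_used, refractory=refractory,
                         cell_id=rec.cell_id)


def build_psth(spikes: SpikeTrainSet, stim_times, bin_size: float,
               window: tuple) -> Psth:
    """Cumulative PSTH over all (episode x stimulus) trials.

    Bins are half-open [lo, lo+bin); a bin edge must fall exactly at t = 0
    and the bin size must divide the window evenly.
    """
    lo, hi = window
    n_bins_f = (hi - lo) / bin_size
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ParameterError("bin_size must divide the window evenly")
    if abs(lo / bin_size - round(lo / bin_size)) > 1e-9:
        raise ParameterError("a bin edge must fall exactly at t = 0")
    counts = np.zeros(n_bins, dtype=int)
    n_trials = 0
    for stim in stim_times:
        for train in spikes.trains:
            rel = train - stim
            idx = np.floor((rel - lo) / bin_size + 1e-9).astype(int)
            ok = (idx >= 0) & (idx < n_bins) & (rel - lo >= -1e-12)
            np.add.at(counts, idx[ok], 1)
            n_trials += 1
    return Psth(bin_size=bin_size, window=(lo, hi), counts=counts,
                n_trials=n_trials)


def rate_per_episode(spikes: SpikeTrainSet) -> np.ndarray:
    """Average firing rate per episode in Hz."""
    return np.array([len(t) / spikes.episode_duration for t in spikes.trains])


def rate_in_window(spikes: SpikeTrainSet, stim_times, window: tuple):
    """Per-trial spike counts and rates in a stimulus-relative window.

    The window [w_lo, w_hi) is half-open; trials whose window falls outside
    the episode are skipped with a warning.  Trial order (episode-major,
    stimulus within episode) is preserved for paired testing.

    Returns
    -------
    counts : ndarray of int
    rates : ndarray of float, Hz
    """
    w_lo, w_hi = window
    if not w_hi > w_lo:
        raise ParameterError("window must have w_hi > w_lo")
    counts = []
    skipped = 0
    for ep, train in enumerate(spikes.trains):
        for stim in stim_times:
            if stim + w_lo < -1e-12 or stim + w_hi > spikes.episode_duration + 1e-12:
                skipped += 1
                continue
            rel = train - stim
            counts.append(int(np.sum((rel >= w_lo) & (rel < w_hi))))
    if skipped:
        logger.warning("rate_in_window: skipped %d trial(s) outside episode",
                       skipped)
    if not counts:
        raise ParameterError("no usable trials for window %s" % (window,))
    counts = np.asarray(counts)
    return counts, counts / (w_hi - w_lo)
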