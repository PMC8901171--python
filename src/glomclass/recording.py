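"""Episodic-sweep data model and plain-text on-disk format.

A recording is a stack of equally long episodes (sweeps) of current samples
in pA, digitised at a fixed rate, together with per-episode stimulus times.
Traces are stored as one row-per-episode CSV; all metadata lives in a JSON
sidecar so fixtures stay diffable.

Conventions used throughout the package: time is in seconds, t = 0 at
episode start; sample i covers the half-open interval [i/fs, (i+1)/fs);
stimulus-relative time has t = 0 at stimulus (flash) onset and a spike or
event exactly at a window edge belongs to the later window.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MODES = ("LCA", "VC", "CC")

TRACES_SUFFIX = ".traces.csv"
META_SUFFIX = ".meta.json"


class FormatError(ValueError):
    """On-disk files are missing, malformed, or inconsistent."""


class ValidationError(ValueError):
    """An in-memory object violates its invariants."""


class ParameterError(ValueError):
    """A parameter value is outside its admissible range."""


@dataclasses.dataclass
class Recording:
    """An episodic sweep set.

    Parameters
    ----------
    traces : ndarray, shape (n_episodes, n_samples)
        Current samples in pA.
    sampling_rate : float
        Digitisation rate in Hz.
    mode : {"LCA", "VC", "CC"}
        Loose cell-attached, voltage clamp, or current clamp.
    stim_times : sequence of float
        Stimulus (flash) onset times in seconds relative to episode start;
        the same stimuli apply to every episode. May be empty.
    holding_potential : float, optional
        Holding potential in mV (voltage clamp only).
    cell_id : str
        Opaque cell label.
    provenance : {"synthetic", "imported"}
    seed : int, optional
        Generator seed when synthetic.
    """

    traces: np.ndarray
    sampling_rate: float
    mode: str
    stim_times: list = dataclasses.field(default_factory=list)
    holding_potential: float | None = None
    cell_id: str = "cell"
    provenance: str = "imported"
    seed: int | None = None

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim == 1:
            self.traces = self.traces[None, :]
        self.stim_times = [float(t) for t in self.stim_times]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.traces.ndim != 2:
            raise ValidationError("traces must be a 2-D (episodes x samples) array")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        bad = ~np.isfinite(self.traces)
        if bad.any():
            episodes = sorted(set(np.nonzero(bad)[0].tolist()))
            raise ValidationError(
                f"non-finite samples in episode(s) {episodes}"
            )
        dur = self.episode_duration
        for t in self.stim_times:
            if not (0.0 <= t < dur):
                raise ValidationError(
                    f"stimulus time {t} s outside episode [0, {dur}) s"
                )

    # -- derived geometry -------------------------------------------------
    @property
    def n_episodes(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def episode_duration(self) -> float:
        """Episode length in seconds (= n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Per-sample times (s); sample i is at i / sampling_rate."""
        return np.arange(self.n_samples) / self.sampling_rate

    def allclose(self, other: "Recording", rtol: float = 1e-5) -> bool:
        """Sample-for-sample equality to ~6 significant digits plus metadata."""
        return (
            self.traces.shape == other.traces.shape
            and np.allclose(self.traces, other.traces, rtol=rtol, atol=1e-12)
            and np.isclose(self.sampling_rate, other.sampling_rate)
            and self.mode == other.mode
            and np.allclose(self.stim_times, other.stim_times)
            and self.cell_id == other.cell_id
        )


@dataclasses.dataclass
class Segment:
    """A stimulus-aligned slice of one episode (t = 0 at stimulus onset)."""

    trace: np.ndarray
    times: np.ndarray
    episode: int
    stim_time: float

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def _base_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (TRACES_SUFFIX, META_SUFFIX):
        if name.endswith(suf):
            return p.parent / name[: -len(suf)]
    return p


def write_recording(rec: Recording, path) -> Path:
    """Write ``<base>.traces.csv`` + ``<base>.meta.json``.

    ``path`` is the base locator (directory/name without suffix).  Output is
    deterministic: identical recordings produce byte-identical files.
    Numeric fidelity is 6 significant digits.
    """
    base = _base_path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    try:
        np.savetxt(base.with_name(base.name + TRACES_SUFFIX), rec.traces,
                   fmt="%.6g", delimiter=",")
        meta = {
            "sampling_rate_hz": rec.sampling_rate,
            "mode": rec.mode,
            "stim_times_s": list(rec.stim_times),
            "holding_potential_mv": rec.holding_potential,
            "cell_id": rec.cell_id,
            "provenance": rec.provenance,
            "seed": rec.seed,
            "n_samples": rec.n_samples,
            "n_episodes": rec.n_episodes,
        }
        with open(base.with_name(base.name + META_SUFFIX), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot write recording at {base}: {exc}") from exc
    return base


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``path`` may be the base locator or either of the two component files.
    """
    base = _base_path(path)
    traces_path = base.with_name(base.name + TRACES_SUFFIX)
    meta_path = base.with_name(base.name + META_SUFFIX)
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    if not traces_path.exists():
        raise FormatError(f"missing trace matrix {traces_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    traces = np.loadtxt(traces_path, delimiter=",", ndmin=2)
    if "n_samples" in meta and traces.shape[1] != meta["n_samples"]:
        raise FormatError(
            f"sidecar declares {meta['n_samples']} samples, "
            f"CSV has {traces.shape[1]} columns"
        )
    if "n_episodes" in meta and traces.shape[0] != meta["n_episodes"]:
        raise FormatError(
            f"sidecar declares {meta['n_episodes']} episodes, "
            f"CSV has {traces.shape[0]} rows"
        )
    return Recording(
        traces=traces,
        sampling_rate=meta["sampling_rate_hz"],
        mode=meta["mode"],
        stim_times=meta.get("stim_times_s") or [],
        holding_potential=meta.get("holding_potential_mv"),
        cell_id=meta.get("cell_id", "cell"),
        provenance=meta.get("provenance", "imported"),
        seed=meta.get("seed"),
    )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def stim_sample_index(stim_time: float, sampling_rate: float) -> int:
    """First sample index belonging to the post-stimulus half-open window."""
    return int(np.ceil(stim_time * sampling_rate - 1e-9))


def segment_by_stimulus(rec: Recording, pre_s: float, post_s: float) -> list:
    """Cut one aligned segment per (episode, stimulus) pair.

    The window is [stim - pre_s, stim + post_s); stimuli whose window does
    not fit inside the episode are skipped with a warning.  Returns a list
    of :class:`Segment` with times relative to the stimulus.
    """
    if pre_s < 0 or post_s < 0:
        raise ParameterError("pre_s and post_s must be >= 0")
    fs = rec.sampling_rate
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    segments = []
    skipped = 0
    for stim in rec.stim_times:
        i0 = stim_sample_index(stim, fs)
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > rec.n_samples:
            skipped += 1
            logger.warning(
                "stimulus at %.4f s skipped: window [%.4f, %.4f) s exceeds episode",
                stim, stim - pre_s, stim + post_s,
            )
            continue
        times = np.arange(lo, hi) / fs - stim
        for ep in range(rec.n_episodes):
            segments.append(
                Segment(trace=rec.traces[ep, lo:hi], times=times,
                        episode=ep, stim_time=stim)
            )
    if not rec.stim_times:
        logger.warning("recording %s has no stimuli; returning no segments",
                       rec.cell_id)
    logger.debug("segment_by_stimulus: %d segments (%d stimuli skipped)",
                 len(segments), skipped)
    return segments
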