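"""Ground-truthed synthetic electrophysiology recordings.

Two generators emulate the statistical structure of the recorded data:

* :func:`simulate_lca` — loose cell-attached sweeps: baseline firing as an
  inhomogeneous Poisson process (2 ms absolute refractory, thinning), a
  multiplicative flash-locked inhibition window, a slow multiplicative
  muscarinic rate kernel (difference of exponentials), optional short-latency
  evoked spikes, a small stimulus-locked capacitive deflection, biphasic
  spike waveforms and Gaussian noise.
* :func:`simulate_vc` — voltage-clamp sweeps: Poisson trains of postsynaptic
  currents (PSCs) with bi-exponential decays and lognormal amplitudes, plus
  either a single evoked PSC at fixed latency or an evoked barrage whose
  event rate decays exponentially after the stimulus.

Every generator returns the exact event/spike times it rendered
(:class:`GroundTruth`), and all randomness flows through a single seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
from scipy import optimize

from .recording import ParameterError, Recording, write_recording
from .spikes import SpikeTrainSet, _enforce_refractory

DEFAULT_SAMPLING_RATE = 20_000.0  # Hz; matches the acquisition rate emulated
MAX_EXPECTED_SPIKES = 10_000     # runaway-rate guard, per episode

#: Class labels understood by the classifier and the cohort generator.
COHORT_LABELS = (
    "nonresponsive",
    "inhibition",
    "brief_excitation",
    "biphasic_inhibition_muscarinic",
    "muscarinic_only",
)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LcaSimConfig:
    """Loose cell-attached simulation parameters (times s, amplitudes pA).

    Defaults emulate a biphasic cell: low irregular baseline firing, full
    flash-locked suppression for 0.39 s and a threefold slow muscarinic
    excitation peaking under a second after the flash and decaying over
    seconds.
    """

    baseline_rate: float = 2.2          # Hz
    stim_times: tuple = (0.5,)          # s within each episode
    inhibition_duration: float = 0.39   # s; 0 disables
    inhibition_depth: float = 1.0       # fraction of rate suppressed
    musc_gain: float = 1.0              # multiplicative peak; 1 disables
    musc_rise: float = 0.3              # s
    musc_decay: float = 3.0             # s
    evoked_spike_prob: float = 0.0      # per flash
    evoked_latency_mean: float = 0.0134  # s
    evoked_latency_sd: float = 0.0099    # s
    capacitive_step_pA: float = 0.0     # signed slow deflection at flash
    spike_amplitude_pA: float = 100.0
    spike_width_ms: float = 1.0
    noise_sd: float = 2.0               # pA
    n_episodes: int = 40
    episode_duration: float = 2.0       # s
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    refractory: float = 0.002           # s
    seed: int | None = None

    def validate(self) -> None:
        if self.baseline_rate < 0:
            raise ParameterError("baseline_rate must be >= 0")
        for name in ("inhibition_depth", "evoked_spike_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.musc_gain < 0:
            raise ParameterError("musc_gain must be >= 0")
        if self.musc_gain != 1.0 and not self.musc_rise < self.musc_decay:
            raise ParameterError("musc_rise must be < musc_decay")
        if self.inhibition_duration < 0:
            raise ParameterError("inhibition_duration must be >= 0")
        for t in self.stim_times:
            if not 0 <= t < self.episode_duration:
                raise ParameterError("stimulus time outside episode")
        peak_rate = self.baseline_rate * max(1.0, self.musc_gain)
        if peak_rate * self.episode_duration > MAX_EXPECTED_SPIKES:
            raise ParameterError("expected spike count per episode > 1e4")


@dataclasses.dataclass
class VcSimConfig:
    """Voltage-clamp simulation parameters (times s, amplitudes pA)."""

    spont_event_rate: float = 2.0       # Hz
    psc_amplitude_mean: float = 62.0    # pA (magnitude)
    psc_amplitude_sd: float = 40.0      # pA
    psc_polarity: str = "inward"        # inward (negative) | outward
    psc_rise: float = 0.0005            # s
    psc_tau1: float = 0.005             # s, fast decay
    psc_tau2: float = 0.005             # s, slow decay
    psc_frac_fast: float = 1.0          # A1 / (A1 + A2)
    evoked_latency: float | None = None  # s after flash; single evoked PSC
    evoked_amplitude_pA: float | None = None  # fixed amplitude; None -> drawn
    barrage_rate0: float = 0.0          # Hz; initial evoked event rate
    barrage_decay: float = 0.5          # s; rate-decay constant
    min_event_interval: float = 0.0     # s; thin closer events (earlier wins)
    noise_sd: float = 2.0               # pA
    n_episodes: int = 20
    episode_duration: float = 2.0
    stim_times: tuple = (0.5,)
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int | None = None

    def validate(self) -> None:
        if self.spont_event_rate < 0 or self.barrage_rate0 < 0:
            raise ParameterError("event rates must be >= 0")
        if not self.psc_tau1 <= self.psc_tau2:
            raise ParameterError("psc_tau1 must be <= psc_tau2")
        if not 0.0 <= self.psc_frac_fast <= 1.0:
            raise ParameterError("psc_frac_fast must be in [0, 1]")
        if self.psc_polarity not in ("inward", "outward"):
            raise ParameterError("psc_polarity must be inward or outward")
        if min(self.psc_rise, self.psc_tau1, self.psc_tau2) <= 0:
            raise ParameterError("time constants must be > 0")
        n_exp = (self.spont_event_rate * self.episode_duration
                 + self.barrage_rate0 * self.barrage_decay * len(self.stim_times))
        if n_exp > MAX_EXPECTED_SPIKES:
            raise ParameterError("expected event count per episode > 1e4")


@dataclasses.dataclass
class GroundTruth:
    """Exact per-episode event/spike times rendered into a Recording."""

    spike_times: list = dataclasses.field(default_factory=list)
    event_times: list = dataclasses.field(default_factory=list)
    event_amplitudes: list = dataclasses.field(default_factory=list)
    label: str | None = None
    config: object | None = None


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _raw_psc(t, rise, tau1, tau2, frac_fast):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = (1.0 - np.exp(-tp / rise)) * (
        frac_fast * np.exp(-tp / tau1) + (1.0 - frac_fast) * np.exp(-tp / tau2)
    )
    return out


def psc_kernel_peak_time(rise, tau1, tau2, frac_fast) -> float:
    """Time of the kernel maximum, located numerically."""
    hi = rise + 5.0 * max(tau1, tau2)
    grid = np.linspace(0.0, hi, 4001)
    i = int(np.argmax(_raw_psc(grid, rise, tau1, tau2, frac_fast)))
    lo = grid[max(i - 1, 0)]
    up = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda x: -_raw_psc(x, rise, tau1, tau2, frac_fast),
        bounds=(lo, up), method="bounded")
    return float(res.x)


def psc_kernel(t, rise, tau1, tau2, frac_fast=1.0):
    """Peak-normalised postsynaptic-current waveform.

    ``(1 - exp(-t/rise)) * (f exp(-t/tau1) + (1-f) exp(-t/tau2))`` for
    t >= 0, zero before, scaled so the maximum is 1.
    """
    if min(rise, tau1, tau2) <= 0:
        raise ParameterError("rise, tau1, tau2 must be > 0")
    if not 0.0 <= frac_fast <= 1.0:
        raise ParameterError("frac_fast must be in [0, 1]")
    t_pk = psc_kernel_peak_time(rise, tau1, tau2, frac_fast)
    peak = _raw_psc(np.array([t_pk]), rise, tau1, tau2, frac_fast)[0]
    scalar = np.isscalar(t)
    out = _raw_psc(np.atleast_1d(t), rise, tau1, tau2, frac_fast) / peak
    return float(out[0]) if scalar else out


def psc_decay_truth(rise, tau1, tau2, frac_fast):
    """Post-peak decay composition of the PSC kernel.

    Decay kinetics are measured from the peak of the current, so the
    effective amplitude weights of the two exponential components are the
    onset weights attenuated by ``exp(-t_peak / tau)``.  Returns
    ``(w1, w2, tau_w)`` with w1 + w2 = 1; this is the ground truth a decay
    fit from the peak should recover.
    """
    t_pk = psc_kernel_peak_time(rise, tau1, tau2, frac_fast)
    a1 = frac_fast * math.exp(-t_pk / tau1)
    a2 = (1.0 - frac_fast) * math.exp(-t_pk / tau2)
    w1, w2 = a1 / (a1 + a2), a2 / (a1 + a2)
    return w1, w2, w1 * tau1 + w2 * tau2


def frac_fast_for_tau_w(target_tau_w, rise, tau1, tau2):
    """Onset fast fraction whose post-peak weighted tau equals the target."""
    from scipy import optimize as _opt

    if not tau1 < target_tau_w < tau2:
        raise ParameterError("target tau_w must lie strictly between the taus")
    return float(_opt.brentq(
        lambda f: psc_decay_truth(rise, tau1, tau2, f)[2] - target_tau_w,
        1e-6, 1.0 - 1e-6))


def _musc_kernel(t, rise, decay):
    """Peak-normalised difference of exponentials (zero for t < 0)."""
    t = np.asarray(t, dtype=float)
    t_pk = math.log(decay / rise) * rise * decay / (decay - rise)
    peak = math.exp(-t_pk / decay) - math.exp(-t_pk / rise)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / decay) - np.exp(-t[pos] / rise)) / peak
    return out


def rate_profile(cfg: LcaSimConfig):
    """Instantaneous firing rate lambda(t) in Hz for one episode.

    lambda(t) = baseline * prod_stims(1 - depth * 1[in inhibition window])
    * (1 + (gain - 1) * sum_stims g(t - stim)), clipped at zero, with g the
    peak-normalised muscarinic kernel.
    """
    cfg.validate()

    def lam(t):
        t = np.asarray(t, dtype=float)
        rate = np.full(t.shape, cfg.baseline_rate)
        for s in cfg.stim_times:
            if cfg.inhibition_duration > 0 and cfg.inhibition_depth > 0:
                inside = (t >= s) & (t < s + cfg.inhibition_duration)
                rate = rate * np.where(inside, 1.0 - cfg.inhibition_depth, 1.0)
            if cfg.musc_gain != 1.0:
                rate = rate * (1.0 + (cfg.musc_gain - 1.0)
                               * _musc_kernel(t - s, cfg.musc_rise, cfg.musc_decay))
        return np.clip(rate, 0.0, None)

    return lam


# ---------------------------------------------------------------------------
# LCA simulation
# ---------------------------------------------------------------------------

def _draw_episode_spikes(cfg: LcaSimConfig, lam, lam_max, rng) -> np.ndarray:
    """Inhomogeneous Poisson by thinning + evoked spikes + refractory."""
    times = np.empty(0)
    if lam_max > 0:
        n = rng.poisson(lam_max * cfg.episode_duration)
        cand = np.sort(rng.uniform(0.0, cfg.episode_duration, size=n))
        keep = rng.uniform(0.0, 1.0, size=n) < lam(cand) / lam_max
        times = cand[keep]
    evoked = []
    for s in cfg.stim_times:
        if cfg.evoked_spike_prob > 0 and rng.uniform() < cfg.evoked_spike_prob:
            lat = -1.0
            while lat < 0.001:  # truncate latency at 1 ms
                lat = rng.normal(cfg.evoked_latency_mean, cfg.evoked_latency_sd)
            if s + lat < cfg.episode_duration:
                evoked.append(s + lat)
    if evoked:
        times = np.sort(np.concatenate([times, evoked]))
    return _enforce_refractory(times, cfg.refractory)


def draw_lca_spike_times(cfg: LcaSimConfig, rng=None) -> list:
    """Ground-truth spike times only (no waveform rendering)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lam = rate_profile(cfg)
    lam_max = cfg.baseline_rate * max(1.0, cfg.musc_gain)
    return [_draw_episode_spikes(cfg, lam, lam_max, rng)
            for _ in range(cfg.n_episodes)]


def simulate_lca_spikes(cfg: LcaSimConfig, rng=None) -> SpikeTrainSet:
    """Exact simulated spike trains packaged for the analysis modules."""
    return SpikeTrainSet(trains=draw_lca_spike_times(cfg, rng),
                         episode_duration=cfg.episode_duration,
                         refractory=cfg.refractory, cell_id="synthetic")


def _biphasic_waveform(amplitude_pA: float, width_s: float, fs: float):
    """One-cycle sine spike waveform; positive peak at sample offset w/4."""
    n = max(int(round(width_s * fs)), 4)
    tau = np.arange(n) / fs
    return amplitude_pA * np.sin(2.0 * np.pi * tau / width_s), n // 4


def _alpha_step(step_pA: float, fs: float, tau_a: float = 0.005):
    """Alpha-shaped capacitive deflection, ~20 ms long, peak = step_pA."""
    n = int(round(5.0 * tau_a * fs))
    tau = np.arange(n) / fs
    return step_pA * (tau / tau_a) * np.exp(1.0 - tau / tau_a)


def simulate_lca(cfg: LcaSimConfig, cell_id: str = "synthetic"
                 ) -> tuple[Recording, GroundTruth]:
    """Render a loose cell-attached recording with known spike times."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    spike_times = draw_lca_spike_times(cfg, rng)
    fs = cfg.sampling_rate
    n_samples = int(round(cfg.episode_duration * fs))
    traces = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_episodes, n_samples)) \
        if cfg.noise_sd > 0 else np.zeros((cfg.n_episodes, n_samples))
    wave, peak_off = _biphasic_waveform(cfg.spike_amplitude_pA,
                                        cfg.spike_width_ms / 1000.0, fs)
    step = _alpha_step(cfg.capacitive_step_pA, fs) \
        if cfg.capacitive_step_pA != 0 else None
    kept = []
    for ep in range(cfg.n_episodes):
        kept_ep = []
        for t in spike_times[ep]:
            i0 = int(round(t * fs)) - peak_off  # positive lobe peaks at t
            j0, j1 = max(i0, 0), min(i0 + len(wave), n_samples)
            if j1 <= j0:
                continue
            traces[ep, j0:j1] += wave[j0 - i0:j1 - i0]
            kept_ep.append(t)
        for s in cfg.stim_times:
            if step is not None:
                i0 = int(round(s * fs))
                j1 = min(i0 + len(step), n_samples)
                traces[ep, i0:j1] += step[: j1 - i0]
        kept.append(np.asarray(kept_ep))
    rec = Recording(traces=traces, sampling_rate=fs, mode="LCA",
                    stim_times=list(cfg.stim_times), cell_id=cell_id,
                    provenance="synthetic", seed=cfg.seed)
    return rec, GroundTruth(spike_times=kept, label=None, config=cfg)


# ---------------------------------------------------------------------------
# VC simulation
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def draw_vc_events(cfg: VcSimConfig, rng=None):
    """Ground-truth PSC onset times and signed amplitudes per episode."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sign = -1.0 if cfg.psc_polarity == "inward" else 1.0
    if cfg.psc_amplitude_sd > 0:
        mu, sig = _lognormal_params(cfg.psc_amplitude_mean, cfg.psc_amplitude_sd)
    times_all, amps_all = [], []
    for _ in range(cfg.n_episodes):
        times = np.empty(0)
        if cfg.spont_event_rate > 0:
            n = rng.poisson(cfg.spont_event_rate * cfg.episode_duration)
            times = rng.uniform(0.0, cfg.episode_duration, size=n)
        fixed_amp_times = []
        for s in cfg.stim_times:
            if cfg.evoked_latency is not None:
                fixed_amp_times.append(s + cfg.evoked_latency)
            if cfg.barrage_rate0 > 0:
                horizon = min(cfg.episode_duration - s,
                              10.0 * cfg.barrage_decay)
                n = rng.poisson(cfg.barrage_rate0 * horizon)
                cand = rng.uniform(0.0, horizon, size=n)
                keep = rng.uniform(size=n) < np.exp(-cand / cfg.barrage_decay)
                times = np.concatenate([times, s + cand[keep]])
        times = np.sort(np.concatenate([times, fixed_amp_times]))
        if cfg.min_event_interval > 0:
            times = _enforce_refractory(times, cfg.min_event_interval)
        if cfg.psc_amplitude_sd > 0:
            amps = sign * rng.lognormal(mu, sig, size=len(times))
        else:
            amps = sign * np.full(len(times), cfg.psc_amplitude_mean)
        if cfg.evoked_amplitude_pA is not None and cfg.evoked_latency is not None:
            for s in cfg.stim_times:
                j = int(np.argmin(np.abs(times - (s + cfg.evoked_latency))))
                amps[j] = sign * cfg.evoked_amplitude_pA
        times_all.append(times)
        amps_all.append(amps)
    return times_all, amps_all


def simulate_vc(cfg: VcSimConfig, cell_id: str = "synthetic"
                ) -> tuple[Recording, GroundTruth]:
    """Render a voltage-clamp recording with known PSC times/amplitudes."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    times_all, amps_all = draw_vc_events(cfg, rng)
    fs = cfg.sampling_rate
    n_samples = int(round(cfg.episode_duration * fs))
    traces = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_episodes, n_samples)) \
        if cfg.noise_sd > 0 else np.zeros((cfg.n_episodes, n_samples))
    kern_len = int(round((cfg.psc_rise + 7.0 * cfg.psc_tau2) * fs))
    kern = psc_kernel(np.arange(kern_len) / fs, cfg.psc_rise, cfg.psc_tau1,
                      cfg.psc_tau2, cfg.psc_frac_fast)
    for ep in range(cfg.n_episodes):
        for t, a in zip(times_all[ep], amps_all[ep]):
            i0 = int(round(t * fs))
            j1 = min(i0 + kern_len, n_samples)
            if j1 <= i0:
                continue
            traces[ep, i0:j1] += a * kern[: j1 - i0]
    rec = Recording(traces=traces, sampling_rate=fs, mode="VC",
                    stim_times=list(cfg.stim_times), holding_potential=0.0,
                    cell_id=cell_id, provenance="synthetic", seed=cfg.seed)
    return rec, GroundTruth(event_times=times_all, event_amplitudes=amps_all,
                            config=cfg)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def preset_config(label: str, *, n_episodes: int = 40,
                  episode_duration: float = 4.0, stim_time: float = 1.5,
                  seed: int | None = None) -> LcaSimConfig:
    """LCA config templates for each response class.

    Effect sizes follow the cohort means the analysis is meant to recover:
    2.2 Hz baseline tripling to ~6.6 Hz for the muscarinic classes, ~8 Hz
    baselines for purely inhibited cells, 0.39 s full suppression, 13.4 ms
    mean evoked-spike latency with an inward capacitive current.
    """
    base = dict(n_episodes=n_episodes, episode_duration=episode_duration,
                stim_times=(stim_time,), seed=seed)
    if label == "nonresponsive":
        return LcaSimConfig(baseline_rate=2.0, inhibition_duration=0.0,
                            **base)
    if label == "inhibition":
        return LcaSimConfig(baseline_rate=8.0, inhibition_duration=0.39,
                            inhibition_depth=1.0, **base)
    if label == "brief_excitation":
        return LcaSimConfig(baseline_rate=0.5, inhibition_duration=0.0,
                            evoked_spike_prob=0.9, capacitive_step_pA=-5.0,
                            **base)
    if label == "biphasic_inhibition_muscarinic":
        return LcaSimConfig(baseline_rate=2.2, inhibition_duration=0.39,
                            inhibition_depth=1.0, musc_gain=3.0, **base)
    if label == "muscarinic_only":
        return LcaSimConfig(baseline_rate=2.2, inhibition_duration=0.0,
                            musc_gain=3.0, **base)
    raise ParameterError(f"unknown class label {label!r}")


def _config_digest(cfg) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def simulate_cohort(spec, out_dir, seed: int | None = None,
                    render: bool = True):
    """Simulate a labelled cohort of cells and write it to disk.

    Parameters
    ----------
    spec : list of (label, config-or-None, n_cells)
        ``config=None`` uses :func:`preset_config` for the label.
    out_dir : path
        Receives one recording per cell plus ``truth.csv``.
    render : bool
        When False, only spike times are drawn and ``truth.csv`` written
        (no trace files) — useful for large statistical runs.

    Returns
    -------
    truth : pandas.DataFrame with cell_id, label, config digest (and the
        spike trains attached in ``truth.attrs['spikes']``).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rows, spikes_by_cell = [], {}
    idx = 0
    for label, cfg, n_cells in spec:
        if label not in COHORT_LABELS:
            raise ParameterError(f"unknown class label {label!r}")
        for _ in range(int(n_cells)):
            child = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            cell_cfg = dataclasses.replace(cfg, seed=child) if cfg is not None \
                else preset_config(label, seed=child)
            cell_id = f"cell{idx:04d}"
            if cell_id in spikes_by_cell:
                raise ParameterError(f"duplicate cell_id {cell_id}")
            if render:
                rec, truth = simulate_lca(cell_cfg, cell_id=cell_id)
                write_recording(rec, out_dir / cell_id)
                spikes_by_cell[cell_id] = truth.spike_times
            else:
                spikes_by_cell[cell_id] = draw_lca_spike_times(cell_cfg)
            rows.append({"cell_id": cell_id, "label": label,
                         "seed": child, "config": _config_digest(cell_cfg)})
            idx += 1
    truth = pd.DataFrame(rows, columns=["cell_id", "label", "seed", "config"])
    truth.to_csv(out_dir / "truth.csv", index=False)
    truth.attrs["spikes"] = spikes_by_cell
    return truth
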