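# Methods

This note documents the models, statistical procedures and numerical
choices behind `glomclass`, and what the synthetic-data studies do and do
not establish.

## Data model and conventions

A *recording* is a set of equally long episodes (sweeps) of current
samples in pA at a fixed sampling rate (synthetic default 20 kHz), with a
list of stimulus (flash) times shared by all episodes. All internal times
are in seconds; milliseconds appear only in report output. Sample *i*
covers the half-open interval [i/fs, (i+1)/fs); stimulus-relative windows
are half-open, so a spike or event exactly at a window edge belongs to the
later window, and a bin edge always falls exactly at t = 0. Episodes are
treated as statistically independent trials; inter-trial gaps are not
modelled. Traces are stored as row-per-episode CSV with a JSON metadata
sidecar — deliberately plain text so that fixtures diff cleanly; vendor
acquisition formats are out of scope.

## Synthetic loose-patch (LCA) model

Spiking is an inhomogeneous Poisson process with a 2 ms absolute
refractory period, sampled by thinning against the rate envelope

λ(t) = r₀ · ∏ₛ(1 − d·1[s ≤ t < s+D]) · (1 + (g−1)·Σₛ G(t−s)),

where r₀ is the baseline rate (cohort presets use 0.5–8 Hz, within the
observed 0–6 Hz range for muscarinic responders and ~8 Hz for purely
inhibited cells), d and D are the inhibition depth and duration (defaults
1.0 and 0.39 s, matching the measured 391 ± 142 ms suppression; whether
suppression is complete is not observable from rates alone, so depth is a
free parameter defaulting to complete), and G is a peak-normalised
difference of exponentials (rise 0.3 s, decay 3 s), so the slow muscarinic
excitation peaks ~0.8 s after the flash and decays over 5–10 s. The gain g
multiplies the baseline rate at the kernel peak; g = 3 reproduces the
reference 2.2 → 6.6 Hz effect in the +1 to +2 s window.

Optional per-flash evoked spikes occur with configurable probability at a
Gaussian latency truncated below at 1 ms (defaults 13.4 ± 9.9 ms for the
early class; the delayed class uses ~329 ± 191 ms). Spikes are rendered as
one-cycle sine biphasic waveforms (positive peak at the spike time);
a signed alpha-shaped deflection (~20 ms, peak at 5 ms) at each flash
models the slow evoked capacitive current; Gaussian noise is added last.
The generator also offers a spike-times-only path
(`simulate_lca_spikes`) used by the large statistical studies, where
rendering tens of millions of samples would add nothing.

## Synthetic voltage-clamp model

PSC trains are homogeneous Poisson (spontaneous) plus, per stimulus,
either a single evoked PSC at fixed latency or a barrage drawn from the
decaying rate r(t) = r₀·e^(−(t−s)/τ_b). Amplitudes are lognormal
(positive support; mean/SD parameterised, default 62 ± 40 pA) with
polarity applied as a sign. Each event is a peak-normalised kernel

k(t) = (1 − e^(−t/rise)) · (f·e^(−t/τ₁) + (1−f)·e^(−t/τ₂)),  k(t<0) = 0.

A `min_event_interval` option thins events earlier-wins, which the
detection studies use to keep noiseless events resolvable by construction.

## Spike detection and PSTHs

Loose-patch action potentials are biphasic capacitive currents whose sign
depends on seal geometry, so detection is polarity-agnostic: local maxima
of |trace| at or above an amplitude threshold, with sub-refractory events
discarded earlier-wins (default 2 ms, a physiological floor). The
`auto` threshold is 6× a scaled-MAD noise estimate per episode; thresholds
below 3× the noise SD trigger a warning. PSTHs accumulate counts over all
(episode × stimulus) trials in half-open bins; the conventional bin sizes
are 20 ms for 2-s episodes and 200 ms for ≥ 15-s episodes.

## Sliding-template event detection

At every offset the PSC template is fitted to the trace by least squares
with free scale and offset; the detection criterion is
scale / SE(fit) with SE = √(SSE/(N−1)) — the classical template-matching
detector. The offset term makes the criterion invariant to baseline
shifts, and the scale/SE ratio makes it invariant to trace rescaling (the
fitted amplitude is linear in the trace). Events are local maxima of the
criterion above threshold (default 3.5); detections within one rise time
keep the larger criterion. Two numerical guards matter on clean data:
SSE is floored at a machine-precision level to avoid 0/0 at perfect fits,
and peaks must exceed a prominence of threshold/2 — over a pure
exponential tail the criterion is *exactly* constant (it is
scale-invariant), and floating-point ripple on that plateau would
otherwise create spurious detections.

Onset of an averaged evoked current is measured at 5 % of the first peak:
baseline is the mean of the 10 ms preceding the stimulus, the first
post-stimulus local extremum exceeding 5× the baseline SD is the peak, and
the onset is the last crossing of 5 % of the peak deflection before it,
linearly interpolated between samples. Latency is onset minus artifact
time, with the ordering enforced.

The evoked-barrage duration uses the cumulative event PSTH (20 ms bins):
baseline mean and SD (n−1 denominator) over the 25 pre-stimulus bins, and
the duration is the time from the stimulus to the start of the first run
of ≥ 5 consecutive bins at or below baseline + 2 SD. "Return to baseline"
is read as ≤ the threshold; the SD is taken across bins of the cumulative
histogram (not across sweeps) as the most literal reading, and the 5-bin
run must be strictly consecutive after any excursion. If no run completes
inside the window the duration equals the window length and is flagged
censored.

## Decay kinetics

The decay of a baseline-subtracted averaged evoked current is fitted from
its peak (t = 0 at the peak) as A₁e^(−t/τ₁), optionally + A₂e^(−t/τ₂), by
bounded least squares (amplitudes ≥ 0, τ ∈ [0.1 ms, 10 s]) from multiple
starts: τ at {0.2, 1, 5}× a crude 1/e-crossing estimate, split-amplitude
combinations for the two-component model; the best RSS wins and bound-
hitting τ values are flagged. Components are ordered τ₁ ≤ τ₂ and
summarised by τ_w = (τ₁A₁ + τ₂A₂)/(A₁ + A₂), which is bounded by the
component τ's. Mono vs bi selection uses AICc computed from the Gaussian
RSS (ties favour the simpler model) — the conventional substitute for a
by-eye "best fitted" judgement.

Two refinements are available and used by the recovery studies: the peak
may be located on a lightly smoothed copy of the average (0.5 ms boxcar;
the fit always runs on raw samples), and the first ~1.5 ms after the peak
may be excluded from the fit window while keeping t = 0 at the peak —
samples at the peak are still contaminated by the rising phase, which
otherwise biases τ_w of fast (~8 ms) currents by ~3 %. Defaults leave both
off.

A reparametrisation point documented here because it is easy to get wrong:
when a kernel with onset weights (f, 1−f) is fitted *from its peak*, the
true component weights of the measured decay are f·e^(−t_pk/τ₁) and
(1−f)·e^(−t_pk/τ₂), renormalised. `synth.psc_decay_truth` computes this
ground truth and `synth.frac_fast_for_tau_w` solves f so that the
post-peak τ_w hits a target exactly; the recovery studies are calibrated
this way for the 8/37/162 ms regimes.

## Response classification

Each component test compares per-trial spike counts in paired
stimulus-relative windows with a Shapiro–Wilk gate on the paired
differences (α_norm = 0.05): normal → paired Student t, otherwise paired
Wilcoxon signed-rank (zeros dropped). All-zero differences short-circuit
to a degenerate non-significant result. Tests are one-sided in the
direction each rule names ("significant decrease/increase"), which makes
the null positive rate of each component ≈ α; a two-sided test combined
with a direction requirement would operate at ≈ α/2 instead. α = 0.05
with no correction across the three component tests (a documented caveat:
an unmodulated cell has ≈ 14 % chance of some positive component).

- *Inhibition*: decrease in [0, w) vs [−w, 0), w ∈ {100, 200} ms, ≥ 30
  trials. Both windows are evaluated and the most significant retained,
  with the p-value Bonferroni-adjusted for the number of windows tested —
  without the adjustment the measured null size is ~0.082, well above the
  nominal α; with it, ~0.04.
- *Slow (muscarinic) excitation*: increase in [+1, +2) vs [−1, 0) s, ≥ 10
  trials. "Spike probability" is operationalised as per-trial counts;
  a binary per-trial occurrence variant would discard rate information at
  these window lengths.
- *Fast excitation*: increase in [0, 0.5) vs [−0.5, 0) s, ≥ 10 trials;
  positives are subtyped by the mean first-spike latency with a 100 ms
  early/delayed boundary (the two observed latency modes are ~13 ms and
  ~330 ms).

Decision table, in priority order: inhibition⁺ → biphasic if slow⁺ else
inhibition; else slow⁺ → muscarinic-only (a slow ramp can also raise the
0–500 ms count, so the fast test is not consulted here); else fast⁺ →
brief excitation; else nonresponsive. A component that lacks the required
trials makes the cell *inconclusive* (distinct from negative). Derived
measures: inhibition duration = mean ± SD over trials of the flash →
first-spike interval (spikeless trials excluded and counted); evoked
capacitive-current polarity = sign of the spike-masked (±3 ms), averaged,
baseline-subtracted current over 0–50 ms, called inward/outward when the
deflection exceeds 3× a standard error that accounts for both the window
mean and the subtracted baseline, else none.

## Calibration and recovery studies (`glomclass.experiments`)

Study sizes were chosen to keep the whole validation suite around a
minute on one CPU while leaving Monte-Carlo error well inside the margins
being tested:

- τ_w recovery: 100 cells per regime, 20 sweeps each, per-sweep SNR 10
  (62 pA peak, 6.2 pA sweep noise → averaged-trace SNR ≈ 45). Observed:
  ≥ 92 % of fits within 5 % of truth in every regime.
- Null calibration: 1000 unmodulated 8 Hz Poisson cells, 40 trials of 4-s
  episodes; observed positive rates ≈ 0.03–0.05 per component.
- Muscarinic power: 200 cells at the 2.2 → 6.6 Hz effect with 21 trials;
  observed power ≈ 1.0.
- Inhibition duration: 100 cells, 0.39 s full suppression then 8 Hz, 2-s
  episodes with the flash at 1 s; expected estimate ≈ 0.39 + 1/8 s minus a
  small censoring term, observed ≈ 0.51 s.
- Event detection: noiseless resolvable PSC trains give recall =
  precision = 1 (events cut off by the episode end are excluded from
  scoring — no template offset can cover them); pure 2 pA noise at
  threshold 3.5 yields ≈ 0 false positives/s.

## What the synthetic studies do not show

The generator reproduces the *statistical* structure the analysis assumes
— Poisson-like spiking, stationary baselines, known kernels, Gaussian
noise — not the full phenomenology of slice recordings: bursting and
rhythmic cells, seal drift, stimulation artifacts, overlapping PSCs at
high rates, correlated (filtered) noise, or run-down. Passing the suite
therefore validates the implementation against its own model class and
the arithmetic against hand-checkable cases; it does not certify
performance on pathological real-world traces. Known limitations: the
classifier assumes a stable baseline across trials (no adaptation), the
inhibition-duration measure is imprecise for slow- or burst-firing cells,
bi-exponential decomposition (as opposed to τ_w) is ill-conditioned when
τ₂/τ₁ ≲ 3, and the barrage rule's bin-level SD makes the threshold
sensitive to sparse baselines.
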