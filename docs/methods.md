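# Methods

`flightload` models a three-load within-subject mental-workload experiment in
a simulated-flight multitasking paradigm and implements the full analysis
chain that such a study requires. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data do
— and do not — establish.

## Task model and synthetic operator

One run lasts 180 s and contains up to four concurrent subtasks. The load
conditions activate nested subsets: **low** = {compensatory tracking,
residual-capacity numeral task}, **medium** adds four meter dashboards,
**high** adds the emergency dot-counting task. Meters and emergencies are
first-class event processes:

* each meter's pointer rises at its own speed (9, 12, 15, 18 °/s by default)
  toward a 30° warning arc at a meter-specific position; a correct key press
  inside the arc resets the pointer, otherwise it falls back after passing
  the arc;
* emergencies present 10–20 dots, live for at most 30 s, and the next group
  appears 30 s after the current one resolves (so inter-onset gaps are ≥ 30 s
  by construction);
* the numeral of the residual-capacity task respawns immediately on a correct
  press and otherwise stays on screen, so the count of correct presses
  measures spare capacity.

The synthetic operator is a limited-capacity resource allocator. Each subtask
requests a share of a unit resource pool when it has a pending demand
(defaults: tracking 0.85, each pending meter warning 0.30, a pending
emergency 0.35, the numeral task 0.60); requests are filled greedily in
priority order (meters → emergencies → tracking → residual), so primary tasks
with pending demands are fully served before the residual task receives
anything. Two read-outs couple load to performance:

* **Tracking** error is a 2-D Ornstein–Uhlenbeck process with diffusion
  `tracking_noise_sd` (mm·s^-1/2, default 30) and mean-reversion rate
  `tracking_gain × share` (gain 2 s⁻¹). When meter/emergency demands claim
  resources, the tracking share and hence the reversion rate drop, the
  stationary error grows, and both the average distance and the number of
  30-mm alarms rise.
* **Numeral throughput** is a renewal process whose inter-attempt time is
  exponential with mean `numeral_latency_s × demand / share`; as the residual
  share shrinks under load, throughput falls.

Responses to discrete events use shifted-exponential latencies (40% fixed
motor floor, 60% exponential) truncated at the event window, with Bernoulli
correctness (meter 0.90, emergency 0.85, numeral 0.95). Meters and
emergencies are modeled as always attended: their demands are top-priority
and fit inside the pool under the defaults, so competition expresses itself
entirely through the tracking and residual shares. This is a deliberate
simplification — an operator model with attention switching at the event
level would add parameters without changing the qualitative pattern the
package is built to reproduce.

**Alarm semantics.** Whether the original tracking software counted alarms
per display refresh or per excursion cannot be determined from task
descriptions alone, so both are implemented: distance is evaluated on a 1-Hz
check grid, and the default `onset` mode counts checks where the distance
exceeds 30 mm and the previous check did not (i.e. excursion onsets at 1-Hz
resolution); `per_check` counts every exceeding check. Grid rate, threshold
and mode are all configuration options.

**Numerics.** The OU process is integrated by Euler–Maruyama at 20 Hz
(`θ·dt < 1` is validated); runs of constant θ are advanced with an exact
vectorized recursion in ≤1024-step chunks to avoid under/overflow of the
geometric weights. Event streams draw from per-subtask child RNG streams of
the session seed, so activating one subtask never perturbs another's draws.

## Tachogram model

RR intervals follow a sinusoids-plus-noise tachogram:
`RR(t_k) = mean_rr(load) + a_LF·sin(2π·0.10·t_k) + a_HF·sin(2π·0.25·t_k + φ) + ε`,
with ε white Gaussian and the interval floored at 20% of the mean as a guard
against absurd beats. The load coupling is a heart-rate slope in bpm per load
step (default +1.2 bpm/step on a 67.2-bpm base, matching the magnitude of
mean-HR differences reported for this kind of manipulation). Defaults
(a_LF = 35 ms, a_HF = 20 ms, ε sd = 30 ms) put SDNN near 45 ms, RMSSD near
50 ms and LF/HF near 1.3 — the range typical of seated young adults. An
integral-pulse-frequency-modulation model would be more physiological; the
sinusoidal tachogram was chosen because it gives every spectral feature a
known ground truth at a fraction of the complexity.

Because the white jitter is beat-to-beat uncorrelated, successive differences
are larger relative to SDNN than in real RR data. Two consequences are
documented rather than hidden: RMSSD runs high relative to SDNN, and the
artifact cleaner (below) would occasionally misflag legitimately noisy
synthetic subjects — so the study runner skips cleaning, which is meant for
real recordings with ectopic beats.

## HRV features

Mean HR is defined as `60000 / mean(RR)` (not the mean of instantaneous
rates); SDNN uses the sample (n−1) denominator; RMSSD is the root mean
square of successive differences. Band powers come from a Lomb–Scargle
periodogram evaluated directly on the uneven beat times (no resampling, no
interpolation bias), scaled so that a sinusoid of amplitude A integrates to
A²/2 ms² (PSD = 2T·P/n), and integrated by the trapezoid rule over half-open
bands LF = [0.04, 0.15) Hz and HF = [0.15, 0.40) Hz so the shared edge is
counted once. A cubic-spline + 4-Hz-resample + Welch path is available as a
cross-check (`method="welch"`). When HF power is zero the LF/HF ratio is
reported as undefined (`None`), never as infinity.

The artifact cleaner replaces any interval differing from the last *accepted*
interval by more than 20% (relative) with the mean of that accepted interval
and the next raw one; keeping the reference at the last accepted value makes
a sustained doubling flag every subsequent beat and trip the
quality-rejection rule (more than ⌈20%⌉ of beats flagged), while a lone
ectopic beat costs one replacement.

## fNIRS forward model and analysis

**Forward.** Activation is `β × (boxcar ⊗ HRF)` per channel, with the
canonical double-gamma HRF (peak 6 s, undershoot 16 s, peak:undershoot 6)
and the regressor normalized to the peak of the sustained-boxcar response,
so β is the peak ΔHbO in μM. ΔHbR is −β/3 times the same shape (typical
anticorrelation; configurable). The run window is 30 s rest + 180 s task +
30 s rest at 2 Hz (480 samples). Noise adds, per channel from independent
streams: a linear drift with slope ~N(0, 0.002 μM/s), a 0.1-Hz Mayer wave
(0.05 μM), a cardiac sinusoid (0.05 μM at 1.1 Hz, synthesized explicitly at
its 2-Hz-sampling alias of 0.9 Hz), and white noise (0.10 μM).

**MBLL.** ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ) with d = 3.5 cm,
DPF = 6.0 at both wavelengths, and the Gratzer/Prahl extinction tabulation at
760/850 nm (ε_HbO = 1486.6/2526.4, ε_HbR = 3843.7/1798.6 cm⁻¹M⁻¹). The d·DPF
product and the μM unit conversion are folded into the 2×2 system matrix, so
inversion is a per-sample linear solve and β stays in μM. The matrix's
condition number is checked (error above 1e6). The original acquisition
software's DPF and extinction values are not public; these defaults are
declared assumptions, and the forward/inverse pair is exact to machine
precision by construction.

**Denoising.** Per channel, a sym8 discrete wavelet decomposition to level
⌊log2 n⌋ − 4 with soft thresholding of all detail coefficients at the
universal threshold σ̂√(2 ln n), σ̂ from the median absolute deviation of the
finest details. This attenuates high-frequency noise while leaving the slow
hemodynamic response essentially untouched (a smooth ramp passes with < 1%
RMS change).

**GLM.** The design holds the task regressor plus orthonormal Legendre drift
columns (order 1 by default). With precoloring (default), data and design
are convolved with the HRF before ordinary least squares — imposing a known
temporal covariance V = SSᵀ rather than estimating one — and inference uses
σ̂² = RSS / tr(RVR) with Satterthwaite effective df = tr(RV)²/tr(RVRV).
AR-style prewhitening is deliberately not the default, to match the
HRF-as-low-pass convention this pipeline follows. Per-design linear-algebra
factors are cached, so repeated fits on the same grid cost one least-squares
solve.

One calibration subtlety: wavelet shrinkage removes high-frequency noise
that the precolored fit ignores anyway, so it barely changes the sampling
variability of β̂ but *does* deflate a residual-based σ̂ (empirically,
SD(β̂)/SE ≈ 1.23 at β = 0, i.e. ~89% two-SE coverage). The end-to-end
estimator therefore takes β from the denoised fit and SE/df from the
undenoised fit; with that pairing, bias stays below 1% and two-SE coverage
is ≈96% across β ∈ {0, 0.2, 0.5, 1.0} μM under the default noise model.
Only the HbO β feeds condition-level inference; the HbR β is computed as a
quality-control read-out. Each condition is fit as its own run (its rest
samples included, boxcar over the task block); channels are opaque ids 1–8
with no cortical registration.

## NASA-TLX

Six dimensions (MD, PD, TD, OP, EF, FR) rated 0–100; weights are the win
counts over the 15 unordered pairwise comparisons (integers 0–5 summing to
15); the overall score is Σ(rating·weight)/15, computed in exact rational
arithmetic and rounded to two decimals only at the end. OP is used as marked
— reverse-coding is an explicit flag that defaults to off, since instruments
differ on the anchoring and the convention modeled here does not state it.

## Inferential layer

The one-way repeated-measures ANOVA is the two-way decomposition with
subject as blocking factor: F = MS_condition/MS_(condition×subject) on
(k−1, (k−1)(n−1)) df, no sphericity adjustment by default (a
Greenhouse–Geisser option would be the natural extension). Note that with
n = 26 and k = 3 the standard denominator df is 50; reports that print
F(2, 26) for such designs are using a nonstandard df convention, and this
package reports the standard one. Post-hoc contrasts are paired t-tests
declared significant at raw p < α/m with m = k(k−1)/2; the threshold is
*displayed* truncated to three decimals (0.05/3 → ".016", the convention
such studies print) while the stored value is exact. Pearson correlations
use the t transform for two-sided p and are reported raw (uncorrected), and
only across measure families — subjective, performance, ECG, brain —
because within-family pairings (e.g. HR with SDNN) are confounded by
construction.

## Study orchestration

Each subject receives all three conditions once, in a Latin-square-rotated
order; between-subject heterogeneity enters through lognormal multipliers on
operator noise/latency and autonomic amplitudes, a Gaussian shift of mean RR
(sd 90 ms), a Gaussian activation intercept (sd 0.10 μM), and a Gaussian
NASA-TLX intercept (sd 8). Load couplings are explicit synthesis parameters:
+1.2 bpm/step on HR, +0.25 μM/step on β, +2 mm·s^-1/2/step on tracking
noise, and per-dimension TLX slopes with MD and TD largest (18 and 20 points
per step) so temporal and mental demand drive the subjective differences.
All couplings are properties of the generator, not claims about human data.

Every stage draws from a child stream of the root seed keyed by
(stage, subject, condition), so the run is bit-reproducible and reseeding
one stage (e.g. fNIRS noise) provably leaves the others' outputs unchanged.
The zero-effect calibration mode (`StudyConfig.zero_load_effects()`) sets
every coupling to zero **and** freezes the task set at the low-load
configuration — necessary because behavioral measures depend structurally on
which subtasks are active — which makes the study an exact null for type-I
calibration of the full pipeline.

## Problem sizes

The shipped calibrations use: 2000 null tables (26 × 3) for the F-test
type-I rate; 1000 random 5 × 3 tables against a brute-force sums-of-squares
oracle; 100 noise seeds per ground-truth β ∈ {0, 0.2, 0.5, 1.0} μM for GLM
recovery; 20 replicate 26-subject studies for the qualitative direction
pattern; and 200 zero-effect studies for the end-to-end null rejection rate.
These sizes put Monte-Carlo standard errors well inside the asserted bands
(e.g. ±0.5% on a 5% rejection rate at 2000 replicates).

## What passing tests do and do not show

The generators reproduce the *structure* of the modeled experiment — event
logic, load couplings, known spectral content, HRF-shaped activation with
known β — so the analysis chain can be validated against ground truth. They
do not reproduce: learning or fatigue across runs, beat-to-beat
autocorrelation of real RR series, motion artifacts or superficial-layer
contamination in fNIRS, order effects (the counterbalancing is exercised but
nothing depends on position), or between-measure correlations beyond those
induced by shared load and subject intercepts. Passing the end-to-end
direction-pattern check therefore shows the pipeline recovers the
qualitative load pattern when it is truly present, and rejects at the
nominal rate when it is absent — not that any particular human-subject
effect size is correct.
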