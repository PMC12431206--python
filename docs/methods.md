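# Methods

This note documents the models, algorithms and numerical choices behind
`radarhrv`, and what the synthetic studies do and do not demonstrate.

## Chest-wall displacement model

The simulated displacement is y(t) = xb(t) + xh(t) + e(t), in mm.

**Respiration** `xb` follows a two-phase template per cycle Tr = Ti + Te:
a quadratic rise to the amplitude Ar during inhalation [0, Ti], and an
exponential decay with time constant τ during exhalation [Ti, Tr],
normalized so the curve is continuous at Ti and returns exactly to 0 at
Tr. Defaults: Ar = 4 mm, Ti = 1.6 s, Te = 2.4 s, τ = 0.8 s, i.e. a
0.25 Hz breathing rate in the middle of the adult band (0.1–0.5 Hz,
~1–12 mm). The template has derivative discontinuities at the phase
boundaries, so its spectrum carries harmonics of the fundamental well
into the heart band — the central difficulty the separation stage must
solve, and deliberately retained.

**Heartbeat** `xh` uses a five-stage template over one beat interval
TRR, tracking the mechanical phases of the cardiac cycle: quadratic
atrial rise to Kp on [0, Tp]; atrial plateau on [Tp, TPR]; Gaussian
ventricular-contraction rise to KQRS on [TPR, TQRS]; ventricular plateau
on [TQRS, TST]; exponential relaxation back to 0 on [TST, TRR] with rate
λ ≥ 5/(TRR − TST) so relaxation completes within the beat. Two
conventions make the printed form self-consistent and are adopted here:
the Gaussian width parameter is σ² = (TPR − TQRS)²/(2·ln(KQRS/Kp)),
which is the unique value making the branch continuous at both TPR
(value Kp) and TQRS (value KQRS); and the relaxation branch is
normalized as KQRS·(e^{−λ(t−TST)} − e^{−λ(TRR−TST)})/(1 − e^{−λ(TRR−TST)}),
which equals KQRS at TST and 0 at TRR. An `as_printed_tail` flag selects
the alternative un-normalized relaxation, which does not return to
baseline. Defaults: Kp = 0.04 mm, KQRS = 0.12 mm, stage fractions
Tp/TPR/TQRS/TST = 0.10/0.15/0.25/0.45 of TRR, mean IBI 0.85 s
(1.18 Hz) — inside the adult heart band (0.8–2.0 Hz, ~0.01–0.2 mm).

**Beat-to-beat variability**: IBIs are i.i.d. Gaussian around the mean
(default SD 30 ms), clipped to [0.5, 1.5]× the mean; each beat's stage
boundaries scale linearly with its IBI. The ground-truth beat marker is
the centre of the maximal plateau [TQRS, TST], because that is the
location any peak detector reports for this template; marker choice only
shifts all beats by a constant and therefore does not affect IBI
statistics.

**Micro-motion noise** `e` is Gaussian noise low-pass filtered below
8 Hz (slow involuntary body motion has no sharp spectral edge; the exact
cutoff is not critical because the separation stage operates mostly
below 2.5 Hz), scaled either to an absolute RMS in mm or to a target
heartbeat-to-noise ratio in dB.

## Radar signal model

A point target at range R produces, per chirp, a complex fast-time tone
at R/ΔR FFT bins (ΔR = c/2B) with carrier phase 4πR/λc, plus a steering
phase π(dh·ux + dv·uz) per receive element at half-wavelength
coordinates (dh, dv) for direction cosines (ux, uz). Chirps within a
frame see the same displacement (one slow-time sample per frame).
Static clutter adds constant tones; receiver noise is complex white
Gaussian at a configurable SNR relative to the target's per-sample
power. Defaults match a compact 60 GHz sensor: fc = 60 GHz, B = 1 GHz
(ΔR ≈ 0.15 m), an L-shaped three-element array at half-wavelength
pitch, 20 Hz frame rate (≥ 5× the maximum heart frequency). Not
modelled: multipath, antenna coupling, range-dependent gain, moving
subjects.

## Localization

MTI is a two-pulse (first-difference) canceller along frames: static
returns cancel exactly; a vibrating target survives with gain
2·sin(ωΔt/2) per frequency component. Range and Doppler FFTs use
Blackman–Harris windows (orthonormal scaling, so Parseval holds
exactly). Beamforming is conventional delay-and-sum on each axis
subarray over a uniform grid of n_beam angles in [−θmax, θmax] with
boresight at index n_beam/2; per-axis energies accumulate squared
magnitudes over chirps and frames and are max-normalized, making
detection invariant to overall cube gain. The fused volume
E3D[i,j,k] = Ehor[k,i]·Ever[k,j] is max-normalized and thresholded at
η (default 0.5); candidates cluster with DBSCAN (eps = 2 index units,
min_samples = 4). Within a cluster, the representative is the member
cell that carries the cluster's per-frame energy maximum most often
(ties broken by aggregate energy) — a frequency-of-occurrence rule
across frames. Index-to-Cartesian conversion has two modes:
`physical` (range k·c/2B along the steering direction; consistent with
the simulator, used for recovery checks) and `linear` (the simplified
mapping x = xdis(i − Nbeam/2), y = k·c/4B, z = zdis(j − Nbeam/2) with
xdis = zdis = cN·tanθmax/(4B·Nbeam)).

## Phase extraction

Per frame, the windowed range FFT is beamformed toward the cluster's
steering angles using all antennas; the complex value at the target
range bin is demodulated by the four-quadrant arctangent, unwrapped
(±2π compensation whenever a successive difference exceeds π), and
mean-removed. Mean removal (rather than first-sample anchoring) makes
the separation input zero-mean. Displacement in mm is y·λc/4π·1000. A
variance filter (default threshold 10⁻⁴ rad²) discards static-reflection
phase series. Sub-bin range migration of a moving target leaves a small
leakage ripple (<1 % of the carrier-phase term at millimetre
displacements and B = 1 GHz).

## Separation

### Objective and constraints

With H(x) the L×K Hankel (trajectory) matrix of a length-T signal
(K = T − L + 1) and R = (1/K)H(x)Hᵀ(x) its covariance, quasi-periodic
signals concentrate eigen-energy in few eigenvalues. The objective

J(xb, xh, n) = αb·Σ_{i>n} λb,i² + αh·Σ_{j>n} λh,j²
             + β‖D²y − xh‖² + γ‖y − xb − xh‖²

penalizes eigenvalue tails of both components, ties the cardiac
component to the second derivative of the measurement (which amplifies
the heartbeat's sharp transients relative to the smooth respiratory
bulk), and enforces additive fidelity. The fourth term's form follows
from the γ factors in the stationarity conditions. The eigenvalue
constraints g_i = λ_i − (1/K)‖Hᵀ(x)u_i‖² = 0 are enforced with
multipliers μ.

### Iteration

Each iteration: (1) λ ← −μ/(2α), clipped at 0 (covariance eigenvalues
are nonnegative); (2) fresh eigendecomposition of each component's
covariance; (3) rank-limited reconstruction — in the product
√(Kλ)·u·vᵀ with v = Hᵀ(x)u/√(Kλ) the √(Kλ) factors cancel, so the
reconstruction is the standard SSA projection Σ_{i≤rank} u_i(Hᵀ(x)u_i)ᵀ
followed by diagonal averaging, well-defined even at λ = 0; (4) signal
updates xb ← y − xh − (1/Kγ)Σ μb,i·DᵀSb,i and
xh ← (γ(y − xb) + βD²y + (1/K)Σ μh,j·DᵀSh,j)/(γ + β), where DᵀS is the
exact adjoint of x ↦ Hᵀ(x)u (a full correlation, equal to the
anti-diagonal sums of u·Sᵀ) and the sign asymmetry between the two
multiplier terms is intentional; (5) μ ← μ + ρ(λ − (1/K)‖S‖²).
Convergence is declared when both components agree with their low-rank
reconstructions in squared norm below ε (default 10⁻⁶); hitting the
iteration cap returns a warning flag, not an exception. The returned
components are the rank-limited reconstructions (identical to the raw
iterates at convergence, and strictly better behaved before it).

### Initialization

The respiratory component is initialized by a least-squares harmonic
fit: the fundamental f0 is the parabolic-interpolated spectral peak in
the respiratory band, and sin/cos regressors at k·f0 up to 2.5 Hz are
fitted to y. This matters: respiration's in-band harmonics (at the
defaults, 1.0 and 1.25 Hz, amplitudes comparable to the whole heartbeat)
must start on the respiratory side, because the iteration has no
mechanism that migrates a spectral line from one component to the other
— a plain low-pass initialization leaves them permanently in the
cardiac channel and caps the achievable heartbeat correlation near 0.4
even without noise. When no dominant respiratory line exists (the
respiratory-band spectral peak is weaker than the heart-band peak), the
initialization falls back to a low-pass, avoiding a spurious comb fit on
heart-dominated input. The cardiac component starts as the heart-band
(0.8–2.0 Hz) residual y − xb⁰.

### Rank selection

The cardiac rank n is the smallest count capturing 95 % of the
eigen-energy of the initialized cardiac component (typically 2–4; the
jittered heartbeat is a slowly phase-modulated oscillation and needs few
components, and a small rank is what rejects broadband noise). The
respiratory reconstruction uses a deeper rank (99.9 % of its
eigen-energy, typically ~10) because the harmonic ladder spans orders of
magnitude in eigen-energy and the weak in-band harmonics must stay on
the respiratory side. Both are overridable.

### Stability and default weights

The input is mean-removed and normalized to unit variance (outputs are
rescaled), which makes the loop gains predictable across amplitudes and
SNRs. Two contraction conditions bound the hyperparameters. First, the
multiplier recursion μ ← μ(1 − ρ/2α) − ρs is stable only for ρ < 4α.
Second, the μ-driven term in the xb update feeds the component's own
dominant structure back with gain ≈ 2α·λ₁·L/(Kγ) (λ₁ ≈ L/2 for the
unit-variance respiratory bulk), and because the alternating fidelity
updates exchange xb-side terms into xh with no contraction margin (the
relaxation factor is γ/(γ+β) ≈ 1), any appreciable steady-state
coupling accumulates respiratory structure in the cardiac estimate
linearly over iterations. The defaults therefore keep the multiplier
machinery present but weak — αb = αh = 0.01, ρ = 10⁻⁵, γ = 10,
max_iter = 30 — so that the eigenvalue constraints are tracked without
destabilizing the fidelity split; the separation accuracy is carried by
the initialization and the rank-limited reconstructions. β = 10⁻⁵
likewise: the second difference is scaled by 1/Δt² (= 400 at 20 Hz), so
the structural term's per-sample magnitude exceeds the cardiac signal's
by orders of magnitude and additionally amplifies wideband noise by ω²;
larger β demonstrably drags the cardiac estimate toward the
noise-amplified second derivative. These defaults were calibrated once
on the synthetic recovery suite (they are part of the algorithm, not of
the study conditions) and are recorded in `SeparationConfig`.

### Degenerate inputs

A constant input returns xb = xh = 0, converged, in one iteration. A
pure-respiration input yields a cardiac estimate below 10 % of the
signal RMS. Non-finite input raises; non-finite iterates raise rather
than returning garbage.

## HRV metrics

Beats are local maxima with a refractory spacing of one minimum cardiac
period (default max rate 2 Hz) and prominence above 0.25× the median
peak prominence. Detected positions are refined to sub-sample
precision, by default to the nearest 2πk crossing of the analytic
(Hilbert) instantaneous phase — on a narrow-band cardiac estimate this
marker is consistent from beat to beat, which matters because at a 20 Hz
frame rate raw sample quantization (50 ms) would otherwise dominate
RMSSD. Parabolic and no-refinement variants are available.

Metric conventions: Mean IBI is the arithmetic mean; RMSSD divides the
sum of squared successive differences by N−1; SDRR defaults to the
population SD over all N intervals (a variant reproducing a formula that
drops the first interval from the sum sits behind `as_printed=True`);
pNN50 counts |ΔIBI| > 50 ms strictly, two-sided, with the interval count
N (not N−1) in the denominator, so its maximum is 100·(N−1)/N.

Beat-sequence alignment for evaluation bins both event trains at 10 ms,
finds the cross-correlation-maximizing lag within ±2 s, and matches
greedily within 250 ms.

## Evaluation aggregation

`evaluate_against_reference` builds per-subject absolute errors
|estimate − reference| per metric and method, averages them per
metric/method, and reports pairwise percentage reductions
(e_a − e_b)/e_a·100. Reductions are computed from means rounded
half-up to 0.01 — the reporting precision of the bundled six-subject
benchmark — so that reported reductions are consistent with the reported
means. The benchmark ships both the value rows and the published
(0.01-rounded) per-subject error cells; recomputing errors from the
value rows agrees with every published cell to that precision.

## Study sizes and what the tests show

The recovery studies use 60 s records at a 20 Hz frame rate (T = 1200,
L = 80, K = 1121), 20 trials, heartbeat-to-noise ratio 10 dB and 30 ms
IBI jitter; localization uses a 64-sample, 64-beam cube with a 4+4
element L-array, 10 s of frames, and two static clutter reflectors.
These sizes exercise every code path at full fidelity while keeping the
suite fast.

Passing them shows that the pipeline recovers sub-millisecond mean-IBI
accuracy and beat-to-beat variability from a synthetic scene whose
component structure matches the generative model — periodic respiration
with a fixed fundamental, i.i.d. IBI jitter, band-limited Gaussian
micro-motion, point-target reflections. Real recordings violate all of
these to some degree: respiratory rate drifts (the harmonic fit would
need short-window tracking), body motion is neither Gaussian nor
stationary, and the chest is an extended reflector. The synthetic
results are therefore a correctness and plausibility check of the
algorithms, not a clinical validation.

## Known limitations

- The harmonic-fit initialization assumes a quasi-stationary respiratory
  fundamental over the analysis window; strongly drifting breathing
  would require windowed re-fitting.
- If a respiratory harmonic coincides with the heart rate to within
  ~1/T Hz, the fit absorbs part of the heartbeat; finite record length
  is the only protection.
- The multiplier loop tracks the eigenvalue constraints only weakly at
  the default step size; it polishes rather than drives the separation
  (see Stability above for why stronger coupling is counterproductive in
  this formulation).
- Offline batch processing only; no streaming, tracking, multi-person
  phase separation, CFAR detection, or frequency-domain HRV.
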