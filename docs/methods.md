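# Methods

## Model

phasekit treats each rhythmic channel as the phase of a weakly perturbed,
noisy limit-cycle oscillator. The network dynamics are

    dφ_i/dt = ω̂_i + Σ_{j≠i} Γ_ij(ψ_ij) + η_i(t),
    ψ_ij = p_i φ_j − p_j φ_i,
    ⟨η_i(t) η_j(t′)⟩ = 2 D_i δ_ij δ(t − t′),

with coprime positive integers (p_i, p_j) per directed edge. The
coupling function is a truncated Fourier series,

    Γ_ij(ψ) = Σ_{m=1..M_ij} a_ij^(m) cos(mψ) + b_ij^(m) sin(mψ).

The constant Fourier term of each coupling is not identifiable
separately from the natural frequency (both are constants in the
regression), so the stored `omega_hat` is their sum and couplings carry
only harmonics m ≥ 1. This is why, when comparing an estimated coupling
function against an externally derived one, the comparison is made after
removing both functions' means.

Assumptions inherited from phase reduction: interactions and noise are
weak relative to the attraction to each limit cycle; coupling depends on
phases only (no amplitude dynamics, no phase–amplitude coupling); the
winding pair (p_i, p_j) is fixed per edge and known or detectable from
the mean frequency ratio. A further practical requirement is that the
phase differences actually explore [0, 2π): for a noise-free, tightly
locked pair ψ visits a single point and the shape of Γ away from that
point is unidentifiable (the intercept and the value of Γ at the locked
ψ remain identifiable, nothing more).

## Phase extraction

Raw signals are converted to phases in three steps.

1. **Analytic signal.** The channel mean is removed and the Hilbert
   transform gives A(t)·exp(iθ(t)). θ is the *protophase*: observable
   but parameterization dependent. A margin of one period at the
   channel's dominant frequency (FFT peak) is discarded at both ends by
   default, because the discrete analytic signal is distorted near the
   record edges. When several channels must stay sample-aligned, the
   caller trims all channels by a common margin instead
   (`trim_periods=0` plus `trim_phase`).
2. **Density estimate.** The circular density f(θ) is estimated as a
   Fourier series from the empirical moments ⟨cos nθ⟩, ⟨sin nθ⟩ up to
   order N_h = 10, evaluated on a 2048-point grid, clipped at ε = 1e−6
   and renormalized. Clipping guarantees a strictly increasing phase
   map even when the truncated series dips slightly negative. N_h = 10
   resolves the waveform asymmetry of strongly nonlinear oscillators
   (the circuit benchmark) while keeping the estimator smooth at the
   record lengths used here; the identity map is recovered exactly when
   all moments vanish.
3. **Correction.** φ(θ) = 2π ∫₀^θ f(θ′) dθ′, applied to the wrapped
   protophase with whole turns carried over, so the winding numbers of φ
   and θ agree by construction. For a stationary oscillator this makes
   the wrapped φ uniform — the Kolmogorov–Smirnov distance to the
   uniform distribution drops relative to θ, which the tests check on
   circuit data.

Phase unwrapping interprets jumps larger than π as wraps; all supported
settings sample much faster than one radian per step. Zero-phase
references can be shifted by a constant (e.g. +π/6, +π/10 for the two
circuit channels) to align the Hilbert-based reference with a
peak-of-signal convention when comparing against externally derived
coupling functions.

Field data preprocessing uses a zero-phase (forward–backward) 4th-order
Butterworth bandpass; envelope mode takes |analytic signal| first and
then bandpasses the envelope, the standard route to slow amplitude
rhythms of a fast carrier (e.g. 3–6 Hz syllabic and 1–3 Hz prosodic
components of a sound envelope).

## Estimation

The forward-difference velocity y_τ = (φ_i(t_{τ+1}) − φ_i(t_τ))/Δt is
regressed on an intercept plus {cos(mψ(t_τ)), sin(mψ(t_τ))} features.
Under Euler discretization the velocity noise is the Wiener increment
divided by Δt, so the regression variance is σ² = 2D/Δt, and the
reported noise strength is D = σ̂²·Δt/2. (Note the increment, not the
velocity, has variance 2DΔt — an easy factor to misplace; recovering
the generating sqrt(2D) on the simulation benchmark pins the
convention.)

**Prior.** Conjugate Gaussian–inverse-gamma: coefficients
N(0, σ²·100·I), σ² ~ IG(10⁻², 10⁻²). Weakly informative and proper — a
proper prior is required for the evidence to be finite. On all
benchmarks the posterior is data-dominated; rescaling the prior scale by
10 either way does not change any selected order.

**Posterior.** Standard conjugate updates:
Σ_new = (Σ₀⁻¹ + XᵀX)⁻¹, χ_new = Σ_new(Σ₀⁻¹χ₀ + Xᵀy),
α_new = α₀ + T/2, β_new = β₀ + ½(yᵀy + χ₀ᵀΣ₀⁻¹χ₀ − χ_newᵀΣ_new⁻¹χ_new).
Point estimates are the posterior means: coefficients χ_new, noise
variance β_new/(α_new − 1). Marginal coefficient standard deviations
are sqrt(β/(α−1) · diag Σ); "recovery within 3 posterior sd" statements
use these.

**Evidence.** The log marginal likelihood is computed from the
Bayes-rule identity log[likelihood × prior / posterior], evaluated at a
parameter point; for an exact conjugate triple the value is independent
of that point, which the tests assert at random points and against a
brute-force quadrature oracle (2-D Gauss–Hermite over the coefficients,
1-D quadrature over the variance) on small problems.

**Order selection.** Per target oscillator, the per-edge Fourier orders
M are chosen to maximize the evidence: exhaustively over {0..M_max}^n
for up to two edges, and by coordinate ascent from the all-zero
assignment otherwise (deterministic edge order, iterated to a fixed
point — an approximation to the exhaustive rule that is exact whenever
the evidence surface is unimodal in each coordinate, which holds on all
benchmarks tried). Ties break toward the smaller total ΣM. The search
builds the design matrix once at M_max and reuses sufficient-statistic
submatrices, so each candidate costs O(k³) rather than O(Tk²).
M_max defaults to 3.

An absent interaction is reported as a selected order M = 0 — the
identically zero function — rather than as small nonzero coefficients;
this is the mechanism behind the "coupling is identically zero"
statements in the benchmarks.

## Simulation

Euler–Maruyama: φ(t+Δt) = φ(t) + [ω̂ + ΣΓ(ψ)]Δt + sqrt(2DΔt)·ξ. One
independent substream per oscillator is spawned from the master seed
(`numpy.random.SeedSequence.spawn`), so enlarging the network never
changes the noise of existing oscillators. Default Δt = 0.01 in
dimensionless settings, 1/fs when matching data; default burn-in is 10%
of the steps (the benchmark runs use burn-in 0 so the row count matches
the nominal record length). Convergence is first order in Δt for the
deterministic part, verified against a high-order integrator.

**Three-oscillator benchmark.** Two slow units (ω = 0.9, 1.1) and one
fast unit (ω = 2.1) with four directed couplings: 0.1·sin(φ₃−φ₁) onto
oscillator 1; 0.1·sin(2φ₁−φ₂) and 0.05·[sin(2φ₃−φ₂) + sin(2(2φ₃−φ₂))]
onto oscillator 2; 0.05·cos(φ₂−2φ₃) onto oscillator 3. Noise: the
stated standard deviation 0.1 is read as the continuous-time scale,
sqrt(2D) = 0.1 per unit time, i.e. D = 0.005 — this matches the
white-noise autocorrelation convention ⟨ηη′⟩ = 2Dδ(t−t′). Because the
per-step reading (increment sd 0.1 at the simulation Δt) is also
defensible, `three_oscillator_model(noise_mode="per_step")` exposes it;
all shipped results use the unit-time reading. Note the cross-frequency
detunings (e.g. 2ω₁−ω₂ = −0.3) exceed the coupling amplitudes, so the
network is *not* phase-locked: the generalized differences drift
through the full circle, which is precisely what makes every part of
each coupling function identifiable.

## Van der Pol circuit ground truth

The two-unit analog circuit is modeled by RC-scaled van der Pol
equations with a unidirectional x₁² drive into the second unit's
x-equation (strength 1/(10·R_coupling·C₂)) and a constant
trajectory-asymmetry term b that captures real-circuit imperfections.
Component defaults: R₁ = 100 kΩ, R₂ = 1 kΩ, R_coupling = 1 MΩ,
C₁ = C₂ = 0.01 µF, V₁ = 0.115 V, V₂ = 0.12 V. The asymmetry term is
per-oscillator, b₁ = 0.4 and b₂ = 0: this is the placement that
reproduces the circuit's measured limit-cycle frequencies (142.27 Hz
and 146.60 Hz computed vs 142.1 and 146.4 measured; 71.14 vs 71.1 with
C₁ doubled). Frequency is invariant under the sign of b (the equations
are symmetric under x,y → −x,−y with b → −b). Doubling C₁ rescales
time exactly, halving the first unit's frequency — the cross-frequency
(1:2) preset.

Integration uses scipy's adaptive solvers throughout: LSODA at
rtol 1e−8 sampled on the fixed output grid for data generation (the
output is still uniformly sampled; adaptivity only controls the internal
error), and DOP853 at rtol ≤ 1e−10 for orbit, period and adjoint work.
Observation noise, when requested, is added to the recorded x channels
only. Theoretical frequencies are computed with the coupling off; the
drive is weak (≈1% of the vector field) so this matters little, but the
uncoupled convention matches how the reference frequencies were
determined.

**Adjoint sensitivity.** The periodic orbit is located by settling onto
the attractor and refining the return time through a Poincaré section at
the x-peak (y = 0 crossing, falling), which also anchors φ = 0 at the
peak of x. The phase sensitivity Z(φ) solves dZ/dt = −J(X(t))ᵀZ;
integrating *backward* in time damps the non-neutral Floquet component,
so repeated backward passes converge to the periodic adjoint, which is
then scaled so Z·F = ω. The identity Z·F = ω then holds at every grid
point (residual < 1e−3 required, ~1e−9 achieved), and Z matches a
direct finite-difference phase-response computation to well under 2%
RMS. A decaying or still-drifting orbit (e.g. V₁ = 0, or a weak cycle
swamped by the b offset) is rejected with a "no limit cycle" error based
on peak-amplitude stability.

**Theoretical coupling.** For the driven unit, averaging the sensitivity
against the coupling field along the locked torus gives

    Γ(ψ) = (1/2πp_i) ∫₀^{2πp_i} Z_x(φ) · (−c · x_src((ψ + p_j φ)/p_i)²) dφ,

with c = 1/(10·R_coupling·C₂); φ runs over p_i target cycles so the
torus line closes (for 1:2, two fast periods against one slow period).
The reverse direction has no physical drive and is identically zero.
The function is returned as a table plus a fitted Fourier series
(M ≤ 5). A 5% relative mismatch between p_i·ω_source and p_j·ω_target
is the cutoff beyond which the averaging premise is rejected.

## Surrogates and ablation

Time-shift surrogates circularly shift one channel's wrapped phase and
re-unwrap, destroying temporal alignment while preserving each
channel's marginal phase distribution exactly. Shifts are drawn
uniformly from 10–90% of the record length (avoiding near-identity
shifts); per-trial shifting is available when trial boundaries exist.
For each replicate the order selection and fit are re-run and the
selected M and coupling power recorded; the empirical p-value of the
original power is (1 + #{surrogate ≥ original})/(1 + n). Under the
null the surrogate order histogram concentrates at M = 0.

Ablation zeroes chosen directed couplings (M → 0) leaving frequencies
and noise untouched; re-simulating the ablated model shows which edge
sustains a locking peak in the ψ histogram (removing the dominant edge
flattens it; removing a weak reverse edge leaves it essentially
unchanged).

## Numerical and design choices

- Histograms: 30 bins on [0, 2π), normalized as densities; L1 distance
  is the comparison metric between experimental/estimated/theoretical
  histograms.
- Winding detection scans coprime pairs up to `max_order` (default 5)
  minimizing |n·ω̄_a − m·ω̄_b|/(n·ω̄_a); mismatches above 5% raise, as
  do ties, since the regression assumes the pair is known.
- Velocity rows pair features at t_τ with the forward difference over
  [t_τ, t_{τ+1}] — the Euler-consistent alignment matching the
  simulator's likelihood.
- Column order in designs is deterministic (intercept, then edges in the
  order given, cos before sin per harmonic); evidence is invariant to
  edge listing order, which is tested.
- Degenerate inputs fail loudly: constant signals ("no oscillation"),
  NaNs, invalid bands, misaligned series, collinear columns under an
  effectively flat prior (named in the error), shifts exceeding the
  record, non-normalizable densities.

## Problem sizes used in shipped checks

Recovery and order-selection studies use 10⁵ steps at Δt = 0.01 (the
posterior standard deviations there make the weakest harmonic, 0.05, a
>15σ detection; at 3×10⁴ steps it is marginal, ~2σ of evidence gain).
Circuit studies use 6–10 s at 15 kHz for frequency measurement and
estimation. The simulate→estimate→simulate histogram closure uses
3×10⁵ steps with 15 bins because the benchmark's cross-frequency
difference drifts slowly (~0.23 rad per unit time), so shorter records
are dominated by histogram sampling noise rather than model mismatch —
re-simulating the *generating* model at 6×10⁴ steps already differs
from itself by L1 ≈ 0.2.

## What the synthetic data do and do not show

The generators emulate: n:m cross-frequency interaction with known
ground truth, white phase noise, strongly nonharmonic waveforms (the
circuit), observation noise on voltages, and unidirectional driving
(circuit; speech-envelope-like toys). They do not emulate: amplitude
dynamics and phase–amplitude coupling, nonstationary or event-locked
frequencies, phase resets by abrupt stimuli, trial-structured artifacts,
volume conduction or shared-reference mixing between channels, or
filtering distortions of broadband field data. Passing tests therefore
demonstrate correctness of the estimator under the phase-model
assumptions, not that any particular real recording satisfies those
assumptions; the surrogate test and the forward/reverse asymmetry check
are the in-package guards most relevant to real data.

## Known limitations

- Evidence-based selection needs the phase differences to explore the
  circle; tightly locked, low-noise pairs leave most of Γ
  unidentifiable (an inherent identifiability limit, not an
  implementation one).
- Coordinate ascent beyond two edges can in principle stop at a local
  evidence optimum; the exhaustive rule is used whenever feasible.
- The protophase correction uses the stationary density; strongly
  nonstationary records violate its premise.
- ω̂ absorbs the couplings' constant terms; "natural frequency" in
  reports means this effective quantity.
- The Euler-consistent likelihood is first order in Δt; at very coarse
  sampling relative to the oscillation, discretization bias enters the
  coefficients before it enters the selected orders.
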