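# phasekit

Estimation of phase-oscillator models — natural frequencies, n:m
cross-frequency coupling functions, and noise strengths — from rhythmic
time-series data, with evidence-based model selection and a full
validation toolkit (stochastic simulation, an electronic van der Pol
circuit ground truth, coupling ablation, and time-shift surrogates).

## Who it is for

Researchers asking *how* two rhythms interact, not just whether they are
correlated: e.g. does a speech envelope entrain a listener's theta-band
EEG, and through what coupling function? Does a slow oscillator drive a
fast one at a 1:2 ratio, or the reverse? Any nearly periodic signals —
neural oscillations, circuit voltages, chemical or mechanical
oscillators — with a fixed sampling rate can be analyzed.

## The model

A network of weakly coupled, noisy limit-cycle oscillators reduces to
phases:

    dφᵢ/dt = ω̂ᵢ + Σ_{j≠i} Γᵢⱼ(pᵢφⱼ − pⱼφᵢ) + ηᵢ(t),
    ⟨ηᵢ(t)ηⱼ(t′)⟩ = 2Dᵢ δᵢⱼ δ(t−t′),

where each 2π-periodic coupling function Γᵢⱼ is a truncated Fourier
series of order Mᵢⱼ in the generalized phase difference
ψ = pᵢφⱼ − pⱼφᵢ (coprime integers pᵢ, pⱼ capture n:m locking, e.g.
ψ = 2φ_slow − φ_fast for 1:2). Phases are extracted from raw signals by
the Hilbert transform and corrected through the empirical circular
density, φ(θ) = 2π∫₀^θ f(θ′)dθ′, so that a free-running oscillator's
phase grows uniformly.

Discretized, the phase velocity (φᵢ(t+Δt) − φᵢ(t))/Δt is linear in the
unknowns {ω̂ᵢ, a⁽ᵐ⁾, b⁽ᵐ⁾}, so estimation is Bayesian linear regression
with a conjugate Gaussian–inverse-gamma prior: the posterior and the log
marginal likelihood (evidence) are closed-form. The Fourier order M of
every coupling is chosen by maximizing the evidence, which automatically
penalizes superfluous harmonics — absent couplings collapse to M = 0,
i.e. the identically zero function. Coupling strength is summarized by
the power ∫₀^{2π}|Γ(ψ)|²dψ and tested against a null distribution from
time-shift surrogates.

## Worked example

Simulate the built-in three-oscillator benchmark network (two slow
units, one fast unit, four directed couplings, 1:1 and 1:2 winding
pairs) and re-estimate it:

```python
import numpy as np
from phasekit import SimConfig, make_fixture_three_oscillators, estimate_model

cfg = SimConfig(dt=0.01, n_steps=100_000, seed=1, burn_in=0)
phases, truth = make_fixture_three_oscillators(cfg)
edges = [(0, 2, 1, 1), (2, 0, 1, 1), (1, 0, 2, 1),
         (1, 2, 2, 1), (0, 1, 1, 2), (2, 1, 1, 2)]   # (target, source, p_i, p_j)
model, details = estimate_model(phases, edges, m_max=3)
osc1 = model.oscillators[0]
print("omega_hat_1 =", round(osc1.omega_hat, 4))
print("Gamma_13 sin coefficient =", round(osc1.couplings[0].b[0], 4))
print("noise scale sqrt(2D) =", round(np.sqrt(2 * osc1.D), 4))
print("selected orders, oscillator 2:", details[1]["evidence"].selected)
```

Output:

```
omega_hat_1 = 0.8925
Gamma_13 sin coefficient = 0.1027
noise scale sqrt(2D) = 0.0998
selected orders, oscillator 2: (1, 2)
```

The generating values are ω₁ = 0.9, a sine coupling of amplitude 0.1
from oscillator 3, and noise scale 0.1; the evidence selects the correct
orders (M = 1 and M = 2) for the fast oscillator's two incoming edges
and M = 0 for every absent edge.

The same estimator is validated against physics: the package simulates a
pair of van der Pol circuit oscillators (components R₁ = 100 kΩ,
R₂ = 1 kΩ, C = 0.01 µF, unidirectional x₁² drive through a 1 MΩ
resistor), extracts corrected phases from the x voltages, and compares
the estimated coupling function with the theoretical one computed by the
adjoint method — see `phasekit bench-circuit`.

## Command line

```sh
phasekit fixtures three-osc --steps 100000 --seed 1 --out phases.csv
phasekit estimate --input phases.csv --edges "0<-2:1:1,1<-0:2:1" --mmax 3 --out model.json
phasekit simulate --model model.json --steps 50000 --seed 7 --out sim.csv
phasekit surrogate --input phases.csv --target 0 --source 2 --n 100 --seed 3 --out null.csv
phasekit vdp --preset cross-freq --duration 20 --fs 15000 --out circuit.csv
phasekit bench-sim --outdir results/sim
phasekit bench-circuit --preset cross-freq --duration 10 --outdir results/circuit
phasekit run --config study.yaml
```

Every benchmark run writes a `manifest.json` (config hash, seed, library
versions) sufficient to reproduce its outputs.

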