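"""Phase-oscillator network models with n:m Fourier coupling functions.

A network of weakly coupled limit-cycle oscillators reduces to phase
equations

    dphi_i/dt = omega_hat_i + sum_j Gamma_ij(psi_ij) + eta_i(t),

where each directed interaction j -> i acts through a 2*pi-periodic
coupling function of the generalized phase difference

    psi_ij = p_i * phi_j - p_j * phi_i

with coprime positive integers (p_i, p_j) (1:1 locking is p_i = p_j = 1;
a slow oscillator locking to two cycles of a fast one enters with
p_i = 2, p_j = 1 when the slow unit is the source).  Coupling functions
are truncated Fourier series; the constant Fourier term is not stored
separately but absorbed into the effective natural frequency
``omega_hat`` since the two are not separately identifiable from data.

The white noise eta_i has autocorrelation 2*D_i*delta(t - t'), so D_i is
a noise strength in rad^2 per unit time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CouplingTerm",
    "OscillatorSpec",
    "PhaseModel",
    "eval_coupling",
    "phase_difference",
    "coupling_power",
    "detect_winding",
]


@dataclass(frozen=True)
class CouplingTerm:
    """One directed n:m interaction as a truncated Fourier series.

    The term modulates oscillator ``target`` (index i) as a function of
    psi = p_i * phi[source] - p_j * phi[target].  ``a`` and ``b`` hold
    the cosine and sine coefficients for harmonics m = 1..M (rad per
    unit time); the constant term lives in the target's ``omega_hat``.
    """

    target: int
    source: int
    p_i: int
    p_j: int
    a: tuple = ()
    b: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "a", tuple(float(v) for v in self.a))
        object.__setattr__(self, "b", tuple(float(v) for v in self.b))
        if self.target == self.source:
            raise ValueError("self-coupling is not allowed")
        if self.p_i < 1 or self.p_j < 1:
            raise ValueError("winding numbers must be positive integers")
        if math.gcd(self.p_i, self.p_j) != 1:
            raise ValueError(
                f"winding pair ({self.p_i}, {self.p_j}) is not gcd-reduced"
            )
        if len(self.a) != len(self.b):
            raise ValueError("a and b must have the same Fourier order")
        if not all(np.isfinite(self.a)) or not all(np.isfinite(self.b)):
            raise ValueError("Fourier coefficients must be finite")

    @property
    def order(self) -> int:
        """Fourier order M (0 means the term is identically zero)."""
        return len(self.a)

    def zeroed(self) -> "CouplingTerm":
        """Copy of this term with M = 0 (identically zero function)."""
        return replace(self, a=(), b=())


def eval_coupling(term: CouplingTerm, psi):
    """Evaluate Gamma(psi) = sum_m a_m cos(m psi) + b_m sin(m psi).

    ``psi`` may be a scalar or an array; the result is 2*pi-periodic.
    """
    psi = np.asarray(psi, dtype=float)
    out = np.zeros_like(psi)
    for m in range(1, term.order + 1):
        out = out + term.a[m - 1] * np.cos(m * psi) + term.b[m - 1] * np.sin(m * psi)
    return out if out.ndim else float(out)


def phase_difference(phi_i, phi_j, p_i: int, p_j: int) -> np.ndarray:
    """Generalized phase difference psi(t) = p_i*phi_j(t) - p_j*phi_i(t).

    ``phi_i`` is the target's phase series, ``phi_j`` the source's; both
    must be unwrapped, share dt, and have equal length.
    """
    if len(phi_i.phi) != len(phi_j.phi):
        raise ValueError(
            f"length mismatch: {len(phi_i.phi)} vs {len(phi_j.phi)}"
        )
    if not np.isclose(phi_i.dt, phi_j.dt):
        raise ValueError("sampling intervals differ")
    return p_i * phi_j.phi - p_j * phi_i.phi


def coupling_power(term: CouplingTerm) -> float:
    """Integrated squared coupling, int_0^2pi |Gamma(psi)|^2 dpsi.

    For a truncated Fourier series without constant term this is exactly
    pi * sum_m (a_m^2 + b_m^2) by orthogonality of the harmonics.
    """
    a = np.asarray(term.a)
    b = np.asarray(term.b)
    return float(np.pi * (a @ a + b @ b))


def detect_winding(phi_a, phi_b, max_order: int = 5, tol: float = 0.05):
    """Infer the reduced integer pair (n, m) with n*phi_a - m*phi_b bounded.

    Scans all coprime pairs with entries <= ``max_order`` and returns the
    one minimizing the relative mismatch |n*wbar_a - m*wbar_b| / (n*wbar_a),
    where wbar is the mean phase velocity of each series.  For a coupling
    term targeting oscillator i with source j, (p_i, p_j) =
    detect_winding(phi_j, phi_i).

    Raises if the best mismatch exceeds ``tol`` or two candidates tie.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    wa = float(np.mean(np.diff(phi_a.phi)) / phi_a.dt)
    wb = float(np.mean(np.diff(phi_b.phi)) / phi_b.dt)
    if wa <= 0 or wb <= 0:
        raise ValueError("mean phase velocities must be positive")
    best = None
    scores = {}
    for n in range(1, max_order + 1):
        for m in range(1, max_order + 1):
            if math.gcd(n, m) != 1:
                continue
            mis = abs(n * wa - m * wb) / (n * wa)
            scores[(n, m)] = mis
            if best is None or mis < scores[best]:
                best = (n, m)
    ties = [
        pair
        for pair, mis in scores.items()
        if pair != best and abs(mis - scores[best]) < 1e-12
    ]
    if ties:
        raise ValueError(
            f"ambiguous winding ratio: candidates {[best] + ties} "
            f"all reach mismatch {scores[best]:.3g}"
        )
    if scores[best] > tol:
        raise ValueError(
            f"no integer ratio <= {max_order} matches the frequency pair "
            f"({wa:.4g}, {wb:.4g}); best candidate {best} has relative "
            f"mismatch {scores[best]:.3g} > {tol}"
        )
    return best


@dataclass
class OscillatorSpec:
    """One oscillator: effective frequency, noise strength, incoming edges.

    ``omega_hat`` (rad per unit time) is the natural frequency plus the
    constant Fourier terms of all incoming couplings; ``D`` (rad^2 per
    unit time) is the white-noise strength.
    """

    omega_hat: float
    D: float = 0.0
    couplings: list = field(default_factory=list)

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("noise strength D must be >= 0")
        keys = [(c.source, c.p_i, c.p_j) for c in self.couplings]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate coupling term for the same (source, p_i, p_j)")


@dataclass
class PhaseModel:
    """A full phase-oscillator network."""

    oscillators: list
    channels: list = None

    def __post_init__(self):
        n = len(self.oscillators)
        if self.channels is None:
            self.channels = [f"osc{i}" for i in range(n)]
        if len(self.channels) != n:
            raise ValueError("one channel label per oscillator required")
        for i, osc in enumerate(self.oscillators):
            for term in osc.couplings:
                if term.target != i:
                    raise ValueError(
                        f"coupling stored under oscillator {i} targets {term.target}"
                    )
                if not (0 <= term.source < n):
                    raise ValueError(f"coupling source {term.source} out of range")

    @property
    def n_oscillators(self) -> int:
        return len(self.oscillators)

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "oscillators": [
                {
                    "omega_hat_rad_s": osc.omega_hat,
                    "D": osc.D,
                    "couplings": [
                        {
                            "source": t.source,
                            "p_i": t.p_i,
                            "p_j": t.p_j,
                            "a": list(t.a),
                            "b": list(t.b),
                        }
                        for t in osc.couplings
                    ],
                }
                for osc in self.oscillators
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseModel":
        oscs = []
        for i, od in enumerate(d["oscillators"]):
            terms = [
                CouplingTerm(
                    target=i,
                    source=cd["source"],
                    p_i=cd["p_i"],
                    p_j=cd["p_j"],
                    a=cd["a"],
                    b=cd["b"],
                )
                for cd in od.get("couplings", [])
            ]
            oscs.append(
                OscillatorSpec(
                    omega_hat=od["omega_hat_rad_s"], D=od["D"], couplings=terms
                )
            )
        return cls(oscillators=oscs, channels=d.get("channels"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhaseModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
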