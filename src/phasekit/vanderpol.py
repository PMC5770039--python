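"""Van der Pol electronic-circuit ground truth.

Two analog van der Pol oscillators (RC-scaled, with a trajectory-
asymmetry term b that matches real-circuit imperfections) serve as a
physical benchmark whose coupling function is known in closed form up to
quadrature:

    dx1/dt = y1 / (R1 C1)
    dy1/dt = (10 V1 - x1^2) y1 / (100 R2 C1) - x1/(R1 C1) + b1/(R1 C1)
    dx2/dt = y2 / (R1 C2) - x1^2 / (10 R_coupling C2)        [if coupled]
    dy2/dt = (10 V2 - x2^2) y2 / (100 R2 C2) - x2/(R1 C2) + b2/(R1 C2)

Oscillator 1 drives oscillator 2 through the x1^2 term; nothing feeds
back, so the reverse coupling function is identically zero.  With the
default components both units run near 145 Hz (1:1 locking); doubling C1
halves oscillator 1's frequency (exact time rescaling of its equations)
for the 1:2 cross-frequency preset.

The phase sensitivity Z(phi) (infinitesimal phase response curve) of
each uncoupled unit is computed by the adjoint method: backward
integration of dZ/dt = -J(X(t))^T Z along the limit cycle, normalized so
Z . F = omega, with zero phase anchored at the peak of x.  Averaging
Z against the coupling vector field over the locked torus yields the
theoretical coupling function to compare against the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model import CouplingTerm
from .phases import SignalRecord

__all__ = [
    "VdPParams",
    "VdPTrajectory",
    "PhaseSensitivity",
    "CouplingFunctionTable",
    "simulate_circuit",
    "measure_frequency",
    "oscillator_frequency",
    "adjoint_sensitivity",
    "theoretical_coupling",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class VdPParams:
    """Component values of the circuit ODEs (SI units).

    ``b1``/``b2`` are the per-oscillator trajectory-asymmetry offsets;
    the default (b1 = 0.4, b2 = 0) reproduces the circuit's measured
    limit-cycle frequencies of 142.1 Hz, 146.4 Hz and (with C1 doubled)
    71.1 Hz.
    """

    R1: float = 100e3
    R2: float = 1e3
    R_coupling: float = 1e6
    C1: float = 0.01e-6
    C2: float = 0.01e-6
    V1: float = 0.115
    V2: float = 0.12
    b1: float = 0.4
    b2: float = 0.0
    coupling: bool = True

    def __post_init__(self):
        for name in ("R1", "R2", "R_coupling", "C1", "C2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def same_frequency(cls, **kw) -> "VdPParams":
        """1:1 preset: both oscillators near 145 Hz."""
        return cls(**kw)

    @classmethod
    def cross_frequency(cls, **kw) -> "VdPParams":
        """1:2 preset: C1 doubled, oscillator 1 at half frequency."""
        kw.setdefault("C1", 0.02e-6)
        return cls(**kw)

    def uncoupled(self) -> "VdPParams":
        return replace(self, coupling=False)


@dataclass
class VdPTrajectory:
    """Sampled circuit state on a uniform time grid (volts, seconds)."""

    t: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    x2: np.ndarray
    y2: np.ndarray

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def to_record(self) -> SignalRecord:
        """x1 and x2 as a two-channel signal record (only x is observed)."""
        return SignalRecord(
            np.column_stack([self.x1, self.x2]), self.fs, ["x1", "x2"]
        )


def _full_field(p: VdPParams):
    c = 1.0 / (10.0 * p.R_coupling * p.C2) if p.coupling else 0.0

    def f(t, s):
        x1, y1, x2, y2 = s
        return [
            y1 / (p.R1 * p.C1),
            (10 * p.V1 - x1 * x1) * y1 / (100 * p.R2 * p.C1)
            - x1 / (p.R1 * p.C1)
            + p.b1 / (p.R1 * p.C1),
            y2 / (p.R1 * p.C2) - c * x1 * x1,
            (10 * p.V2 - x2 * x2) * y2 / (100 * p.R2 * p.C2)
            - x2 / (p.R1 * p.C2)
            + p.b2 / (p.R1 * p.C2),
        ]

    return f


def _single_field(p: VdPParams, oscillator: int):
    """Isolated-unit vector field and Jacobian for oscillator 1 or 2."""
    if oscillator == 1:
        C, V, b = p.C1, p.V1, p.b1
    elif oscillator == 2:
        C, V, b = p.C2, p.V2, p.b2
    else:
        raise ValueError("oscillator must be 1 or 2")
    k1 = 1.0 / (p.R1 * C)
    k2 = 1.0 / (100 * p.R2 * C)

    def f(t, s):
        x, y = s
        return [k1 * y, (10 * V - x * x) * y * k2 - k1 * x + k1 * b]

    def jac(s):
        x, y = s
        return np.array(
            [[0.0, k1], [-2.0 * x * y * k2 - k1, (10 * V - x * x) * k2]]
        )

    return f, jac


def simulate_circuit(
    params: VdPParams,
    duration: float,
    dt: float,
    noise_sd: float = 0.0,
    seed: int = None,
    x0=(0.1, 0.0, -0.1, 0.0),
    rtol: float = 1e-8,
) -> VdPTrajectory:
    """Integrate the four-dimensional circuit ODEs on a fixed output grid.

    ``noise_sd`` adds Gaussian observation noise (volts) to the recorded
    x channels only -- the circuit dynamics stay deterministic.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    t_eval = np.arange(0.0, duration, dt)
    sol = solve_ivp(
        _full_field(params),
        (0.0, float(t_eval[-1])),
        np.asarray(x0, dtype=float),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=1e-10,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"circuit integration diverged: {sol.message}")
    if np.max(np.abs(sol.y)) > 1e3:
        raise RuntimeError("circuit integration diverged (unbounded state)")
    x1, y1, x2, y2 = sol.y
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x1 = x1 + noise_sd * rng.standard_normal(x1.size)
        x2 = x2 + noise_sd * rng.standard_normal(x2.size)
    return VdPTrajectory(sol.t, x1, y1, x2, y2)


def measure_frequency(traj: VdPTrajectory, channel: str, transient_s: float = 0.5):
    """Mean cycle rate (Hz) from upward zero crossings after a transient.

    The channel is mean-removed over the retained window; crossing times
    are linearly interpolated between samples.
    """
    if channel not in ("x1", "y1", "x2", "y2"):
        raise KeyError(f"unknown channel {channel!r}")
    mask = traj.t >= transient_s
    t = traj.t[mask]
    x = getattr(traj, channel)[mask]
    if t.size < 4:
        raise ValueError("record too short after transient")
    x = x - np.mean(x)
    up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
    if up.size < 3:
        raise ValueError("fewer than 3 upward zero crossings; no oscillation?")
    frac = -x[up] / (x[up + 1] - x[up])
    tc = t[up] + frac * (t[up + 1] - t[up])
    return float((tc.size - 1) / (tc[-1] - tc[0]))


def oscillator_frequency(
    params: VdPParams,
    oscillator: int,
    duration: float = 6.0,
    transient_s: float = 1.0,
    rtol: float = 1e-9,
) -> float:
    """Limit-cycle frequency (Hz) of one isolated unit.

    Integrates the single-oscillator field (coupling off) and measures
    the upward-zero-crossing rate of x after the transient.
    """
    f, _ = _single_field(params, oscillator)
    n = int(duration * 2e4)
    t_eval = np.linspace(0.0, duration, n)
    sol = solve_ivp(
        f, (0.0, duration), [0.1, 0.0], method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=1e-11,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    traj = VdPTrajectory(sol.t, sol.y[0], sol.y[1], sol.y[0] * 0, sol.y[0] * 0)
    return measure_frequency(traj, "x1", transient_s=transient_s)


@dataclass
class PhaseSensitivity:
    """Phase sensitivity Z(phi) and limit cycle X(phi) of one unit.

    ``phi`` is a uniform grid on [0, 2*pi) anchored so phi = 0 at the
    peak of x; ``Z`` has shape (n, 2) and satisfies Z . F(X) = omega at
    every grid point (the defining normalization of the infinitesimal
    phase response curve).
    """

    phi: np.ndarray
    Z: np.ndarray
    X: np.ndarray
    omega: float  # rad/s
    period: float  # s

    @property
    def frequency(self) -> float:
        return self.omega / TWO_PI

    def _interp(self, arr: np.ndarray, phi):
        phi = np.mod(np.asarray(phi, dtype=float), TWO_PI)
        grid = np.concatenate([self.phi, [TWO_PI]])
        out = np.empty(phi.shape + (arr.shape[1],))
        for c in range(arr.shape[1]):
            vals = np.concatenate([arr[:, c], [arr[0, c]]])
            out[..., c] = np.interp(phi, grid, vals)
        return out

    def Z_at(self, phi):
        return self._interp(self.Z, phi)

    def X_at(self, phi):
        return self._interp(self.X, phi)


def _find_limit_cycle(f, settle_time: float, x0, rtol: float):
    """Settle onto the cycle and locate the x-peak section (y = 0, falling)."""

    def peak_event(t, s):
        return s[1]

    peak_event.direction = -1.0

    sol = solve_ivp(
        f, (0.0, settle_time), x0, method="DOP853", rtol=rtol, atol=1e-12,
        events=peak_event, dense_output=True,
    )
    ev_t = sol.t_events[0]
    ev_s = sol.y_events[0]
    # keep events from the second half only (post-transient)
    late = ev_t > settle_time / 2
    ev_t, ev_s = ev_t[late], ev_s[late]
    if ev_t.size < 6:
        raise RuntimeError("no limit cycle: too few x-peaks after transient")
    amp = np.abs(ev_s[-1, 0] - np.mean(sol.y[0][sol.t > settle_time / 2]))
    if amp < 1e-3:
        raise RuntimeError("no limit cycle: oscillation decayed")
    peaks = ev_s[:, 0]
    if np.ptp(peaks) > 1e-3 * np.max(np.abs(peaks)):
        raise RuntimeError(
            "no limit cycle: peak amplitudes still drifting after the "
            "settling window (decaying orbit or unconverged transient)"
        )
    period = float(np.mean(np.diff(ev_t[-5:])))
    anchor = ev_s[-1]
    # one refinement pass: integrate a full return from the anchor
    sol2 = solve_ivp(
        f, (0.0, 1.5 * period), anchor, method="DOP853", rtol=rtol, atol=1e-13,
        events=peak_event,
    )
    ret = sol2.t_events[0]
    ret = ret[ret > 0.5 * period]
    if ret.size == 0:
        raise RuntimeError("no limit cycle: orbit did not return to the section")
    period = float(ret[0])
    anchor = sol2.y_events[0][-1] if sol2.y_events[0].size else anchor
    # re-anchor exactly on the section from the refined state
    return np.asarray(anchor, dtype=float), period


def adjoint_sensitivity(
    params: VdPParams,
    oscillator: int = 1,
    n_grid: int = 256,
    settle_time: float = 0.5,
    rtol: float = 1e-10,
    max_loops: int = 40,
) -> PhaseSensitivity:
    """Phase sensitivity of one isolated unit by the adjoint method.

    Finds the periodic orbit (Poincare section at the x-peak), then
    integrates the adjoint variational equation dZ/dt = -J^T Z backward
    in time; backward integration damps the non-periodic Floquet
    component, so Z converges to the periodic sensitivity, which is then
    normalized to Z . F = omega at the anchor.
    """
    f, jac = _single_field(params, oscillator)
    anchor, period = _find_limit_cycle(f, settle_time, [0.1, 0.0], rtol)
    omega = TWO_PI / period
    orbit = solve_ivp(
        f, (0.0, period), anchor, method="DOP853", rtol=rtol, atol=1e-13,
        dense_output=True,
    )

    def x_of_t(t):
        return orbit.sol(np.mod(t, period))

    def adj_backward(t, z):
        # tau runs forward; physical time is -tau
        s = x_of_t(-t)
        return jac(s).T @ z

    z = np.array([1.0, 0.0])
    prev = None
    for _ in range(max_loops):
        sol = solve_ivp(
            adj_backward, (0.0, period), z, method="DOP853",
            rtol=rtol, atol=1e-13,
        )
        z = sol.y[:, -1]
        z = z / np.linalg.norm(z)
        if prev is not None and np.linalg.norm(z - prev) < 1e-12:
            break
        prev = z.copy()
    # one final backward pass storing grid values; grid time t_k maps to tau = period - t_k
    t_grid = period * np.arange(n_grid) / n_grid
    sol = solve_ivp(
        adj_backward, (0.0, period), z, method="DOP853",
        rtol=rtol, atol=1e-13, dense_output=True,
    )
    Z = np.empty((n_grid, 2))
    Z[0] = sol.y[:, -1]  # tau = period corresponds to t = -period, one full turn
    for k in range(1, n_grid):
        Z[k] = sol.sol(period - t_grid[k])
    X = x_of_t(t_grid).T
    # normalize so Z . F = omega at every grid point (scale fixed at anchor)
    F0 = np.asarray(f(0.0, X[0]))
    scale = omega / float(Z[0] @ F0)
    Z = Z * scale
    phi = TWO_PI * t_grid / period
    return PhaseSensitivity(phi=phi, Z=Z, X=X, omega=omega, period=period)


@dataclass
class CouplingFunctionTable:
    """Tabulated 2*pi-periodic coupling function plus a Fourier fit.

    ``a0`` is the constant (frequency-shift) part; ``term`` carries the
    fitted harmonics as a :class:`~phasekit.model.CouplingTerm`.
    """

    psi: np.ndarray
    gamma: np.ndarray
    a0: float
    term: CouplingTerm

    def __call__(self, psi):
        grid = np.concatenate([self.psi, [TWO_PI]])
        vals = np.concatenate([self.gamma, [self.gamma[0]]])
        return np.interp(np.mod(psi, TWO_PI), grid, vals)


def theoretical_coupling(
    sens_target: PhaseSensitivity,
    sens_source: PhaseSensitivity,
    p_i: int,
    p_j: int,
    params: VdPParams,
    n_psi: int = 128,
    n_avg: int = 512,
    fourier_order: int = 5,
    target: int = 1,
    source: int = 0,
) -> CouplingFunctionTable:
    """Adjoint-predicted coupling function Gamma(psi) for the driven unit.

    The drive enters the target's x-equation as -x_source^2 /
    (10 R_coupling C2).  Averaging Z_x of the target against that field
    along the locked torus (psi = p_i*phi_source - p_j*phi_target held
    fixed) gives

        Gamma(psi) = <Z_x(phi) * (-c) * x_src((psi + p_j*phi)/p_i)^2>_phi

    with phi running over p_i target cycles so the torus line closes.
    The reverse direction has no physical drive and is identically zero.
    """
    w_t = sens_target.omega
    w_s = sens_source.omega
    mismatch = abs(p_i * w_s - p_j * w_t) / (p_i * w_s)
    if mismatch > 0.05:
        raise ValueError(
            f"frequency ratio mismatch {mismatch:.3f} > 5% for winding "
            f"pair ({p_i}, {p_j})"
        )
    c = 0.0 if np.isinf(params.R_coupling) else 1.0 / (
        10.0 * params.R_coupling * params.C2
    )
    psi_grid = TWO_PI * np.arange(n_psi) / n_psi
    phi = TWO_PI * p_i * np.arange(n_avg * p_i) / (n_avg * p_i)
    zx = sens_target.Z_at(phi)[:, 0]
    gamma = np.empty(n_psi)
    for r, psi in enumerate(psi_grid):
        phi_src = (psi + p_j * phi) / p_i
        xs = sens_source.X_at(phi_src)[:, 0]
        gamma[r] = np.mean(zx * (-c) * xs * xs)
    a0 = float(np.mean(gamma))
    centered = gamma - a0
    a = np.empty(fourier_order)
    b = np.empty(fourier_order)
    for m in range(1, fourier_order + 1):
        a[m - 1] = 2.0 * np.mean(centered * np.cos(m * psi_grid))
        b[m - 1] = 2.0 * np.mean(centered * np.sin(m * psi_grid))
    term = CouplingTerm(
        target=target, source=source, p_i=p_i, p_j=p_j, a=tuple(a), b=tuple(b)
    )
    return CouplingFunctionTable(psi=psi_grid, gamma=gamma, a0=a0, term=term)
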