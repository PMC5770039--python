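"""Phase extraction from rhythmic signals.

The observable angle of the analytic signal (the *protophase* theta,
obtained via the Hilbert transform) is parameterization dependent: even
a free-running, noise-free oscillator traces it at a nonuniform rate.
The asymptotic phase phi used by phase-reduction theory grows uniformly.
This module converts raw signals into corrected, unwrapped phase series:

1. ``analytic_protophase``  -- Hilbert transform, theta(t) and envelope A(t);
2. ``estimate_density``     -- Fourier estimate of the circular density f(theta);
3. ``protophase_to_phase``  -- phi(theta) = 2*pi * int_0^theta f(theta') dtheta',
   which maps the empirical theta distribution onto the uniform one.

Plus phase velocities (the regression response variable), zero-phase
shifts, and the bandpass / envelope preprocessing used for field data
such as EEG and speech envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "SignalRecord",
    "ProtophaseSeries",
    "DensityMap",
    "PhaseSeries",
    "analytic_protophase",
    "estimate_density",
    "protophase_to_phase",
    "shift_zero_phase",
    "phase_velocity",
    "bandpass_and_envelope",
    "trim_phase",
    "read_signals_csv",
    "write_phases_csv",
    "read_phases_csv",
]

TWO_PI = 2.0 * np.pi


@dataclass
class SignalRecord:
    """Multichannel rhythmic time series with a uniform sampling rate.

    ``samples`` has shape (n_samples, n_channels); ``fs`` is in Hz.
    """

    samples: np.ndarray
    fs: float
    channels: list = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] == 1 and self.samples.shape[1] > 1:
            self.samples = self.samples.T
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] < 4:
            raise ValueError("need at least 4 samples per channel")
        if self.channels is None:
            self.channels = [f"ch{i}" for i in range(self.samples.shape[1])]
        if len(self.channels) != self.samples.shape[1]:
            raise ValueError("one label per channel required")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def channel(self, name) -> np.ndarray:
        if isinstance(name, str):
            if name not in self.channels:
                raise KeyError(f"no channel named {name!r}; have {self.channels}")
            name = self.channels.index(name)
        return self.samples[:, name]


@dataclass
class ProtophaseSeries:
    """Wrapped analytic-signal angle theta in [0, 2*pi) plus envelope A(t)."""

    theta: np.ndarray
    amplitude: np.ndarray
    dt: float
    label: str = ""

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.theta.shape != self.amplitude.shape:
            raise ValueError("theta and amplitude must share shape")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be >= 0")


@dataclass
class PhaseSeries:
    """Unwrapped, corrected phase of one channel at uniform sampling."""

    phi: np.ndarray
    dt: float
    label: str = ""

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.size < 2:
            raise ValueError("phase series needs at least 2 samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phase series contains non-finite values")

    @property
    def wrapped(self) -> np.ndarray:
        return np.mod(self.phi, TWO_PI)


@dataclass
class DensityMap:
    """Fourier-series estimate of the circular density f(theta).

    ``coef_cos[n-1]`` and ``coef_sin[n-1]`` are the empirical circular
    moments <cos n*theta> and <sin n*theta>, so

        f(theta) = (1/2pi) * (1 + 2 * sum_n (c_n cos + s_n sin)(n*theta)),

    evaluated on a ``grid_size``-point grid, clipped at ``eps`` and
    renormalized so the density integrates to one.
    """

    coef_cos: np.ndarray
    coef_sin: np.ndarray
    grid_size: int = 2048
    eps: float = 1e-6

    def __post_init__(self):
        self.coef_cos = np.asarray(self.coef_cos, dtype=float)
        self.coef_sin = np.asarray(self.coef_sin, dtype=float)
        if self.coef_cos.shape != self.coef_sin.shape:
            raise ValueError("cos and sin coefficient arrays must match")
        if not (
            np.all(np.isfinite(self.coef_cos)) and np.all(np.isfinite(self.coef_sin))
        ):
            raise ValueError("non-normalizable density: non-finite coefficients")
        if self.grid_size < 8:
            raise ValueError("grid_size too small")

    @property
    def n_harmonics(self) -> int:
        return len(self.coef_cos)

    def grid(self) -> np.ndarray:
        """Closed evaluation grid on [0, 2*pi] (endpoint included)."""
        return np.linspace(0.0, TWO_PI, self.grid_size + 1)

    def density(self) -> np.ndarray:
        """Clipped, renormalized density on :meth:`grid`."""
        theta = self.grid()
        f = np.full_like(theta, 1.0 / TWO_PI)
        for n in range(1, self.n_harmonics + 1):
            f = f + (
                self.coef_cos[n - 1] * np.cos(n * theta)
                + self.coef_sin[n - 1] * np.sin(n * theta)
            ) / np.pi
        f = np.clip(f, self.eps, None)
        total = np.trapezoid(f, theta)
        if not np.isfinite(total) or total <= 0:
            raise ValueError("non-normalizable density")
        return f / total

    def phase_map(self):
        """Strictly increasing map phi(theta) with phi(0)=0, phi(2pi)=2pi."""
        theta = self.grid()
        f = self.density()
        cum = np.concatenate(
            [[0.0], np.cumsum((f[1:] + f[:-1]) * 0.5 * np.diff(theta))]
        )
        return theta, TWO_PI * cum / cum[-1]


def analytic_protophase(
    record: SignalRecord, channel, trim_periods: float = 1.0
) -> ProtophaseSeries:
    """Protophase and envelope of one channel via the analytic signal.

    The channel mean is removed first.  A margin of ``trim_periods``
    oscillation periods (at the channel's dominant frequency) is dropped
    at both ends to suppress Hilbert-transform edge effects; pass 0 to
    keep the full record.
    """
    s = record.channel(channel)
    if not np.all(np.isfinite(s)):
        raise ValueError("signal contains non-finite values")
    s = s - np.mean(s)
    if np.ptp(s) == 0:
        raise ValueError("no oscillation: constant signal")
    z = hilbert(s)
    theta = np.mod(np.angle(z), TWO_PI)
    amp = np.abs(z)

    n_trim = 0
    if trim_periods > 0:
        spec = np.abs(np.fft.rfft(s))
        freqs = np.fft.rfftfreq(len(s), record.dt)
        k = int(np.argmax(spec[1:])) + 1
        f_dom = freqs[k]
        if f_dom > 0:
            n_trim = int(round(trim_periods * record.fs / f_dom))
        if 2 * n_trim > len(s) - 4:
            n_trim = max(0, (len(s) - 4) // 2)
    sl = slice(n_trim, len(s) - n_trim if n_trim else None)
    label = channel if isinstance(channel, str) else record.channels[channel]
    return ProtophaseSeries(theta[sl], amp[sl], record.dt, label=label)


def estimate_density(
    theta: ProtophaseSeries, n_harmonics: int = 10, grid_size: int = 2048
) -> DensityMap:
    """Circular density of the protophase from empirical Fourier moments.

    ``n_harmonics = 0`` yields the uniform density.
    """
    t = theta.theta if isinstance(theta, ProtophaseSeries) else np.asarray(theta)
    if t.size == 0:
        raise ValueError("empty protophase series")
    if n_harmonics < 0:
        raise ValueError("n_harmonics must be >= 0")
    n = np.arange(1, n_harmonics + 1)
    c = np.array([np.mean(np.cos(k * t)) for k in n])
    s = np.array([np.mean(np.sin(k * t)) for k in n])
    return DensityMap(c, s, grid_size=grid_size)


def protophase_to_phase(theta: ProtophaseSeries, density: DensityMap) -> PhaseSeries:
    """Corrected phase phi = 2*pi * int_0^theta f, applied sample-wise.

    The map is applied to the wrapped protophase; full turns of theta are
    carried over so each winding of theta adds exactly 2*pi to phi.
    """
    grid, phi_of = density.phase_map()
    unwrapped = np.unwrap(theta.theta)
    turns = np.floor(unwrapped / TWO_PI)
    wrapped = unwrapped - TWO_PI * turns
    phi = np.interp(wrapped, grid, phi_of) + TWO_PI * turns
    return PhaseSeries(phi, theta.dt, label=theta.label)


def shift_zero_phase(phi: PhaseSeries, offset_rad: float) -> PhaseSeries:
    """Move the zero-phase reference: add a constant offset to all phases."""
    if not np.isfinite(offset_rad):
        raise ValueError("offset must be finite")
    return PhaseSeries(phi.phi + offset_rad, phi.dt, label=phi.label)


def phase_velocity(phi: PhaseSeries) -> np.ndarray:
    """Forward-difference phase velocity, (phi[t+1] - phi[t]) / dt.

    Length is one less than the phase series; this is the response
    variable of the coupling-function regression.
    """
    if phi.dt <= 0:
        raise ValueError("dt must be positive")
    return np.diff(phi.phi) / phi.dt


def bandpass_and_envelope(
    record: SignalRecord, low_hz: float, high_hz: float, mode: str = "band"
) -> SignalRecord:
    """Zero-phase 4th-order Butterworth bandpass, or band-filtered envelope.

    ``mode="band"``: forward-backward bandpass of each channel.
    ``mode="envelope"``: take |analytic signal| of each (mean-removed)
    channel first, then bandpass the envelope -- the standard way to pull
    slow amplitude rhythms (e.g. syllabic 3-6 Hz or prosodic 1-3 Hz
    components of a sound envelope) out of a fast carrier.
    """
    if not (0 < low_hz < high_hz < record.fs / 2):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for fs={record.fs} Hz"
        )
    if mode not in ("band", "envelope"):
        raise ValueError("mode must be 'band' or 'envelope'")
    sos = butter(4, [low_hz, high_hz], btype="bandpass", fs=record.fs, output="sos")
    out = np.empty_like(record.samples)
    for k in range(record.samples.shape[1]):
        x = record.samples[:, k]
        if mode == "envelope":
            x = np.abs(hilbert(x - np.mean(x)))
        out[:, k] = sosfiltfilt(sos, x)
    return SignalRecord(out, record.fs, list(record.channels))


def trim_phase(phi: PhaseSeries, n_start: int, n_end: int = 0) -> PhaseSeries:
    """Drop samples from both ends (used to align channels after margins)."""
    stop = len(phi.phi) - n_end if n_end else None
    return PhaseSeries(phi.phi[n_start:stop], phi.dt, label=phi.label)


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_signals_csv(path, fs: float, sep: str = ",") -> SignalRecord:
    """Read a delimited file (header row of channel labels) as signals."""
    df = pd.read_csv(path, sep=sep)
    return SignalRecord(df.to_numpy(dtype=float), fs, list(df.columns))


def write_phases_csv(path, series, sep: str = ",") -> None:
    """Write one or more phase series as columns time_s, phi_rad_<label>."""
    if isinstance(series, PhaseSeries):
        series = [series]
    n = len(series[0].phi)
    dt = series[0].dt
    for s in series:
        if len(s.phi) != n or not np.isclose(s.dt, dt):
            raise ValueError("all series must share length and dt")
    data = {"time_s": np.arange(n) * dt}
    for k, s in enumerate(series):
        label = s.label or f"ch{k}"
        data[f"phi_rad_{label}"] = s.phi
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def read_phases_csv(path, sep: str = ","):
    """Read phase series written by :func:`write_phases_csv`."""
    df = pd.read_csv(path, sep=sep)
    t = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(t)))
    out = []
    for col in df.columns:
        if col == "time_s":
            continue
        label = col[len("phi_rad_"):] if col.startswith("phi_rad_") else col
        out.append(PhaseSeries(df[col].to_numpy(dtype=float), dt, label=label))
    return out
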