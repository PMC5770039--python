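import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from phasekit import (
    DensityMap,
    PhaseSeries,
    SignalRecord,
    analytic_protophase,
    bandpass_and_envelope,
    estimate_density,
    phase_velocity,
    protophase_to_phase,
    shift_zero_phase,
)
from phasekit.phases import read_phases_csv, write_phases_csv

TWO_PI = 2 * np.pi


def _tone(f=5.0, fs=500.0, duration=10.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalRecord(amp * np.cos(TWO_PI * f * t), fs, ["s"]), t


class TestAnalyticProtophase:
    def test_cosine_advances_at_carrier_frequency(self):
        record, _ = _tone(f=5.0)
        proto = analytic_protophase(record, "s")
        inst_f = np.diff(np.unwrap(proto.theta)) / (TWO_PI * record.dt)
        assert np.mean(inst_f) == pytest.approx(5.0, rel=1e-3)

    def test_scale_invariance_of_angle_and_envelope(self):
        r1, _ = _tone(amp=1.0)
        r3, _ = _tone(amp=3.0)
        p1 = analytic_protophase(r1, "s")
        p3 = analytic_protophase(r3, "s")
        # compare as angles (values may sit on either side of the 0/2pi seam)
        assert np.allclose(
            np.angle(np.exp(1j * (p1.theta - p3.theta))), 0.0, atol=1e-9
        )
        assert np.median(p3.amplitude) == pytest.approx(3.0, rel=1e-2)

    def test_constant_signal_rejected(self):
        record = SignalRecord(np.ones(100), 100.0, ["s"])
        with pytest.raises(ValueError, match="no oscillation"):
            analytic_protophase(record, "s")

    def test_nan_rejected(self):
        x = np.sin(np.linspace(0, 20, 200))
        x[50] = np.nan
        with pytest.raises(ValueError, match="finite"):
            analytic_protophase(SignalRecord(x, 100.0, ["s"]), "s")

    def test_zero_protophase_marks_signal_peaks(self, vdp_traj):
        # Hilbert zero-phase reference points sit near the x1 maxima
        record = vdp_traj.to_record()
        proto = analytic_protophase(record, "x1")
        x = record.channel("x1")
        x = x[len(x) // 2:]
        theta = proto.theta[len(proto.theta) - len(x):]
        near_zero = np.abs(np.angle(np.exp(1j * theta))) < 0.05
        assert np.all(x[near_zero] > 0.5 * x.max())


class TestDensity:
    def test_uniform_protophase_gives_flat_density(self):
        theta = np.linspace(0, TWO_PI, 10_000, endpoint=False)
        dm = estimate_density(theta, n_harmonics=5)
        assert np.all(np.abs(dm.coef_cos) < 1e-10)
        assert np.all(np.abs(dm.coef_sin) < 1e-10)

    def test_cosine_perturbed_density_recovers_harmonic(self):
        # rejection sampling from f(theta) = (1 + 0.5 cos theta) / 2pi
        rng = np.random.default_rng(7)
        theta = []
        while len(theta) < 100_000:
            cand = rng.uniform(0, TWO_PI, 200_000)
            keep = rng.uniform(0, 1.5, 200_000) < 1 + 0.5 * np.cos(cand)
            theta.extend(cand[keep])
        theta = np.asarray(theta[:100_000])
        dm = estimate_density(theta, n_harmonics=8)
        # relative first cosine harmonic of f is 2*<cos theta> = 0.5
        assert 2 * dm.coef_cos[0] == pytest.approx(0.5, abs=0.02)
        # density curve matches a histogram oracle
        grid = dm.grid()
        f = dm.density()
        hist, edges = np.histogram(theta, bins=64, range=(0, TWO_PI), density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        assert np.max(np.abs(np.interp(centers, grid, f) - hist)) < 0.02

    def test_vdp_density_positive_and_matches_histogram(self, vdp_traj):
        proto = analytic_protophase(vdp_traj.to_record(), "x1")
        dm = estimate_density(proto, n_harmonics=10)
        f = dm.density()
        assert np.all(f > 0)
        hist, edges = np.histogram(
            proto.theta, bins=64, range=(0, TWO_PI), density=True
        )
        centers = 0.5 * (edges[1:] + edges[:-1])
        l1 = np.mean(np.abs(np.interp(centers, dm.grid(), f) - hist)) * TWO_PI
        assert l1 < 0.15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_density(np.array([]))


class TestProtophaseToPhase:
    def test_uniform_density_is_identity(self):
        dm = DensityMap(np.zeros(5), np.zeros(5))
        theta, phi = dm.phase_map()
        assert np.allclose(phi, theta, atol=1e-9)

    def test_cosine_density_closed_form(self):
        # f = (1 + 0.5 cos)/2pi  =>  phi(theta) = theta + 0.5 sin(theta)
        dm = DensityMap(np.array([0.25]), np.array([0.0]))
        theta, phi = dm.phase_map()
        assert np.allclose(phi, theta + 0.5 * np.sin(theta), atol=1e-5)
        # independent quadrature oracle at a few points
        for th in (0.7, 2.0, 5.5):
            oracle = TWO_PI * quad(
                lambda u: (1 + 0.5 * np.cos(u)) / TWO_PI, 0, th
            )[0]
            assert np.interp(th, theta, phi) == pytest.approx(oracle, abs=1e-5)

    def test_winding_number_preserved(self):
        rng = np.random.default_rng(0)
        raw = np.cumsum(rng.uniform(0.0, 0.2, 5000))
        proto = _as_proto(raw)
        dm = DensityMap(np.array([0.2, -0.1]), np.array([0.05, 0.0]))
        phi = protophase_to_phase(proto, dm)
        turns_theta = np.floor(raw[-1] / TWO_PI) - np.floor(raw[0] / TWO_PI)
        turns_phi = np.floor(phi.phi[-1] / TWO_PI) - np.floor(phi.phi[0] / TWO_PI)
        assert turns_phi == turns_theta

    def test_uniformization_on_circuit_data(self, vdp_traj):
        proto = analytic_protophase(vdp_traj.to_record(), "x1")
        dm = estimate_density(proto, n_harmonics=10)
        phi = protophase_to_phase(proto, dm)
        ks_theta = kstest(proto.theta / TWO_PI, "uniform").statistic
        ks_phi = kstest(np.mod(phi.phi, TWO_PI) / TWO_PI, "uniform").statistic
        assert ks_phi < ks_theta


def _as_proto(raw_theta):
    from phasekit import ProtophaseSeries

    return ProtophaseSeries(
        np.mod(raw_theta, TWO_PI), np.ones_like(raw_theta), 0.01
    )


class TestShiftAndVelocity:
    def test_zero_offset_is_identity(self):
        phi = PhaseSeries(np.linspace(0, 10, 50), 0.1)
        assert np.allclose(shift_zero_phase(phi, 0.0).phi, phi.phi)

    def test_full_turn_leaves_wrapped_values_unchanged(self):
        phi = PhaseSeries(np.linspace(0, 10, 50), 0.1)
        shifted = shift_zero_phase(phi, TWO_PI)
        assert np.allclose(shifted.wrapped, phi.wrapped, atol=1e-12)

    def test_linear_phase_gives_constant_velocity(self):
        omega = 2.1
        t = np.arange(0, 5, 0.01)
        v = phase_velocity(PhaseSeries(omega * t, 0.01))
        assert v.shape == (len(t) - 1,)
        assert np.allclose(v, omega)

    def test_velocity_inverts_cumulative_sum(self):
        rng = np.random.default_rng(3)
        v_true = rng.normal(2.0, 0.5, 999)
        phi = PhaseSeries(np.concatenate([[0.0], np.cumsum(v_true * 0.01)]), 0.01)
        assert np.allclose(phase_velocity(phi), v_true, atol=1e-10)


class TestBandpassAndEnvelope:
    def test_passband_tone_attenuation_below_5_percent(self):
        record, _ = _tone(f=4.5, fs=500.0, duration=20.0)
        out = bandpass_and_envelope(record, 3.0, 6.0, mode="band")
        x = out.channel("s")[2000:-2000]
        assert np.max(np.abs(x)) > 0.95

    def test_envelope_recovers_slow_modulation(self):
        fs = 2000.0
        t = np.arange(int(20 * fs)) / fs
        a = 1.0 + 0.5 * np.cos(TWO_PI * 2.0 * t)
        record = SignalRecord(a * np.cos(TWO_PI * 100.0 * t), fs, ["am"])
        out = bandpass_and_envelope(record, 1.0, 4.0, mode="envelope")
        x = out.channel("am")[4000:-4000]
        oracle = 0.5 * np.cos(TWO_PI * 2.0 * t)[4000:-4000]  # bandpassed envelope
        assert np.sqrt(np.mean((x - oracle) ** 2)) < 0.05

    def test_invalid_band_rejected(self):
        record, _ = _tone()
        with pytest.raises(ValueError, match="invalid band"):
            bandpass_and_envelope(record, 6.0, 3.0)
        with pytest.raises(ValueError, match="invalid band"):
            bandpass_and_envelope(record, 3.0, 400.0)


def test_phase_csv_round_trip(tmp_path):
    phi = [
        PhaseSeries(np.linspace(0, 9, 100), 0.1, label="a"),
        PhaseSeries(np.linspace(1, 22, 100), 0.1, label="b"),
    ]
    path = tmp_path / "phases.csv"
    write_phases_csv(path, phi)
    back = read_phases_csv(path)
    assert [s.label for s in back] == ["a", "b"]
    for orig, rec in zip(phi, back):
        assert np.allclose(orig.phi, rec.phi)
        assert rec.dt == pytest.approx(0.1)
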