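"""High-pass filtering, amplitude maps, percentile traces and strain."""

import numpy as np
import pytest

from vaviq.mesh import SurfaceMesh
from vaviq.series import FieldSeries
from vaviq.synthetic import make_tube
from vaviq.vibration import (
    highpass_filter,
    highpass_strain,
    percentile_trace,
    vibration_amplitude,
)

FS = 2000.0
DT = 1.0 / FS


def _series(signal: np.ndarray, n_nodes: int = 1) -> FieldSeries:
    """Scalar signal placed on the x-component of every node."""
    values = np.zeros((signal.size, n_nodes, 3))
    values[:, :, 0] = signal[:, None]
    return FieldSeries("displacement", values, DT, cycle_length=1.0)


def brickwall_highpass(signal: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    """Independent FFT zero-out oracle."""
    spec = np.fft.rfft(signal)
    freqs = np.fft.rfftfreq(signal.size, dt)
    spec[freqs < cutoff] = 0.0
    return np.fft.irfft(spec, n=signal.size)


class TestHighpassFilter:
    def test_dc_rejection(self):
        s = _series(np.full(4000, 2.5))
        out = highpass_filter(s, 25.0)
        assert np.abs(out.values).max() <= 1e-12 * 2.5

    def test_passband_identity_50hz(self):
        t = np.arange(4000) * DT
        s = _series(1.7 * np.sin(2 * np.pi * 50 * t))
        out = highpass_filter(s, 25.0)
        # ignore filter edges
        core = out.values[500:-500, 0, 0]
        assert np.abs(core).max() == pytest.approx(1.7, rel=0.01)

    def test_matches_fft_brickwall_oracle(self, rng):
        t = np.arange(6000) * DT
        x = np.sin(2 * np.pi * 5 * t) + 0.6 * np.sin(2 * np.pi * 50 * t + 1.0)
        out = highpass_filter(_series(x), 25.0).values[:, 0, 0]
        oracle = brickwall_highpass(x, DT, 25.0)
        sl = slice(500, -500)
        rms_err = np.sqrt(np.mean((out[sl] - oracle[sl]) ** 2))
        rms_ref = np.sqrt(np.mean(oracle[sl] ** 2))
        assert rms_err / rms_ref <= 0.02

    def test_linearity(self, rng):
        x = rng.normal(size=4000)
        y = rng.normal(size=4000)
        f = lambda sig: highpass_filter(_series(sig), 25.0).values[:, 0, 0]
        np.testing.assert_allclose(
            f(2.0 * x + 3.0 * y), 2.0 * f(x) + 3.0 * f(y), atol=1e-10
        )

    def test_energy_never_amplified(self, rng):
        x = rng.normal(size=4000)
        out = highpass_filter(_series(x), 25.0).values[:, 0, 0]
        assert np.sqrt(np.mean(out**2)) <= np.sqrt(np.mean(x**2)) * (1 + 1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            # 0.1 s of data cannot support a 25 Hz high-pass
            highpass_filter(
                FieldSeries("displacement", np.zeros((200, 1, 3)), DT, 0.1), 25.0
            )


class TestVibrationAmplitude:
    def test_zero_field(self):
        amp, mags = vibration_amplitude(_series(np.zeros(2000)))
        assert np.all(amp == 0)

    def test_sinusoid_mean_magnitude_is_2A_over_pi(self):
        # closed form: mean |A sin| = 2A/pi
        t = np.arange(2000) * DT
        A_mm = 0.004
        amp, _ = vibration_amplitude(_series(A_mm * np.sin(2 * np.pi * 50 * t)))
        # 5e-3 covers the discrete-sampling bias of mean |sin| at 40
        # samples per period
        assert amp[0] == pytest.approx(2 * (A_mm * 1000) / np.pi, rel=5e-3)

    def test_non_integer_cycles_warns_and_truncates(self):
        t = np.arange(2500) * DT  # 1.25 cycles
        sig = np.sin(2 * np.pi * 50 * t)
        with pytest.warns(UserWarning, match="non-integer"):
            amp, _ = vibration_amplitude(_series(sig))
        amp_full, _ = vibration_amplitude(_series(sig[:2000]))
        assert amp[0] == pytest.approx(amp_full[0])


class TestPercentileTrace:
    def test_constant_field(self):
        mags = np.full((5, 40), 3.3)
        np.testing.assert_allclose(percentile_trace(mags, 99), 3.3)

    def test_type6_interpolation_oracle(self):
        # brute-force exclusive plotting positions: pos = q/100*(n+1)
        mags = np.arange(1.0, 101.0)[None, :]
        assert percentile_trace(mags, 99)[0] == pytest.approx(99.99)

        def oracle(values, q):
            x = np.sort(values)
            pos = q / 100 * (len(x) + 1)
            lo = int(np.floor(pos)) - 1
            if lo < 0:
                return x[0]
            if lo >= len(x) - 1:
                return x[-1]
            return x[lo] + (pos - np.floor(pos)) * (x[lo + 1] - x[lo])

        rng = np.random.default_rng(5)
        vals = rng.normal(size=(3, 57))
        for q in (10, 50, 90, 99):
            np.testing.assert_allclose(
                percentile_trace(vals, q),
                [oracle(v, q) for v in vals],
                rtol=1e-12,
            )

    def test_q100_is_max(self, rng):
        mags = rng.random((4, 30))
        np.testing.assert_allclose(percentile_trace(mags, 100), mags.max(axis=1))

    def test_empty_nodes_rejected(self):
        with pytest.raises(ValueError):
            percentile_trace(np.zeros((5, 0)), 99)


class TestHighpassStrain:
    def test_rigid_translation_strain_free(self, small_tube):
        mesh, _ = small_tube
        values = np.tile(np.array([0.3, -0.2, 0.5]), (100, mesh.n_nodes, 1))
        s = FieldSeries("displacement", values, 0.01, 1.0)
        assert np.abs(highpass_strain(mesh, s)).max() <= 1e-12

    def test_rigid_rotation_second_order(self, small_tube):
        # small rotation theta about z: strain exactly 0 for Green-Lagrange,
        # tiny numerically
        mesh, _ = small_tube
        theta = 1e-3
        c, s_ = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s_, 0], [s_, c, 0], [0, 0, 1]])
        disp = mesh.node_coords @ R.T - mesh.node_coords
        values = np.tile(disp, (100, 1, 1))
        strain = highpass_strain(
            mesh, FieldSeries("displacement", values, 0.01, 1.0)
        )
        assert np.abs(strain).max() <= 1e-10

    @pytest.mark.parametrize("n_circ", [16, 48])
    def test_uniform_inflation_matches_hoop_closed_form(self, n_circ):
        # radial inflation by stretch lambda: E_hoop = (lambda^2 - 1)/2
        lam = 1.002
        mesh, _ = make_tube(3.0, 20.0, n_axial=15, n_circ=n_circ)
        disp = (lam - 1.0) * mesh.node_coords.copy()
        disp[:, 2] = 0.0
        values = np.tile(disp, (50, 1, 1))
        strain = highpass_strain(mesh, FieldSeries("displacement", values, 0.02, 1.0))
        expected = (lam**2 - 1) / 2
        interior = np.abs(strain - expected) / expected
        assert np.median(interior) <= 1e-6

    def test_node_count_mismatch(self, small_tube):
        mesh, _ = small_tube
        with pytest.raises(ValueError, match="mismatch"):
            highpass_strain(
                mesh, FieldSeries("displacement", np.zeros((10, 5, 3)), 0.1, 1.0)
            )
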