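"""Wall-shear indices, Q-criterion and index-vibration correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from vaviq.hemodynamics import osi, q_criterion, tawss, wss_spi
from vaviq.series import FieldSeries, VelocityGradientSeries
from vaviq.stats import IndexCorrelationModel, correlate_indices
from vaviq.synthetic import generate_traction_series, generate_velocity_gradients, make_tube

DT = 1e-3


def _traction(values):
    return FieldSeries("wall_traction", values, DT, cycle_length=values.shape[0] * DT)


class TestShearIndices:
    def test_constant_traction(self):
        v = np.tile(np.array([0.9, 1.2, 0.0]), (1000, 4, 1))  # |tau| = 1.5
        assert tawss(_traction(v)) == pytest.approx(np.full(4, 1.5))
        assert osi(_traction(v)) == pytest.approx(np.zeros(4), abs=1e-12)

    def test_sinusoid_tawss_and_full_reversal_osi(self):
        t = np.arange(1000) * DT
        tau0 = 2.0
        v = np.zeros((1000, 2, 3))
        v[:, :, 0] = tau0 * np.sin(2 * np.pi * t)[:, None]
        assert tawss(_traction(v))[0] == pytest.approx(2 * tau0 / np.pi, rel=1e-3)
        assert osi(_traction(v))[0] == pytest.approx(0.5, abs=1e-3)

    def test_zero_field(self):
        v = np.zeros((100, 3, 3))
        assert np.all(tawss(_traction(v)) == 0)
        assert np.all(osi(_traction(v)) == 0)

    def test_asymmetric_reversal_hand_integral(self):
        # half cycle at +2, half at -1: OSI = 0.5*(1 - |2-1|/(2+1)) = 1/3
        v = np.zeros((1000, 1, 3))
        v[:500, 0, 0] = 2.0
        v[500:, 0, 0] = -1.0
        assert osi(_traction(v))[0] == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_rigid_rotation_invariance(self, rng):
        v = rng.normal(size=(400, 5, 3))
        theta = 0.9
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        np.testing.assert_allclose(tawss(_traction(v)), tawss(_traction(v @ R.T)), rtol=1e-12)
        np.testing.assert_allclose(osi(_traction(v)), osi(_traction(v @ R.T)), rtol=1e-9, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        hnp.arrays(
            float,
            (40, 3, 3),
            elements=hst.floats(-100, 100, allow_nan=False),
        )
    )
    def test_osi_bounds_arbitrary_traction(self, values):
        out = osi(FieldSeries("wall_traction", values, DT, cycle_length=40 * DT))
        assert np.all(out >= 0.0) and np.all(out <= 0.5)


class TestQCriterion:
    def test_solid_rotation_positive_omega_squared(self):
        q = q_criterion(generate_velocity_gradients("solid_rotation", 3.0))
        assert q == pytest.approx(np.full((1, 4), 9.0))

    def test_simple_shear_zero(self):
        q = q_criterion(generate_velocity_gradients("simple_shear", 5.0))
        assert q == pytest.approx(np.zeros((1, 4)), abs=1e-12)

    def test_pure_extension_negative(self):
        q = q_criterion(generate_velocity_gradients("pure_extension", 2.0))
        assert q == pytest.approx(np.full((1, 4), -4.0))

    def test_frame_invariance(self, rng):
        g = rng.normal(size=(3, 6, 3, 3))
        grads = VelocityGradientSeries(g, np.zeros((6, 3)))
        # orthogonal frame change: grad' = R grad R^T
        theta = 0.4
        R = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        rotated = VelocityGradientSeries(
            np.einsum("ij,tpjk,lk->tpil", R, g, R), np.zeros((6, 3))
        )
        np.testing.assert_allclose(q_criterion(grads), q_criterion(rotated), rtol=1e-10)

    def test_unknown_regime(self):
        with pytest.raises(ValueError, match="unknown regime"):
            generate_velocity_gradients("vortex", 1.0)


class TestTractionRegimes:
    def test_steady(self, small_tube):
        mesh, _ = small_tube
        s = generate_traction_series(mesh, "steady", magnitude_pa=1.5, dt=1e-3, n_cycles=2)
        assert tawss(s)[0] == pytest.approx(1.5)
        assert osi(s)[0] == pytest.approx(0.0, abs=1e-12)

    def test_oscillatory_reversal_limit(self, small_tube):
        mesh, _ = small_tube
        s = generate_traction_series(mesh, "oscillatory", dt=1e-3, n_cycles=2)
        assert osi(s)[0] == pytest.approx(0.5, abs=1e-3)

    def test_turbulent_like_spi_parseval(self, small_tube):
        # 30% of the mean-removed power placed above the cutoff by
        # construction; SPI of the magnitude signal must recover it
        mesh, _ = small_tube
        s = generate_traction_series(
            mesh, "turbulent_like", dt=5e-4, n_cycles=3, seed=4, hf_power_frac=0.3,
            magnitude_pa=3.0,
        )
        val = wss_spi(s, 25.0)[0]
        assert val == pytest.approx(0.3, abs=0.02)

    def test_unknown_regime(self, small_tube):
        mesh, _ = small_tube
        with pytest.raises(ValueError, match="unknown regime"):
            generate_traction_series(mesh, "laminar-ish")


def _corr_table(metric_values, patient_ids, metric_name):
    rows = []
    counter = {}
    for v, p in zip(metric_values, patient_ids):
        k = counter.get(p, 0)
        counter[p] = k + 1
        rows.append(
            {
                "patient_id": p,
                "group_label": "g",
                "slice_index": k,
                "arclength_mm": k + 0.5,
                "metric_name": metric_name,
                "mean_value": v,
            }
        )
    return pd.DataFrame(rows)


class TestIndexCorrelation:
    def test_exact_affine_relation_gives_R_one(self):
        rng = np.random.default_rng(0)
        patients = np.repeat([f"P{i}" for i in range(4)], 25)
        x = rng.random(100)
        offsets = np.repeat([0.0, 1.0, -0.5, 2.0], 25)
        y = 3.0 * x + offsets + 5.0
        res = IndexCorrelationModel(x, y, patients).fit()
        assert res.conditional_R == pytest.approx(1.0, abs=1e-4)
        assert res.slope == pytest.approx(3.0, abs=1e-4)

    def test_null_slope_rarely_significant(self):
        # independent covariate: nominal-level false positives only
        reject = 0
        n_rep = 200
        rng = np.random.default_rng(42)
        patients = np.repeat([f"P{i}" for i in range(6)], 25)
        offs = {f"P{i}": o for i, o in enumerate(rng.normal(0, 1, 6))}
        for _ in range(n_rep):
            x = rng.random(150)
            y = rng.normal(0, 1, 150) + np.array([offs[p] for p in patients])
            res = IndexCorrelationModel(x, y, patients).fit()
            reject += res.p_value < 0.05
        assert reject / n_rep <= 0.10

    def test_recovers_generating_conditional_correlation(self):
        # y = b x + u_patient + e with known variance budget
        b, su, se = 1.0, 0.8, 0.6
        r_true = np.sqrt(
            (b**2 * 1.0 + su**2) / (b**2 * 1.0 + su**2 + se**2)
        )
        rng = np.random.default_rng(7)
        rs = []
        patients = np.repeat([f"P{i}" for i in range(6)], 25)
        for _ in range(50):
            x = rng.normal(0, 1.0, 150)
            u = rng.normal(0, su, 6)
            y = b * x + np.repeat(u, 25) + rng.normal(0, se, 150)
            rs.append(IndexCorrelationModel(x, y, patients).fit().conditional_R)
        assert abs(np.mean(rs) - r_true) <= 0.1

    def test_refuses_single_patient(self):
        with pytest.raises(ValueError, match="< 2 patients"):
            IndexCorrelationModel(np.ones(10), np.ones(10), np.repeat("P1", 10))

    def test_correlate_indices_table_api(self):
        rng = np.random.default_rng(1)
        patients = np.repeat(["P1", "P2", "P3"], 25)
        x = rng.random(75)
        wss = _corr_table(x, patients, "spi")
        vib = _corr_table(2.0 + 4.0 * x, patients, "amp_um")
        out = correlate_indices(
            wss, vib, index_names=("spi",), vib_names=("amp_um",)
        )
        assert len(out) == 1
        assert out.loc[0, "conditional_R"] == pytest.approx(1.0, abs=1e-4)
        out_log = correlate_indices(
            wss, vib, log_transform=True, index_names=("spi",), vib_names=("amp_um",)
        )
        assert bool(out_log.loc[0, "log10_transformed"]) is True
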