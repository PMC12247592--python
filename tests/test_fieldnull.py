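"""Field model fitting, RMS-on-sphere closed form, and coil nulling."""

import numpy as np
import pytest

from megeeg import (
    CoilCalibration,
    FieldModel,
    SphereSpec,
    fit_field_model,
    generate_fieldmap_session,
    meg_layout,
    nulling_cycle,
    rms_on_sphere,
    rms_on_sphere_montecarlo,
    solve_null_currents,
)
from megeeg.fieldnull import _design_matrix, rigid_transform_geometry
from megeeg.io_bundle import MotionTrace


def random_model(rng):
    return FieldModel.from_params(rng.standard_normal(8) * [3, 3, 3, 5, 5, 5, 5, 5])


class TestFieldModel:
    def test_param_round_trip(self):
        rng = np.random.default_rng(0)
        p = rng.standard_normal(8)
        m = FieldModel.from_params(p)
        np.testing.assert_allclose(m.to_params(), p, atol=1e-14)

    def test_gradient_symmetric_traceless(self):
        m = FieldModel.from_params([0, 0, 0, 1.0, -2.0, 0.5, 0.3, 0.7])
        assert np.allclose(m.G, m.G.T)
        assert abs(np.trace(m.G)) < 1e-12

    def test_asymmetric_gradient_rejected(self):
        G = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            FieldModel(G=G)


class TestFitFieldModel:
    def test_noiseless_exact_recovery(self):
        """Inverse crime: simulated data refit to < 1e-6 relative error."""
        rng = np.random.default_rng(1)
        truth = random_model(rng)
        geom = meg_layout(8)
        opm, motion = generate_fieldmap_session(
            truth, geometry=geom, noise=0.0, duration=20.0, seed=3
        )
        fitted, resid = fit_field_model(opm, motion, geom)
        scale = np.abs(truth.to_params()).max()
        assert np.abs(fitted.to_params() - truth.to_params()).max() < 1e-6 * scale
        assert resid < 1e-9 * scale

    def test_static_head_recovers_b0_with_warning(self):
        import warnings

        geom = meg_layout(4)
        truth = FieldModel(B0=np.array([2.0, -1.0, 0.5]))
        n = 100
        motion = MotionTrace(fs_motion=120.0, position=np.zeros((n, 3)))
        N = np.stack([c.orientation for c in geom])
        opm = np.tile((N @ truth.B0)[:, None], (1, n))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            fitted, _ = fit_field_model(opm, motion, geom)
        assert any("static" in str(x.message) for x in rec)
        np.testing.assert_allclose(fitted.B0, truth.B0, atol=1e-9)
        assert np.allclose(fitted.G, 0.0)

    def test_linearity_in_field(self):
        rng = np.random.default_rng(2)
        truth = random_model(rng)
        geom = meg_layout(6)
        opm, motion = generate_fieldmap_session(
            truth, geometry=geom, noise=0.0, duration=10.0, seed=4
        )
        f1, _ = fit_field_model(opm, motion, geom)
        f2, _ = fit_field_model(2.0 * opm, motion, geom)
        np.testing.assert_allclose(f2.to_params(), 2.0 * f1.to_params(),
                                   rtol=1e-9)

    def test_residual_orthogonal_to_design(self):
        """The fit is the pseudoinverse solution."""
        rng = np.random.default_rng(3)
        truth = random_model(rng)
        geom = meg_layout(6)
        opm, motion = generate_fieldmap_session(
            truth, geometry=geom, noise=0.05, duration=10.0, seed=5
        )
        fitted, _ = fit_field_model(opm, motion, geom)
        positions = np.stack([c.position for c in geom])
        orientations = np.stack([c.orientation for c in geom])
        x_room, n_room = rigid_transform_geometry(motion, positions,
                                                  orientations)
        A = _design_matrix(x_room, n_room)
        resid = opm.T.reshape(-1) - A @ fitted.to_params()
        proj = A.T @ resid
        assert np.abs(proj).max() < 1e-9 * np.abs(A.T @ opm.T.reshape(-1)).max()

    def test_noisy_recovery_within_three_se(self):
        """10 pT sensor noise: errors behave like a well-calibrated
        least-squares estimator across seeds."""
        rng = np.random.default_rng(6)
        truth = random_model(rng)
        geom = meg_layout(8)
        errs = []
        for seed in range(60):
            opm, motion = generate_fieldmap_session(
                truth, geometry=geom, noise=0.01, duration=20.0, seed=seed
            )
            fitted, _ = fit_field_model(opm, motion, geom)
            errs.append(fitted.to_params() - truth.to_params())
        errs = np.asarray(errs)
        se = errs.std(axis=0)
        # bias much smaller than the spread
        assert np.all(np.abs(errs.mean(axis=0)) < 3.0 * se / np.sqrt(60))
        # per-seed errors nearly always inside 3 SE
        frac = np.mean(np.abs(errs) < 3.0 * se[None, :])
        assert frac >= 0.97

    def test_mismatched_motion_length(self):
        geom = meg_layout(4)
        motion = MotionTrace(fs_motion=120.0, position=np.zeros((10, 3)))
        with pytest.raises(ValueError, match="sample-for-sample"):
            fit_field_model(np.zeros((8, 5)), motion, geom)


class TestRmsOnSphere:
    def test_uniform_field_only(self):
        m = FieldModel(B0=np.array([3.0, 0.0, 4.0]))
        assert rms_on_sphere(m) == pytest.approx(5.0)

    def test_radius_zero_limit(self):
        rng = np.random.default_rng(7)
        m = random_model(rng)
        small = rms_on_sphere(m, SphereSpec(radius=1e-9))
        assert small == pytest.approx(np.linalg.norm(m.B0), rel=1e-9)

    def test_gradient_only_matches_montecarlo(self):
        m = FieldModel.from_params([0, 0, 0, 2.0, -1.0, 0.5, 1.5, 0.8])
        sphere = SphereSpec(radius=0.25)
        closed = rms_on_sphere(m, sphere)
        mc = rms_on_sphere_montecarlo(m, sphere, n_points=1_000_000, seed=1)
        assert abs(closed - mc) / mc < 1e-3

    def test_offcentre_sphere(self):
        m = FieldModel.from_params([1.0, 0.5, -0.3, 2.0, 1.0, 0.4, 0.2, 0.9])
        sphere = SphereSpec(radius=0.2, centre=np.array([0.05, -0.02, 0.1]))
        closed = rms_on_sphere(m, sphere)
        mc = rms_on_sphere_montecarlo(m, sphere, n_points=500_000, seed=2)
        assert abs(closed - mc) / mc < 2e-3


class TestSolveNullCurrents:
    def test_ideal_basis_exact_null(self):
        rng = np.random.default_rng(8)
        m = random_model(rng)
        currents, resid = solve_null_currents(m, CoilCalibration.ideal())
        assert rms_on_sphere(resid) < 1e-9
        np.testing.assert_allclose(currents, -m.to_params(), atol=1e-12)

    def test_uniform_only_calibration_leaves_gradient(self):
        """Closed form of the unnullable part: R ||G||_F / sqrt(3)."""
        m = FieldModel.from_params([2.0, -1.0, 3.0, 1.0, 0.5, 0.2, 0.8, 0.4])
        cal = CoilCalibration(np.vstack([np.eye(3), np.zeros((5, 3))]))
        _, resid = solve_null_currents(m, cal)
        R = 0.25
        expected = R * np.sqrt(np.sum(m.G**2)) / np.sqrt(3.0)
        assert rms_on_sphere(resid, SphereSpec(radius=R)) == pytest.approx(
            expected, rel=1e-9
        )

    def test_currents_linear_in_field(self):
        rng = np.random.default_rng(9)
        m = random_model(rng)
        cal = CoilCalibration.window_coils(27, seed=1)
        c1, _ = solve_null_currents(m, cal)
        c2, _ = solve_null_currents(FieldModel.from_params(3 * m.to_params()),
                                    cal)
        np.testing.assert_allclose(c2, 3 * c1, rtol=1e-9)

    def test_ill_conditioned_rejected(self):
        mat = np.zeros((8, 4))
        mat[0] = [1.0, 1.0, 1.0, 1.0]
        mat[1] = [1.0, 1.0, 1.0, 1.0 + 1e-12]
        with pytest.raises(ValueError, match="ill-conditioned"):
            solve_null_currents(FieldModel(B0=np.ones(3)),
                                CoilCalibration(mat))


class TestNullingCycle:
    def test_ideal_noiseless_one_shot(self):
        rng = np.random.default_rng(10)
        m = random_model(rng)
        steps = nulling_cycle(
            m, meg_layout(6), CoilCalibration.ideal(), iterations=1,
            noise=0.0, seed=0,
        )
        assert steps[-1].rms_after < 1e-9

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            nulling_cycle(FieldModel(), meg_layout(4),
                          CoilCalibration.ideal(), iterations=0)

    def test_rms_trajectory_decreases(self):
        from megeeg import default_remnant_field

        rng = np.random.default_rng(11)
        cal = CoilCalibration.window_coils(27, seed=3)
        true_cal = CoilCalibration(
            cal.matrix * (1 + 0.05 * rng.standard_normal(cal.matrix.shape))
        )
        steps = nulling_cycle(
            default_remnant_field(), meg_layout(6), cal, iterations=2,
            true_cal=true_cal, seed=1,
        )
        assert steps[0].rms_after < steps[0].rms_before
        assert steps[1].rms_after <= steps[0].rms_after
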