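"""End-to-end pipeline: evaluation points, determinism, extension,
coordinate comparison, and the circular-well consistency properties."""

import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.stats import spearmanr

import tmrc
from conftest import BETA

SEVEN_MINIMA_ANGLES = (2 * np.arange(7) + 1) * np.pi / 7  # cos(7 theta) = -1


@pytest.fixture(scope="module")
def sw_field():
    """Seven-well pipeline on the 40x40 grid, lag 0.1, two components."""
    cfg = tmrc.PipelineConfig(
        potential="circular_well", potential_params={"k": 7},
        beta=BETA, lag=0.1, dt=1e-3, M=300, r=1, r_out=2,
        eval_points={
            "mode": "grid", "lower": [-2, -2], "upper": [2, 2], "counts": [40, 40],
        },
        observables={
            "mode": "explicit",
            "coefficients": tmrc.DOUBLE_WELL_COEFFICIENTS.tolist(),
        },
        seed=5,
    )
    return tmrc.compute_rc(cfg)


class TestEvalPoints:
    def test_grid_includes_corners(self, dw_grid_config):
        pts = tmrc.generate_eval_points(dw_grid_config)
        assert pts.shape == (1200, 2)
        for corner in ([-2, -1], [-2, 2], [2, -1], [2, 2]):
            assert np.any(np.all(pts == corner, axis=1))

    def test_two_by_two_grid(self):
        cfg = tmrc.PipelineConfig(
            potential="harmonic", potential_params={"dimension": 2},
            beta=1.0, lag=0.1, dt=1e-2, M=1, r=0,
            eval_points={"mode": "grid", "lower": [0, 0], "upper": [1, 1],
                         "counts": [2, 2]},
        )
        pts = tmrc.generate_eval_points(cfg)
        assert sorted(map(tuple, pts)) == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_subsample_reproducible(self):
        cfg = tmrc.PipelineConfig(
            potential="harmonic", potential_params={"dimension": 1},
            beta=1.0, lag=0.1, dt=1e-2, M=1, r=0,
            eval_points={"mode": "subsample", "x0": [0.0], "total_time": 10.0,
                         "stride": 0.1, "count": 20},
            seed=3,
        )
        a = tmrc.generate_eval_points(cfg)
        b = tmrc.generate_eval_points(cfg)
        assert np.array_equal(a, b)

    def test_oversized_grid_refused(self):
        cfg = tmrc.PipelineConfig(
            potential="harmonic", potential_params={"dimension": 2},
            beta=1.0, lag=0.1, dt=1e-2, M=1, r=0,
            eval_points={"mode": "grid", "lower": [0, 0], "upper": [1, 1],
                         "counts": [4000, 4000]},
        )
        with pytest.raises(tmrc.ConfigurationError):
            tmrc.generate_eval_points(cfg)


class TestComputeRc:
    def test_full_pipeline_determinism(self):
        cfg = tmrc.PipelineConfig(
            potential="double_well", beta=BETA, lag=0.1, dt=1e-2, M=20, r=1,
            eval_points={"mode": "grid", "lower": [-1.5, -0.5],
                         "upper": [1.5, 1.5], "counts": [8, 6]},
            seed=11,
        )
        a = tmrc.compute_rc(cfg)
        b = tmrc.compute_rc(cfg)
        assert np.array_equal(a.rc_values, b.rc_values)
        assert np.array_equal(a.embedded.points, b.embedded.points)

    def test_lag_zero_embeds_linearly(self):
        cfg = tmrc.PipelineConfig(
            potential="double_well", beta=BETA, lag=0.0, dt=1e-2, M=1, r=1,
            eval_points={"mode": "grid", "lower": [-1, -0.5], "upper": [1, 1.5],
                         "counts": [6, 5]},
            observables={"mode": "explicit",
                         "coefficients": tmrc.DOUBLE_WELL_COEFFICIENTS.tolist()},
            seed=2,
        )
        field = tmrc.compute_rc(cfg)
        expect = field.eval_points @ tmrc.DOUBLE_WELL_COEFFICIENTS.T
        np.testing.assert_allclose(field.embedded.points, expect, rtol=0, atol=1e-15)
        assert field.rc_values.shape == (30, 1)

    def test_rc_values_equal_psi_of_embedded(self, sw_field):
        assert np.array_equal(sw_field.rc_values, sw_field.dm_model.psi_train)
        assert sw_field.fallback_rc.shape == (1600, 3)


class TestSevenWell:
    def test_rc_nearly_constant_on_metastable_sets(self, sw_field):
        """Both components vary little inside each of the seven wells
        compared with their global variation."""
        pts = sw_field.eval_points
        global_std = sw_field.rc_values.std(axis=0)
        for theta in SEVEN_MINIMA_ANGLES:
            center = np.array([np.cos(theta), np.sin(theta)])
            mask = np.linalg.norm(pts - center, axis=1) < 0.25
            assert mask.sum() >= 4
            local_std = sw_field.rc_values[mask].std(axis=0)
            assert np.all(local_std < 0.2 * global_std)

    def test_dominant_eigenfunctions_are_functions_of_rc(self, sw_field, seven_well):
        """The seven dominant eigenfunctions vary little across rc level
        sets; the first two non-dominant ones vary strongly."""
        gen = tmrc.generator_spectrum(
            seven_well, BETA, [-2, -2], [2, 2], [40, 40], lag=0.1, m=10
        )
        v = seven_well(sw_field.eval_points)
        weights = np.exp(-BETA * (v - v.min()))
        spreads = []
        for j in range(9):
            resid = tmrc.projection_error(
                gen.eigenvectors[:, j], sw_field.rc_values, 8, weights=weights
            )
            rms = np.sqrt(np.average(gen.eigenvectors[:, j] ** 2, weights=weights))
            spreads.append(resid / rms)
        spreads = np.asarray(spreads)
        # residual relative to each eigenfunction's equilibrium-weighted rms
        assert np.all(spreads[1:7] < 0.25)
        assert np.all(spreads[7:9] > 0.5)


class TestTenDimensional:
    def test_ten_dim_rc_matches_two_dim_shape(self):
        """xi computed in R^10 and on the planar restriction of the same
        dynamics give the same reaction-coordinate cloud shape."""
        A = tmrc.draw_linear_observables(10, 1, seed=77).coefficients
        base = dict(
            beta=BETA, lag=0.1, dt=1e-3, M=400, r=1, r_out=2, seed=19,
        )
        cfg10 = tmrc.PipelineConfig(
            potential="circular_well_10d", potential_params={"k": 7},
            observables={"mode": "explicit", "coefficients": A.tolist()},
            eval_points={"mode": "subsample", "x0": [1.0] + [0.0] * 9,
                         "total_time": 1500.0, "stride": 1e-2, "count": 700},
            **base,
        )
        field10 = tmrc.compute_rc(cfg10)
        pts2 = field10.eval_points[:, :2]
        cfg2 = tmrc.PipelineConfig(
            potential="circular_well", potential_params={"k": 7},
            observables={"mode": "explicit", "coefficients": A[:, :2].tolist()},
            eval_points={"mode": "explicit", "points": pts2.tolist()},
            **base,
        )
        field2 = tmrc.compute_rc(cfg2)
        m1, m2, disparity = procrustes(field10.rc_values, field2.rc_values)
        diam = np.max(np.linalg.norm(m1[:, None] - m1[None, :], axis=-1))
        rms = np.sqrt(disparity / len(m1))
        assert rms < 0.1 * diam


class TestExtendRc:
    def test_nearest_at_eval_point_is_exact(self, sw_field):
        q = sw_field.eval_points[[10, 500]]
        vals = tmrc.extend_rc(sw_field, q, method="nearest")
        assert np.array_equal(vals, sw_field.rc_values[[10, 500]])

    def test_equidistant_tie_takes_lower_index(self):
        cfg = tmrc.PipelineConfig(
            potential="harmonic", potential_params={"dimension": 1},
            beta=1.0, lag=0.1, dt=1e-2, M=30, r=0, r_out=1,
            eval_points={"mode": "explicit", "points": [[-1.0], [0.0], [1.0], [2.0]]},
            observables={"mode": "explicit", "coefficients": [[1.0]]},
            seed=1,
        )
        field = tmrc.compute_rc(cfg)
        val = tmrc.extend_rc(field, [[0.5]], method="nearest")
        assert np.array_equal(val[0], field.rc_values[1])

    def test_nystrom_close_to_nearest(self, sw_field):
        rng = np.random.default_rng(8)
        theta = rng.uniform(0, 2 * np.pi, 40)
        radius = rng.uniform(0.8, 1.2, 40)
        q = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
        near = tmrc.extend_rc(sw_field, q, method="nearest")
        nyst = tmrc.extend_rc(sw_field, q, method="nystrom")
        span = sw_field.rc_values.max(0) - sw_field.rc_values.min(0)
        assert np.all(np.abs(near - nyst) < 0.1 * span)


class TestCompareCoordinates:
    def test_identity_coordinate_has_small_errors(self, rng):
        states = np.concatenate([[0.0, 1.0], rng.uniform(0, 1, 400)])
        traj = tmrc.Trajectory(states[:, None], 1.0,
                               tmrc.IntegratorSpec(dt=1.0, beta=1.0))
        part = tmrc.BoxPartition([0.0], [1.0], [8])
        ref = tmrc.spectrum(tmrc.ulam_full(traj, part, 1.0, symmetrize=True), 4)
        table = tmrc.compare_coordinates(
            traj, {"identity": lambda x: x[:, 0]}, 8, 1.0, 4, reference=ref
        )
        assert len(table) == 1
        assert np.all(table.filter(like="abs_err").to_numpy() < 1e-12)

    def test_table_has_requested_eigenvalues(self, rng):
        states = rng.uniform(0, 1, 300)
        traj = tmrc.Trajectory(states[:, None], 1.0,
                               tmrc.IntegratorSpec(dt=1.0, beta=1.0))
        table = tmrc.compare_coordinates(
            traj, {"a": lambda x: x[:, 0], "b": lambda x: 1 - x[:, 0]}, 6, 1.0, 3
        )
        assert list(table.index) == ["a", "b"]
        assert "lambda_2" in table.columns


class TestConfig:
    def test_unknown_and_missing_keys(self):
        with pytest.raises(tmrc.ConfigurationError):
            tmrc.PipelineConfig.from_dict({"potential": "double_well", "nope": 1})
        with pytest.raises(tmrc.ConfigurationError):
            tmrc.PipelineConfig.from_dict({"potential": "double_well"})

    def test_resolved_is_serializable(self, dw_grid_config):
        import json

        doc = json.dumps(dw_grid_config.resolved())
        assert "double_well" in doc


def test_projected_eigenvalue_bound_consistency(dw_field, dw_traj):
    """The observed slow-eigenvalue loss under projection onto xi_bar is
    within the perturbation bound built from the empirical projection
    error of the slow eigenfunction."""
    part = tmrc.BoxPartition([-2, -1], [2, 2], [40, 30])
    op = tmrc.ulam_full(dw_traj, part, 1.0, symmetrize=True)
    full = tmrc.spectrum(op, 3)
    # phi_1 on occupied cells, normalized in the occupation measure
    pi = op.occupation
    phi1 = full.eigenvectors[:, 1]
    phi1 = phi1 / np.sqrt(np.sum(pi * phi1**2))
    centers = part.centers()[op.active_cells]
    rc_cells = tmrc.extend_rc(dw_field, centers, method="nearest")
    eps = tmrc.projection_error(phi1, rc_cells, 40, weights=pi)
    bound = eps / np.sqrt(1 - min(eps, 0.99) ** 2)
    xi_traj = tmrc.extend_rc(dw_field, dw_traj.states, method="nearest")
    proj = tmrc.spectrum(
        tmrc.ulam_projected(dw_traj, xi_traj, 40, 1.0, symmetrize=True), 3
    )
    gap = abs(full.eigenvalues[1] - proj.eigenvalues[1])
    assert gap <= bound + 0.01  # slack for the Monte-Carlo noise floor


def test_double_well_embedding_monotone_in_x1(dw_field):
    """Embedded components order points along the transition direction:
    high rank correlation with x1 within horizontal slices."""
    pts = dw_field.eval_points
    z = dw_field.embedded.points
    for lo, hi in ((-0.5, 0.0), (0.0, 0.5), (0.5, 1.0)):
        mask = (pts[:, 1] >= lo) & (pts[:, 1] < hi)
        rho = spearmanr(z[mask, 0], pts[mask, 0]).statistic
        assert abs(rho) > 0.9
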