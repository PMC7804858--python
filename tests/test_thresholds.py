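"""Threshold inversion: exceedance probabilities, Z_crit solvers, ΔZ, and the
(M_crit, alpha) sensitivity surface."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from cohoprior import (
    ThresholdSpec,
    compute_delta_z,
    delta_z_table,
    exceedance_probability,
    sensitivity_grid,
    solve_z_crit,
)
from cohoprior.model import ConvergenceError
from cohoprior.synthetic import ConfigurationError
from cohoprior.thresholds import (
    PRESERVATION,
    RESTORATION,
    crossing_points,
    require_converged,
    solve_z_crit_bisection,
)
from tests.conftest import make_posterior


def type1_quantile(values, q):
    """Independent inverse-empirical-CDF quantile (smallest x with F(x) >= q)."""
    xs = np.sort(np.asarray(values))
    k = max(int(np.ceil(q * xs.size)), 1)
    return xs[k - 1]


class TestExceedance:
    def test_single_draw_step_function(self):
        post = make_posterior([0.0], 1.0)
        assert exceedance_probability(post, "T0", 1.0, 0.5) == 1.0
        assert exceedance_probability(post, "T0", -1.0, 0.5) == 0.0

    def test_two_draw_half(self):
        post = make_posterior(np.array([1.0, -1.0]), 1.0)
        assert exceedance_probability(post, "T0", 0.0, 0.5) == 0.5

    def test_tiny_m_crit_always_exceeded(self):
        post = make_posterior(np.array([0.3, -0.7, 1.2]), 1.0)
        for z in (-15.0, 0.0, 15.0):
            assert exceedance_probability(post, "T0", z, 1e-12) == 1.0

    def test_cdf_like_in_z(self):
        rng = np.random.default_rng(0)
        post = make_posterior(rng.normal(0, 2, 50), np.exp(rng.normal(0, 0.3, 50)))
        zs = np.linspace(-20, 20, 101)
        vals = [exceedance_probability(post, "T0", z, 0.3) for z in zs]
        assert vals[0] == 0.0 and vals[-1] == 1.0
        assert all(0 <= v <= 1 for v in vals)
        assert (np.diff(vals) >= 0).all()


class TestSolveZCrit:
    def test_single_draw_unique_crossing(self):
        post = make_posterior([0.0], 1.0)
        for alpha in (0.2, 0.5, 0.9):
            with pytest.warns(RuntimeWarning):
                assert solve_z_crit(post, "T0", ThresholdSpec(0.5, alpha)) == 0.0

    def test_constructed_crossing_points_quantile(self):
        # intercepts chosen so crossings at m_crit = 0.5 are {-1, 0, 1, 2}
        post = make_posterior(np.array([1.0, 0.0, -1.0, -2.0]), 1.0)
        np.testing.assert_allclose(
            np.sort(crossing_points(post, "T0", 0.5)), [-1, 0, 1, 2])
        spec = ThresholdSpec(0.5, 0.75)
        z = solve_z_crit(post, "T0", spec)
        assert z == type1_quantile([-1, 0, 1, 2], 0.25) == -1.0
        # step-function consistency at 1e-4 resolution
        assert exceedance_probability(post, "T0", z, 0.5) >= 0.25
        assert exceedance_probability(post, "T0", z - 1e-4, 0.5) < 0.25
        assert solve_z_crit_bisection(post, "T0", spec) == pytest.approx(z, abs=1e-6)

    def test_more_stringent_alpha_lowers_z_crit(self):
        rng = np.random.default_rng(1)
        post = make_posterior(rng.normal(-1, 1, 200), np.exp(rng.normal(0.3, 0.2, 200)))
        z95 = solve_z_crit(post, "T0", ThresholdSpec(0.3, 0.95))
        z80 = solve_z_crit(post, "T0", ThresholdSpec(0.3, 0.80))
        assert z95 <= z80

    def test_invalid_spec_rejected(self):
        for bad in ((0.0, 0.9), (1.0, 0.9), (0.3, 0.0), (0.3, 1.0)):
            with pytest.raises(ConfigurationError):
                ThresholdSpec(*bad)


class TestDeltaZ:
    def test_degenerate_preservation(self):
        # all crossings at 2.0, all Z_cur at 1.2 -> delta 0.8 for every alpha
        post = make_posterior(np.full(8, -2.0), 1.0,
                              z_draws=np.full((8, 1), 1.2))
        for alpha in (0.5, 0.8, 0.95):
            r = compute_delta_z(post, "T0", ThresholdSpec(0.5, alpha))
            assert r.delta_z == pytest.approx(0.8)
            assert r.category == PRESERVATION

    def test_degenerate_restoration(self):
        post = make_posterior(np.full(8, -2.0), 1.0,
                              z_draws=np.full((8, 1), 3.0))
        r = compute_delta_z(post, "T0", ThresholdSpec(0.5, 0.9))
        assert r.delta_z == pytest.approx(-1.0)
        assert r.category == RESTORATION

    def test_z_cur_quantile_rule(self):
        post = make_posterior(np.full(4, -2.0), 1.0,
                              z_draws=np.array([0.0, 1.0, 2.0, 3.0]).reshape(4, 1))
        r = compute_delta_z(post, "T0", ThresholdSpec(0.5, 0.95))
        expected_q = type1_quantile([0, 1, 2, 3], 0.95)
        assert r.z_cur_alpha_quantile == expected_q == 3.0
        assert r.delta_z == pytest.approx(2.0 - 3.0)

    def test_table_matches_scalar_path(self, posterior300):
        ids = posterior300.subbasin_ids[:25]
        spec = ThresholdSpec()
        tab = delta_z_table(posterior300, ids, spec, force=True)
        for _, row in tab.iloc[::6].iterrows():
            r = compute_delta_z(posterior300, row["subbasin_id"], spec)
            assert row["delta_z"] == pytest.approx(r.delta_z)
            assert row["category"] == r.category

    def test_partition_is_complete(self, posterior300):
        tab = delta_z_table(posterior300, posterior300.subbasin_ids,
                            ThresholdSpec(), force=True)
        n_r = (tab["category"] == RESTORATION).sum()
        n_p = (tab["category"] == PRESERVATION).sum()
        assert n_r + n_p == len(posterior300.subbasin_ids)

    def test_require_converged_gate(self):
        post = make_posterior([0.0], 1.0)
        post.converged = False
        with pytest.raises(ConvergenceError):
            require_converged(post)
        require_converged(post, force=True)  # no raise


class TestSensitivityGrid:
    def test_single_cell_matches_compute_delta_z(self, posterior300):
        sid = posterior300.subbasin_ids[3]
        grid = sensitivity_grid(posterior300, [sid], [0.3], [0.95], force=True)
        r = compute_delta_z(posterior300, sid, ThresholdSpec(0.3, 0.95))
        assert len(grid) == 1
        assert grid["delta_z"].iloc[0] == pytest.approx(r.delta_z)

    def test_delta_z_ordered_in_m_crit(self, posterior300):
        ids = posterior300.subbasin_ids[:40]
        grid = sensitivity_grid(posterior300, ids, [0.2, 0.3, 0.4], [0.95],
                                force=True)
        for _, g in grid.groupby("subbasin_id"):
            g = g.sort_values("m_crit")
            assert (np.diff(g["delta_z"]) >= 0).all()

    def test_empty_grid_rejected(self, posterior300):
        with pytest.raises(ValueError):
            sensitivity_grid(posterior300, posterior300.subbasin_ids[:2], [], [0.9])
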