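"""Raking: simplex scaling, IPF, hierarchical consistency, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthexp import synth
from healthexp.raking import (
    IPFError,
    RakeResult,
    RakingError,
    ShareDraws,
    ipf,
    max_consistency_violation,
    percentile_bounds,
    rake,
    rake_draw,
    rake_simplex,
    summarise,
)
from healthexp.taxonomy import TOTAL


def ipf_oracle(m, rows, cols, tol=1e-12, max_iter=100000):
    """Naive alternating-scaling reference, independent of the library path."""
    m = np.array(m, dtype=float)
    for _ in range(max_iter):
        for i in range(m.shape[0]):
            s = m[i].sum()
            if s > 0:
                m[i] *= rows[i] / s
        for j in range(m.shape[1]):
            s = m[:, j].sum()
            if s > 0:
                m[:, j] *= cols[j] / s
        if (
            np.abs(m.sum(axis=1) - rows).max() < tol
            and np.abs(m.sum(axis=0) - cols).max() < tol
        ):
            break
    return m


class TestRakeSimplex:
    def test_already_consistent_unchanged(self):
        np.testing.assert_allclose(
            rake_simplex([0.25, 0.25], 0.5), [0.25, 0.25], atol=1e-15
        )

    def test_proportional_scaling(self):
        np.testing.assert_allclose(
            rake_simplex([0.3, 0.3], 0.5), [0.25, 0.25], atol=1e-15
        )

    def test_ratios_preserved(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 5.0, 10)
        out = rake_simplex(v, 1.0)
        assert out.sum() == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(out / out[0], v / v[0], rtol=1e-12)

    def test_all_zero_input_rejected(self):
        with pytest.raises(RakingError, match="all-zero"):
            rake_simplex([0.0, 0.0], 1.0)

    def test_negative_rejected(self):
        with pytest.raises(RakingError):
            rake_simplex([-0.1, 0.5], 1.0)


class TestIPF:
    def test_fixed_point(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = ipf(m, m.sum(axis=1), m.sum(axis=0))
        np.testing.assert_allclose(out, m, atol=1e-9)

    def test_hand_computed_2x2(self):
        out = ipf([[1.0, 1.0], [1.0, 1.0]], [3.0, 1.0], [2.0, 2.0])
        np.testing.assert_allclose(out, [[1.5, 1.5], [0.5, 0.5]], atol=1e-9)

    def test_margin_sum_mismatch_rejected(self):
        with pytest.raises(IPFError, match="disagree"):
            ipf([[1.0, 1.0], [1.0, 1.0]], [2.0, 2.0], [2.0, 3.0])

    def test_structural_zero_infeasibility(self):
        with pytest.raises(IPFError, match="infeasible"):
            ipf([[0.0, 0.0], [1.0, 1.0]], [1.0, 1.0], [1.0, 1.0])

    def test_zero_cells_stay_zero(self):
        out = ipf([[0.0, 2.0], [3.0, 4.0]], [1.0, 3.0], [1.5, 2.5])
        assert out[0, 0] == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive_oracle_on_random_3x3(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 3.0, (3, 3))
        rows = rng.uniform(0.5, 2.0, 3)
        cols = rng.uniform(0.5, 2.0, 3)
        cols *= rows.sum() / cols.sum()
        ours = ipf(m, rows, cols, tol=1e-12)
        ref = ipf_oracle(m, rows, cols)
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_odds_ratios_preserved(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0.2, 4.0, (4, 5))
        rows = rng.uniform(0.5, 2.0, 4)
        cols = rng.uniform(0.5, 2.0, 5)
        cols *= rows.sum() / cols.sum()
        out = ipf(m, rows, cols, tol=1e-13)
        orig = (m[0, 0] * m[2, 3]) / (m[0, 3] * m[2, 0])
        new = (out[0, 0] * out[2, 3]) / (out[0, 3] * out[2, 0])
        assert new == pytest.approx(orig, rel=1e-8)

    def test_batched_matches_loop(self):
        rng = np.random.default_rng(6)
        ms = rng.uniform(0.1, 2.0, (4, 3, 3))
        rows = rng.uniform(0.5, 2.0, (4, 3))
        cols = rng.uniform(0.5, 2.0, (4, 3))
        cols *= (rows.sum(axis=1) / cols.sum(axis=1))[:, None]
        batch = ipf(ms, rows, cols, tol=1e-12)
        for k in range(4):
            np.testing.assert_allclose(
                batch[k], ipf(ms[k], rows[k], cols[k], tol=1e-12), atol=1e-9
            )


def _draw_dict(truth, i=0, rng=None, noise=0.0):
    lay = truth.layout
    sd = truth.shares
    rng = rng or np.random.default_rng(0)

    def n(x):
        return float(x) * (np.exp(rng.normal(0, noise)) if noise else 1.0)

    d = {}
    for j, c in enumerate(lay.hc_l1):
        d[(c, TOTAL)] = n(sd.hc_l1[i, 0, j])
    for j, c in enumerate(lay.hc_leaf):
        d[(c, TOTAL)] = n(sd.hc_leaf[i, 0, j])
    for j, c in enumerate(lay.hp_l1):
        d[(TOTAL, c)] = n(sd.hp_l1[i, 0, j])
    for j, c in enumerate(lay.hp_leaf):
        d[(TOTAL, c)] = n(sd.hp_leaf[i, 0, j])
    for a, ca in enumerate(lay.hc_l1):
        for b, cb in enumerate(lay.hp_l1):
            d[(ca, cb)] = n(sd.cross_l1[i, 0, a, b])
    for a, ca in enumerate(lay.hc_leaf):
        for b, cb in enumerate(lay.hp_leaf):
            d[(ca, cb)] = n(sd.cross_leaf[i, 0, a, b])
    return d


class TestRakeDraw:
    def test_consistent_draw_is_a_fixed_point(self, small_world):
        d = _draw_dict(small_world)
        out = rake_draw(d, small_world.layout.hc, small_world.layout.hp)
        for k in d:
            assert out[k] == pytest.approx(d[k], abs=1e-9)

    def test_raked_draw_satisfies_all_constraints(self, small_world):
        d = _draw_dict(small_world, noise=0.4, rng=np.random.default_rng(3))
        out = rake_draw(d, small_world.layout.hc, small_world.layout.hp)
        lay = small_world.layout
        assert sum(out[(c, TOTAL)] for c in lay.hc_l1) == pytest.approx(1.0, abs=1e-8)
        assert sum(out[(TOTAL, c)] for c in lay.hp_l1) == pytest.approx(1.0, abs=1e-8)
        for parent in lay.hc_l1:
            kids = lay.hc.children(parent)
            if kids:
                assert sum(out[(k, TOTAL)] for k in kids) == pytest.approx(
                    out[(parent, TOTAL)], abs=1e-8
                )
        for c in lay.hc_leaf:
            assert sum(out[(c, p)] for p in lay.hp_leaf) == pytest.approx(
                out[(c, TOTAL)], abs=1e-8
            )
        for p in lay.hp_leaf:
            assert sum(out[(c, p)] for c in lay.hc_leaf) == pytest.approx(
                out[(TOTAL, p)], abs=1e-8
            )

    def test_raking_preserves_interaction_structure(self, small_world):
        """Perturb only the cross cells of a consistent draw; after raking,
        the level-1 block odds ratios sit closer (in log space) to the
        perturbed draw's than to independence (log OR 0) — IPF preserves
        the interaction structure while fixing the margins."""
        rng = np.random.default_rng(9)
        d = _draw_dict(small_world)
        lay = small_world.layout
        for k in d:
            if k[0] != TOTAL and k[1] != TOTAL:
                d[k] *= float(np.exp(rng.normal(0, 0.4)))
        out = rake_draw(d, small_world.layout.hc, small_world.layout.hp)

        def log_or(t, i1, i2, j1, j2):
            a, b = lay.hc_l1[i1], lay.hc_l1[i2]
            p, q = lay.hp_l1[j1], lay.hp_l1[j2]
            return (
                np.log(t[(a, p)]) + np.log(t[(b, q)])
                - np.log(t[(a, q)]) - np.log(t[(b, p)])
            )

        closer = 0
        pairs = [(0, 1, 0, 1), (0, 2, 1, 3), (1, 3, 2, 4), (2, 4, 0, 5)]
        for i1, i2, j1, j2 in pairs:
            orig = log_or(d, i1, i2, j1, j2)
            raked = log_or(out, i1, i2, j1, j2)
            if abs(raked - orig) <= abs(raked - 0.0):
                closer += 1
        assert closer >= 3

    def test_incomplete_draw_rejected(self, small_world):
        d = _draw_dict(small_world)
        d.pop(("HC1", TOTAL))
        with pytest.raises(RakingError, match="cover"):
            rake_draw(d, small_world.layout.hc, small_world.layout.hp)


def _perturbed_draws(truth, n_draws=20, sigma=0.3, seed=9):
    rng = np.random.default_rng(seed)
    sd = truth.shares

    def p(a):
        return a * np.exp(rng.normal(0, sigma, size=(a.shape[0], n_draws) + a.shape[2:]))

    return ShareDraws(
        index=sd.index, layout=sd.layout,
        hc_l1=p(sd.hc_l1), hc_leaf=p(sd.hc_leaf), hp_l1=p(sd.hp_l1),
        hp_leaf=p(sd.hp_leaf), cross_l1=p(sd.cross_l1), cross_leaf=p(sd.cross_leaf),
    )


class TestRakeBatch:
    def test_conservation_and_nonnegativity(self, small_world):
        res = rake(_perturbed_draws(small_world))
        assert res.draw_ok.all()
        assert max_consistency_violation(res.draws) < 1e-8
        for name in ("hc_l1", "hc_leaf", "hp_l1", "hp_leaf", "cross_l1",
                     "cross_leaf"):
            assert (getattr(res.draws, name) >= 0).all()

    def test_idempotence(self, small_world):
        res = rake(_perturbed_draws(small_world))
        res2 = rake(res.draws)
        np.testing.assert_allclose(
            res2.draws.cross_leaf, res.draws.cross_leaf, atol=1e-9
        )
        np.testing.assert_allclose(res2.draws.hc_l1, res.draws.hc_l1, atol=1e-9)

    def test_get_derives_aggregates_consistently(self, small_world):
        res = rake(_perturbed_draws(small_world))
        sd = res.draws
        # level-1 margin of the cross table equals the level-1 total
        np.testing.assert_allclose(
            sd.get("HC1", TOTAL),
            sum(sd.get("HC1", p) for p in sd.layout.hp_leaf),
            atol=1e-8,
        )


class TestSummarise:
    def _result(self, truth, draws):
        return RakeResult(draws, iterations=1, max_residual=0.0,
                          draw_ok=np.ones(draws.n_draws, dtype=bool))

    def test_identical_draws_collapse(self, small_world):
        sd = small_world.shares
        tiled = ShareDraws(
            index=sd.index, layout=sd.layout,
            hc_l1=np.repeat(sd.hc_l1, 10, axis=1),
            hc_leaf=np.repeat(sd.hc_leaf, 10, axis=1),
            hp_l1=np.repeat(sd.hp_l1, 10, axis=1),
            hp_leaf=np.repeat(sd.hp_leaf, 10, axis=1),
            cross_l1=np.repeat(sd.cross_l1, 10, axis=1),
            cross_leaf=np.repeat(sd.cross_leaf, 10, axis=1),
        )
        out = summarise(self._result(small_world, tiled), small_world.envelope)
        row = out[(out["hc"] == "HC1") & (out["hp"] == TOTAL)].iloc[0]
        assert row["lower_share"] == pytest.approx(row["mean_share"], rel=1e-12)
        assert row["upper_share"] == pytest.approx(row["mean_share"], rel=1e-12)

    def test_percentiles_use_hazen_interpolation(self):
        draws = np.arange(1, 1001) / 1000.0
        lo, hi = percentile_bounds(draws)
        assert lo == pytest.approx(0.0255, abs=1e-12)
        assert hi == pytest.approx(0.9755, abs=1e-12)

    def test_bounds_bracket_mean_and_usd_identity(self, small_world):
        draws = _perturbed_draws(small_world, n_draws=30)
        res = rake(draws)
        out = summarise(res, small_world.envelope)
        assert (out["lower_share"] <= out["mean_share"] + 1e-12).all()
        assert (out["mean_share"] <= out["upper_share"] + 1e-12).all()
        env = small_world.envelope.set_index(["country", "year"])["the_pc"]
        the = env.loc[list(zip(out["country"], out["year"]))].to_numpy()
        np.testing.assert_allclose(
            out["mean_usd_pc"], out["mean_share"] * the, rtol=1e-12
        )

    def test_all_failed_draws_is_an_error(self, small_world):
        draws = _perturbed_draws(small_world, n_draws=5)
        res = RakeResult(draws, 1, 0.0, draw_ok=np.zeros(5, dtype=bool))
        with pytest.raises(RakingError, match="successful"):
            summarise(res, small_world.envelope)
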