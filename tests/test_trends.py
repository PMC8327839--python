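"""GDP trend curves, income-group aggregation and report files."""

import numpy as np
import pandas as pd
import pytest

from healthexp import harmonize as hz
from healthexp import raking as rk
from healthexp import synth, trends
from healthexp.taxonomy import TOTAL, default_hc_tree, default_hp_tree, load_table1_fixture


def _estimates(cov, shares, cell=("HC1", TOTAL)):
    return pd.DataFrame(
        {
            "country": cov["country"], "year": cov["year"],
            "hc": cell[0], "hp": cell[1], "mean_share": shares,
        }
    )


def _cov_grid(n_countries=10, T=18, seed=0, slope=0.0, noise=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_countries):
        base = rng.uniform(6.5, 10.5)
        for t in range(T):
            lg = base + 0.02 * t
            rows.append((f"C{i:03d}", 2000 + t, lg))
    df = pd.DataFrame(rows, columns=["country", "year", "log_gdp"])
    df["gdp_pc"] = np.exp(df["log_gdp"])
    logit_share = -2.0 + slope * (df["log_gdp"] - 8.5) + rng.normal(0, noise, len(df))
    df["share"] = hz.inv_logit(logit_share.to_numpy())
    return df


class TestFitGdpTrend:
    def test_positive_slope_world_gives_increasing_curve(self):
        df = _cov_grid(slope=0.8, noise=0.1)
        tf = trends.fit_gdp_trend(_estimates(df, df["share"]), df, ("HC1", TOTAL))
        lo, hi = np.percentile(tf.log_gdp_grid, [10, 90])
        sel = (tf.log_gdp_grid >= lo) & (tf.log_gdp_grid <= hi)
        assert (np.diff(tf.share[sel]) > 0).mean() > 0.95

    def test_null_world_curve_is_flat_within_uncertainty(self):
        df = _cov_grid(slope=0.0, noise=0.1, seed=3)
        tf = trends.fit_gdp_trend(_estimates(df, df["share"]), df, ("HC1", TOTAL))
        total_variation = np.abs(np.diff(tf.share)).sum()
        width = (tf.upper - tf.lower).mean()
        assert total_variation <= 2 * width

    def test_constant_share_gives_flat_curve(self):
        df = _cov_grid(seed=5)
        tf = trends.fit_gdp_trend(
            _estimates(df, np.full(len(df), 0.3)), df, ("HC1", TOTAL),
            select_penalty=False,
        )
        np.testing.assert_allclose(tf.share, 0.3, atol=1e-6)

    def test_insufficient_points_rejected(self):
        df = _cov_grid(n_countries=1, T=10)
        with pytest.raises(trends.TrendError, match="< 30"):
            trends.fit_gdp_trend(_estimates(df, df["share"]), df, ("HC1", TOTAL))

    def test_no_extrapolation_outside_observed_support(self):
        df = _cov_grid(seed=7)
        tf = trends.fit_gdp_trend(_estimates(df, df["share"]), df, ("HC1", TOTAL))
        with pytest.raises(trends.TrendError, match="support"):
            tf.predict(tf.gdp_range[1] + 1.0)
        inside = tf.predict((tf.gdp_range[0] + tf.gdp_range[1]) / 2)
        assert 0 <= inside[0] <= 1

    def test_fitted_shares_within_bounds(self):
        df = _cov_grid(slope=1.5, noise=0.3, seed=9)
        tf = trends.fit_gdp_trend(_estimates(df, df["share"]), df, ("HC1", TOTAL))
        for arr in (tf.share, tf.lower, tf.upper):
            assert ((arr >= 0) & (arr <= 1)).all()


def _rake_result(truth, n_draws=20, sigma=0.2, seed=4):
    rng = np.random.default_rng(seed)
    sd = truth.shares

    def p(a):
        return a * np.exp(rng.normal(0, sigma, size=(a.shape[0], n_draws) + a.shape[2:]))

    draws = rk.ShareDraws(
        index=sd.index, layout=sd.layout,
        hc_l1=p(sd.hc_l1), hc_leaf=p(sd.hc_leaf), hp_l1=p(sd.hp_l1),
        hp_leaf=p(sd.hp_leaf), cross_l1=p(sd.cross_l1), cross_leaf=p(sd.cross_leaf),
    )
    return rk.rake(draws)


class TestAggregateGroups:
    def test_single_country_group_is_identity(self, small_world):
        res = _rake_result(small_world)
        groups = {c: c for c in small_world.income_group}     # one group each
        out = trends.aggregate_groups(res, small_world.envelope, groups,
                                      cells=[("HC1", TOTAL)])
        row = out[(out["group"] == "C000") & (out["year"] == 2000)].iloc[0]
        i = 0   # C000, first year
        d = res.draws.get("HC1", TOTAL)[i]
        assert row["mean_share"] == pytest.approx(d.mean(), rel=1e-10)

    def test_weighted_mean_of_two_equal_the_countries(self, layout):
        idx = pd.DataFrame({"country": ["A", "B"], "year": [2010, 2010]})
        nL, nH = len(layout.hc_leaf), len(layout.hp_leaf)
        ones = np.ones((2, 3, 1))
        draws = rk.ShareDraws(
            index=idx, layout=layout,
            hc_l1=np.tile([[0.2]], (2, 3, len(layout.hc_l1))),
            hc_leaf=ones.repeat(nL, axis=2), hp_l1=ones.repeat(len(layout.hp_l1), 2),
            hp_leaf=ones.repeat(nH, axis=2),
            cross_l1=np.ones((2, 3, len(layout.hc_l1), len(layout.hp_l1))),
            cross_leaf=np.ones((2, 3, nL, nH)),
        )
        draws.hc_l1[0, :, 0] = 0.2
        draws.hc_l1[1, :, 0] = 0.4
        res = rk.RakeResult(draws, 0, 0.0, np.ones(3, dtype=bool))
        env = pd.DataFrame(
            {"country": ["A", "B"], "year": [2010, 2010],
             "the_pc": [100.0, 50.0], "population": [1e6, 2e6],
             "the_total": [1e8, 1e8]}
        )
        out = trends.aggregate_groups(res, env, {"A": "g", "B": "g"},
                                      cells=[("HC1", TOTAL)])
        assert out.iloc[0]["mean_share"] == pytest.approx(0.3, rel=1e-12)

    def test_group_mean_share_is_convex(self, small_world):
        res = _rake_result(small_world)
        groups = small_world.income_group
        out = trends.aggregate_groups(res, small_world.envelope, groups,
                                      cells=[("HC5", TOTAL)])
        sd = res.draws
        glabels = np.array([groups[c] for c in sd.index["country"]])
        years = sd.index["year"].to_numpy()
        d = sd.get("HC5", TOTAL)
        for r in out.itertuples():
            sel = (glabels == r.group) & (years == r.year)
            assert d[sel].min() - 1e-12 <= r.mean_share <= d[sel].max() + 1e-12

    def test_per_capita_pooling_identity(self, small_world):
        """Group per-capita USD equals pooled numerator over pooled
        population, exactly."""
        res = _rake_result(small_world)
        env = small_world.envelope
        out = trends.aggregate_groups(res, env, small_world.income_group,
                                      cells=[("HC1", TOTAL)])
        sd = res.draws
        g0 = out.iloc[0]
        groups = small_world.income_group
        sel = np.array(
            [groups[c] == g0["group"] for c in sd.index["country"]]
        ) & (sd.index["year"].to_numpy() == g0["year"])
        e = env.set_index(["country", "year"]).loc[
            list(zip(sd.index["country"][sel], sd.index["year"][sel]))
        ]
        num = (sd.get("HC1", TOTAL)[sel] * e["the_total"].to_numpy()[:, None]).sum(0)
        assert g0["mean_usd_pc"] == pytest.approx(
            (num / e["population"].sum()).mean(), rel=1e-10
        )

    def test_unmapped_country_is_an_error(self, small_world):
        res = _rake_result(small_world)
        groups = dict(small_world.income_group)
        groups.pop("C000")
        with pytest.raises(trends.TrendError, match="C000"):
            trends.aggregate_groups(res, small_world.envelope, groups)


class TestReport:
    def _table1_summary(self):
        """Published global per-capita table recast as a one-entity summary."""
        t1 = load_table1_fixture()
        codes = set(t1["code"])
        hc = default_hc_tree()
        rows = []
        for r in t1.itertuples():
            # leaves of the *published* table: level-2 rows plus level-1
            # categories printed without a breakdown
            if hc.nodes[r.code].level == 2 or not (codes & set(hc.children(r.code))):
                rows.append(
                    {
                        "country": "GLOBAL", "year": 2017, "hc": r.code,
                        "hp": TOTAL, "mean_share": np.nan,
                        "lower_share": np.nan, "upper_share": np.nan,
                        "mean_usd_pc": float(r.mean), "lower_usd_pc": float(r.lower),
                        "upper_usd_pc": float(r.upper),
                    }
                )
        return pd.DataFrame(rows)

    def test_level1_rows_are_child_aggregates(self, tmp_path):
        trends.report(self._table1_summary(), None, tmp_path,
                      default_hc_tree(), default_hp_tree())
        out = pd.read_csv(tmp_path / "table1_hc.csv").set_index("code")
        assert out.loc["HC1", "usd_pc"] == 523
        assert out.loc["HC5", "usd_pc"] == 178
        assert out.loc["HC4", "usd_pc"] == 59          # childless level-1 passes through

    def test_empty_input_writes_header_only_files(self, tmp_path):
        empty = self._table1_summary().iloc[0:0]
        trends.report(empty, None, tmp_path, default_hc_tree(), default_hp_tree())
        df = pd.read_csv(tmp_path / "table1_hc.csv")
        assert df.empty and "usd_pc" in df.columns

    def test_outputs_are_deterministic(self, tmp_path, small_world):
        res = _rake_result(small_world)
        summary = rk.summarise(res, small_world.envelope)
        gs = trends.aggregate_groups(res, small_world.envelope,
                                     small_world.income_group,
                                     cells=[("HC1", "HP1")])
        for d in ("a", "b"):
            trends.report(summary, gs, tmp_path / d, default_hc_tree(),
                          default_hp_tree(), envelope=small_world.envelope)
        for name in ("table1_hc.csv", "table1_hp.csv", "cross_matrix_high.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_unwritable_directory_is_an_error(self, tmp_path):
        target = tmp_path / "occupied"
        target.write_text("not a directory")
        with pytest.raises(trends.TrendError, match="cannot write"):
            trends.report(self._table1_summary(), None, target,
                          default_hc_tree(), default_hp_tree())
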