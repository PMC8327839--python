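"""Expenditure-composition trends and report generation.

Two analyses sit on top of the raked estimates.  First, the relationship
between a category's share of total health expenditure and national income:
a penalized-spline generalised additive model of the share on smooth terms
in log GDP per capita and calendar year (the year smooth controls for
secular trends so the GDP curve is not confounded by time).  The response
uses a fractional-logit (quasi-binomial) family, which respects the [0, 1]
bounds without clipping.  Second, aggregation of country estimates to World
Bank income groups: group shares are THE-weighted means and group per-capita
values pool numerators and denominators, computed draw-wise *before* taking
percentiles so that group uncertainty intervals are coherent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .raking import RakeResult, percentile_bounds
from .taxonomy import TOTAL, CategoryTree, aggregate_children


class TrendError(ValueError):
    pass


@dataclass
class TrendFit:
    """A fitted share-vs-GDP curve for one cell, year held at its median.

    The curve is defined over the observed GDP support only; evaluating
    outside it is an error, not an extrapolation.
    """

    cell: tuple
    log_gdp_grid: np.ndarray
    share: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    gdp_range: tuple[float, float]     # (min, max) of log GDP pc observed
    basis_df: tuple[int, int]
    alpha: tuple[float, float]

    def predict(self, log_gdp_pc) -> np.ndarray:
        x = np.atleast_1d(np.asarray(log_gdp_pc, dtype=float))
        lo, hi = self.gdp_range
        if np.any(x < lo) or np.any(x > hi):
            raise TrendError(
                f"log GDP outside the observed support [{lo:.3f}, {hi:.3f}]"
            )
        return np.interp(x, self.log_gdp_grid, self.share)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log_gdp_pc": self.log_gdp_grid,
                "gdp_pc": np.exp(self.log_gdp_grid),
                "share": self.share,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def fit_gdp_trend(
    estimates: pd.DataFrame,
    cov: pd.DataFrame,
    cell: tuple,
    basis_df: tuple[int, int] = (6, 5),
    n_grid: int = 100,
    select_penalty: bool = True,
) -> TrendFit:
    """Fit share ~ s(log GDP pc) + s(year) for one cell.

    ``estimates`` is an :func:`healthexp.raking.summarise` frame (or any
    frame with country, year, hc, hp, mean_share).  Smoothing parameters are
    chosen by generalized cross-validation when ``select_penalty`` is true.
    """
    hc, hp = cell
    rows = estimates[(estimates["hc"] == hc) & (estimates["hp"] == hp)]
    merged = rows.merge(cov[["country", "year", "gdp_pc"]], on=["country", "year"])
    if len(merged) < 30:
        raise TrendError(
            f"cell {cell}: {len(merged)} country-year points < 30 required"
        )
    lg = np.log(merged["gdp_pc"].to_numpy(dtype=float))
    yr = merged["year"].to_numpy(dtype=float)
    y = merged["mean_share"].to_numpy(dtype=float)
    X = np.column_stack([lg, yr])
    degree = [3, 3]
    include_year = np.ptp(yr) > 0
    if not include_year:
        X, basis_df, degree = X[:, :1], (basis_df[0],), [3]
    bs = BSplines(X, df=list(basis_df), degree=degree)
    alpha = [1.0] * len(basis_df)
    gam = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs, alpha=alpha,
                 family=sm.families.Binomial())
    lo, hi = float(lg.min()), float(lg.max())
    grid_lg = np.linspace(lo, hi, n_grid)
    if np.ptp(y) < 1e-12:
        # constant response: the GAM degenerates (perfect separation in the
        # IRLS sense); the flat curve is exact
        const = np.full(n_grid, float(y[0]))
        return TrendFit(cell, grid_lg, const, const.copy(), const.copy(),
                        (lo, hi), tuple(basis_df), tuple(alpha))
    if select_penalty:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                alpha = list(np.atleast_1d(gam.select_penweight()[0]))
                gam = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs, alpha=alpha,
                             family=sm.families.Binomial())
        except Exception:            # singular GCV search: keep default penalty
            pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = gam.fit(scale="X2")
    grid_X = np.column_stack([grid_lg, np.full(n_grid, np.median(yr))])
    if not include_year:
        grid_X = grid_X[:, :1]
    exog = np.column_stack([np.ones(n_grid), bs.transform(grid_X)])
    eta = exog @ res.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", exog, res.cov_params(), exog))
    link = res.family.link
    return TrendFit(
        cell=cell,
        log_gdp_grid=grid_lg,
        share=link.inverse(eta),
        lower=link.inverse(eta - 1.96 * se),
        upper=link.inverse(eta + 1.96 * se),
        gdp_range=(lo, hi),
        basis_df=tuple(basis_df),
        alpha=tuple(float(a) for a in np.atleast_1d(alpha)),
    )


# --------------------------------------------------------------------------
# Income-group aggregation
# --------------------------------------------------------------------------


def aggregate_groups(
    result: RakeResult,
    envelope: pd.DataFrame,
    groups: dict[str, str],
    cells: list[tuple] | None = None,
) -> pd.DataFrame:
    """Aggregate raked draws to income groups, draw-wise.

    For each draw and year: group share = sum_c(share_c * THE_c) / sum_c THE_c
    and group per-capita USD = sum_c(share_c * THE_c) / sum_c population_c
    over member countries; percentile bounds are then taken across draws.
    """
    sd = result.draws
    ok = result.draw_ok
    idx = sd.index
    unmapped = sorted(set(idx["country"]) - set(groups))
    if unmapped:
        raise TrendError(f"countries not mapped to an income group: {unmapped}")
    env = envelope.set_index(["country", "year"])
    keys = list(zip(idx["country"], idx["year"]))
    the = env.loc[keys, "the_total"].to_numpy() if "the_total" in env.columns else (
        env.loc[keys, "the_pc"] * env.loc[keys, "population"]
    ).to_numpy()
    pop = env.loc[keys, "population"].to_numpy()
    glabels = np.array([groups[c] for c in idx["country"]])
    years = idx["year"].to_numpy()
    lay = sd.layout
    if cells is None:
        cells = (
            [(c, TOTAL) for c in lay.hc.codes]
            + [(TOTAL, c) for c in lay.hp.codes]
            + [(a, b) for a in lay.hc_l1 for b in lay.hp_l1]
        )
    rows = []
    for g in sorted(set(glabels)):
        for year in sorted(set(years)):
            sel = (glabels == g) & (years == year)
            if not sel.any():
                continue
            w_the, w_pop = the[sel], pop[sel]
            for hc, hp in cells:
                d = np.asarray(sd.get(hc, hp), dtype=float)[sel][:, ok]
                num = (d * w_the[:, None]).sum(axis=0)
                share = num / w_the.sum()
                usd_pc = num / w_pop.sum()
                lo_s, hi_s = percentile_bounds(share)
                lo_u, hi_u = percentile_bounds(usd_pc)
                rows.append(
                    (g, int(year), hc, hp, share.mean(), lo_s, hi_s,
                     usd_pc.mean(), lo_u, hi_u)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "year", "hc", "hp", "mean_share", "lower_share",
            "upper_share", "mean_usd_pc", "lower_usd_pc", "upper_usd_pc",
        ],
    )


# --------------------------------------------------------------------------
# Report files
# --------------------------------------------------------------------------


def table1_rows(
    usd_pc: dict[str, float], tree: CategoryTree,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-capita USD rows for one axis, level-1 rows summed from children.

    ``usd_pc`` must provide every leaf (level-2, or childless level-1) value;
    a level-1 value with children is always the exact aggregate of its
    children, reproducing the hierarchy arithmetic of the published global
    table.
    """
    rows = []
    for code in tree.codes:
        node = tree.nodes[code]
        if node.level > 2:
            continue
        kids = [k for k in tree.children(code) if tree.nodes[k].level == 2]
        if node.level == 1 and kids and all(k in usd_pc for k in kids):
            value = aggregate_children(usd_pc, tree, code)
        elif code in usd_pc:
            # a level-1 category whose breakdown was not estimated passes
            # its own value through
            value = usd_pc[code]
        elif node.level == 2:
            continue
        else:
            raise TrendError(f"no value or complete child set for {code!r}")
        lo, hi = (bounds or {}).get(code, (np.nan, np.nan))
        rows.append((code, node.label, node.level, value, lo, hi))
    return pd.DataFrame(
        rows, columns=["code", "label", "level", "usd_pc", "lower", "upper"]
    )


def _global_values(summary: pd.DataFrame, envelope: pd.DataFrame | None, column: str):
    """Population-weighted global per-capita value per cell."""
    if envelope is not None:
        env = envelope.set_index(["country", "year"])["population"]
        w = env.loc[list(zip(summary["country"], summary["year"]))].to_numpy()
    else:
        w = np.ones(len(summary))
    s = summary.assign(_w=w, _wv=summary[column] * w)
    agg = s.groupby(["hc", "hp"])[["_w", "_wv"]].sum()
    return (agg["_wv"] / agg["_w"]).to_dict()


def report(
    summary: pd.DataFrame,
    groups: pd.DataFrame | None,
    out_dir,
    hc_tree: CategoryTree,
    hp_tree: CategoryTree,
    envelope: pd.DataFrame | None = None,
    trend_fits: list[TrendFit] | None = None,
) -> list[Path]:
    """Write the standard output files; contents deterministic given inputs.

    Emits a global per-capita table per axis (level-1 rows aggregated from
    level-2 children), a level-1 cross-classification share matrix per income
    group, and one curve file per trend fit.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise TrendError(f"cannot write to {out_dir}: {exc}") from exc
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    for axis, tree in (("hc", hc_tree), ("hp", hp_tree)):
        sel = summary[
            (summary[axis] != TOTAL)
            & (summary["hp" if axis == "hc" else "hc"] == TOTAL)
        ]
        if sel.empty:
            _write(
                pd.DataFrame(
                    columns=["code", "label", "level", "usd_pc", "lower", "upper"]
                ),
                f"table1_{axis}.csv",
            )
            continue
        vals = _global_values(sel, envelope, "mean_usd_pc")
        lo = _global_values(sel, envelope, "lower_usd_pc")
        hi = _global_values(sel, envelope, "upper_usd_pc")
        pick = (lambda k: k[0]) if axis == "hc" else (lambda k: k[1])
        flat = {pick(k): v for k, v in vals.items()}
        bounds = {pick(k): (lo[k], hi[k]) for k in vals}
        _write(table1_rows(flat, tree, bounds), f"table1_{axis}.csv")

    if groups is not None and not groups.empty:
        cross = groups[(groups["hc"] != TOTAL) & (groups["hp"] != TOTAL)]
        for g in sorted(cross["group"].unique()):
            latest = cross[cross["group"] == g]
            year = latest["year"].max()
            mat = (
                latest[latest["year"] == year]
                .pivot(index="hc", columns="hp", values="mean_share")
                .sort_index()
            )
            _write(mat.reset_index(), f"cross_matrix_{g}.csv")

    for tf in trend_fits or []:
        _write(tf.to_frame(), f"trend_{tf.cell[0]}_{tf.cell[1]}.csv")

    import json

    from . import __version__

    manifest = {
        "package_version": __version__,
        "n_summary_rows": int(len(summary)),
        "n_group_rows": int(len(groups)) if groups is not None else 0,
        "n_trend_fits": len(trend_fits or []),
        "files": sorted(p.name for p in written),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(path)
    return written
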