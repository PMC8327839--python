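"""Raking: enforcing hierarchical consistency on posterior draws.

The share regressions cannot constrain modelled categories to sum to their
aggregates: level-1 shares of an axis need not sum to one, children need not
sum to their parent, and the HC x HP cross table need not reproduce the axis
margins.  Each posterior draw is therefore *raked* — proportionally rescaled —
top-down:

1. level-1 HC shares are scaled onto the unit simplex; likewise level-1 HP;
2. within each level-1 parent, level-2 (leaf) children are scaled so they sum
   to the parent's raked share;
3. the level-1 HC x HP cross matrix is adjusted to the raked level-1 margins
   by iterative proportional fitting (IPF);
4. the leaf-level cross matrix is raked cyclically over three constraint
   families — leaf HC row totals, leaf HP column totals, and the
   level-1 x level-1 block totals from step 3 — until the worst relative
   discrepancy falls below tolerance.

Proportional scaling preserves the interaction (odds-ratio) structure of the
modelled table, so raking keeps "the original proportions from the models
while the totals sum correctly" in the multidimensional space.  Uncertainty
intervals are then the 2.5th and 97.5th percentiles across raked draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import TOTAL, CategoryTree, Layout


class RakingError(ValueError):
    pass


class IPFError(RakingError):
    pass


def rake_simplex(values, target: float):
    """Proportionally scale a non-negative vector to a positive total.

    The output is ``values * target / sum(values)`` along the last axis;
    ratios between entries are preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    total = values.sum(axis=-1, keepdims=True)
    if np.any((total <= 0) & (np.asarray(target) > 0)):
        raise RakingError("cannot rake an all-zero vector to a positive target")
    if np.any(values < 0):
        raise RakingError("negative entries are not rakeable")
    return values * (np.asarray(target) / np.where(total > 0, total, 1.0))


def _margin_resid(achieved, target):
    scale = np.maximum(np.abs(target), 1e-12)
    return np.abs(achieved - target) / scale


def _ipf_core(m, rows, cols, tol, max_iter):
    """Alternating scaling with an active set; returns per-table residuals."""
    lead = m.shape[:-2]
    R, C = m.shape[-2:]
    B = int(np.prod(lead)) if lead else 1
    m2 = m.reshape(B, R, C)
    rt = np.broadcast_to(rows, lead + (R,)).reshape(B, R)
    ct = np.broadcast_to(cols, lead + (C,)).reshape(B, C)
    active = np.arange(B)
    resid_el = np.full(B, np.inf)
    for _ in range(max_iter):
        sub, r_t, c_t = m2[active], rt[active], ct[active]
        rs = sub.sum(axis=-1)
        sub *= (r_t / np.where(rs > 0, rs, 1.0))[..., :, None]
        cs = sub.sum(axis=-2)
        sub *= (c_t / np.where(cs > 0, cs, 1.0))[..., None, :]
        m2[active] = sub
        r = np.maximum(
            _margin_resid(sub.sum(axis=-1), r_t).max(axis=-1),
            _margin_resid(sub.sum(axis=-2), c_t).max(axis=-1),
        )
        resid_el[active] = r
        active = active[r >= tol]
        if active.size == 0:
            break
    return m2.reshape(lead + (R, C)), (resid_el.reshape(lead) if lead else resid_el[0])


def ipf(
    matrix,
    row_margins,
    col_margins,
    tol: float = 1e-10,
    max_iter: int = 1000,
):
    """Iterative proportional fitting of a non-negative matrix to margins.

    Alternately scales rows and columns until both margins match within
    ``tol`` (relative).  Zero cells stay zero, and the cross-product (odds)
    ratios of strictly positive sub-blocks are preserved — IPF moves the table
    the minimal Kullback-Leibler distance onto the margin constraints.

    Arrays may carry leading batch dimensions; the last two axes are the
    table.  Margins broadcast accordingly (``row_margins`` over the
    second-to-last axis, ``col_margins`` over the last).
    """
    m = np.array(matrix, dtype=float)
    rows = np.asarray(row_margins, dtype=float)
    cols = np.asarray(col_margins, dtype=float)
    if np.any(m < 0) or np.any(rows < 0) or np.any(cols < 0):
        raise IPFError("matrix and margins must be non-negative")
    rsum = rows.sum(axis=-1)
    csum = cols.sum(axis=-1)
    scale = np.maximum(np.abs(rsum), 1e-12)
    if np.any(np.abs(rsum - csum) / scale > max(tol, 1e-8)):
        raise IPFError(
            f"margin totals disagree: rows sum to {rsum!r}, columns to {csum!r}"
        )
    # structural feasibility: a positive margin needs a positive row/column
    if np.any((m.sum(axis=-1) <= 0) & (rows > 0)) or np.any(
        (m.sum(axis=-2) <= 0) & (cols > 0)
    ):
        raise IPFError("positive margin over an all-zero row or column is infeasible")

    out, resid = _ipf_core(m, rows, cols, tol, max_iter)
    worst = float(np.max(resid))
    if worst >= tol:
        raise IPFError(
            f"IPF did not converge in {max_iter} iterations; residual {worst:.3e}"
        )
    return out


# --------------------------------------------------------------------------
# Structured posterior draws
# --------------------------------------------------------------------------


@dataclass
class ShareDraws:
    """Posterior draws of every modelled share, in structured array form.

    Arrays are indexed ``(country-year, draw, ...)``; ``index`` gives the
    country-year row order.  ``get(hc, hp)`` returns draws for any of the
    cross-classification cells or margins, deriving aggregates (level-1
    margins of the cross table, mixed-level cells) by summation.
    """

    index: pd.DataFrame
    layout: Layout
    hc_l1: np.ndarray      # (n_cy, n_draws, n_hc_l1)
    hc_leaf: np.ndarray    # (n_cy, n_draws, n_hc_leaf)
    hp_l1: np.ndarray
    hp_leaf: np.ndarray
    cross_l1: np.ndarray   # (n_cy, n_draws, n_hc_l1, n_hp_l1)
    cross_leaf: np.ndarray  # (n_cy, n_draws, n_hc_leaf, n_hp_leaf)
    provenance: str = "pre-raking"

    @property
    def n_draws(self) -> int:
        return self.hc_l1.shape[1]

    def _hc_leaf_ix(self, code):
        lay = self.layout
        if code in lay.hc_leaf:
            return [lay.hc_leaf.index(code)]
        return lay.hc_children_of(code)

    def _hp_leaf_ix(self, code):
        lay = self.layout
        if code in lay.hp_leaf:
            return [lay.hp_leaf.index(code)]
        return lay.hp_children_of(code)

    def get(self, hc: str = TOTAL, hp: str = TOTAL) -> np.ndarray:
        """Draws (n_cy, n_draws) for one cell; aggregates are derived sums."""
        lay = self.layout
        if hc == TOTAL and hp == TOTAL:
            return self.hc_l1.sum(axis=-1)
        if hp == TOTAL:
            if hc in lay.hc_l1:
                return self.hc_l1[:, :, lay.hc_l1.index(hc)]
            return self.hc_leaf[:, :, lay.hc_leaf.index(hc)]
        if hc == TOTAL:
            if hp in lay.hp_l1:
                return self.hp_l1[:, :, lay.hp_l1.index(hp)]
            return self.hp_leaf[:, :, lay.hp_leaf.index(hp)]
        if hc in lay.hc_l1 and hp in lay.hp_l1:
            return self.cross_l1[:, :, lay.hc_l1.index(hc), lay.hp_l1.index(hp)]
        hi = self._hc_leaf_ix(hc)
        pi = self._hp_leaf_ix(hp)
        return self.cross_leaf[:, :, hi, :][:, :, :, pi].sum(axis=(-1, -2))


@dataclass
class RakeResult:
    draws: ShareDraws
    iterations: int
    max_residual: float
    draw_ok: np.ndarray = field(default=None)  # (n_draws,) bool

    @property
    def n_successful(self) -> int:
        return int(self.draw_ok.sum())


def _scale_to_parent(leaf, parent_vals, parent_idx, member_matrix):
    """Scale leaf groups so each group sums to its parent value."""
    sums = leaf @ member_matrix                      # (..., n_parent)
    if np.any((sums <= 0) & (parent_vals > 0)):
        raise RakingError("all-zero leaf group under a positive parent share")
    f = parent_vals / np.where(sums > 0, sums, 1.0)
    return leaf * f[..., parent_idx]


def _member_matrix(parent_idx, n_parent):
    M = np.zeros((len(parent_idx), n_parent))
    M[np.arange(len(parent_idx)), parent_idx] = 1.0
    return M


def rake_arrays(
    hc_l1,
    hc_leaf,
    hp_l1,
    hp_leaf,
    cross_l1,
    cross_leaf,
    layout: Layout,
    tol: float = 1e-10,
    max_cycles: int = 500,
):
    """Core raking on arrays with arbitrary leading batch dimensions.

    Returns the six raked arrays plus ``(cycles_used, max_residual)`` where
    the residual is the worst relative constraint discrepancy of the leaf
    cross table at exit.
    """
    hc_pi = np.asarray(layout.hc_leaf_parent)
    hp_pi = np.asarray(layout.hp_leaf_parent)
    Mh = _member_matrix(hc_pi, len(layout.hc_l1))
    Mp = _member_matrix(hp_pi, len(layout.hp_l1))

    for arr, name in ((hc_l1, "hc_l1"), (hc_leaf, "hc_leaf"), (hp_l1, "hp_l1"),
                      (hp_leaf, "hp_leaf"), (cross_l1, "cross_l1"),
                      (cross_leaf, "cross_leaf")):
        if np.any(np.asarray(arr) < 0):
            raise RakingError(f"negative values in {name}")

    # step 1: level-1 simplexes
    hc_l1 = rake_simplex(hc_l1, 1.0)
    hp_l1 = rake_simplex(hp_l1, 1.0)
    # step 2: children to raked parents
    hc_leaf = _scale_to_parent(np.asarray(hc_leaf, dtype=float), hc_l1, hc_pi, Mh)
    hp_leaf = _scale_to_parent(np.asarray(hp_leaf, dtype=float), hp_l1, hp_pi, Mp)
    # step 3: level-1 cross table onto the raked level-1 margins; slow
    # elements are carried in the per-element residual rather than fatal
    cross_l1 = np.array(cross_l1, dtype=float)
    if np.any((cross_l1.sum(axis=-1) <= 0) & (np.asarray(hc_l1) > 0)) or np.any(
        (cross_l1.sum(axis=-2) <= 0) & (np.asarray(hp_l1) > 0)
    ):
        raise IPFError("positive margin over an all-zero row or column is infeasible")
    cross_l1, resid3 = _ipf_core(cross_l1, hc_l1, hp_l1, tol, max_cycles)
    # step 4: cyclic raking of the leaf cross table over three constraint
    # families, with an active set so converged tables drop out of the loop
    lead = np.asarray(cross_leaf).shape[:-2]
    R, C = len(layout.hc_leaf), len(layout.hp_leaf)
    B = int(np.prod(lead)) if lead else 1
    m = np.array(cross_leaf, dtype=float).reshape(B, R, C)
    hcl = np.broadcast_to(hc_leaf, lead + (R,)).reshape(B, R)
    hpl = np.broadcast_to(hp_leaf, lead + (C,)).reshape(B, C)
    cl1 = np.broadcast_to(cross_l1, lead + cross_l1.shape[-2:]).reshape(
        B, len(layout.hc_l1), len(layout.hp_l1)
    )
    MhT = Mh.T.copy()
    active = np.arange(B)
    cycles = np.zeros(B, dtype=int)
    resid_el = np.full(B, np.inf)
    for cycle in range(1, max_cycles + 1):
        sub, rt, ct, bt = m[active], hcl[active], hpl[active], cl1[active]
        rs = sub.sum(axis=-1)
        sub *= (rt / np.where(rs > 0, rs, 1.0))[..., :, None]
        cs = sub.sum(axis=-2)
        sub *= (ct / np.where(cs > 0, cs, 1.0))[..., None, :]
        blocks = MhT @ (sub @ Mp)
        if np.any((blocks <= 0) & (bt > 0)):
            raise RakingError("all-zero leaf block under a positive level-1 cross share")
        f = bt / np.where(blocks > 0, blocks, 1.0)
        sub *= f[..., hc_pi[:, None], hp_pi[None, :]]
        m[active] = sub
        # after the block step the block family is exact; only the row and
        # column families can still be off
        r = np.maximum(
            _margin_resid(sub.sum(axis=-1), rt).max(axis=-1),
            _margin_resid(sub.sum(axis=-2), ct).max(axis=-1),
        )
        resid_el[active] = r
        cycles[active] = cycle
        active = active[r >= tol]
        if active.size == 0:
            break
    resid_el = np.maximum(resid_el.reshape(lead) if lead else resid_el[0], resid3)
    return (
        hc_l1, hc_leaf, hp_l1, hp_leaf, cross_l1, m.reshape(lead + (R, C)),
        int(cycles.max()), resid_el,
    )


def rake_draw(
    draw: dict,
    hc: CategoryTree,
    hp: CategoryTree,
    tol: float = 1e-10,
    max_cycles: int = 500,
) -> dict:
    """Rake a single draw given as ``{(hc_code, hp_code): share}``.

    The draw must cover all modelled quantities: every HC total
    ``(code, TOTAL)``, every HP total ``(TOTAL, code)``, the level-1 cross
    cells and the leaf cross cells.  Returns a fully consistent dict covering
    all cross-classification cells and totals.
    """
    lay = Layout(hc, hp)
    try:
        hc_l1 = np.array([draw[(c, TOTAL)] for c in lay.hc_l1], dtype=float)
        hc_leaf = np.array([draw[(c, TOTAL)] for c in lay.hc_leaf], dtype=float)
        hp_l1 = np.array([draw[(TOTAL, c)] for c in lay.hp_l1], dtype=float)
        hp_leaf = np.array([draw[(TOTAL, c)] for c in lay.hp_leaf], dtype=float)
        cl1 = np.array(
            [[draw[(a, b)] for b in lay.hp_l1] for a in lay.hc_l1], dtype=float
        )
        cleaf = np.array(
            [[draw[(a, b)] for b in lay.hp_leaf] for a in lay.hc_leaf], dtype=float
        )
    except KeyError as exc:
        raise RakingError(f"draw does not cover modelled cell {exc.args[0]}") from exc
    hc_l1, hc_leaf, hp_l1, hp_leaf, cl1, cleaf, _, resid = rake_arrays(
        hc_l1, hc_leaf, hp_l1, hp_leaf, cl1, cleaf, lay, tol=tol, max_cycles=max_cycles
    )
    if resid >= max(tol, 1e-8):
        raise IPFError(f"cyclic raking did not converge; residual {resid:.3e}")
    out: dict = {}
    for i, c in enumerate(lay.hc_l1):
        out[(c, TOTAL)] = float(hc_l1[i])
    for i, c in enumerate(lay.hc_leaf):
        out[(c, TOTAL)] = float(hc_leaf[i])
    for i, c in enumerate(lay.hp_l1):
        out[(TOTAL, c)] = float(hp_l1[i])
    for i, c in enumerate(lay.hp_leaf):
        out[(TOTAL, c)] = float(hp_leaf[i])
    hc_pi = np.asarray(lay.hc_leaf_parent)
    hp_pi = np.asarray(lay.hp_leaf_parent)
    for ai, a in enumerate(lay.hc_leaf):
        for bi, b in enumerate(lay.hp_leaf):
            out[(a, b)] = float(cleaf[ai, bi])
    # derived: any (hc, hp) pair where either code is an aggregate
    for a in hc.codes:
        a_ix = [lay.hc_leaf.index(a)] if a in lay.hc_leaf else lay.hc_children_of(a)
        for b in hp.codes:
            if (a, b) in out:
                continue
            b_ix = [lay.hp_leaf.index(b)] if b in lay.hp_leaf else lay.hp_children_of(b)
            out[(a, b)] = float(cleaf[np.ix_(a_ix, b_ix)].sum())
    return out


def rake(
    draws: ShareDraws,
    tol: float = 1e-10,
    max_cycles: int = 500,
    chunk: int = 64,
) -> RakeResult:
    """Rake every draw of every country-year, chunked over country-years.

    A chunk whose cyclic stage fails to converge has its draws flagged (not
    dropped); downstream summaries use successful draws only.
    """
    n_cy, n_draws = draws.hc_l1.shape[:2]
    out = ShareDraws(
        index=draws.index,
        layout=draws.layout,
        hc_l1=np.empty_like(draws.hc_l1, dtype=float),
        hc_leaf=np.empty_like(draws.hc_leaf, dtype=float),
        hp_l1=np.empty_like(draws.hp_l1, dtype=float),
        hp_leaf=np.empty_like(draws.hp_leaf, dtype=float),
        cross_l1=np.empty_like(draws.cross_l1, dtype=float),
        cross_leaf=np.empty_like(draws.cross_leaf, dtype=float),
        provenance="post-raking",
    )
    draw_ok = np.ones(n_draws, dtype=bool)
    worst_resid, worst_iters = 0.0, 0
    for lo in range(0, n_cy, chunk):
        hi = min(lo + chunk, n_cy)
        sl = slice(lo, hi)
        res = rake_arrays(
            np.asarray(draws.hc_l1[sl], dtype=float),
            np.asarray(draws.hc_leaf[sl], dtype=float),
            np.asarray(draws.hp_l1[sl], dtype=float),
            np.asarray(draws.hp_leaf[sl], dtype=float),
            np.asarray(draws.cross_l1[sl], dtype=float),
            np.asarray(draws.cross_leaf[sl], dtype=float),
            draws.layout,
            tol=tol,
            max_cycles=max_cycles,
        )
        (out.hc_l1[sl], out.hc_leaf[sl], out.hp_l1[sl], out.hp_leaf[sl],
         out.cross_l1[sl], out.cross_leaf[sl], iters, resid) = res
        worst_resid = max(worst_resid, float(np.max(resid)))
        worst_iters = max(worst_iters, iters)
        # flag any draw with a non-converged country-year rather than drop it
        draw_ok &= ~(np.asarray(resid).max(axis=0) >= max(tol, 1e-8))
    return RakeResult(out, iterations=worst_iters, max_residual=worst_resid,
                      draw_ok=draw_ok)


def max_consistency_violation(sd: ShareDraws) -> float:
    """Worst absolute violation of the sum constraints across all draws."""
    lay = sd.layout
    Mh = _member_matrix(np.asarray(lay.hc_leaf_parent), len(lay.hc_l1))
    Mp = _member_matrix(np.asarray(lay.hp_leaf_parent), len(lay.hp_l1))
    v = [
        np.abs(sd.hc_l1.sum(axis=-1) - 1.0).max(),
        np.abs(sd.hp_l1.sum(axis=-1) - 1.0).max(),
        np.abs(sd.hc_leaf @ Mh - sd.hc_l1).max(),
        np.abs(sd.hp_leaf @ Mp - sd.hp_l1).max(),
        np.abs(sd.cross_leaf.sum(axis=-1) - sd.hc_leaf).max(),
        np.abs(sd.cross_leaf.sum(axis=-2) - sd.hp_leaf).max(),
        np.abs(Mh.T @ (np.asarray(sd.cross_leaf, dtype=float) @ Mp) - sd.cross_l1).max(),
    ]
    return float(max(v))


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------

#: percentile definition: Hyndman-Fan type 5 linear interpolation, whose
#: 2.5th/97.5th percentiles of {1..1000}/1000 are 0.0255 and 0.9755
PCT_METHOD = "hazen"


def percentile_bounds(draws: np.ndarray, axis: int = -1):
    lo = np.percentile(draws, 2.5, axis=axis, method=PCT_METHOD)
    hi = np.percentile(draws, 97.5, axis=axis, method=PCT_METHOD)
    return lo, hi


def summarise(result: RakeResult, envelope: pd.DataFrame) -> pd.DataFrame:
    """Mean and 2.5th/97.5th-percentile bounds per cell x country-year.

    Covers all HC totals, HP totals and every HC x HP cross-classification
    cell, in share space and 2017-USD-per-capita space (share x THE per
    capita).  Only draws that raked successfully enter the summary.
    """
    ok = result.draw_ok
    if ok.sum() < 2:
        raise RakingError("fewer than 2 successful raked draws; cannot summarise")
    sd = result.draws
    lay = sd.layout
    env = envelope.set_index(["country", "year"])["the_pc"]
    the_pc = env.loc[list(zip(sd.index["country"], sd.index["year"]))].to_numpy()

    cells: list[tuple[str, str]] = (
        [(c, TOTAL) for c in lay.hc.codes]
        + [(TOTAL, c) for c in lay.hp.codes]
        + [(a, b) for a in lay.hc.codes for b in lay.hp.codes]
    )
    frames = []
    for hc_code, hp_code in cells:
        d = np.asarray(sd.get(hc_code, hp_code), dtype=float)[:, ok]
        mean = d.mean(axis=1)
        lo, hi = percentile_bounds(d, axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "country": sd.index["country"].to_numpy(),
                    "year": sd.index["year"].to_numpy(),
                    "hc": hc_code,
                    "hp": hp_code,
                    "mean_share": mean,
                    "lower_share": lo,
                    "upper_share": hi,
                    "mean_usd_pc": mean * the_pc,
                    "lower_usd_pc": lo * the_pc,
                    "upper_usd_pc": hi * the_pc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
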