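"""Bayesian regression of logit-transformed expenditure shares on covariates.

Every modelled quantity — a level-1 or level-2 HC total, an HP total, or an
HC x HP cross cell — is a share of total health expenditure, logit
transformed to stay bound between 0 and 1, and regressed on national
covariates: log GDP per capita, the government share of health spending, the
Healthcare Access and Quality index, maternal education, total fertility,
female HIV prevalence, urban population share, and (by default) calendar
year.  The model for cell *k* is a hierarchical linear model

    logit(s_ck(t)) = x_ct' beta_k + alpha_ck + eps,   alpha_ck ~ N(0, tau_k^2)

with a country random intercept, weakly-informative zero-centred normal
priors (scale 2.5) on standardised-covariate slopes, and inverse-gamma
priors on the dispersions.  The model is fully conjugate, so the posterior
is sampled by a seeded Gibbs sampler; split-R-hat convergence diagnostics
are recorded per fit.  Posterior predictive draws are produced for *all*
country-years, including countries that never reported: those receive
predictions through their covariates plus the prior over country intercepts.

Cells reported too rarely to fit on their own are shrunk to a pooled model:
all cells sharing the same hierarchical parent (or parent pair, for cross
cells) are stacked with a cell random offset, so that something defensible
predicts even cells observed almost nowhere.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import ShareTensor, inv_logit, logit
from .raking import ShareDraws
from .taxonomy import TOTAL, Layout

DEFAULT_COVARIATES = [
    "log_gdp_pc", "gov_share", "haq", "maternal_educ", "tfr", "hiv_prev",
    "urban_prop",
]


class ModelError(ValueError):
    pass


def _stable_seed(key) -> int:
    """Deterministic 31-bit seed from a cell key (hash() is salted)."""
    return zlib.crc32(repr(key).encode()) & 0x7FFFFFFF


class InsufficientDataError(ModelError):
    pass


@dataclass
class ModelSpec:
    """Configuration of one cell regression (and of the whole pipeline).

    ``iterations`` is the per-chain Gibbs length including ``warmup``;
    retained draws total ``chains * (iterations - warmup)`` and are
    resampled down (deterministically) to ``n_draws`` at prediction time.
    """

    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    include_country_intercept: bool = True
    include_year_term: bool = True
    prior_scale_beta: float = 2.5
    prior_scale_intercept: float = 5.0
    n_draws: int = 1000
    seed: int = 0
    chains: int = 2
    iterations: int = 1000
    warmup: int = 500
    min_obs: int = 10
    rhat_threshold: float = 1.05
    #: draw from the full posterior predictive (residual term included).  The
    #: residual absorbs both reporting error and the structural deviation of
    #: a country-year's true composition from the covariate model, and both
    #: belong in the uncertainty of an unreported cell; latent-only draws
    #: materially undercover the truth in simulation.
    predictive_noise: bool = True

    def __post_init__(self):
        if self.n_draws < 2:
            raise ModelError("n_draws must be >= 2")
        if self.warmup >= self.iterations:
            raise ModelError("warmup must be smaller than iterations")


def design_matrix(cov: pd.DataFrame, spec: ModelSpec):
    """Build (X, names) from a covariate table; GDP enters as log GDP pc."""
    cols, names = [], []
    for name in spec.covariates:
        if name == "log_gdp_pc":
            x = np.log(cov["gdp_pc"].to_numpy(dtype=float))
        else:
            if name not in cov.columns:
                raise ModelError(f"covariate {name!r} absent from covariate table")
            x = cov[name].to_numpy(dtype=float)
        cols.append(x)
        names.append(name)
    if spec.include_year_term:
        cols.append(cov["year"].to_numpy(dtype=float))
        names.append("year")
    if not cols:                         # intercept-only specification
        return np.empty((len(cov), 0)), names
    return np.column_stack(cols), names


@dataclass
class CellPosterior:
    """Posterior draws for one (possibly pooled) cell regression."""

    cell: tuple
    spec: ModelSpec
    coef_names: list[str]
    beta: np.ndarray            # (S, p+1) on the standardised scale, incl. intercept
    alpha: np.ndarray           # (S, n_countries)
    cell_offset: np.ndarray | None  # (S, n_cells) for pooled fits
    sigma2: np.ndarray          # (S,)
    tau2: np.ndarray            # (S,)
    tau2_cell: np.ndarray | None  # (S,) offset dispersion, pooled fits only
    countries: list[str]
    pooled_cells: list[tuple] | None
    x_mean: np.ndarray
    x_sd: np.ndarray
    rhat: dict[str, float]
    n_obs: int

    @property
    def converged(self) -> bool:
        return all(v <= self.spec.rhat_threshold for v in self.rhat.values())

    def coef_table(self) -> pd.DataFrame:
        """Posterior summaries of slopes on the *original* covariate scale."""
        slopes = self.beta[:, 1:] / self.x_sd[None, :]
        intercept = self.beta[:, 0] - (self.beta[:, 1:] * (self.x_mean / self.x_sd)).sum(
            axis=1
        )
        names = ["intercept"] + self.coef_names
        draws = np.column_stack([intercept, slopes])
        return pd.DataFrame(
            {
                "coef": names,
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0, ddof=1),
                "q2.5": np.percentile(draws, 2.5, axis=0, method="hazen"),
                "q97.5": np.percentile(draws, 97.5, axis=0, method="hazen"),
            }
        )


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chain, n_iter) draw matrix."""
    n_chain, n_iter = chains.shape
    half = n_iter // 2
    if half < 2:
        return float("nan")
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _gibbs(
    y: np.ndarray,
    X: np.ndarray,
    country_idx: np.ndarray,
    n_countries: int,
    cell_idx: np.ndarray | None,
    n_cells: int,
    spec: ModelSpec,
    rng: np.random.Generator,
):
    """Conjugate Gibbs sampler for the hierarchical linear model.

    X already includes the leading intercept column and standardised
    covariates.  Returns per-chain stacked post-warmup draws.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty_base = X.T @ y
    XtZc = np.zeros((p, n_countries))
    np.add.at(XtZc.T, country_idx, X)
    counts_c = np.bincount(country_idx, minlength=n_countries).astype(float)
    sy_base = np.bincount(country_idx, weights=y, minlength=n_countries)
    if cell_idx is not None:
        XtZk = np.zeros((p, n_cells))
        np.add.at(XtZk.T, cell_idx, X)
        counts_k = np.bincount(cell_idx, minlength=n_cells).astype(float)
    prior_prec = np.ones(p) / spec.prior_scale_beta**2
    prior_prec[0] = 1.0 / spec.prior_scale_intercept**2
    a_sig, b_sig = 0.001, 0.001
    a_tau, b_tau = 1.0, 0.25

    keep = spec.iterations - spec.warmup
    out = {
        "beta": np.empty((spec.chains, keep, p)),
        "alpha": np.empty((spec.chains, keep, n_countries)),
        "gamma": np.empty((spec.chains, keep, n_cells)) if cell_idx is not None else None,
        "sigma2": np.empty((spec.chains, keep)),
        "tau2": np.empty((spec.chains, keep)),
        "tau2_k": np.empty((spec.chains, keep)) if cell_idx is not None else None,
    }
    for ch in range(spec.chains):
        beta = np.linalg.solve(XtX + np.diag(prior_prec), Xty_base)
        alpha = np.zeros(n_countries)
        gamma = np.zeros(n_cells) if cell_idx is not None else None
        resid0 = y - X @ beta
        sigma2 = max(float(np.var(resid0)), 1e-4)
        tau2 = 0.25
        tau2_k = 0.25
        for it in range(spec.iterations):
            # beta, with country intercepts marginalised out (blocked update:
            # marginally y_c ~ N(X_c beta, sigma2 I + tau2 11'), whose inverse
            # only needs per-country sums — avoids the intercept/random-
            # intercept ridge that cripples the naive Gibbs step)
            if gamma is not None:
                g_obs = gamma[cell_idx]
                Xty = Xty_base - XtZk @ gamma
                sy = sy_base - np.bincount(country_idx, weights=g_obs,
                                           minlength=n_countries)
            else:
                g_obs = 0.0
                Xty, sy = Xty_base, sy_base
            if spec.include_country_intercept:
                w = tau2 / (sigma2 * (sigma2 + counts_c * tau2))
                A = XtX / sigma2 - (XtZc * w) @ XtZc.T + np.diag(prior_prec)
                rhs = Xty / sigma2 - XtZc @ (w * sy)
            else:
                A = XtX / sigma2 + np.diag(prior_prec)
                rhs = Xty / sigma2
            L = np.linalg.cholesky(A)
            mu = np.linalg.solve(A, rhs)
            z = rng.standard_normal(p)
            beta = mu + np.linalg.solve(L.T, z)
            fitted_fx = X @ beta
            # country intercepts | beta
            if spec.include_country_intercept and tau2 > 0:
                r = y - fitted_fx - g_obs
                s = np.bincount(country_idx, weights=r, minlength=n_countries)
                var = 1.0 / (counts_c / sigma2 + 1.0 / tau2)
                alpha = var * s / sigma2 + np.sqrt(var) * rng.standard_normal(n_countries)
                sse_a = float(alpha @ alpha)
                tau2 = 1.0 / rng.gamma(a_tau + n_countries / 2, 1.0 / (b_tau + sse_a / 2))
            # cell offsets (pooled fits), constrained to sum to zero so the
            # pooled intercept stays identified
            if gamma is not None:
                r = y - fitted_fx - alpha[country_idx]
                s = np.bincount(cell_idx, weights=r, minlength=n_cells)
                var = 1.0 / (counts_k / sigma2 + 1.0 / tau2_k)
                gamma = var * s / sigma2 + np.sqrt(var) * rng.standard_normal(n_cells)
                shift = gamma.mean()
                gamma = gamma - shift
                beta[0] += shift
                fitted_fx = X @ beta
                tau2_k = 1.0 / rng.gamma(
                    a_tau + n_cells / 2, 1.0 / (b_tau + float(gamma @ gamma) / 2)
                )
            # residual variance
            r = y - fitted_fx - alpha[country_idx]
            if gamma is not None:
                r = r - gamma[cell_idx]
            sigma2 = 1.0 / rng.gamma(a_sig + n / 2, 1.0 / (b_sig + float(r @ r) / 2))
            if it >= spec.warmup:
                j = it - spec.warmup
                out["beta"][ch, j] = beta
                out["alpha"][ch, j] = alpha
                if gamma is not None:
                    out["gamma"][ch, j] = gamma
                out["sigma2"][ch, j] = sigma2
                out["tau2"][ch, j] = tau2
                if gamma is not None:
                    out["tau2_k"][ch, j] = tau2_k
    return out


def _fit_arrays(
    y: np.ndarray,
    Xraw: np.ndarray,
    coef_names: list[str],
    countries: np.ndarray,
    cells: np.ndarray | None,
    cell_labels: list[tuple] | None,
    spec: ModelSpec,
    cell_key: tuple,
    seed: int,
) -> CellPosterior:
    sds = Xraw.std(axis=0)
    zero_var = [coef_names[i] for i in np.flatnonzero(sds == 0)]
    if zero_var:
        raise ModelError(f"covariate(s) with zero variance in the data: {zero_var}")
    means = Xraw.mean(axis=0)
    Z = (Xraw - means) / sds
    X = np.column_stack([np.ones(len(Z)), Z])
    country_codes, country_idx = np.unique(countries, return_inverse=True)
    if cells is not None:
        _, cell_idx = np.unique(cells, return_inverse=True)
        n_cells = len(cell_labels)
    else:
        cell_idx, n_cells = None, 0
    rng = np.random.default_rng([spec.seed, seed & 0x7FFFFFFF])
    res = _gibbs(y, X, country_idx, len(country_codes), cell_idx, n_cells, spec, rng)
    rhat = {"sigma2": _split_rhat(np.log(res["sigma2"]))}
    for j, name in enumerate(["intercept"] + coef_names):
        rhat[f"beta[{name}]"] = _split_rhat(res["beta"][:, :, j])
    if spec.include_country_intercept:
        rhat["tau2"] = _split_rhat(np.log(res["tau2"]))
    S = spec.chains * (spec.iterations - spec.warmup)
    post = CellPosterior(
        cell=cell_key,
        spec=spec,
        coef_names=coef_names,
        beta=res["beta"].reshape(S, -1),
        alpha=res["alpha"].reshape(S, -1),
        cell_offset=res["gamma"].reshape(S, -1) if res["gamma"] is not None else None,
        sigma2=res["sigma2"].reshape(S),
        tau2=res["tau2"].reshape(S),
        tau2_cell=res["tau2_k"].reshape(S) if res["tau2_k"] is not None else None,
        countries=list(country_codes),
        pooled_cells=cell_labels,
        x_mean=means,
        x_sd=sds,
        rhat=rhat,
        n_obs=len(y),
    )
    if not post.converged:
        warnings.warn(
            f"cell {cell_key}: split-R-hat above {spec.rhat_threshold} "
            f"({max(post.rhat.values()):.3f}); treat draws with caution",
            stacklevel=2,
        )
    return post


def _cell_observations(tensor: ShareTensor, cov: pd.DataFrame, cell: tuple):
    hc, hp = cell
    rows = tensor.cell_frame(hc, hp)
    merged = rows.merge(cov, on=["country", "year"], how="left")
    if merged["gdp_pc"].isna().any():
        missing = merged[merged["gdp_pc"].isna()][["country", "year"]].iloc[0]
        raise ModelError(
            f"country-year ({missing['country']}, {missing['year']}) absent "
            "from covariate table"
        )
    return merged


def fit_cell_model(
    spec: ModelSpec, tensor: ShareTensor, cov: pd.DataFrame, cell: tuple = (None, None)
) -> CellPosterior:
    """Fit the hierarchical regression for one modelled cell.

    ``cell`` is ``(hc_code_or_TOTAL, hp_code_or_TOTAL)``.  Raises
    :class:`InsufficientDataError` below ``spec.min_obs`` observations — the
    pipeline then falls back to the pooled model for the cell's parent block.
    """
    merged = _cell_observations(tensor, cov, cell)
    if len(merged) < spec.min_obs:
        raise InsufficientDataError(
            f"cell {cell}: {len(merged)} observations < min_obs={spec.min_obs}"
        )
    y = logit(merged["share"].to_numpy(dtype=float))
    X, names = design_matrix(merged, spec)
    return _fit_arrays(
        y, X, names, merged["country"].to_numpy(), None, None, spec, cell,
        seed=_stable_seed(cell),
    )


def predict_draws(
    posterior: CellPosterior,
    cov: pd.DataFrame,
    n_draws: int | None = None,
    seed: int | None = None,
    include_observation_noise: bool = False,
    cell: tuple | None = None,
) -> np.ndarray:
    """Posterior predictive draws of the cell's share for every covariate row.

    Returns an ``(n_rows, n_draws)`` array strictly inside (0, 1).  With
    ``include_observation_noise=True`` (the pipeline default, via
    ``ModelSpec.predictive_noise``) draws come from the full posterior
    predictive; otherwise they are draws of the latent mean share (linear
    predictor plus country effect) only.  Countries absent from the fit draw
    their intercept from ``N(0, tau^2)``.
    """
    spec = posterior.spec
    n_draws = n_draws or spec.n_draws
    X, names = design_matrix(cov, spec)
    if names != posterior.coef_names:
        raise ModelError("covariate set differs from the fitted specification")
    Z = (X - posterior.x_mean) / posterior.x_sd
    S = posterior.beta.shape[0]
    take = (np.arange(n_draws) * S) // n_draws if S >= n_draws else np.arange(n_draws) % S
    rng = np.random.default_rng(
        [spec.seed, 17, (seed if seed is not None else 0) & 0x7FFFFFFF]
    )
    beta = posterior.beta[take]
    mu = beta[:, 0][None, :] + Z @ beta[:, 1:].T        # (n_rows, n_draws)
    cmap = {c: i for i, c in enumerate(posterior.countries)}
    country_rows = cov["country"].to_numpy()
    known = np.array([cmap.get(c, -1) for c in country_rows])
    alpha = posterior.alpha[take]                        # (n_draws, C)
    tau = np.sqrt(posterior.tau2[take])
    add = np.where(
        (known >= 0)[:, None],
        alpha[:, np.clip(known, 0, None)].T,
        0.0,
    )
    if (known < 0).any() and spec.include_country_intercept:
        unseen = np.unique(country_rows[known < 0])
        z = rng.standard_normal((len(unseen), n_draws))
        u_alpha = z * tau[None, :]
        umap = {c: i for i, c in enumerate(unseen)}
        for r in np.flatnonzero(known < 0):
            add[r] = u_alpha[umap[country_rows[r]]]
    mu = mu + add
    if posterior.cell_offset is not None:
        if cell is None:
            raise ModelError("pooled posterior needs the target cell for prediction")
        if cell in posterior.pooled_cells:
            k = posterior.pooled_cells.index(cell)
            mu = mu + posterior.cell_offset[take][:, k][None, :]
        else:
            # cell never observed anywhere in the pool: offset from its prior
            tau_k = np.sqrt(posterior.tau2_cell[take])
            mu = mu + (rng.standard_normal(n_draws) * tau_k)[None, :]
    if include_observation_noise:
        mu = mu + rng.standard_normal(mu.shape) * np.sqrt(posterior.sigma2[take])[None, :]
    return inv_logit(mu)


# --------------------------------------------------------------------------
# Whole-pipeline fitting
# --------------------------------------------------------------------------


def _fit_pool(
    spec: ModelSpec,
    tensor: ShareTensor,
    cov: pd.DataFrame,
    cells: list[tuple],
    key: tuple,
) -> CellPosterior | None:
    frames = []
    for cell in cells:
        f = _cell_observations(tensor, cov, cell)
        if not f.empty:
            f = f.copy()
            f["_cell"] = [cell] * len(f)
            frames.append(f)
    if not frames:
        return None
    merged = pd.concat(frames, ignore_index=True)
    if len(merged) < spec.min_obs:
        return None
    y = logit(merged["share"].to_numpy(dtype=float))
    X, names = design_matrix(merged, spec)
    labels = sorted(set(merged["_cell"]))
    cell_arr = np.array([labels.index(c) for c in merged["_cell"]])
    return _fit_arrays(
        y, X, names, merged["country"].to_numpy(), cell_arr, labels, spec, key,
        seed=_stable_seed(key),
    )


def _prior_only_draws(spec, cov, n_draws, seed):
    """Last-resort prediction when a family has no usable data at all."""
    rng = np.random.default_rng([spec.seed, 23, seed & 0x7FFFFFFF])
    mu = rng.normal(0.0, spec.prior_scale_intercept, size=(1, n_draws))
    return inv_logit(np.broadcast_to(mu, (len(cov), n_draws)).copy())


def fit_pipeline(
    tensor: ShareTensor,
    cov: pd.DataFrame,
    spec: ModelSpec,
    layout: Layout,
    progress: bool = False,
) -> tuple[ShareDraws, pd.DataFrame]:
    """Fit every modelled quantity and assemble predictive draws.

    Modelled quantities: all HC totals, all HP totals, the level-1 cross
    matrix and the leaf cross matrix.  Per cell: an individual fit when the
    cell has at least ``spec.min_obs`` reported observations; otherwise a
    pooled fit over its parent block (cells sharing the hierarchical parent,
    with cell offsets); otherwise a family-wide pool; otherwise prior-only
    draws.  Returns the draw tensor plus a per-cell fit log.
    """
    cy = cov[["country", "year"]].drop_duplicates().reset_index(drop=True)
    n_cy, n_draws = len(cy), spec.n_draws
    lay = layout
    sd = ShareDraws(
        index=cy,
        layout=lay,
        hc_l1=np.empty((n_cy, n_draws, len(lay.hc_l1)), dtype=np.float64),
        hc_leaf=np.empty((n_cy, n_draws, len(lay.hc_leaf)), dtype=np.float64),
        hp_l1=np.empty((n_cy, n_draws, len(lay.hp_l1)), dtype=np.float64),
        hp_leaf=np.empty((n_cy, n_draws, len(lay.hp_leaf)), dtype=np.float64),
        cross_l1=np.empty(
            (n_cy, n_draws, len(lay.hc_l1), len(lay.hp_l1)), dtype=np.float64
        ),
        cross_leaf=np.empty(
            (n_cy, n_draws, len(lay.hc_leaf), len(lay.hp_leaf)), dtype=np.float64
        ),
        provenance="pre-raking",
    )

    def block_of(cell):
        hc, hp = cell
        bh = hc if hc == TOTAL else (lay.hc.parent(hc) or hc)
        bp = hp if hp == TOTAL else (lay.hp.parent(hp) or hp)
        return (bh, bp)

    # targets: (cell key, destination array, index into trailing axes)
    targets: list[tuple[tuple, str, tuple]] = []
    for j, c in enumerate(lay.hc_l1):
        targets.append(((c, TOTAL), "hc_l1", (j,)))
    for j, c in enumerate(lay.hc_leaf):
        targets.append(((c, TOTAL), "hc_leaf", (j,)))
    for j, c in enumerate(lay.hp_l1):
        targets.append(((TOTAL, c), "hp_l1", (j,)))
    for j, c in enumerate(lay.hp_leaf):
        targets.append(((TOTAL, c), "hp_leaf", (j,)))
    for a_i, a in enumerate(lay.hc_l1):
        for b_i, b in enumerate(lay.hp_l1):
            targets.append(((a, b), "cross_l1", (a_i, b_i)))
    for a_i, a in enumerate(lay.hc_leaf):
        for b_i, b in enumerate(lay.hp_leaf):
            targets.append(((a, b), "cross_leaf", (a_i, b_i)))

    seen: dict[tuple, tuple] = {}       # cell already written (leaf == parent reuse)
    pools: dict[tuple, CellPosterior | None] = {}
    family_pools: dict[str, CellPosterior | None] = {}
    log_rows = []
    for count, (cell, dest, ix) in enumerate(targets):
        if cell in seen:
            prev_dest, prev_ix = seen[cell]
            getattr(sd, dest)[(slice(None), slice(None)) + ix] = getattr(
                sd, prev_dest
            )[(slice(None), slice(None)) + prev_ix]
            continue
        n_obs = len(tensor.cell_frame(*cell))
        post, route = None, "individual"
        if n_obs >= spec.min_obs:
            post = fit_cell_model(spec, tensor, cov, cell)
            draws = predict_draws(
                post, cov, n_draws, seed=count,
                include_observation_noise=spec.predictive_noise,
            )
        else:
            block = block_of(cell)
            if block not in pools:
                members = [t for t, _, _ in targets if block_of(t) == block]
                pools[block] = _fit_pool(spec, tensor, cov, members, block)
            post, route = pools[block], f"pooled{block}"
            if post is None:
                if dest not in family_pools:
                    members = [t for t, d, _ in targets if d == dest]
                    family_pools[dest] = _fit_pool(spec, tensor, cov, members,
                                                   ("family", dest))
                post, route = family_pools[dest], f"family:{dest}"
            if post is not None:
                draws = predict_draws(
                    post, cov, n_draws, seed=count,
                    cell=cell if post.cell_offset is not None else None,
                    include_observation_noise=spec.predictive_noise,
                )
            else:
                draws, route = _prior_only_draws(spec, cov, n_draws, count), "prior"
        getattr(sd, dest)[(slice(None), slice(None)) + ix] = draws
        seen[cell] = (dest, ix)
        log_rows.append(
            {
                "hc": cell[0], "hp": cell[1], "n_obs": n_obs, "route": route,
                "max_rhat": max(post.rhat.values()) if post is not None else np.nan,
                "converged": post.converged if post is not None else False,
            }
        )
        if progress and count % 100 == 0:
            print(f"  fitted {count}/{len(targets)} quantities", flush=True)
    return sd, pd.DataFrame(log_rows)


def holdout_validate(
    tensor: ShareTensor,
    cov: pd.DataFrame,
    spec: ModelSpec,
    frac_held: float,
    seed: int = 0,
    cells: list[tuple] | None = None,
):
    """Mask a fraction of reported cells, refit, and score the predictions.

    Reports RMSE on the logit scale and empirical coverage of 95% posterior
    predictive intervals (which include the residual term, since held-out
    values are noisy observations) over the held-out cells.
    """
    if not 0 < frac_held < 1:
        raise ModelError("frac_held must be strictly between 0 and 1")
    rng = np.random.default_rng([spec.seed, 29, seed & 0x7FFFFFFF])
    data = tensor.data
    if cells is None:
        counts = data.groupby(["hc", "hp"]).size()
        cells = [c for c, n in counts.items() if n >= spec.min_obs + 2]
    sq_err, covered, n_held, skipped = [], [], 0, []
    for cell in cells:
        frame = tensor.cell_frame(*cell).reset_index(drop=True)
        n_hold = int(round(frac_held * len(frame)))
        if n_hold == 0 or len(frame) - n_hold < spec.min_obs:
            skipped.append(cell)
            warnings.warn(f"cell {cell} skipped: holdout would leave too few rows",
                          stacklevel=2)
            continue
        hold_ix = rng.choice(len(frame), size=n_hold, replace=False)
        mask = np.zeros(len(frame), dtype=bool)
        mask[hold_ix] = True
        train = frame[~mask]
        test = frame[mask]
        sub = ShareTensor(
            pd.concat(
                [data[(data["hc"] != cell[0]) | (data["hp"] != cell[1])], train]
            ).reset_index(drop=True),
            tensor.countries,
            tensor.years,
        )
        post = fit_cell_model(spec, sub, cov, cell)
        test_cov = test[["country", "year"]].merge(cov, on=["country", "year"])
        pred = predict_draws(
            post, test_cov, spec.n_draws, seed=seed, include_observation_noise=True
        )
        y = logit(test["share"].to_numpy(dtype=float))
        yhat = logit(np.median(pred, axis=1))
        lo, hi = np.percentile(pred, [2.5, 97.5], axis=1, method="hazen")
        s = test["share"].to_numpy(dtype=float)
        sq_err.extend((y - yhat) ** 2)
        covered.extend((s >= lo) & (s <= hi))
        n_held += len(test)
    if n_held == 0:
        raise ModelError("holdout left no scoreable cells")
    return {
        "rmse_logit": float(np.sqrt(np.mean(sq_err))),
        "coverage95": float(np.mean(covered)),
        "n_held": n_held,
        "n_cells": len(cells) - len(skipped),
        "skipped_cells": skipped,
    }
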