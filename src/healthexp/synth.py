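"""Synthetic National Health Accounts worlds.

Real cross-classified health-expenditure accounts are sparse in a very
particular way: axis *totals* are reported far more often than cross cells
(on the order of 8% of the HC x HP matrix is reported in an average
country-year), richer countries and later years report more, a handful of
reported values are zeroes, and pre-2011 reports may follow the older
SHA 2000 category guidelines.  This module generates ground-truth worlds —
smooth country covariate trajectories, an expenditure envelope, and
hierarchically consistent true share tensors driven by those covariates —
and then pushes them through a reporting process with exactly that
missingness structure, so every downstream stage (harmonisation, regression,
raking) can be tested against a known truth.

Truth construction: each modelled category gets an unconstrained score
(cell intercept + covariate linear predictor + country intercept); level-1
shares are the softmax of level-1 scores, children are a nested softmax
within their parent, and the leaf cross table is an independence-times-
interaction product (HC margin x HP margin x low-rank log-linear
interaction) normalised onto the exact margins by IPF.  All consistency
constraints therefore hold by construction, to numerical precision.

Defaults are *scenario* parameters: the reporting propensities target the
observed ~8% cross-cell rate with a roughly 2x high-income/low-income
gradient, while dispersion and noise magnitudes are plausible but not
estimates of real reporting error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import raking
from .harmonize import COV_COLUMNS, OBS_COLUMNS, inv_logit
from .taxonomy import (
    TOTAL,
    CategoryTree,
    Layout,
    default_hc_tree,
    default_hp_tree,
)

INCOME_GROUPS = ("low", "lower_middle", "upper_middle", "high")


class SynthError(ValueError):
    pass


@dataclass
class WorldConfig:
    """Scenario parameters of a synthetic world.

    Covariate effects on the logit-share scale are drawn per category from
    ``N(0, coef_scale^2)`` (seeded, so they are part of the world's truth);
    country intercepts from ``N(0, country_sd^2)``.  Reported amounts carry
    multiplicative log-normal noise with log-scale sigma ``noise_sd`` — the
    noise keeps amounts positive and is roughly symmetric on the logit scale.
    Reporting propensities are per-record probabilities modulated by income
    group (about 2x from low to high income) and calendar year; the cross-cell
    base rate targets the ~8% average observed in country-reported matrices.
    """

    n_countries: int = 50
    years: tuple[int, int] = (2000, 2017)
    seed: int = 0
    coef_scale: float = 0.4
    intercept_scale: float = 1.0
    country_sd: float = 0.5
    noise_sd: float = 0.2
    interaction_scale: float = 0.3
    p_l1_total: float = 0.6
    p_l2_total: float = 0.4
    p_cross: float = 0.08
    income_factors: tuple[float, ...] = (0.65, 0.85, 1.1, 1.4)
    year_factor_range: tuple[float, float] = (0.8, 1.2)
    zero_rate: float = 0.01
    sha2000_rate: float = 0.3
    never_report_frac: float = 0.25
    hc_tree: CategoryTree = field(default_factory=default_hc_tree)
    hp_tree: CategoryTree = field(default_factory=default_hp_tree)

    def __post_init__(self):
        if self.n_countries <= 0:
            raise SynthError("n_countries must be positive (empty world)")
        if self.years[1] < self.years[0]:
            raise SynthError("empty year range")
        for name in ("p_l1_total", "p_l2_total", "p_cross", "zero_rate",
                     "sha2000_rate", "never_report_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name}={v} outside [0, 1]")
        for name in ("coef_scale", "country_sd", "noise_sd", "interaction_scale"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be non-negative")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def noise_free(config: WorldConfig) -> WorldConfig:
    """A copy of ``config`` with every reporting distortion switched off."""
    return replace(config, noise_sd=0.0, zero_rate=0.0, sha2000_rate=0.0)


@dataclass
class TruthBundle:
    """A fully known world: covariates, envelope and consistent true shares."""

    config: WorldConfig
    layout: Layout
    covariates: pd.DataFrame
    envelope: pd.DataFrame          # country, year, the_pc, population, the_total
    income_group: dict[str, str]
    shares: raking.ShareDraws       # n_draws == 1, exact truth
    coefficients: dict              # cell key -> coefficient vector (z-scale)

    @property
    def index(self) -> pd.DataFrame:
        return self.shares.index

    def true_share(self, country, year, hc=TOTAL, hp=TOTAL) -> float:
        sel = (self.index["country"] == country) & (self.index["year"] == year)
        i = int(np.flatnonzero(sel.to_numpy())[0])
        return float(self.shares.get(hc, hp)[i, 0])


#: covariate columns entering cell scores, in order
SCORE_COVARIATES = [
    "log_gdp_pc", "gov_share", "haq", "maternal_educ", "tfr", "hiv_prev",
    "urban_prop",
]

_GDP_BASE = {"low": 6.8, "lower_middle": 8.0, "upper_middle": 9.2, "high": 10.4}


def _covariates(config: WorldConfig, rng) -> tuple[pd.DataFrame, dict[str, str]]:
    years = np.array(config.year_list)
    T = len(years)
    rows = []
    groups: dict[str, str] = {}
    for i in range(config.n_countries):
        name = f"C{i:03d}"
        g = INCOME_GROUPS[i % 4]
        groups[name] = g
        base = _GDP_BASE[g] + rng.normal(0, 0.3)
        wiggle = np.cumsum(rng.normal(0, 0.01, T))
        log_gdp = base + 0.02 * np.arange(T) + wiggle
        gdp_pc = np.exp(log_gdp)
        haq = np.clip(10.5 * (log_gdp - 5.0) + rng.normal(0, 3), 5, 97)
        educ = np.clip(1.6 * (log_gdp - 5.5) + rng.normal(0, 0.7), 0.5, 16)
        tfr = np.clip(9.0 - 0.85 * log_gdp + rng.normal(0, 0.3), 1.2, 7.5)
        hiv = np.clip(
            rng.lognormal(-5.5, 1.0) * np.ones(T) * (1 + 0.2 * rng.normal(size=1)),
            1e-5, 0.25,
        )
        urban = np.clip(0.12 * (log_gdp - 4.0) + rng.normal(0, 0.05), 0.05, 0.97)
        the_share = np.clip(0.055 + 0.01 * rng.normal() + 0.0005 * np.arange(T),
                            0.02, 0.15)
        the_pc = gdp_pc * the_share
        pop = np.exp(rng.normal(16.0, 1.2)) * (1.01 ** np.arange(T))
        for t in range(T):
            rows.append(
                (name, int(years[t]), the_pc[t], pop[t], gdp_pc[t],
                 float(np.clip(0.35 + 0.05 * (log_gdp[t] - 8) + rng.normal(0, 0.02),
                               0.05, 0.95)),
                 haq[t], educ[t], tfr[t], float(hiv[t]), urban[t])
            )
    cov = pd.DataFrame(rows, columns=COV_COLUMNS)
    return cov, groups


def _zscores(cov: pd.DataFrame) -> np.ndarray:
    X = np.column_stack(
        [np.log(cov["gdp_pc"].to_numpy())]
        + [cov[c].to_numpy() for c in SCORE_COVARIATES[1:]]
    )
    m, s = X.mean(axis=0), X.std(axis=0)
    s[s == 0] = 1.0
    return (X - m) / s


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def generate_world(config: WorldConfig) -> TruthBundle:
    """Generate a seeded ground-truth world.

    Identical config (including seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    cov, groups = _covariates(config, rng)
    lay = Layout(config.hc_tree, config.hp_tree)
    Z = _zscores(cov)                                 # (n_cy, p)
    n_cy, p = Z.shape
    countries = cov["country"].to_numpy()
    country_ids = pd.factorize(countries)[0]
    n_countries = config.n_countries

    coefficients: dict = {}

    def scores_for(keys: list) -> np.ndarray:
        """(n_cy, n_cells) score matrix; coefficients recorded per key."""
        k = len(keys)
        B = rng.normal(0, config.coef_scale, size=(k, p))
        c = rng.normal(0, config.intercept_scale, size=k)
        U = rng.normal(0, config.country_sd, size=(k, n_countries))
        for j, key in enumerate(keys):
            coefficients[key] = B[j].copy()
        return c[None, :] + Z @ B.T + U[:, country_ids].T

    # level-1 shares on each axis
    hc_l1 = _softmax(scores_for([(c, TOTAL) for c in lay.hc_l1]))
    hp_l1 = _softmax(scores_for([(TOTAL, c) for c in lay.hp_l1]))
    # nested softmax within parents -> leaf shares
    hc_leaf = np.empty((n_cy, len(lay.hc_leaf)))
    for j, parent in enumerate(lay.hc_l1):
        kids = lay.hc_children_of(parent)
        if len(kids) == 1 and lay.hc_leaf[kids[0]] == parent:
            hc_leaf[:, kids] = hc_l1[:, [j]]
            continue
        props = _softmax(scores_for([(lay.hc_leaf[i], TOTAL) for i in kids]))
        hc_leaf[:, kids] = props * hc_l1[:, [j]]
    hp_leaf = np.empty((n_cy, len(lay.hp_leaf)))
    for j, parent in enumerate(lay.hp_l1):
        kids = lay.hp_children_of(parent)
        if len(kids) == 1 and lay.hp_leaf[kids[0]] == parent:
            hp_leaf[:, kids] = hp_l1[:, [j]]
            continue
        props = _softmax(scores_for([(TOTAL, lay.hp_leaf[i]) for i in kids]))
        hp_leaf[:, kids] = props * hp_l1[:, [j]]

    # leaf cross table: independence x low-rank interaction, then exact IPF
    a = rng.normal(0, config.interaction_scale, size=len(lay.hc_leaf))
    b = rng.normal(0, config.interaction_scale, size=len(lay.hp_leaf))
    gamma = np.exp(np.outer(a, b))
    cross0 = hc_leaf[:, :, None] * hp_leaf[:, None, :] * gamma[None, :, :]
    cross_leaf = raking.ipf(cross0, hc_leaf, hp_leaf, tol=1e-13, max_iter=2000)
    Mh = raking._member_matrix(np.asarray(lay.hc_leaf_parent), len(lay.hc_l1))
    Mp = raking._member_matrix(np.asarray(lay.hp_leaf_parent), len(lay.hp_l1))
    cross_l1 = np.einsum("nij,ia,jb->nab", cross_leaf, Mh, Mp)

    shares = raking.ShareDraws(
        index=cov[["country", "year"]].copy(),
        layout=lay,
        hc_l1=hc_l1[:, None, :],
        hc_leaf=hc_leaf[:, None, :],
        hp_l1=hp_l1[:, None, :],
        hp_leaf=hp_leaf[:, None, :],
        cross_l1=cross_l1[:, None, :, :],
        cross_leaf=cross_leaf[:, None, :, :],
        provenance="truth",
    )
    envelope = cov[["country", "year", "the_pc", "population"]].copy()
    envelope["the_total"] = envelope["the_pc"] * envelope["population"]
    return TruthBundle(
        config=config,
        layout=lay,
        covariates=cov,
        envelope=envelope,
        income_group=groups,
        shares=shares,
        coefficients=coefficients,
    )


# --------------------------------------------------------------------------
# Reporting process
# --------------------------------------------------------------------------

# inverse SHA 2011 -> SHA 2000 re-coding consistent with the default mapping
# rules: immunisation (HC6.2) and surveillance (HC6.5) merge into the coarse
# SHA 2000 "prevention of communicable diseases" code, healthy-condition
# monitoring (HC6.4) splits into the two SHA 2000 many_to_one sources, and
# IEC programmes (HC6.1) have no SHA 2000 slot, so such lines simply do not
# appear in an SHA 2000 report (folding them into NEC would bias that leaf).
_SHA2000_MERGE = {"HC6.2": "HC6.3", "HC6.5": "HC6.3"}
_SHA2000_SPLIT = {"HC6.4": (("HC6.1", 0.6), ("HC6.2", 0.4))}
_SHA2000_DROP = {"HC6.1"}


def conversion_factors(config: WorldConfig) -> pd.DataFrame:
    """Synthetic local-currency -> 2017-USD conversion factors.

    One currency per country, with a seeded (currency, year) factor table
    emitted alongside the observations; real exchange-rate/deflator series
    are an input to the pipeline, not something it estimates.
    """
    rng = np.random.default_rng([config.seed, 7])
    rows = []
    for i in range(config.n_countries):
        cur = f"CUR{i:03d}"
        base = rng.lognormal(0.0, 1.0)
        for t, year in enumerate(config.year_list):
            rows.append((cur, year, base * np.exp(0.01 * t + rng.normal(0, 0.005))))
    return pd.DataFrame(rows, columns=["currency", "year", "factor"])


def _recode_sha2000(rows: list[dict]) -> list[dict]:
    merged: dict = {}
    out = []
    for r in rows:
        hc = r["hc_code"]
        r = dict(r, sha_version=2000)
        if hc in _SHA2000_DROP:
            continue
        if hc in _SHA2000_SPLIT:
            for code, w in _SHA2000_SPLIT[hc]:
                out.append(dict(r, hc_code=code, amount=r["amount"] * w))
            continue
        hc2 = _SHA2000_MERGE.get(hc)
        if hc2 is not None:
            key = (hc2, r["hp_code"])
            if key in merged:
                merged[key]["amount"] += r["amount"]
            else:
                merged[key] = dict(r, hc_code=hc2)
            continue
        out.append(r)
    # NEC/rename targets may collide with rows already carrying that code
    for key, r in merged.items():
        match = next(
            (o for o in out if (o["hc_code"], o["hp_code"]) == key), None
        )
        if match is not None:
            match["amount"] += r["amount"]
        else:
            out.append(r)
    return out


def apply_reporting(
    truth: TruthBundle, config: WorldConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Push a truth world through the sparse reporting process.

    Returns ``(observations, conversion_factors)``.  Per country-year, each
    candidate record — every HC total, HP total and HC x HP cross cell — is
    reported with a propensity depending on record type, income group and
    year; reported amounts are the true share times the envelope with
    multiplicative log-normal noise, expressed in a synthetic local currency.
    A configured fraction of reports is replaced by zero, and pre-2011
    country-years may be re-coded to SHA 2000 categories.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 11])
    lay = truth.layout
    factors = conversion_factors(config)
    fmap = {(r.currency, int(r.year)): float(r.factor) for r in factors.itertuples()}

    yr0, yr1 = config.years
    span = max(yr1 - yr0, 1)
    f0, f1 = config.year_factor_range
    silent = set(
        rng.choice(
            sorted(truth.income_group),
            size=int(round(config.never_report_frac * config.n_countries)),
            replace=False,
        )
    )

    hc_codes = lay.hc.codes
    hp_codes = lay.hp.codes
    cands: list[tuple[str, str, int]] = []   # (hc, hp, type 0=l1 total,1=l2 total,2=cross)
    for c in hc_codes:
        cands.append((c, TOTAL, 0 if lay.hc.nodes[c].level == 1 else 1))
    for c in hp_codes:
        cands.append((TOTAL, c, 0 if lay.hp.nodes[c].level == 1 else 1))
    for a in hc_codes:
        for b in hp_codes:
            cands.append((a, b, 2))
    type_p = np.array([config.p_l1_total, config.p_l2_total, config.p_cross])
    cand_p = type_p[np.array([t for _, _, t in cands])]
    true_vals = {
        (hc, hp): truth.shares.get(hc, hp)[:, 0] for hc, hp, _ in cands
    }

    env = truth.envelope.set_index(["country", "year"])
    rows: list[dict] = []
    for i, (country, year) in enumerate(
        zip(truth.index["country"], truth.index["year"])
    ):
        if country in silent:
            continue
        g = truth.income_group[country]
        gf = config.income_factors[INCOME_GROUPS.index(g)]
        yf = f0 + (f1 - f0) * (year - yr0) / span
        p = np.clip(cand_p * gf * yf, 0.0, 1.0)
        hit = rng.random(len(cands)) < p
        if not hit.any():
            continue
        the_total = float(env.loc[(country, year), "the_total"])
        cur = f"CUR{int(country[1:]):03d}"
        factor = fmap[(cur, int(year))]
        noise = (
            np.exp(rng.normal(0.0, config.noise_sd, size=int(hit.sum())))
            if config.noise_sd > 0
            else np.ones(int(hit.sum()))
        )
        cy_rows = []
        for (hc, hp, _), nz in zip(
            [c for c, h in zip(cands, hit) if h], noise
        ):
            share = float(true_vals[(hc, hp)][i])
            # a reported component never exceeds the reported total
            usd = min(share * the_total * nz, the_total)
            if config.zero_rate > 0 and rng.random() < config.zero_rate:
                usd = 0.0
            cy_rows.append(
                {
                    "country": country,
                    "year": int(year),
                    "hc_code": None if hc == TOTAL else hc,
                    "hp_code": None if hp == TOTAL else hp,
                    "amount": usd / factor,
                    "currency": cur,
                    "report_vintage": int(year) + 2,
                    "sha_version": 2011,
                    "is_capital_formation": False,
                }
            )
        if (
            year < 2011
            and config.sha2000_rate > 0
            and rng.random() < config.sha2000_rate
        ):
            cy_rows = _recode_sha2000(cy_rows)
        rows.extend(cy_rows)
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return obs, factors


def linear_cell_dataset(
    beta: np.ndarray,
    n_countries: int = 15,
    years: tuple[int, int] = (2000, 2017),
    intercept: float = -3.0,
    country_sd: float = 0.3,
    noise_sd: float = 0.2,
    seed: int = 0,
):
    """A single-cell world drawn exactly from the regression model family.

    Generates covariates, then logit shares ``x'beta + alpha_c + eps`` with
    the given coefficient vector *on the standardised covariate scale*.
    Returns ``(covariates, shares, true_logit_mean)`` aligned row-wise; used
    for parameter-recovery and calibration checks where the model family must
    match the generator.
    """
    beta = np.asarray(beta, dtype=float)
    if len(beta) != len(SCORE_COVARIATES):
        raise SynthError(
            f"beta must have {len(SCORE_COVARIATES)} entries, got {len(beta)}"
        )
    rng = np.random.default_rng([seed, 3])
    T = years[1] - years[0] + 1
    n = n_countries * T
    # identifiable design: independent country-level trajectories with real
    # within-country variation, unlike the deliberately income-correlated
    # covariates of generate_world (where single slopes are confounded)
    p = len(SCORE_COVARIATES)
    z = np.empty((n_countries, T, p))
    for j in range(p):
        base = rng.normal(0, 1.0, size=(n_countries, 1))
        walk = np.cumsum(rng.normal(0, 0.25, size=(n_countries, T)), axis=1)
        z[:, :, j] = base + walk
    Z = z.reshape(n, p)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    cov = pd.DataFrame(
        {
            "country": np.repeat([f"C{i:03d}" for i in range(n_countries)], T),
            "year": np.tile(np.arange(years[0], years[1] + 1), n_countries),
            "gdp_pc": np.exp(9.0 + 0.5 * Z[:, 0]),
            "gov_share": np.clip(0.5 + 0.08 * Z[:, 1], 0.01, 0.99),
            "haq": 60.0 + 10.0 * Z[:, 2],
            "maternal_educ": 8.0 + 2.0 * Z[:, 3],
            "tfr": 3.5 + 0.8 * Z[:, 4],
            "hiv_prev": np.clip(0.05 + 0.012 * Z[:, 5], 1e-4, 1.0),
            "urban_prop": np.clip(0.5 + 0.11 * Z[:, 6], 0.01, 0.99),
            "the_pc": 500.0,
            "population": 1e7,
        }
    )[COV_COLUMNS]
    cids = pd.factorize(cov["country"])[0]
    alpha = rng.normal(0, country_sd, size=n_countries)
    mu = intercept + Z @ beta + alpha[cids]
    y = mu + rng.normal(0, noise_sd, size=len(mu))
    return cov, inv_logit(y), mu
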