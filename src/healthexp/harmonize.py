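"""Cleaning and harmonisation of reported National Health Accounts tables.

Country-reported expenditure tables arrive as long-format observation rows —
an HC total, an HP total, or one HC x HP cross cell per row, each with a
currency, a report vintage and an SHA guideline version.  This module applies
the cleaning rules of the estimation pipeline:

* when the same country-year appears in several report vintages, the most
  recently issued report wins (with an explicit per-country-year override
  list for reports with known completeness/accuracy problems);
* reported zeroes are removed — they systematically bias share models low —
  and capital formation is removed to align totals with the SHA 2011
  definition of current health expenditure;
* amounts are converted to 2017 US dollars with supplied conversion factors;
* amounts are divided by the country-year total-health-expenditure envelope
  to give shares, with unreported cells kept *missing* (never zero);
* shares are logit transformed for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import TOTAL, CategoryTree

#: schema of an observation table (long format, one report line per row)
OBS_COLUMNS = [
    "country",
    "year",
    "hc_code",
    "hp_code",
    "amount",
    "currency",
    "report_vintage",
    "sha_version",
    "is_capital_formation",
]

#: schema of the covariate/envelope table
COV_COLUMNS = [
    "country",
    "year",
    "the_pc",          # total health expenditure per capita, 2017 USD
    "population",
    "gdp_pc",          # GDP per capita, 2017 USD
    "gov_share",       # government share of THE, in [0,1]
    "haq",             # Healthcare Access and Quality index (0-100)
    "maternal_educ",   # average years of maternal education
    "tfr",             # total fertility rate
    "hiv_prev",        # age-standardised female HIV prevalence, in [0,1]
    "urban_prop",      # proportion of population living in urban areas
]

LOGIT_EPS = 1e-6


class HarmonizeError(ValueError):
    pass


def validate_observations(obs: pd.DataFrame) -> None:
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise HarmonizeError(f"observation table missing columns {missing}")
    if not np.isfinite(obs["amount"].to_numpy(dtype=float)).all():
        raise HarmonizeError("non-finite amount in observation table")
    no_code = obs["hc_code"].isna() & obs["hp_code"].isna()
    if no_code.any():
        raise HarmonizeError(
            f"{int(no_code.sum())} rows carry neither an HC nor an HP code"
        )


def dedupe_vintages(
    obs: pd.DataFrame, overrides: dict[tuple[str, int], int] | None = None
) -> pd.DataFrame:
    """Keep, per (country, expenditure-year), only the newest report vintage.

    ``overrides`` maps (country, year) to a vintage to prefer instead, for
    reports where the newest vintage has known completeness or accuracy
    issues — that judgement is configuration, not a heuristic.
    """
    if obs.empty:
        return obs.copy()
    overrides = overrides or {}
    best = obs.groupby(["country", "year"])["report_vintage"].transform("max")
    keep = obs["report_vintage"] == best
    for (country, year), vintage in overrides.items():
        sel = (obs["country"] == country) & (obs["year"] == year)
        keep = keep & ~sel | (sel & (obs["report_vintage"] == vintage))
    return obs[keep].reset_index(drop=True)


def drop_zero_and_capital(obs: pd.DataFrame) -> pd.DataFrame:
    """Remove reported zeroes and capital-formation rows.

    Zeroes are removed because retaining them systematically drags share
    estimates down; an unreported cell is treated as missing, never zero.
    Negative amounts are a data error, not something to drop silently.
    """
    amounts = obs["amount"].to_numpy(dtype=float)
    if (amounts < 0).any():
        bad = obs[amounts < 0].iloc[0]
        raise HarmonizeError(
            f"negative amount for {bad['country']} {bad['year']} "
            f"({bad['hc_code']}, {bad['hp_code']}): {bad['amount']}"
        )
    keep = (amounts != 0) & ~obs["is_capital_formation"].astype(bool)
    return obs[keep].reset_index(drop=True)


def convert_to_usd2017(obs: pd.DataFrame, factors) -> pd.DataFrame:
    """Convert amounts to 2017 USD via (currency, year) -> factor.

    ``factors`` is a mapping or a DataFrame with columns
    ``currency, year, factor``; ``amount_usd = amount * factor``.
    """
    if isinstance(factors, pd.DataFrame):
        factors = {
            (r.currency, int(r.year)): float(r.factor)
            for r in factors.itertuples()
        }
    out = obs.copy()
    fvals = np.empty(len(out))
    for i, (cur, yr) in enumerate(zip(out["currency"], out["year"])):
        if cur == "USD2017":
            fvals[i] = 1.0
            continue
        key = (cur, int(yr))
        if key not in factors:
            raise HarmonizeError(f"no conversion factor for currency {cur!r}, year {yr}")
        fvals[i] = factors[key]
    out["amount"] = out["amount"].to_numpy(dtype=float) * fvals
    out["currency"] = "USD2017"
    return out


@dataclass
class ShareTensor:
    """Reported expenditure shares on the country-year x HC x HP grid.

    Only *reported* cells are stored; every other grid cell is missing — a
    distinct state from zero.  ``data`` columns: country, year, hc, hp, share,
    where the pseudo-code :data:`healthexp.taxonomy.TOTAL` marks a margin
    (an HC total has hp == TOTAL and vice versa).
    """

    data: pd.DataFrame
    countries: list[str]
    years: list[int]
    _lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._lookup = {
            (r.country, r.year, r.hc, r.hp): r.share for r in self.data.itertuples()
        }

    def is_reported(self, country, year, hc=TOTAL, hp=TOTAL) -> bool:
        return (country, year, hc, hp) in self._lookup

    def share(self, country, year, hc=TOTAL, hp=TOTAL) -> float:
        """The reported share, or NaN when the cell is missing."""
        return self._lookup.get((country, year, hc, hp), float("nan"))

    def cell_frame(self, hc=TOTAL, hp=TOTAL) -> pd.DataFrame:
        """Reported rows for one (hc, hp) cell across country-years."""
        sel = (self.data["hc"] == hc) & (self.data["hp"] == hp)
        return self.data[sel]

    @property
    def n_reported(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["reported"] = True
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ShareTensor":
        df = pd.read_csv(path).drop(columns=["reported"], errors="ignore")
        return cls(df, sorted(df["country"].unique()), sorted(df["year"].unique()))


def to_share_tensor(
    obs: pd.DataFrame,
    cov: pd.DataFrame,
    hc: CategoryTree,
    hp: CategoryTree,
    tol: float = 1e-6,
) -> ShareTensor:
    """Divide harmonised amounts by the THE envelope to get reported shares.

    Precondition: ``obs`` is fully harmonised — one vintage per country-year,
    amounts in 2017 USD, SHA 2011 codes.  Surviving duplicate rows for one
    cell (sub-line items) are summed before division.  Cells never reported
    stay missing.
    """
    validate_observations(obs)
    if not (obs["currency"] == "USD2017").all():
        raise HarmonizeError("observations must be converted to USD2017 first")
    if (obs["sha_version"] != 2011).any():
        raise HarmonizeError("observations must be re-coded to SHA 2011 first")
    env = {
        (r.country, int(r.year)): float(r.the_pc) * float(r.population)
        for r in cov.itertuples()
    }
    work = obs.copy()
    work["hc"] = work["hc_code"].fillna(TOTAL)
    work["hp"] = work["hp_code"].fillna(TOTAL)
    for code, tree, axis in ((work["hc"], hc, "HC"), (work["hp"], hp, "HP")):
        unknown = set(code.unique()) - set(tree.codes) - {TOTAL}
        if unknown:
            raise HarmonizeError(f"unknown {axis} codes in observations: {sorted(unknown)}")
    grouped = (
        work.groupby(["country", "year", "hc", "hp"], as_index=False)["amount"].sum()
    )
    shares = np.empty(len(grouped))
    for i, r in enumerate(grouped.itertuples()):
        key = (r.country, int(r.year))
        if key not in env:
            raise HarmonizeError(f"country-year {key} absent from covariate table")
        shares[i] = r.amount / env[key]
        if shares[i] > 1 + tol:
            raise HarmonizeError(
                f"share {shares[i]:.4f} > 1 for {key} cell ({r.hc}, {r.hp})"
            )
    grouped["share"] = np.clip(shares, 0.0, 1.0)
    grouped = grouped.drop(columns=["amount"])
    return ShareTensor(
        grouped,
        countries=sorted(cov["country"].unique()),
        years=sorted(int(y) for y in cov["year"].unique()),
    )


def logit(p, eps: float = LOGIT_EPS):
    """log(p / (1-p)) with shares clipped into [eps, 1-eps] first.

    Clipping keeps the transform finite at the boundaries without materially
    moving any plausible share.
    """
    p = np.asarray(p, dtype=float)
    if not np.isfinite(p).all():
        raise HarmonizeError("non-finite input to logit")
    p = np.clip(p, eps, 1.0 - eps)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Exact inverse of :func:`logit` on the open interval."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise HarmonizeError("non-finite input to inv_logit")
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if out.ndim == 0 else out
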