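# Methods

`healthexp` estimates a complete country-year time-series of national health
expenditures cross-classified by SHA 2011 healthcare functions (HC) and
providers (HP), from sparse country-reported National Health Accounts.  The
pipeline has four stages — harmonisation, share regression, raking,
trend/report generation — plus a synthetic-data generator that makes every
stage testable against a known truth.  This note records the model, its
assumptions, the defaults, and the design choices made where the procedure
was genuinely open.

## Coordinate system

The default retained taxonomy keeps 41 HC and 21 HP categories at hierarchy
levels 1–2, giving 861 cross-classification cells.  Level-1 categories with
a published level-2 breakdown carry their standard SHA 2011 children plus an
NEC ("not elsewhere classified") residual leaf; categories without a
breakdown (ancillary services HC4 internals, rest-of-economy providers,
etc.) are completed with standard SHA 2011 subcodes or stand as their own
single leaf.  Both trees are JSON/YAML-overridable: the retained set is
configuration, only its invariants (forest structure, level nesting,
uniqueness) are code.  Level-3 nodes are representable for data storage but
excluded from modelling, because third-level reporting is too sparse to
estimate.

SHA 2000-coded reports are re-coded to SHA 2011 by a rule table
(configuration, not code).  Rule semantics: `one_to_one` and `many_to_one`
rules re-code deterministically (amounts summed within country-year for
shared targets); `one_to_many_ambiguous` rules — SHA 2000 categories split
across several SHA 2011 categories with undefined proportions, e.g. the old
"prevention of communicable diseases" block — cause the observation to be
*dropped* and its targets left missing, to be estimated by the model rather
than apportioned by guesswork.

## Harmonisation

Cleaning rules, in order:

1. **Vintages** — when one country-year appears in several report vintages,
   the newest report wins.  Overrides for reports with known
   completeness/accuracy problems are an explicit per-country-year
   configuration list, because that judgement was human, not algorithmic.
2. **Zeroes and capital** — reported zeroes are removed (keeping them drags
   share regressions systematically low); capital formation is removed so
   totals match the SHA 2011 current-expenditure envelope.  A negative
   amount is a validation error, never a silent drop.
3. **Currency** — amounts convert to 2017 USD by supplied (currency, year)
   factors; exchange-rate/deflator construction is an input, not estimated.
4. **Shares** — amounts divide by the country-year total-health-expenditure
   (THE) envelope.  Duplicate surviving rows for one cell (sub-line items)
   are summed.  An unreported cell is *missing*, a state distinct from
   zero, throughout the pipeline.

Shares are logit transformed for modelling, with clipping to
[1e-6, 1−1e-6] so the transform stays finite; no plausible share is moved
materially by the clip.  All modelling happens in share space; USD per
capita is produced only at reporting time as share × THE per capita.

## Share regression

Each modelled quantity — every HC total, HP total, the level-1 cross matrix
and the leaf-level cross matrix — gets an independent hierarchical linear
model on the logit share:

    logit(s_ct) = x_ct' β + α_c + ε_ct,   α_c ~ N(0, τ²),  ε ~ N(0, σ²)

Covariates: log GDP per capita, government share of THE, HAQ index,
maternal education years, total fertility rate, female HIV prevalence,
urban population proportion, and (default on) calendar year.  Covariates
are standardised internally; slopes get N(0, 2.5²) priors on that scale,
the intercept N(0, 5²), and the variances inverse-gamma priors
(σ²: IG(0.001, 0.001); τ²: IG(1, 0.25)).  The model is conjugate, so the
posterior is drawn by a seeded Gibbs sampler with the country intercepts
marginalised out of the β update (the naive update mixes pathologically
along the intercept/random-intercept ridge).  Split-R̂ is recorded per fit;
fits above 1.05 are flagged, never silently accepted.

**Why independent fits + raking, not one joint model:** the two-stage
architecture (unconstrained per-cell regressions, then raking to restore
additivity) mirrors the estimation procedure this package re-implements;
a joint multivariate likelihood over 600+ compositional cells would be a
different — and far heavier — model.

**Sparse cells.** A cell with fewer than `min_obs` (default 10) reports
falls back to a pooled model over its parent block (all cells sharing the
same level-1 parent or parent pair), stacked with zero-sum cell offsets and
an offset dispersion; a cell unobserved even there uses a family-wide pool,
and as a last resort prior-only draws.  Something defensible must predict
cells observed almost nowhere.

**Prediction.** Posterior predictive draws are produced for *all*
country-years, including never-reporting countries, whose country intercept
is drawn from N(0, τ²).  Draws include the residual term by default
(`ModelSpec.predictive_noise`): the residual absorbs both reporting error
and the structural deviation of a country-year's true composition from the
covariate model, and both belong in the uncertainty of an unreported cell —
in simulation, latent-only intervals undercover the known truth
substantially while full predictive intervals are calibrated.  GDP enters
as log GDP per capita, the standard scale for expenditure-composition work.

**Hold-out validation** masks a fraction of reported cells, refits, and
scores logit-scale RMSE and 95%-interval coverage on the held-out cells
(these are noisy observations, so their predictive intervals include the
residual term by construction).

## Raking

Raking restores exact additivity on each posterior draw, per country-year,
top-down:

1. level-1 HC shares are scaled onto the unit simplex; likewise HP;
2. within each level-1 parent, leaf children scale to the parent's raked
   share (a childless level-1 node stands as its own leaf);
3. the level-1 HC×HP cross matrix is raked to the level-1 margins by
   iterative proportional fitting (IPF);
4. the leaf cross matrix is raked cyclically over three constraint families
   — leaf row totals, leaf column totals, and the level-1 block totals from
   step 3 — until the worst relative discrepancy drops below tolerance
   (default 1e-10; cycle cap 500).

The top-down order guarantees each stage's margins are feasible for the
next.  IPF preserves the interaction (odds-ratio) structure of the modelled
tables while the totals sum correctly; zero cells stay zero, and a positive
margin over an all-zero slice is an infeasibility *error*, not a silent
repair (model predictions are strictly inside (0,1), so structural zeros
arise only in stress tests).  A draw whose cyclic stage misses the cycle
cap is flagged and excluded from summaries, not dropped silently.  The
batch implementation vectorises over draws and country-years with an
active-set loop, in float64.

**Summaries.**  Means and 2.5th/97.5th-percentile bounds over raked draws,
per cell × country-year, in share and USD-per-capita space.  Percentiles
use the Hyndman–Fan type-5 ("hazen") linear-interpolation definition, under
which the bounds of the draws {1,…,1000}/1000 are 0.0255 and 0.9755.

## Trends and aggregation

The share-vs-income relationship for a cell is a penalized-spline GAM:
share ~ s(log GDP pc) + s(year), fractional-logit (binomial) family with
estimated scale, B-spline bases (default df 6 and 5), smoothing chosen by
generalized cross-validation via `statsmodels` `GLMGam.select_penweight`.
The year smooth controls for secular trends so the GDP curve is not a time
artefact.  Curves are defined over the observed GDP support only —
evaluation outside it raises, by design.  An exactly constant response
short-circuits to the flat curve (the IRLS fit degenerates there).

Income-group aggregation is draw-wise *before* percentile computation:
group share = Σ_c share_c·THE_c / Σ_c THE_c and group USD per capita
= Σ_c share_c·THE_c / Σ_c population_c over member countries.  Membership
is an input table with a single reference-year mapping.

## Synthetic worlds

The generator emulates the *structure* of compiled National Health
Accounts, not any real country:

- **Covariates** follow smooth country trajectories anchored to one of four
  income groups, deliberately correlated the way development indicators are
  (HAQ, education, fertility, urbanisation all track log GDP).
- **Truth shares**: each modelled category gets a score = cell intercept
  (N(0,1)) + covariate effects (N(0, 0.4²) per cell, on the standardised
  scale) + country intercept (N(0, 0.5²)); level-1 shares are the softmax
  over level-1 scores, children a nested softmax within their parent, and
  the leaf cross table an independence × rank-1 log-linear interaction
  (N(0, 0.3²) factors) normalised onto the exact margins by IPF.  All
  hierarchical constraints hold by construction to ~1e-15.
- **Reporting**: every HC total, HP total and cross cell is a candidate
  record, reported with propensities 0.60 / 0.40 / 0.08 (level-1 totals /
  level-2 totals / cross cells), modulated ≈2× from low- to high-income
  groups and rising over the years; the cross-cell base rate targets the
  ~8% average completeness of real reported matrices, and totals are
  reported at a much higher rate, as observed.  A quarter of countries
  never report.  Amounts carry multiplicative log-normal noise (σ = 0.2 —
  positive amounts, roughly symmetric logit-scale errors; the magnitude is
  a scenario parameter, not an estimate of real reporting error), are
  capped at the envelope, expressed in a synthetic per-country currency
  with an emitted conversion-factor table, zeroed with probability 0.01,
  and pre-2011 country-years are re-coded to SHA 2000 with probability 0.3
  (merging the ambiguous prevention block, splitting healthy-condition
  monitoring into its two SHA 2000 sources, and dropping categories with no
  SHA 2000 slot).

What a green test does *not* establish: the generator's covariate process
is smoother and its noise better behaved than real accounts; softmax truth
means per-cell logit shares are only approximately linear in covariates, so
end-to-end checks include genuine model misspecification but not reporting
pathologies like systematic category misassignment or within-report
inconsistency.  Separately, `linear_cell_dataset` draws a single cell
exactly from the regression family with an *identifiable* (independent,
time-varying) covariate design; it exists for parameter-recovery and
calibration checks, where the income-collinear world would confound
individual slopes — as the real data would.

## Numerical choices

- logit clipping 1e-6; share-over-envelope tolerance 1e-6 before erroring.
- IPF and raking tolerance 1e-10 relative, iteration caps 1000 (IPF) and
  500 (cyclic stage); conservation audited to 1e-8 absolute.
- Percentiles: Hyndman–Fan type 5.
- Gibbs: 2 chains × 1000 iterations (500 warmup) by default; draws
  subsampled deterministically to `n_draws` = 1000; all randomness flows
  from explicit seeds (cell-specific streams derived via CRC32, not
  Python's salted `hash`).
- Draw tensors are float64; raking is chunked over country-years (64 per
  chunk) to bound memory.

## Known limitations

- Mixed-level cross observations (a level-1 HC against a level-2 HP) are
  harmonised and stored but do not inform the fit; only totals, the
  level-1 cross matrix and the leaf cross matrix are modelled.
- Cells are fit independently; cross-cell posterior correlation enters only
  through raking, so joint uncertainty across cells is approximate.
- The retained-category lists and the SHA 2000 mapping shipped as defaults
  are structural stand-ins completed from the published hierarchy; both are
  designed to be replaced by configuration.
- Income-group membership is static; year-varying group changes are out of
  scope.
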