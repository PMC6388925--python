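# Methods

This note documents the models and procedures `posdev` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## Performance indicators

Five scores approximate the five development goals (food security,
nutrition, income, environmental sustainability, social equity):

* **Caloric food security.** The sufficiency ratio divides per-MAE daily
  food availability by the caloric requirement (default 2,550 kcal/MAE/day,
  Tanzania's recommended intake) and caps at 1. Because availability is
  already expressed per MAE per day, it is *not* divided by household size
  again — doing so would double-count the MAE normalisation. Sufficiency
  and the number of food-secure months (12 − insecure months) are
  standardized to mean 0 / sd 1 (their units are incommensurable: a
  fraction vs months) and the household scores on the first principal
  component form the composite. The component is sign-oriented by positive
  loading sum so that higher = more food secure; if the two measures were
  negatively correlated no orientation can increase with both, and the fit
  warns. The fraction of variance explained by PC-1 is reported with the
  fit.
* **Dietary diversity.** Harmonic mean of good- and lean-season HDDS. The
  harmonic mean penalises a weak season more than the arithmetic mean
  (h ≤ a, equality iff the seasons are equal); it is defined as 0 when
  either season is 0, its limiting infimum, since 2/(1/g + 1/l) is
  otherwise undefined there.
* **Cash income.** Farm-gate plus off-farm income.
* **GHG score.** Emissions × (−1), making all five dimensions
  maximisation-oriented. Emission totals are an input column; recomputing
  them from activity data is out of scope.
* **Gender equity.** The published per-household-type formulas live in a
  supplement that is not reproduced here, so the package implements a
  configurable linear-discount family as a documented stand-in:
  score = 1 − w(type) · 2 · |female_share − 0.5|, clipped to [0, 1]. It is
  1 exactly at an equal split for every type and symmetric about 0.5.
  Default weights: couples and absent-spouse households 1.0; single-headed
  households 0.5 (a single head cannot fully share decisions, so their
  deviation is discounted). The weight table is config-replaceable.

**Outlier capping.** Each indicator column is winsorised: values beyond a
validity bound are replaced by the most extreme observed in-range value.
The default bound is the 99th-percentile *observed* order statistic
(numpy `method="lower"`), capping the high end only; absolute per-indicator
bounds and low-end capping are configurable. Using an observed order
statistic rather than an interpolated percentile makes the operation
idempotent: re-applying the rule to a capped vector finds the same bound
and changes nothing. The original analysis identified outliers by
graphical inspection; a percentile default is the closest reproducible
automatic rule, and judgment-based absolute bounds can be supplied in
config.

## Relative performance

Absolute scores confound behaviour with endowments, so deviance is defined
on residuals over expected performance. Per dimension, a median regression
(quantile τ = 0.5, fixed — the config rejects any other value) is fit on
up to five covariate groups: land (ha), livestock (TLU), household size
(MAE), region (dummy group, entering and leaving together, counted as
levels − 1 parameters), and market access. Market access is proxied by the
mean observed market orientation of the household's village (self
included), on the assumption that village-mean utilisation reflects
potential access.

Fitting is delegated to `statsmodels` QuantReg (IRLS); any algorithm that
attains the global check-loss minimum within tolerance is acceptable, and
the test suite verifies optimality against an exhaustive
vertex-interpolation oracle on small instances (the optimal median fit
interpolates p + 1 data points).

Model selection is an exhaustive search over all 2⁵ covariate subsets per
dimension using an AIC for quantile regression. No standard AIC exists at
the median; the asymmetric-Laplace profile-likelihood form is used:

    AIC = 2k + 2n · ln( (1/n) Σᵢ ρ₀.₅(eᵢ) ),   ρ₀.₅(e) = |e|/2,

with k the number of coefficients including the intercept and additive
constants dropped. This is a monotone function of mean check loss
penalised by 2k, matching common practice; a perfect fit (zero loss, up to
1e-9·n numerically) yields a −∞ sentinel with a warning. Ties break toward
fewer parameters, then earlier lexicographic subset order — deterministic
given input order. Covariates enter untransformed.

## Pareto ranking

x dominates y when xᵢ ≥ yᵢ in every dimension with at least one strict
inequality (standard weak-dominance-with-strict-improvement; identical
residual vectors co-rank). Rank-1 is the non-dominated set; removing it
and recomputing gives rank-2, whose members are dominated only by rank-1
households. Positive deviants are all households with rank ≤
`max_front_rank` (default 2; front depth is a config choice because the
"reasonable number" of deviants is data-driven). Comparisons use raw
floating-point residuals with no epsilon: residuals are continuous, so
exact ties only arise structurally. The implementation is plain O(n²·d)
pairwise peeling — at survey scale (n ≈ 500) this is milliseconds, and the
suite checks exact agreement with an independent brute-force oracle.

## Deviance profile

Residuals are z-standardized per dimension over *all* households (sample
sd, ddof = 1, consistent with the correlation conventions used
downstream), so a deviant-group mean of, say, +0.7 reads as "0.7 sd above
the population mean". Strata: land deciles from empirical ranks (ties
share the lower decile — deterministic and robust to heaped survey
values), crossed with a livestock median split (low iff TLU ≤ median; with
a median of 0 this is presence/absence). Profile tables aggregate deciles
in pairs (1+2, …, 9+10) household-weighted, report livestock classes and
the overall deviant mean, and emit empty strata as zero-count rows.
Pearson correlations between the deviance dimensions are computed over
deviants only, with two-sided p-values flagged at p < .05 (unadjusted; no
multiple-testing correction by design). The group comparison uses Welch's
t-test by default for numeric characteristics — a deliberate robustness
deviation from the classical Student test, which remains available via
`group_test: student` — and a chi-square independence test for categorical
ones.

## Case selection

One deviant per occupied stratum, rank-1 preferred unconditionally over
rank-2 within a stratum. Diversity of the selected subset is its mean
crowding distance over four characteristics (MAE, land, livestock, market
access; region is excluded as categorical), min-max normalized within the
deviant pool. The NSGA-II convention assigns boundary points infinite
distance, which makes a mean ill-defined; boundaries instead receive a
finite contribution of 2 per characteristic, strictly above the interior
maximum of 1, preserving "extremes are most diverse" while keeping the
mean usable as an objective. The "stepwise" maximisation is a greedy pass
over strata (ascending land decile, low livestock before high) followed by
single-swap improvement passes until no swap helps; on every instance
small enough to enumerate, this attains the exhaustive optimum (asserted
in tests). Distances are computed within the provisional selection;
computing them within the full deviant pool is exposed as a config switch
since either reading of the original procedure is defensible.

## Resource homologues

Six resource endowments are configurable expressions over survey columns;
the published proxy definitions live in an unreproduced supplement, so the
defaults are documented stand-ins: agro-ecological ability = crop
diversity, labor = MAE, financial capital = total income, land holdings =
ha, livestock holdings = TLU, social capital = the market-access proxy.
Profiles are z-standardized before Euclidean distance — in raw units
income would dominate the metric. Euclidean (not Mahalanobis) distance is
intentional: positive and negative deviations count equally and
correlations between resources are ignored. A household that is itself a
visited deviant matches itself at distance 0 (so per-homologue counts sum
to the full sample); a config switch excludes self-matches. Ties break by
ascending household id. Practice menus are unions over the k = 3
homologues' recorded practices; a visited deviant with no recorded
practice contributes nothing.

## Synthetic data

The generator emulates the *structure* of the study data, not its exact
marginals: 521 households by default, three regions with (20, 20, 4)
villages and ~12 households per village; log-normal land (mean ≈ 3.7 ha);
zero-inflated log-normal livestock (median 0 TLU); truncated-normal MAE
(mean 4.2); village-level Beta market orientation; outcomes (availability,
insecure months, seasonal HDDS, incomes, GHG, decision shares) that depend
on land, market access and region so the regression stage has real signal
to remove. A continuous latent "management quality" ~ N(0, 1) enters every
outcome with a coefficient equal to that outcome's noise scale on its link
(log-sd for log-normal/gamma outcomes, 1/√λ on the Poisson log-rate, an
sd-matched logit slope for binomial HDDS, a deviation-shrink matched to
the share sd for decision shares), so one latent sd moves each outcome by
about one noise sd. Planted deviants (default 10% of households) get an
additional favourable latent shift of `deviant_effect` (default 2.0, i.e.
≈ two noise sd on every outcome). All randomness flows through one seeded
generator with deterministically spawned substreams; the same seed yields
byte-identical tables.

What the generator does *not* emulate: reporting error and heaping,
missingness, informative non-response, spatial autocorrelation beyond the
village/region hierarchy, and realistic Tanzanian marginal distributions.
Tests passing on synthetic data therefore demonstrate that the pipeline
recovers the kind of structure it assumes — covariate-driven outcomes plus
household-level behavioural deviation — not that any particular real
survey satisfies those assumptions.

The practice catalog generator anchors every practice on one planted
deviant (so each practice has a holder) and adds further holder–practice
pairs at a rate calibrated to a mean of ~2.2 practices per deviant.

## Numerical conventions and degenerate inputs

* z-standardization throughout uses sample sd (ddof = 1); constant columns
  raise rather than silently producing zeros.
* Median-fit residual signs satisfy the median band |share(e > 0) − ½| ≤
  2/√n up to tie mass; this is asserted per fit in the tests.
* Validation drops records listwise when any indicator-required field is
  missing or out of range (residual ranks are undefined on imputed
  outcomes); more than 50% of records failing aborts the run as a schema
  mismatch. Duplicate household ids and villages spanning regions are
  table-level errors.
* All-tied land values collapse to decile 1 with a warning; an all-zero
  livestock column makes everyone "low".
* Negative GHG emissions are kept (score becomes positive) with a warning.

## Known limitations

* The gender-equity family and the six resource proxies are structural
  stand-ins for unpublished supplementary formulas; conclusions sensitive
  to either should be checked against the replaced expressions via config.
* The AIC variant for median regression is one defensible choice among
  several; the exhaustive-search selector makes swapping the criterion
  trivial.
* Deviant counts depend on front depth and on capping choices; the
  pipeline reports its own counts and never hard-codes published ones.
* Qualitative practice discovery (interviews, farm visits) is represented
  only by the practice-catalog input; the pipeline is honest about what is
  computable from the survey alone.
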