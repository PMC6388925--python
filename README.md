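# posdev

Positive Deviance analysis of multi-indicator rural household surveys.

Development programmes for smallholder agriculture pursue several goals at
once — food security, nutrition, income, environmental sustainability,
gender equity — and the practices worth promoting differ between households
with different resources. `posdev` implements the quantitative backbone of
the Positive Deviance approach for this multi-objective setting: it finds
the households that do *better than expected given their endowments* across
all five dimensions simultaneously, profiles where that deviance
concentrates, selects a diverse subset for qualitative follow-up, and then
matches every surveyed household to the positive deviants most similar to
it in resources, yielding a household-specific menu of candidate practices.

It is aimed at researchers and development practitioners working with
RHoMIS-style household survey tables (one row per household: land in ha,
livestock in TLU, household size in male adult equivalents, seasonal
dietary-diversity scores, incomes, GHG emissions, decision-making shares).

## Method

1. **Indicators.** Five performance scores per household *i*:
   caloric food security (PC-1 of the standardized capped sufficiency ratio
   min(availability / 2550, 1) and the number of food-secure months
   12 − m_i), dietary diversity (harmonic mean of good- and lean-season
   HDDS), cash income (farm + off-farm, US$/yr), GHG score (−1 × emissions,
   so less is better becomes more is better), and gender equity
   (1 − w(type) · 2·|f_i − 0.5|, maximal at an equal decision split).
   Implausible outliers are replaced by the largest observed in-range value.
2. **Relative performance.** Per dimension, a median regression
   (τ = 0.5, check loss ρ₀.₅(e) = |e|/2) of the score on land, livestock,
   household size, region, and village-mean market access; covariate subsets
   are chosen by an asymmetric-Laplace AIC, `2k + 2n ln(Σρ/n)`, over all
   2⁵ subsets. The residual e_i = y_i − ŷ_i is household *i*'s deviance.
3. **Pareto ranking.** A household is a positive deviant if its 5-vector of
   residuals lies on the rank-1 (non-dominated) or rank-2 front
   (dominated only by rank-1 households).
4. **Profile.** Residuals are z-standardized over the whole sample; mean
   deviance of the deviant group is reported per resource stratum (land
   deciles × livestock median split, 20 strata), with Pearson correlations
   between deviance dimensions and a deviants-vs-others comparison table.
5. **Case selection.** One deviant per occupied stratum (rank-1 preferred),
   the subset chosen to maximise mean NSGA-II crowding distance over
   household size, land, livestock and market access.
6. **Resource homologues.** Every household is matched to its k = 3 nearest
   visited deviants by Euclidean distance on six standardized resource
   proxies; the union of their observed practices is the household's
   practice menu, and menu membership counts give per-practice target
   numbers.

## Worked example

Generate a synthetic survey with planted deviants and run the pipeline:

```bash
posdev synth --seed 42 --out demo/
posdev run --input demo/survey.csv --outdir demo/results --seed 42
```

or from Python:

```python
from posdev import SyntheticSpec, generate_households, run_positive_deviance

records, truth = generate_households(SyntheticSpec(seed=42))
summary = run_positive_deviance(records)
print(summary["rank_counts"], summary["n_positive_deviants"])
print(summary["selected_models"]["cash_income"])
```

which prints

```
{1: 29, 2: 68} 97
['land_ha', 'market_access']
```

Of the 521 generated households, 29 sit on the rank-1 Pareto front of the
five residual dimensions and 68 on rank-2, so 97 households (~19%) are
flagged as positive deviants; for cash income the AIC search kept land and
market access as performance determinants, and the residual over that
median fit is each household's income deviance. The run summary further
reports that deviants occupy 19 of the 20 resource strata, and the case
selection picks one deviant per occupied stratum (19 cases, mean crowding
distance 1.23). Stage tables (`indicators.csv`, `residuals.csv`,
`pareto.csv`, `strata.csv`, `deviance_profile.csv`, `case_selection.csv`,
`homologues.csv`, `practice_targeting.csv`) and `run_summary.json` land in
the output directory.

With a real survey export, pass a YAML config to adapt column names,
capping bounds, gender-equity weights or resource-proxy expressions; see
`docs/methods.md` for every knob and its default.

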