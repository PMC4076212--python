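# geoadd

Bayesian geo-additive mapping of overweight/obesity prevalence from
DHS-style survey data.

`geoadd` is for epidemiologists and biostatisticians who need to estimate
the geographic distribution of a binary nutrition outcome — combined
overweight/obesity (BMI ≥ 25) versus normal weight — across administrative
regions while adjusting for individual-level risk factors, as in national
Demographic and Health Surveys. It implements the full pipeline: WHO BMI
categorization and analysis-set construction, descriptive prevalence
cross-tabs with chi-square / Mann-Whitney tests and crude odds ratios,
maximum-likelihood logistic regression with grouped age, and a fully
Bayesian geo-additive logit model

    eta_i = x_i' beta + f(age_i) + f(partner_age_i) + u_{s(i)} + v_{s(i)}

with penalized B-spline (RW2) priors on the smooth age effects `f`, an
intrinsic CAR (ICAR) prior on structured spatial effects `u`, iid Gaussian
unstructured region effects `v`, inverse-gamma hyperpriors on all variances,
and exact Pólya-Gamma-augmented Gibbs sampling. Outputs are posterior
odds-ratio (POR) tables with credible regions, nonlinear-effect curves with
80% bands, and choropleth-ready maps categorizing each region's total
effect u + v as positive / negative / not significant.

Because the real survey microdata are restricted-access, the package ships
a synthetic-data generator that emulates the record schema and the published
marginal profile of the 2008 Nigeria DHS (including the 31-region state
aggregation and its adjacency graph) with fully known ground truth, so every
stage is testable end to end.

## Worked example

```python
from geoadd import (SimulationConfig, simulate_survey, make_lattice_graph,
                    build_analysis_set, gibbs_sampler, MCMCConfig,
                    summarize_fixed, nonlinear_curve, categorize_map)

graph = make_lattice_graph(4)
records, truth = simulate_survey(
    SimulationConfig(n_individuals=4000, graph=graph, seed=1))
analysis = build_analysis_set(records)
print("ledger:", analysis.ledger)

draws = gibbs_sampler(analysis, graph=graph,
                      config=MCMCConfig(iterations=2000, burn_in=500,
                                        thinning=3, seed=2))
por = summarize_fixed(draws)
print(por.loc[por.term.isin(["residence[urban]", "wealth[richest]"]),
              ["term", "display"]].to_string(index=False))
curve = nonlinear_curve(draws, "age_respondent")
print("age-effect peak:",
      curve["age_respondent"][curve["posterior_mean"].idxmax()])
print(categorize_map(draws)["category"].value_counts().to_dict())
```

prints

```
ledger: {'input': 4000, 'underweight_excluded': 469, 'incomplete_excluded': 0, 'retained': 3531}
            term           display
residence[urban] 1.43 (1.18, 1.73)
 wealth[richest] 3.04 (2.31, 3.98)
age-effect peak: 49.0
{'none': 7, 'negative': 5, 'positive': 4}
```

The ledger shows the 4,000 simulated women split into the underweight
stratum (excluded, mirroring the survey analysis convention) and the
retained binary-outcome analysis set. The POR rows read as "urban residents
have 1.43 (95% CR 1.18–1.73) times the odds of overweight/obesity of rural
residents, adjusted for everything else in the model" — the generator's true
values are 1.24 and 3.45, inside both intervals. The smooth age effect peaks
near the true peak at 45 years, and the map table counts how many of the 16
lattice regions have credible regions for their total spatial effect above,
below, or straddling zero at the 80% nominal level.

The same pipeline is available from the shell:

```sh
geoadd demo --seed 3 --scale small --out demo_run/   # one-command demo
geoadd simulate --nigeria --n 25000 --seed 1 --out sim/
geoadd preprocess --in sim/records.csv --out analysis.csv --ledger ledger.json
geoadd describe --in analysis.csv --by state,wealth --out tables/
geoadd fit-marginal --in analysis.csv --out marginal_or.csv
geoadd fit-geoadd --in analysis.csv --graph sim/graph.txt --seed 1 --out draws/
geoadd summarize --draws draws/ --map-level 0.80 --out report/
```

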