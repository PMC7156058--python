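# splicerail

Statistical evaluation of splicing/polyadenylation mRNA biomarkers of
myotonic dystrophy type 1 (DM1).

DM1 is caused by an expanded CTG repeat whose length — the Modal Allele
Length (MAL), in repeat units — tracks disease severity. Because the
expansion disrupts alternative splicing and polyadenylation genome-wide,
probe-level exon-array expression can be used to predict an *effective
repeat length*: the repeat size as judged by the degree of splicing
disruption. An effective treatment should lower the effective repeat
length even though the genomic repeat is unchanged, which makes such a
predictor a candidate molecular endpoint for clinical trials.

`splicerail` is for statisticians and genomics analysts building or
auditing that kind of biomarker. It provides:

* **Predictor** — repeated 70/30 resampling; per repetition, selection of
  the (up to) 500 probes most |Pearson|-correlated with MAL on the
  training participants, then a 2-component PLSR fit (lasso, linear
  regression and random-forest comparators behind the same interface).
  Test predictions are pooled across repetitions into
  R² = corr(predicted, measured)² and RMSD.
* **Simulated-null significance** — the R² of a "random predictor" is
  simulated by permuting MAL and rerunning the full loop (selection
  included); the empirical p-value is (1 + #{null ≥ observed})/(n_null+1).
* **Power analysis** — Monte-Carlo power to detect a 10/20/50% reduction
  in effective repeat length for cohorts of 10–200, using the evaluated
  model's own prediction-error distribution and a fully simulation-based
  two-tailed rejection region at α = 0.05.
* **Railway plots** — Manhattan-style per-gene views of signed
  −log10 p from per-probe regressions of intensity on MAL, probeset-
  coloured, with nominal and Bonferroni thresholds; Fisher's method and
  Bonferroni correction for combining evidence across studies.
* **Data layer** — Affymetrix CEL v4 binary reader/writer, quantile
  normalisation + log2, strict protein-coding annotation filtering,
  per-gene probe tables, and a synthetic-data generator that emulates the
  whole study (cohort, chip layout, biomarker effects) so everything runs
  without any external download.

See `docs/methods.md` for the model, its assumptions and every numerical
convention.

## Worked example

Generate a synthetic study with a strong biomarker signal and evaluate it:

```python
from splicerail import (
    SyntheticConfig, generate_dataset, build_probe_table,
    PredictorConfig, evaluate_with_null,
)

ds = generate_dataset(SyntheticConfig(seed=1, effect_beta=2.0, noise_sd=0.5))
table, _ = build_probe_table(ds.raw_intensities, ds.annotation)
mal = ds.cohort.set_index("participant_id")["mal"]

cfg = PredictorConfig(gene_set=tuple(ds.biomarker_genes),
                      n_repetitions=200, seed=1)
res = evaluate_with_null(table, mal, cfg, n_null=199)
print(f"R2={res.r2:.3f}  p={res.p_value:.3f}  RMSD={res.rmsd:.1f}")
```

This prints

```
R2=0.937  p=0.005  RMSD=84.6
```

i.e. the pooled cross-validated predictions explain 93.7% of MAL variance
(in the correlation sense), the p-value sits at the floor of a 199-replicate
null (0.005 = 1/200, so the observed R² beat every permutation null), and
predictions are off by ~85 repeat units RMS. Feed the result into the power
module to size a trial:

```python
from splicerail.power import (PowerConfig, power_table,
                              residual_pool_from_evaluation,
                              mal_pool_from_evaluation)

pw = power_table(PowerConfig(n_sim=10_000, seed=1),
                 residual_pool_from_evaluation(res),
                 mal_pool_from_evaluation(res))
print(pw.loc[30, "effect_0.5"])   # 1.0 — a 50% effect is certain at n=30
```

The same workflow is scriptable from the shell (`splicerail simulate`,
`preprocess`, `evaluate`, `power`, `railway`, `run-all`); `run-all
--simulate --profile test` executes every stage end to end on generated
data and writes tab-delimited outputs plus a JSON run manifest.

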