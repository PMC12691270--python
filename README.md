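# siristrat

Survival risk stratification for oropharyngeal head-and-neck cancer
from three pre-treatment variables: the systemic inflammation response
index (SIRI), Karnofsky performance status (KPS) and smoking history.

Large random survival forests predict these outcomes well but cannot be
used at the bedside.  This package implements the pipeline that distils
a forest into an interpretable rule:

1. **Random survival forest** (1000 trees, log-rank splitting) over the
   cohort covariates, with C-index, permutation variable importance and
   time-dependent AUC.
2. **Forest-derived cutoff discovery** — the core algorithm.  Every
   internal-node threshold for a continuous predictor is harvested from
   the forest; the kernel density of those thresholds (node-size
   weighted) is compared with the kernel density of the predictor in
   the training data, and cutoffs are taken at concentrated local
   maxima of the difference, discarding any cutoff that carves off less
   than 10% of the cohort.  With SIRI this recovers the clinical
   threshold 3.5.
3. **Robust decision tree** on the discretized covariates (depth ≤ 3,
   leaf ≥ 40, log-rank splitting), whose leaves are merged into three
   ordered risk groups by training Kaplan–Meier survival at 24 months:

       SIRI ≥ 3.5                     → Group 3 (worst, regardless of rest)
       SIRI < 3.5 and KPS ≤ 70        → Group 3
       SIRI < 3.5, KPS > 70, ever-smoker  → Group 2
       SIRI < 3.5, KPS > 70, never-smoker → Group 1

4. **Validation statistics** — KM curves, log-rank tests, pairwise Cox
   hazard ratios with Holm–Bonferroni adjustment, 75th-percentile risk
   stratification, calibration and cloglog recalibration.

The original patient cohorts are private, so the package ships a
synthetic-cohort generator with the published covariate marginals
(SIRI median 1.34, KPS bands 27/64/9%, smoking 31/54/15%) and a Weibull
proportional-hazards process with planted threshold effects at
SIRI = 3.5 and KPS = 70 — every pipeline stage can therefore be tested
against known ground truth.  SIRI itself is computed from a complete
blood count as `neutrophils × monocytes / lymphocytes`.

## Worked example

```python
from siristrat import PipelineConfig, run_full

result = run_full(PipelineConfig(seed=1, outdir="scratch/run1"))
print(result["cutoffs"]["siri"])     # [3.4769611499497017]
for rule in result["tree_rules"]:
    print(rule)
print(round(result["agreement_with_truth"], 3))
```

prints

```
[3.4769611499497017]
IF kps in {60} THEN group 3 (n=43)
IF kps not in {60} AND smoking in {ever} THEN group 2 (n=251)
IF kps not in {60} AND smoking not in {ever} THEN group 1 (n=126)
0.922
```

The pipeline generated a 600-patient cohort, split it 70/30, fitted the
forest on the training part, rediscovered a SIRI cutoff of 3.48 (true
planted value 3.5), grew and merged the tree, and assigned 92.2% of
test patients to their true planted risk group (this seed's tree routes
high-SIRI patients through the smoking branch, the dominant source of
its 8% disagreement).  The accompanying report contains the test-set
log-rank p (0.0016 here) and pairwise hazard ratios (Group 2 vs 1:
2.87; 3 vs 1: 4.34; 3 vs 2: 1.62).

A command-line interface mirrors the stages:

```sh
siristrat simulate --seed 1 --outdir run
siristrat discover run/train.csv --variable siri
siristrat full --seed 1 --outdir run
```

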