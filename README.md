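# emprs

Episodic-memory-weighted polygenic risk scores (emPRS) for cognitive
decline in preclinical Alzheimer's disease.

Conventional Alzheimer's polygenic risk scores weight variants by
disease-risk odds ratios, and their associations with cognition — above
all once APOE is removed — have been inconsistent. `emprs` implements an
alternative: weight each variant of a fixed 27-gene panel by its effect
size on **decline in verbal episodic memory**, the domain that
deteriorates first in preclinical disease, measured in a reference sample
of amyloid-high cognitively normal older adults. The score of a subject is

    emPRS = Σₙ RAₙ · dₙ

where RAₙ ∈ {0,1} indicates carriage of variant *n*'s assigned risk
genotype (the faster-declining dominant-model group) and dₙ is its
Cohen's *d* on verbal-episodic-memory slopes. Scores are computed with
and without the APOE ε4 entry, and evaluated against decline in three
cognitive composites (global, verbal episodic memory, AIBL-PACC) in a
held-out test sample, overall and stratified by ε4 carriage.

The package is aimed at researchers evaluating endophenotype-weighted
scores in longitudinal ageing cohorts: it ships the published weight
panel, derives fresh panels from slope data, resolves APOE ε genotypes
from rs429358/rs7412, applies the KL-VS homozygote exclusion, and fits
the random-intercept mixed models used for validation. A synthetic-cohort
generator with genotype-dependent decline provides fully reproducible
end-to-end runs without access to restricted study data.

## Worked example

Score a subject who carries the APOE ε4 risk genotype plus the three
largest non-APOE weights (MEF2C, the HLA cluster, FERMT2):

```python
from emprs import load_reference_panel, compute_emprs
from emprs.scoring import GenotypeRecord, exemplar_calls

panel = load_reference_panel()
rec = GenotypeRecord.from_calls(
    "subj01", exemplar_calls(panel, {"APOE", "MEF2C", "HLA cluster", "FERMT2"})
)
[score] = compute_emprs([rec], panel)
print(f"emPRS with APOE:    {score.emprs_with_apoe:.3f}")
print(f"emPRS without APOE: {score.emprs_without_apoe:.3f}")
```

```
emPRS with APOE:    1.283
emPRS without APOE: 0.811
```

0.811 is the hand-sum of the three non-APOE weights
(0.278 + 0.256 + 0.277); adding APOE contributes exactly its weight,
0.472 — ε4 dosage beyond carriage does not change it.

The full pipeline — simulate a 226-subject amyloid-high cohort, exclude
KL-VS homozygotes, split reference/test, derive weights from reference
slopes, score and evaluate the test sample:

```sh
emprs run-all --n 226 --seed 7 --out runs/demo
```

```
seed=7
panel: 27 entries
simulated: 226 subjects
abeta_filter: in=226 retained=226 excluded=0
klvs_exclusion: in=226 retained=221 excluded=5
split: reference=148 test=73
slopes: method=blup n=148 excluded=0
weights: derived=27 skipped=0
scoring: test=73 scored=73
evaluation: 12 association records
```

`runs/demo/associations.tsv` then holds one row per composite ×
score-variant × stratum with the baseline coefficient α and the
score-by-time interaction β (composite units per unit score per month)
and their Wald p-values; `derived_panel.tsv` is a scoring-ready panel of
the freshly derived weights. Reruns with the same seed are byte-identical.

Other subcommands (`emprs simulate`, `derive-weights`, `score`,
`evaluate`) expose the individual stages; the same functionality is
available as a library (`emprs.synthetic`, `emprs.weights`,
`emprs.scoring`, `emprs.evaluation`, `emprs.pipeline`).

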