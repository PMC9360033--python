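# amlclass

Unified molecular classification and risk stratification for acute myeloid
leukemia (AML), with a six-state outcome model and the clustering and
benchmarking machinery used to derive and validate the classes.

## The problem

At AML diagnosis, treatment decisions (consolidation intensity, transplant
timing, trial eligibility) hinge on classification and risk stratification,
yet standard guidelines lean heavily on cytogenetics, which are informative
in fewer than half of patients. This package implements a framework in which
cytogenetics and mutations in a 32-gene panel assign **every** patient to
exactly one of 16 molecular classes, and class membership plus FLT3-ITD
status drive a three-tier risk score that serves as a drop-in refinement of
ELN2017. It is aimed at computational hematology groups who want a tested,
scriptable implementation of the classifier, the risk rules and the
multi-state outcome engine, together with a synthetic-cohort generator so
every component can be exercised without access to patient data.

## What is inside

- **`amlclass.classify`** — a deterministic rule hierarchy (first match
  wins) over coded cytogenetic lesions and oncogenic mutation calls:
  t(15;17), inv(16), t(8;21), KMT2A t(11;x), t(6;9), inv(3), TP53/complex
  karyotype (≥3 unbalanced abnormalities), trisomies (≥1 whole-chromosome
  gain, no deletions), sAML2 (≥2 mutations among the 11 secondary-AML-like
  genes SRSF2, SF3B1, U2AF1, ZRSR2, ASXL1, EZH2, BCOR, STAG2, RUNX1, SETBP1,
  MLL-PTD), biallelic CEBPA, NPM1, sAML1 (exactly one sAML gene),
  DNMT3A+IDH, WT1, then mNOS and no-events. Includes TP53 allelic-state
  annotation (mono-allelic vs multi-hit via ≥2 mutations, 17p loss, or
  VAF > 65%).
- **`amlclass.risk`** — ELN2017 reference stratification and the proposed
  score: class → {Favorable^P, Intermediate^P, Adverse^P}, with two one-tier
  FLT3-ITD shifts (NPM1 class → Intermediate^P; any Intermediate^P class →
  Adverse^P), independent of the ITD allelic ratio.
- **`amlclass.multistate`** — six clinical states (alive post-induction,
  alive in CR, relapse, and three absorbing death states), transition
  hazards h_ij(t|Z) = h_ij,0(t)·exp(β′_ij Z), Aalen–Johansen occupancy,
  per-transition Cox fits, patient-level occupancy prediction with
  bootstrap bands, and contributing factors β_ij·(Z − Z_median).
- **`amlclass.clustering`** — the ab-initio derivation machinery: a two-step
  Dirichlet-process mixture over the binary patient-by-lesion matrix
  (collapsed Gibbs, Gamma hyperprior on the concentration), cosine-similarity
  component merging, hyperparameter grid search, and rule-based
  post-processing that requires the class-defining lesion to be present.
- **`amlclass.benchmark`** — IPCW concordance index, 75/25 train/test model
  comparison with bootstrap CIs and pairwise tests, permutation feature
  importance, and a pluggable learner contract (a penalized Cox learner is
  bundled).
- **`amlclass.synthetic`** — class-first cohort generator: genotypes,
  clinical covariates and six-state trajectories with known ground truth.
- **`amlclass` CLI** — `simulate`, `classify`, `risk`, `multistate
  fit/predict`, `cluster`, `benchmark`, `calculate` (the offline risk
  calculator).

## Worked example

The published vignette patient — 63 years old, normal karyotype, mutations
in *BCOR* and *SF3B1* — is intermediate risk under ELN2017 but carries two
secondary-AML-type mutations:

```python
from amlclass import LesionProfile, MutationCall, classify_patient, proposed_stratify

p = LesionProfile.build(
    "PD25176a-like",
    mutations=[MutationCall("BCOR", vaf=0.35), MutationCall("SF3B1", vaf=0.42)],
)
a = classify_patient(p)
r = proposed_stratify(a, p)
print(a.aml_class.value, r.eln2017.value, r.proposed.value)
```

prints

```
sAML2 intermediate adverse_p
```

i.e. the patient classifies as sAML2 (two of the eleven class-defining
secondary-AML genes) and is re-stratified from ELN2017 intermediate to
Adverse^P. `examples/` contains one short script per capability
(classification + risk, multi-state prediction, clustering, model
comparison); each prints its numbers with a note on what they mean. For
instance `examples/classify_and_risk.py` prints:

```
patient             class         ELN2017       proposed        shift
PD25176a-like       sAML2         intermediate  adverse_p       none
NPM1 + FLT3-ITD     NPM1          intermediate  intermediate_p  npm1_itd_down
complex karyotype   TP53_complex  adverse       adverse_p       none
triple trisomy      trisomies     intermediate  intermediate_p  none
```

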