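# Methods

This note documents the models implemented in `amlclass`, their
assumptions, the defaults that matter, and what the synthetic-data tests
do and do not establish.

## Inputs and vocabulary

Cytogenetics enter as pre-coded tokens from a controlled vocabulary
(`amlclass.vocab`), one token per recurrent abnormality, not as free-text
ISCN karyotype strings — mirroring how curated cohort deposits encode
lesions as binary columns. Each token carries a structural category
(fusion / gain / loss / deletion / other) and an `unbalanced` flag:
reciprocal translocations and inversions are balanced; gains, losses,
deletions and `other_unbalanced` are unbalanced. Mutations are per-call
records (gene, consequence, VAF, oncogenicity); FLT3-ITD and the KMT2A
(MLL) partial tandem duplication are ordinary calls with dedicated
consequence values (`itd`, `ptd`), so each is a single binary feature
downstream. All times are years from diagnosis.

The bundled gene panel (`data/panel.yaml`) lists 32 myeloid driver genes
and flags the 11 secondary-AML-like (sAML) class-defining features. The
panel is configuration, not code: swapping a corrected list requires no
code change.

## The 16-class hierarchy

Classification is a total, deterministic first-match rule walk
(`data/hierarchy.yaml`, ranks 1→16): the six fusion/inversion-defined WHO
entities first, then TP53/complex, trisomies, sAML2, biallelic CEBPA,
NPM1, sAML1, DNMT3A+IDH, WT1, and finally mNOS / no-events, which make
the function total. Design choices worth calling out:

- **Complex karyotype** = ≥3 unbalanced abnormalities, *excluding*
  pure-gain karyotypes: a karyotype whose unbalanced lesions are all
  whole-chromosome gains belongs to the trisomy class however many gains
  it carries. Without this exclusion ≥3 trisomies could never reach the
  trisomy class.
- **TP53/complex** fires on an oncogenic TP53 mutation *or* a complex
  karyotype — they form one joint class.
- **Trisomy class** = ≥1 gain and no deletions or monosomies; co-occurring
  balanced abnormalities are tolerated (the defining fusions all rank
  earlier anyway).
- **sAML counting** is over distinct class-defining *features*: ten gene
  symbols plus MLL-PTD (an MLL call with `ptd` consequence; other MLL
  calls do not count). One feature → sAML1, two or more → sAML2.
- **biCEBPA** requires ≥2 distinct oncogenic CEBPA calls as the biallelic
  proxy; a single CEBPA mutation is not class defining.
- **FLT3 neutrality.** FLT3-ITD is risk modifying, never class defining —
  including in the mNOS rule: ITD calls are excluded from the "any driver
  left" count, so toggling ITD can never move a patient between classes
  (verified exhaustively in the tests). Non-ITD FLT3 calls still count as
  drivers for mNOS.
- A missing karyotype is treated as "no cytogenetic lesions" for rule
  evaluation; the flag is retained on the profile.

TP53 allelic state: multi-hit iff ≥2 TP53 mutations, or ≥1 mutation with a
concomitant 17p/chromosome-17 deletion, or ≥1 mutation with VAF > 0.65
(LOH); exactly one mutation otherwise is mono-allelic. The threshold is
strict (> 0.65), and a missing VAF simply cannot trigger the LOH route.

## Risk stratification

The proposed score maps classes to base strata — Favorable^P:
{APL, inv(16), t(8;21), biCEBPA, NPM1, no-events}; Intermediate^P:
{sAML1, trisomies, WT1, DNMT3A+IDH, t(6;9), mNOS, KMT2A t(11;x)};
Adverse^P: {sAML2, TP53/complex, inv(3)} — then applies exactly one
FLT3-ITD shift where applicable: NPM1 class → Intermediate^P, any base
Intermediate^P → Adverse^P. Shifts never move more than one tier, never
upward, and ignore the ITD allelic ratio. The KMT2A t(11;x) base stratum
is a configurable default (intermediate): the class enumeration that
anchors the mapping does not name it explicitly.

The ELN2017 reference implements the published three-tier genetic table.
Two resolution choices: APL (t(15;17)), formally outside the ELN table, is
reported favorable; and the single `t(11;x)` token cannot isolate t(9;11)
(intermediate under ELN2017) from other KMT2A fusions, so it is treated as
adverse. An ITD with missing allelic ratio counts as high ratio
(conservative); this matters only for the ELN reference, never for the
proposed score.

## Six-state model

States: alive post-induction (1), alive in CR (2), relapse (3), death
without CR (4), death in CR (5), death after relapse (6); permitted
transitions 1→2, 1→4, 2→3, 2→5, 3→6; death states absorbing. A patient
who died in CR without a recorded relapse is routed 2→5; a recorded
relapse routes the death 3→6. Patients with inconsistent timepoints
(relapse without CR, non-increasing times) are excluded and reported, as
cohorts with missing timepoints are in practice.

All transitions run on one clock — time from diagnosis (clock-forward);
records entering a state later than time zero are handled as left
truncation. The Markov assumption is as usual: the future depends on
history only through the current state.

- **Non-parametric occupancy** is Aalen–Johansen product integration of
  Nelson–Aalen transition-hazard increments. Rows of P(t) sum to 1 by
  construction and absorbing occupancy is non-decreasing; under zero
  censoring the estimator equals the empirical state count exactly (an
  oracle test enforces this at n = 200).
- **Per-transition Cox models** are fitted by partial likelihood
  (lifelines, Efron tie handling — continuous simulated times make ties
  measure-zero; a Breslow-ties fit would coincide) with transition-specific
  **Breslow** baseline cumulative-hazard increments computed in-package:
  dH₀(t) = dN(t) / Σ_at-risk exp(β′z). With zero covariates this is the
  Nelson–Aalen increment, so the semi-parametric path reproduces the
  non-parametric estimator to machine precision (tested at 1e-8). A
  transition with zero events is flagged unestimable.
- **Prediction** scales each baseline by exp(β′z) and product-integrates;
  a discrete increment that would overshoot row mass is renormalized.
  Predictions can start from diagnosis or from CR attainment. Bootstrap
  bands resample patients (not records), percentile method, 200 replicates
  by default.
- **Contributing factors** are β_ij^(k)·(z^(k) − median^(k)) per covariate,
  with medians taken over that transition's at-risk records. Unspecified
  covariates are imputed at those medians, hence contribute exactly zero;
  negative values mark protective presentations. Covariates outside the
  training 2.5–97.5% range raise an outlier warning on the prediction
  rather than an error.

## Dirichlet-process clustering

The class-derivation machinery is a DP mixture over the binary
patient-by-lesion matrix, sampled by collapsed Gibbs in the
Chinese-restaurant representation with an Escobar–West resampling step for
the concentration parameter under a Gamma(shape, rate) hyperprior
(defaults 2, 1). The default base distribution is **Bernoulli–Beta**
(Beta(1,1) per feature) — the natural conjugate choice for 0/1 lesion
indicators; a Gaussian base (fixed observation variance 0.25, conjugate
normal prior on the mean) is selectable for parity with implementations
that model the binary matrix as continuous. Defaults: 200 sweeps, 100
burn-in, 8 initial clusters, cosine merge threshold 0.95 — the sweep/burn-in
counts are this package's own defaults, sized so that well-separated
planted structure (signal 0.9 vs background 0.02) is recovered reliably.

After sampling, the final partition defines the components; per-patient
assignment probabilities are the posterior membership probabilities of
that partition's components (mixture weight × component likelihood,
normalized). This is deterministic given the partition and avoids the
label-matching problem of aggregating co-assignment frequencies across
sweeps. Merging joins components with cosine similarity ≥ threshold by
transitive closure and re-aggregates probabilities. The two-step fit
reruns the sampler on patients below the confidence threshold and appends
the second pass's components. Grid search ranks configurations
lexicographically by (number of high-confidence components, mean top
probability, mean top1−top2 delta), ties broken by grid order; a
component is high-confidence when at least half its members are.
Post-processing enforces the defining-lesion constraint — a patient can
only be assigned to a component whose class-defining lesion they carry
(else the highest-probability eligible component, else unassigned/mNOS) —
and supports manual splits of mixed components by a discriminating lesion.
The sampler is seeded and exactly reproducible.

## Benchmark harness

The IPCW C-index weights each admissible pair (earlier patient has an
observed event strictly before the later patient's time) by
1/G(T_i−)², with G the Kaplan–Meier censoring-survival estimate, and
scores 1 for a concordant risk ordering, 0.5 for a tie. With no censoring
it reduces exactly to Harrell's C (enforced against O(n²) enumeration at
1e-12). Truncation of admissible pairs at a time horizon τ is available
and the comparison workflow uses τ = the 95th percentile of training
follow-up to stabilize the weights; the bare estimator applies no
truncation by default so that the uncensored equivalence is exact.

Model comparison draws 75% of patients for training (any internal CV the
learner performs happens there), computes the held-out C-index on the
remaining 25%, bootstrap-resamples the test set 100 times for percentile
CIs, and compares sets with a two-sided z score on bootstrap standard
errors (no multiplicity adjustment). The percentile interval is widened to
contain the point estimate when a finite bootstrap leaves it outside.
Learners are pluggable via `fit(X, times, events)` / `predict(X)`;
the bundled penalized Cox learner cross-validates the elastic-net mix over
0–1 in 0.2 steps and a small log-spaced penalty grid. Permutation
importance permutes each feature 50 times and reports the mean ratio
reference-C / permuted-C (ratio > 1 ⇒ informative), without direction of
effect.

## Synthetic cohorts

The generator draws a class label per patient (default prevalences: the
cohort shares where printed — complex karyotype 10.3%, trisomies 11.2%,
sAML2 23.7%, sAML1 4.7%, WT1 2%, DNMT3A/IDH 1%, mNOS 6%, no-events 2% —
and representative adult-AML frequencies elsewhere, NPM1 absorbing the
remainder at 19.1%), then class-conditional genotypes: class-defining
lesions deterministically in strict mode, plus passengers (TP53 in 65% of
complex karyotypes; FLT3-ITD per class, 72% in t(6;9), 40% in NPM1 and
WT1). Clinical covariates follow the printed class contrasts (median age
62 for complex karyotype, 65.5 for sAML-like, 41 for WT1, 56 elsewhere;
blasts 51 vs 65; antecedent hematologic disorder 32% vs 11.4%).
Trajectories use exponential transition hazards scaled by
exp(β′z) on proposed-risk indicators and age (defaults in
`synthetic.DEFAULT_HAZARDS`: e.g. CR at 2.5/yr, induction death 0.45/yr
with adverse log-HR 1.1), with administrative censoring uniform on 3–8
years. Competing transitions resolve by first event.

In strict mode no earlier-rank lesion can contaminate a profile, so the
hierarchy recovers the generating label for 100% of patients — this
validates the classifier/generator pair, not the biological fidelity of
either. Noisy mode adds a contaminating class-defining lesion with
probability ε per patient; agreement degrades continuously with ε. What
the generator does **not** emulate: VAF distributions beyond a single
per-call value, co-mutation correlation structure within classes beyond
the explicit rules, non-exponential (e.g. ageing or cure-fraction)
hazards, and covariate-dependent censoring. Passing tests therefore
demonstrate correctness of the machinery under the stated generative
model, not performance on real cohorts.

## Numerical choices and degenerate inputs

- Occupancy row-stochasticity is exact up to float error (asserted at
  1e-9); overshooting discrete increments are renormalized row-wise.
- Empty cytogenetics yield zero karyotype features; an all-censored
  dataset leaves occupancy at the initial distribution; an all-zero lesion
  matrix collapses to one cluster; a zero-event transition or zero-event
  concordance input is an explicit error/flag, never a silent NaN.
- Cosine merging uses a 1e-12 tolerance so exactly identical components
  merge at threshold 1.0.
- Degenerate outcome records (zero-length sojourns after rounding) are
  excluded with a reason rather than nudged.

## Problem sizes

The test-suite simulations run at n = 200–2000 patients (2000 for hazard-
ratio recovery and null-concordance calibration), clustering at n = 300
with K ∈ {2, 3, 5} over 5 seeds, and the exhaustive classifier check over
all 2¹⁸ subsets of a 10-lesion/8-gene universe. The acceptance script
uses a 2000-patient cohort. These sizes give stable Monte-Carlo behavior
for every asserted tolerance while keeping a full run in minutes on one
CPU.

## Known limitations

- The ELN2017 reference cannot distinguish t(9;11) without a dedicated
  token (see above); WHO-2016 mapping and ELN2022/ICC schemas are out of
  scope.
- The classifier's 32-gene panel is a reconstruction of the published
  panel's documented membership; it is shipped as editable configuration.
- Clustering reproduces the *procedure* (two-step DP, merging, grid
  search, post-processing), validated on planted structure; it does not
  attempt to reproduce the published 14-cluster solution, which involved
  manual curation of a specific cohort.
- Absolute C-index values from the published cohort comparisons are not
  reproducible without the underlying patient data; the harness reproduces
  the workflow and its calibration properties (null ≈ 0.5, noise
  permutation ratio ≈ 1).
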