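# Methods

This note records the models implemented in `folatenet`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot show.

## Cohort coding

Each of the seven folate-pathway loci is treated as biallelic with three
genotype classes ordered (major homozygote, heterozygote, minor
homozygote) and expanded into three one-hot indicators, giving 21 binary
columns; the micronucleus frequency BNMN‰ (per mille binucleated
micronucleated lymphocytes) is min-max scaled over the cohort to [0, 1]
and appended, for 22 bounded inputs. The target codes a case mother
(mother of a Down-syndrome child) as 1, so sensitivity is recall on
cases. Min-max scaling was chosen because both networks downstream assume
inputs in [0, 1]; the (min, max) pair is stored on the encoded matrix so
held-out data can be scaled identically (values are clipped into [0, 1]).
A cohort with a degenerate BNMN range encodes the column as a constant
0.5 and warns. Group summaries use the sample SD (n−1). The *MTHFR*
1298 CC class is a legal label even when absent from a cohort — schemas
are fixed; data need not cover every class.

CSV input requires a header; decimal comma and decimal point are both
accepted for BNMN (European tables typically print comma decimals), and a
column-name mapping absorbs unknown header spellings.

## Synthetic cohort generator

The generator emulates the statistical structure of a small case-control
micronucleus/genotype study:

* **Genotype marginals** are sampled per group directly at the genotype
  level from configured class probabilities (by default the published
  per-group count fractions, 29 cases / 32 controls). No Hardy–Weinberg
  assumption is imposed, because studies report genotype counts, not
  allele counts.
* **BNMN‰** is drawn from a normal truncated at zero with group-specific
  (mean, SD) = (16.5, 7.6) for cases and (9.3, 3.1) for controls by
  default. Truncation prevents negative per-mille values; its exact
  effect is accounted for in tests via the truncated normal's closed-form
  moments (it shifts the case mean by ≈ +0.29‰ and is negligible for
  controls, where zero lies 3 SDs below the mean).
* **Linkage couplings** between two loci are modelled at the haplotype
  level: a 2×2 haplotype frequency table per group, two independent
  haplotype draws per subject, genotypes read off the allele pair. The
  planting operation fixes one (rare) haplotype's frequency and rescales
  the other three cells so both loci's allele marginals are preserved
  exactly; infeasible combinations (outside the Fréchet bounds
  [max(0, f_a+f_b−1), min(f_a, f_b)]) are rejected with the violated
  constraint. The study-calibrated default plants the *MTHFR* 677T–1298C
  and *TYMS* 2R–6bp(−) haplotypes at frequency 0, the minimal model of
  the "rare, negatively selected" haplotypes reported for these pairs.
  Note that coupled loci then follow random-union (Hardy–Weinberg-like)
  genotype marginals implied by the allele frequencies rather than the
  raw genotype-count fractions; the uncoupled calibration is used when
  exact marginal recovery is the point.
* **Noise loci** carry group-independent class probabilities drawn once
  from a flat Dirichlet and fixed, so they have zero association with the
  label by construction.

The group signal is carried entirely by the calibrated group differences
themselves (e.g. *RFC1* 80 AA in 1/29 cases vs 10/32 controls, and the
BNMN shift, whose implied point-biserial correlation with case status is
≈ 0.54); there is no separate effect-size knob, but every probability and
moment is overridable.

What the generator does **not** model: family structure, Hardy–Weinberg
deviations at coupled loci, covariates (age, diet, smoking), missing
genotypes, or any causal pathway between genotype and BNMN within a
group. Passing recovery tests on this data therefore shows the pipeline
recovers planted marginal and dependence structure — not that the
biological conclusions transfer to any real cohort.

## Back-propagation perceptron

A single-hidden-layer network, 4 hidden units by default, logistic
sigmoid on both layers, trained by classic per-pattern back-propagation
of squared error with momentum. Squared error (not cross-entropy) keeps
the optimiser the plain "minimise the error function" gradient descent of
the original small-network literature. Defaults — learning rate 0.1,
momentum 0.9, 500 epochs, uniform(−0.5, 0.5) seeded initialisation,
per-epoch shuffling — are standard for small bounded tabular problems and
are all exposed in `TrainConfig`. `early_stop_tol` stops training when
the epoch-mean squared error falls below it (0 = run all epochs, the
default, so results are a pure function of the config). The decision
threshold is 0.5 on the sigmoid output, ties classifying as positive.
Determinism is exact: same data and config give bit-identical weights.
The inner loop is numba-JIT-compiled; the fallback path runs the same
update order in Python.

ROC AUC is computed by midranks (exact Mann–Whitney probability with
ties); sensitivity/specificity/accuracy come from the confusion counts,
and a metric whose denominator is empty is reported as missing, never 0.

## TWIST: evolutionary split + variable selection

A genome is one bit per record (subset a/b) plus one bit per feature.
Fitness is the mean of the two directions' generalisation accuracy, each
from a reduced-budget perceptron (100 epochs) trained on the masked
features of one subset and scored on the other; the final reported
networks are retrained at full budget by the validation stage. Invalid
genomes — empty mask, or a subset missing a class — score 0 rather than
being repaired (simpler and unbiased). Training visit order is
canonicalised by lexicographic sort of (masked row, label), making
fitness a function of the record sets only.

The optimiser is a generational GA: tournament selection (size 2),
uniform crossover (rate 0.9), bit-flip mutation (rate 1/genome length),
2 elites copied unchanged, and 10% random-immigrant "doping" per
generation, population 30, 100 generations — all configurable. Fitness
values are cached by genome, and the running best genome is returned.

Two caveats are deliberate and documented:

* The "similar probability density in both halves" goal is realised only
  implicitly — two-direction accuracy rewards splits on which both halves
  generalise to each other; no explicit density-similarity term is added.
* The best genome's fitness is an **optimised** statistic and is
  optimistically biased: on data with no group signal at all the GA still
  reaches ≈ 0.7–0.8 by exploiting sampling noise in the split (a
  winner's-curse effect; an unoptimised random genome scores ≈ 0.5 on the
  same data, which the tests verify). Selection output must therefore
  always be judged by the blind 5x2 validation stage, never by the
  wrapper's internal fitness.

## 5x2 validation

Five seeded halvings, stratified by class (per class the halves differ by
at most one member; tiny cohorts make unstratified halving degenerate),
each used in both directions with a freshly initialised network whose
seed derives from the master seed and run index; weights are frozen
before the held-out half is scored. The result is a 10-row table plus the
exact arithmetic mean row, exported in the column order Sensitivity /
Specificity / Global accuracy / ROC AUC. An instrumentation hook exposes
each run's train/test index sets so leakage can be asserted in tests.

## Auto-Contractive Map and connectivity graph

Each variable i has a mono weight v(i) and each pair (j, i) a weight
w(j, i), all starting at 0 and bounded by the contraction constant C
(default: the number of nodes). Per record, with input m_in ∈ [0, 1]:

    m_s(i)   = m_in(i) · (1 − v(i)/C)
    Net(i)   = Σ_j m_s(j) · (1 − w(j,i)/C)
    m_out(i) = m_s(i) · (1 − Net(i)/C)
    Δv(i)    = α · (m_in(i) − m_s(i)) · (1 − v(i)/C)
    Δw(j,i)  = α · (m_s(i) − m_out(i)) · (1 − w(j,i)/C) · m_s(j)

with α = 0.1, stopping when the epoch-mean |Δw| < 1e-6 or at 1000
epochs. The (1 − w/C) factor contracts every update, so 0 ≤ w < C always;
pairwise weights grow with co-activation, fastest for variables that fire
together. Under zero initialisation the v-update's driving term
m_in − m_s is identically zero, so mono weights stay at 0 and m_s = m_in;
they are retained for non-zero initialisations. Training is fully
deterministic (fixed record order, no randomness).

Downstream: W is symmetrised by averaging (the map is undirected),
distances are d = C − w, the minimum spanning tree is computed by Kruskal
with ties broken lexicographically on (smaller, larger) node-name pairs
for reproducibility, edge strengths are reported as w/C ∈ [0, 1] (an
order-preserving bijection), and hubs are all nodes of maximal tree
degree. The two condition labels (case, control) enter the map as binary
indicator nodes, and BNMN enters as its continuous [0, 1] column.
Exports: DOT (the tree only, strengths to 2 decimals), GraphML and a JSON
edge list with an `in_mst` flag per edge.

Long training drives all weights toward C, but at different exponential
rates, so the distance *ordering* — which is all the MST uses — remains
informative at the epoch cap.

## Test problem sizes and planted-structure fixtures

Stochastic recovery tests use fixed seed sets, and problem sizes chosen
to make the planted structure the dominant effect:

* Marginal recovery: 10,000 subjects per group, 4 binomial SEs.
* Linkage-coupling adjacency and BNMN-to-case-node proximity: 10 seeded
  study-sized cohorts (n = 61), requiring ≥ 8/10.
* Planted hub: one hub variable, three satellites each equal to the hub
  with 25% independent flips, and two independent distractors, n = 200.
  The 25% flip rate makes satellite–satellite association (agreement
  0.625) quadratically weaker than hub–satellite association (0.75), so
  the tree must route through the hub; with many distractors the
  *distractors'* random tree attachment, not the planted structure,
  dominates the failure modes.
* Surrogate pipeline performance: 10 seeded study-calibrated cohorts,
  full GA budget, blind 5x2; asserts mean ROC AUC > 0.75 and the BNMN
  variable kept in ≥ 8/10 runs.

## Known limitations

* The GA operators are one reasonable realisation of a doped evolutionary
  wrapper; selected variable *sets* vary across seeds on n = 61 cohorts
  (the dominant BNMN variable is stable, weak genotype indicators are
  not), so set-level agreement with any single published selection should
  be read as an expectation, not a guarantee.
* The Auto-CM update rules realise the documented contract (bounded
  co-activation weights, deterministic training) and are swappable behind
  the training interface; other published variants differ in detail.
* The wrapper's internal fitness is optimistically biased on null data
  (see above); it is reported as a diagnostic, never as a performance
  estimate.
* Subject-level real data are not bundled; all shipped results are
  synthetic-cohort computations.
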