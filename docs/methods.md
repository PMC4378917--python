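# Methods

## The phenotyping model

`phenoforest` treats clinical phenotyping as unsupervised learning on a
mixed-type feature table. The central object is the random-forest
proximity: two subjects are similar to the extent that unpruned
classification trees route them into the same terminal node. Because trees
split natively on continuous thresholds, binary flags and categorical level
subsets, the proximity needs no scaling, no dummy coding and no metric
assumptions — the properties that make it suitable for tables mixing
spirometry, anthropometry, genotype groups and culture flags.

### Unsupervised forest (Addcl1 contrast)

To obtain proximities without labels, the *n* real rows are contrasted with
*n* synthetic rows in which each variable is resampled independently with
replacement from its own empirical marginal. Synthetic rows keep every
marginal distribution but destroy the joint dependence structure, so a
forest discriminating real from synthetic concentrates exactly on that
structure. This is the independent-marginal ("Addcl1") scheme; the
alternative uniform-hyperrectangle scheme is not implemented but the
contrast generator is a single function
(`forest.make_synthetic_contrast`), kept separate so it can be swapped.

Forest defaults: 1500 trees, `mtry = ⌊√p⌋`, terminal node size 1
(grown to purity). Splits maximise the Gini impurity decrease over `mtry`
variables drawn without replacement per node; zero-gain splits are accepted
when a valid candidate exists, since locally uninformative splits (XOR-type
interactions) can still lead to pure descendants. Tie-breaks are
deterministic everywhere: lowest variable index, then lowest threshold
(continuous) or lowest level-subset bitmask (categorical; subsets are
enumerated exhaustively, which is cheap at ≤ 3 levels). All randomness
derives from one integer seed through `numpy.random.SeedSequence`
substreams keyed by (purpose, tree index), so individual trees are
unchanged when `n_trees` grows and every result is bit-reproducible.

Proximities are counted over **all** trees with every row run down every
tree and normalised by `n_trees` (the long-standing reference default); an
`oob_proximity` flag restricts counts to tree-wise out-of-bag pairs with
per-pair normalisation. The matrix is validated on construction
(symmetric, unit diagonal, entries in [0, 1]).

### OOB evaluation and permutation importance

Each row is predicted by majority vote over the trees in which it was
out-of-bag (ties to the lowest class index); rows that are in-bag
everywhere are excluded from the denominator and counted. Importance is the
per-tree OOB accuracy drop after permuting one variable's OOB values,
averaged over trees, with its standard error across trees; a variable that
is constant in the data has importance exactly 0 because its permutation is
the identity.

### PAM

Partitioning Around Medoids runs on `D = 1 − P`: greedy BUILD seeding
followed by steepest-descent SWAP (the single best medoid/non-medoid
exchange per iteration, until no exchange reduces the cost). Ties break to
the lowest row index, so PAM needs no seed. `k` is a user input; the
published analyses of this design use k = 3…6 and the package follows that
convention rather than automating model selection. A brute-force post-check
in the tests confirms the 1-swap local optimality at termination, and on
small instances the cost is compared against exhaustive enumeration of all
medoid sets. (On latent-structure instances PAM matches the global optimum
in ≈ 96–99 % of cases; on uniformly scattered points the rate drops to
~88 %, indistinguishable from the R `cluster::pam` reference, which was
cross-checked on identical instances.)

### Dimension reduction and the two-stage pipeline

A supervised forest trained to predict the initial PAM classes provides the
importance ranking; the top-*m* variables (default m = 8) feed a second
unsupervised forest and a second PAM. The selected set is always
data-driven — it is never hard-coded, because published variable lists for
this procedure differ between sources (with/without Brasfield or gender).
An optional `consensus_k` setting averages importance ranks over several k
before selecting. The final classes are validated by a third supervised
forest (OOB error and confusion matrix) and embedded by classical
(Torgerson) MDS.

### Classical MDS

Double-centre `−½ D∘D`, eigendecompose, embed on the leading non-negative
eigenvalues scaled by √λ. `1 − P` is generally non-Euclidean; negative
eigenvalues are truncated to zero and their relative mass
`Σ|λ⁻| / Σ|λ|` is reported as a quality diagnostic (typically ~0.02–0.1
for forest dissimilarities). Eigenvector signs are fixed by making the
largest-magnitude entry of each axis positive; coordinates are therefore
identical across runs and platforms, and geometric tests compare pairwise
distances (rotation-invariant) rather than raw coordinates.

### Enrichment

For each (class, trait) pair a 2×2 class-vs-nonclass table is tested with
the two-sided Fisher exact test (sum of hypergeometric probabilities of
outcomes no more probable than the observed one). The reported odds ratio
is the conditional MLE (0 when the in-class/present cell is empty, +∞ when
the complementary cell is), with the sample OR `ad/bc` also emitted;
a trait constant across the cohort yields p = 1 and OR reported as 1 with a
note. Benjamini–Hochberg correction is applied across all class × trait
tests of a run by default — the widest defensible family — with a
`per-trait` option. Combination traits are logical ANDs of two flags.
Significance is declared at adjusted p < 0.05.

### Stability

Two clusterings at the same k, a few years apart, are compared on their
shared subjects. Letters are matched by maximum total overlap (Hungarian
assignment; exact, and equal to exhaustive permutation search at k ≤ 6) —
interpretive matching by phenotype description is not reproducible, so
overlap matching is the default and a profile-distance alternative can be
added on top of the reported overlap matrix. Under the matched labels the
report gives the transition count matrix, per-origin-class leaving
proportions (*p* Transitions), per-destination shares of all transitions
(*f* Transitions) and per-class death/transplant tallies. Subjects lost to
death or transplant are excluded from transition counts and appear only in
the event tallies.

## The synthetic cohort generator

`simulate_cohort` draws subjects from a mixture of latent classes. Each
class specifies truncated-normal (mean, sd) for age, FEV1 %, FVC %, height,
weight and Brasfield score, a male probability, pancreatic-sufficiency and
CFTR-group probabilities, and per-organism prevalences. Truncation bounds
(age 18–80 y, FEV1 15–140 %, FVC 20–150 %, height 1.40–2.00 m, weight
35–120 kg, Brasfield 3–25, integer-rounded) are plausible adult-CF ranges
chosen as synthetic design values. FVC % is floored at 0.9 × FEV1 % to keep
the spirometric relation plausible; BMI and the age × FEV1 % product are
computed, never drawn, so cohort invariants hold by construction. Optional
iid standard-normal noise variables and Bernoulli noise traits support
selection and false-discovery null tests.

`simulate_followup` emulates a re-assessment three years later: per-class
persistence probability (movers are redrawn from their new class,
retaining identity and gender), continuous drift for persisters (sd =
`drift_sd` × class sd), per-class death/transplant hazard (events removed
from follow-up and reported separately), ages advanced by the gap, and new
accruals up to a target size.

Four presets are shipped. `fig4_like_k5` (n = 211, five classes, follow-up
target 211, event hazard concentrated in the low lung-health classes)
mirrors the qualitative structure of published adult-CF phenotypes: one low
lung-health poorly-nourished class, one older male class with low lung
health, one median female-dominated class, one well-nourished
high-lung-health male class enriched for pancreatic sufficiency and
residual-function CFTR mutations, and one young female class. All numeric
values are synthetic choices for qualitative realism, deliberately not
digitised from any figure. `separable_k3` separates three classes by ≥ 3 sd
and injects a PA prevalence of 0.8 vs 0.1 for enrichment power tests;
`noise_heavy` makes exactly the eight lung-health/nutrition variables
informative, holds every trait's distribution constant across classes, and
appends ten pure-noise variables; `null_one_class` is a single homogeneous
class.

**What the generator does not emulate:** real within-class correlations
beyond the FVC/FEV1 floor and the derived variables (e.g. height–gender,
age–Brasfield), measurement error, longitudinal FEV1 decline, informative
missingness (the generator emits complete cases only), or registry-level
genotype–phenotype structure. Passing tests therefore demonstrate that the
pipeline recovers structure of the planted kind at realistic sizes and
noise levels — not that any particular real cohort has five classes.

## Numerical and design choices

- **Severity bands**: the age × FEV1 % product is banded at
  severe < 1000 ≤ moderate ≤ 1600 < mild. The borders are "approximate" in
  the source literature; the closed/open convention here is fixed for
  determinism and configurable.
- **Complete-case policy**: rows with any missing value are rejected at
  load time with a (line, reason) report; no imputation.
- **Culture aggregation**: an organism is present iff ≥ 2 positive cultures
  in the 365 days up to and including the subject's reference date
  (per-subject reference dates supported; a cohort-level snapshot date
  otherwise).
- **Class lettering**: by ascending mean age × FEV1 % product, a
  deterministic proxy for the interpretive letter assignment used in
  clinical reports (A = lowest accrued lung health).
- **Degenerate inputs**: empty 2×2 tables, k outside [1, n], MDS dims ≥ n,
  single-class supervised fits, mismatched k in class matching, and
  infeasible generator means all raise informative errors rather than
  propagating NaNs.
- **Problem sizes in tests/acceptance**: the test-suite pipelines run at
  n = 50–211 subjects with 40–300 trees, and the acceptance script uses
  300-tree forests for the full-size (n = 211 and n = 200) cohorts and
  150-tree forests for the seed-sweep; at these sizes all checked
  properties (ARI ≥ 0.7, exact 8-variable selection, stage-2 < stage-1 OOB
  error) hold with comfortable margins while keeping a full run in the
  low minutes on one CPU.

## Known limitations

- The forest is classification-only, with no missing-value handling
  (complete cases are a data-model invariant) and no class weighting.
- Proximity computation is dense O(n² · trees); fine for clinic-scale
  cohorts (hundreds of subjects), not for biobank scale.
- PAM is the classical O(k(n−k)²)-per-iteration algorithm, not CLARA/
  CLARANS; k must be supplied by the user.
- The conditional-MLE odds ratio is reported without exact confidence
  intervals.
- Stability analysis compares two independent clusterings; it does not
  re-predict old classes on new data, and it cannot attribute transitions
  to specific variables.
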