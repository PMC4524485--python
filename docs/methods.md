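# Methods

This note documents the models implemented in `msyphylo`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Perfect phylogeny

Input is a binary sites × samples matrix with known ancestral states
(0 = ancestral, 1 = derived, `.` = missing).  Two sites are compatible
iff their derived-carrier sets are nested or disjoint (the rooted
three-gamete condition); `check_compatibility` tests all pairs with
bitset arithmetic and reports one witness sample per forbidden overlap
category.  When the matrix is compatible, its distinct derived sets form
a laminar family; `build_mp_tree` materializes that family as the unique
rooted tree: sites with identical derived sets collapse onto one branch,
nesting gives parent/child structure, samples with identical genotypes
become sister tips under a zero-mutation split, and polytomies are kept
as polytomies (no arbitrary binarization).

Numerical/degenerate choices:

* sites invariant across all loaded samples are dropped with a warning —
  they carry no placement information on this sample set;
* sites with missing calls are placed by their *observed* derived set
  (no imputation); the affected samples are recorded per site in
  `tree.unresolved` so downstream users can see exactly what was
  unresolved;
* output is canonicalized (children ordered by descendant-tip count,
  then smallest tip label; mutation sets sorted by name), so the tree is
  a pure function of the matrix contents, independent of row/column
  order.

## Dating

**Clock.**  `CalibratedClock` holds a per-site substitution rate
(default 0.716 × 10⁻⁹/site/year, a fossil-calibrated value specific to
the 1.5-Mb MSY target this package models) and the target length
(default 1,495,512 bp).  Their product, ~1.07 × 10⁻³ mutations per
lineage-year, converts mutation counts to years (≈ 934 years per
mutation).

**rho.**  `rho_statistic` is the mean mutation-count path length from a
node to its descendant tips; `rho_sigma` is the Saillard estimator
σ² = n⁻² Σ_b n_b² m_b over branches below the node (n_b = descendant
tips through branch b, m_b = mutations on b), which accounts for the
covariance induced by shared branches.  The reported 95% interval is the
normal approximation ρ ± 1.96σ floored at zero — the common convention
in rho dating; the exact interval convention used by legacy tools is not
published, so this choice is explicit and testable.

A structural caveat: ρ(parent) is the tip-weighted **mean** over
children of ρ(child) + (connecting branch count).  On unbalanced trees a
parent's point age can therefore fall *below* one child's — this is a
property of the estimator, not a bug, and the test suite asserts the
weighted-mean identity rather than a (false) parent ≥ max-child
ordering.

**Bayesian sampler.**  `bayes_node_ages` runs Metropolis-within-Gibbs
over internal-node ages with:

* likelihood: per-branch Poisson(λ · duration) on the observed branch
  mutation counts.  On a perfect phylogeny the full column likelihood
  factorizes to exactly these counts, and substitution-model
  exchangeabilities are unidentifiable from binary presence data, so
  this is the sufficient-statistic version of a strict-clock sequence
  model — a deliberate simplification, not a claim of equivalence to
  full sequence-level samplers;
* prior: a coalescent whose population trajectory expands exponentially
  toward the present — backwards in time, size N₀ shrinking at rate g
  until it reaches the ancestral size r·N₀, constant earlier.  The three
  hyperparameters are sampled under lognormal(10, 3) for N₀ (natural
  log; N is in "coalescent years", i.e. effective size × generation
  time), Exponential(mean 0.2) for the ratio r, and Uniform[0, 0.00133]
  per year for g;
* default chain: 200,000 elementary updates, sampled every 200, 20%
  burn-in, seed 1515.  These desk-scale defaults give effective sample
  sizes of a few hundred per node on 33-tip trees in ~10 s; longer
  chains are config-reachable.  Low ESS triggers a warning, never an
  error.  Runs are bit-reproducible under a fixed seed.

Node summaries are posterior means with 95% highest-posterior-density
intervals.  On synthetic 33-tip genealogies the rho and Bayesian point
ages correlate at r > 0.998.

## Haplogroup classification

The marker hierarchy is a rooted tree of haplogroup nodes, each defined
by one or more phylogenetically equivalent mutations (any one derived
call identifies the branch; disagreement among equivalents is a
validation error, since a perfect phylogeny forbids it).  The shipped
default (`data/e_tree.yaml`) encodes the haplogroup-E topology as far as
the published text states it, including the basal V3725 | M75 dichotomy
with V44 sister to P147, the M215 → M35 | V16 split, the Z827 | V68
bifurcation of M35, the tripartite V1515 clade and the revised M78
substructure.  Branches the text does not name are omitted rather than
invented.

`next_markers` implements staged screening: it returns the defining
markers of the untested children of the deepest derived node.  Siblings
carry an optional integer `stage`; children at a later stage are planned
only after every earlier-stage sibling has been tested ancestral.  This
encodes screens of the form "type the common subclade first, the rare
sister only on the remainder" (e.g. V16 is only typed on
M215*(×M35) chromosomes).

Paragroup semantics: a call gets the `*` suffix only when *every* child
of the called node was tested and found ancestral; with untested
children the label is flagged `(unresolved)` instead, and the untested
children are listed — mirroring the `X*(×list)` notation that records
exactly which children were excluded.

## Discrete phylogeography

Regions are the six macroregions Central-Western Africa, Southern
Africa, Eastern Africa, Northern Africa, Europe and Rest-of-world.
Two inference modes:

* `fitch_state_sets` — minimum-change parsimony via unit-cost dynamic
  programming with an outside pass; on binary trees this reproduces
  classic two-pass Fitch sets and stays exact on polytomies.  A node's
  set contains the states it takes in at least one minimum-change
  labelling;
* `bayes_regions` — a symmetric equal-exchangeability CTMC (the 6-state
  analogue of the Jukes-Cantor chain) along branches whose durations
  come from node ages in years (unit lengths as fallback).  The
  migration rate gets an Exponential prior with mean 5/total-tree-length
  (about five expected migrations on the whole tree) sampled by
  random-walk Metropolis; tips with multi-region assignments enter the
  pruning as indicator vectors; the root prior is uniform.  For each
  retained iteration one *joint* single-region labelling of all
  ancestral nodes is drawn from the conditional posterior, so every
  sample assigns exactly one region per node; marginals are tallies of
  those draws.  `exact_node_posteriors` provides the closed-form
  fixed-rate marginals (inside–outside message passing) used as the
  test oracle; fixed-rate MCMC agrees with it to total variation < 0.005
  at 10⁵ samples.

This single-rate symmetric model is a stand-in for unpublished
"Bayesian binary MCMC" machinery in legacy phylogeography tools: it
targets the same per-node marginal summaries from the same inputs.  Two
consequences worth knowing:

* with uniform tip regions the posterior concentrates on the shared
  state without reaching 1.0 exactly — the prior keeps mass on hidden
  migration paths (quadrature gives ~0.89 on a 3-tip toy tree, ~1.0 on
  realistic trees);
* deep-node posteriors are **sensitive to the per-leaf region table**.
  The synthetic reference assignment (`reference.synthetic_tip_regions`)
  is reconstructed from textual descriptions of each clade's range, and
  at deep nodes it produces different best regions than the published
  analysis, whose per-leaf table was richer.  Shallow, well-sampled
  clades (e.g. the V1515 node) reproduce the published near-certain
  Eastern-Africa placement.

## Kriging

Frequencies are interpolated by ordinary kriging on a regular lat/lon
grid (default 50 columns × 45 rows; bounding box = data extent padded
5%).  Distances are great-circle (haversine) kilometres — appropriate at
continental scale.  The empirical semivariogram is binned (12 bins),
restricted to lags ≤ half the maximum distance (beyond which it is
unreliable), and fitted by pair-count-weighted least squares with an
exponential model by default (spherical selectable): γ(h) = c₀ +
(c − c₀)(1 − e^(−3h/a)) with nugget c₀, sill c and practical range a.
Each cell solves the standard constrained system; the Lagrange
construction forces weights to sum to one (checked numerically to
~10⁻¹⁶), zero nugget gives exact interpolation at observation sites, and
estimates are clamped to [0, 1] *after* solving (clamping never moves an
in-range value).  Degenerate inputs: constant data yield a zero-variance
model and the unweighted mean everywhere; fully colocated observations
are an error; a singular kriging matrix falls back to a regularized
solve with a warning.  Frequencies are unweighted by sample size by
default (weighting is exposed as data, not applied silently).

## Synthetic generator

`simulate_genealogy` delegates the haploid coalescent to msprime
(`ploidy=1`) with the same expansion trajectory the dating prior
assumes; times are converted to years via the generation time.
Defaults mirror the study scale: 33 tips, current male effective size
5,000, ancestral/current ratio 0.2, growth 6.65 × 10⁻⁴/year (the
midpoint of the dating prior's growth range), generation time 30 years —
giving root ages around 55–60 ka under the calibrated clock, with a few
hundred segregating sites per replicate.  `drop_mutations` places
Poisson(λ · duration) fresh, uniquely named sites on every branch
(infinite sites — matching the empirical absence of recurrent
mutations in this system); `evolve_regions` draws CTMC endpoint states
down the tree; `emit_genotype_panel` assigns each tip a lineage through
the marker hierarchy and fills its record by repeatedly asking the
staged planner and answering truthfully, so panels are consistent with
the screening cascade by construction.  Everything is reproducible from
one seed.

What the generator does **not** emulate: recombination (none on the
MSY), selection, population structure beyond the region CTMC,
genotyping/sequencing error, and missing data.  Passing round-trip tests
therefore show correctness of the algorithms under the model's own
assumptions — not robustness to call errors or homoplasy in real data.

`reference.py` is a different kind of synthetic data: a reconstruction
of a published study's data *shapes* from printed numbers (node ages in
ka, the 13-mutation haplogroup-E stem, survey totals 5,222 / 1,147 /
1,141).  Branch mutation counts are expected counts under the calibrated
clock (rounded, or Poisson with a seed), so rho dating of the rebuilt
tree reproduces the printed ages by construction — it validates the
pipeline's mechanics end-to-end at the published scale, not the
published inference itself.

## Problem sizes used in tests

Oracle-equivalence tests enumerate exhaustively where feasible: the
tree builder against 1,000 random matrices up to 8 samples × 12 sites;
Fitch parsimony against full enumeration of internal labelings on trees
up to 6 tips (6 states make larger enumeration infeasible); region MCMC
against exact pruning at 10⁵ samples; rho calibration on 500 simulated
33-tip genealogies.  Statistical assertions use closed-form expectations
with standard-error-based tolerances.

## Known limitations

* The Bayesian dating sampler updates one node age at a time; on trees
  much larger than ~100 tips mixing will be slow and the default chain
  should be lengthened.
* The marker hierarchy covers the branches the source text names; it is
  data (YAML), so extending it requires no code changes.
* The CTMC region model assumes a single symmetric rate; asymmetric or
  distance-informed migration is out of scope.
* Kriging treats frequencies as Gaussian observations; near 0 or 1 the
  clamped estimates are biased toward the interior, and no binomial
  sampling-noise model is applied.
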