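# Methods

## Model and assumptions

A clonal hierarchy is a rooted labeled tree whose nodes are clones and whose
edges record the order in which mutations were acquired. The model assumes:

* every mutation is acquired exactly once and never reverts
  (infinite-sites-style irreversibility), so each clone's genotype is the
  set of mutations on its root path;
* all mutations are heterozygous, so VAFs can be rescaled to a common
  per-cell scale; copy-number effects and homozygous variants are out of
  scope;
* the sample is purely leukemic after normalization: the most abundant
  mutation's VAF is rescaled to 100% per timepoint.

With clones numbered from the root in nondecreasing depth, the genotype
matrix `A` (`a_ij = 1` iff clone `j` carries mutation `i`) is unit upper
triangular with determinant 1. Clone frequencies `x` and bulk VAFs `b`
(percent) are linked by `A x = b`, solved exactly by back-substitution:
`x_n = b_n`, `x_j = b_j − Σ_{k>j} a_jk x_k`. The data are *compatible* with
a hierarchy iff `x ≥ 0`. Because the founder row of `A` is all ones,
compatible founder-rooted solutions conserve mass: `Σ x_i = b_founder = 100`.

Candidate trees are enumerated exhaustively via the Prüfer bijection
(`n^(n−2)` trees per fixed root, `n^(n−1)` rooted trees). Enumeration
streams one tree at a time and refuses `n` above a configurable limit
(default 8, i.e. 262,144 fixed-root trees), because the combinatorial
growth makes exhaustive search infeasible beyond small clone numbers —
which is also the regime where bulk panels operate.

## Fitting under measurement error

Incompatible data are fit per candidate by the convex quadratic program

    minimize ||W (A x − b)||_2   s.t.  x_i ≥ 0,  Σ x_i = 100,

with `W = diag(w_i)` and `w_i = 1 / (CI half-width)` when confidence
intervals are supplied (1 otherwise). The solver is an active-set method
(Lawson–Hanson style with the sum constraint folded into each KKT solve on
the free variables), which reaches the global optimum of these ≤ 8-variable
problems to machine precision; a scipy SLSQP fallback guards against
active-set breakdown. The tests confirm the optimum against a dense simplex
grid search and against random feasible points.

**Exactness.** A candidate is declared exact iff its back-substitution
solution is non-negative (tolerance `1e−9` on the percent scale) at every
timepoint. The conventional residual threshold `||Ax − b|| < 1e−15/1e−16`
is kept as the constant `EXACTNESS_EPSILON` but is not used for the
decision: back-substitution is algebraically exact, whereas a generic
double-precision optimizer cannot certify a residual at that level.
Exactness is decided on unweighted back-substitution; weights only shape
the ranking of inexact fits. Tiny negative components (within tolerance)
are clamped to zero and the vector rescaled to its pre-clamp sum — which is
100 for normalized input, but deliberately not forced to 100 for perturbed
input, where `b_founder ≠ 100` is itself the signal.

**Multi-timepoint aggregation.** Each timepoint is fit independently (clone
frequencies may change between diagnosis and relapse); the combined
residual is the root of the sum of squared per-timepoint residuals, which
treats timepoints symmetrically. A tree is exact iff it is compatible at
every timepoint.

**Ranking.** Fits are sorted by combined residual with ties broken by a
canonical key (root position, Prüfer code over sorted labels), so repeated
runs produce identical orderings. Ranks use the competition ("min")
convention: ties share the better rank; the report metadata records the
convention. `rank_summary` reports the true tree's rank, whether it is
optimal (no strictly smaller residual, tolerance `1e−9`), exact, and
whether the optimum is unique.

**Root choice.** In founder mode the root is the most abundant allele.
With several timepoints the score is the summed VAF across timepoints
(for a single normalized timepoint this is exactly "the allele at 100");
all alleles tied at the maximum (within `1e−9`) are enumerated as roots and
the results merged. In wildtype mode a healthy reference allele (`WT`) at
100% is prepended (unless already present) and all trees are rooted there.
Relaxation by `x%` multiplies every mutated-allele VAF by `(100 − x)/100`;
on exact data whose clone frequencies summed to 100 the wild-type clone of
the true hierarchy then takes frequency exactly `x`.

Alleles missing at one timepoint are read as VAF 0 there (with a warning):
an absent measurement is indistinguishable from an absent clone in a VAF
table, and joint fits require a shared allele universe.

## Robustness experiments

* **Multinomial resampling** emulates sampling error: clone counts are
  redrawn from `Multinomial(n_cells, f)` and the bulk VAFs recomputed from
  the replicate's empirical frequencies. Because the reconstruction is
  linear, the mean reconstructed frequencies converge to the truth.
* **Gaussian perturbation** emulates sequencing error: `N(0, sd²)` noise
  (percent) is added per allele; draws outside [0, 100] are excluded by
  redrawing that allele (a whole-replicate redraw policy is available as a
  switch). Perturbed data are *not* re-normalized — noise on the founder
  allele destabilizing root identification is precisely the failure mode of
  interest, and re-normalizing would erase it. Reconstruction of perturbed
  data therefore runs with normalization disabled.
* **Uniqueness experiment**: for every fixed-root topology on `n` clones,
  clone-frequency vectors are drawn uniformly from the simplex (flat
  Dirichlet; drawn independently per timepoint), exact bulk VAFs computed,
  and the number of topologies compatible with all timepoints counted.
  This path is fully vectorized (pre-computed inverses of all candidate
  matrices), so 16 topologies × 10,000 datasets × 2 timepoints run in
  under a second. The "uniform on the simplex" reading of a random clone
  distribution is a choice; the resulting uniqueness rates could shift
  under a different sampling law, though the qualitative ordering (linear
  hierarchies more identifiable than root-branched ones; two timepoints
  more identifiable than one) is structural.

Every experiment derives its randomness from a single seed through numpy
`SeedSequence` spawn keys, one child generator per component and replicate,
so adding replicates never shifts earlier draws and all summaries are
bitwise reproducible.

## Synthetic patients

The generator emulates the study conditions of clonally resolved AML
cohorts: 2–7 clones related by a uniformly random fixed-root labeled tree
(uniform Prüfer sequence), flat-Dirichlet clone frequencies per timepoint
(diagnosis and relapse by default), a single-cell table of `n_cells`
multinomially sampled cells (default 500, a typical per-sample yield;
`n_cells=None` keeps exact frequencies), bulk VAFs computed from the table,
and optional Gaussian VAF noise. In wildtype mode the healthy root clone
receives a configurable `healthy_fraction` (default 0: purely leukemic).

What it deliberately does not model: allelic dropout, doublets or
genotyping error in the single-cell table (treated as ground truth),
read-count noise models (the fit is least-squares, not likelihood-based),
copy-number changes, and SNV clustering (cluster centers are accepted as
input, not computed). Passing tests on these synthetic patients therefore
demonstrates correctness of the combinatorics, the algebra and the
optimization under the stated error models — not robustness to artifacts
the generator omits.

## Numerical choices

* Feasibility/rank-tie tolerance: `1e−9` on the percent scale (solution
  components and residual comparisons). Input VAFs absorb round-off of up
  to `1e−7` at the [0, 100] boundaries.
* Exact determinants use fraction-free Bareiss elimination over Python
  integers — no floating-point round-off enters the invariant check.
* Degenerate inputs: all-zero timepoints, duplicate allele ids, fractional
  (0–1) frequencies, and infeasible minimum-clone-frequency floors are
  rejected with explicit errors rather than silently rescaled.
* Problem sizes in the test and acceptance runs — exhaustive checks to
  `n = 6` (1,296 fixed-root trees), 200 synthetic patients, 1,000
  resampling replicates, 10,000 uniqueness datasets per topology — keep
  the full suite in the tens of seconds while exercising every code path
  at the same clone counts the method targets in practice.

## Known limitations

* Exhaustive enumeration caps practical clone numbers at ~8; there is no
  heuristic tree search, by design.
* The uniqueness statistics depend on the simplex sampling law (see above).
* Weights enter the ranking but not the exactness decision.
* Mode choice (founder vs wildtype root) is the caller's: the package does
  not infer sample purity from the data.
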