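"""Error-analysis experiments for clonal-hierarchy reconstruction.

Ground truth is a single-cell clone table: a binary clone-by-mutation
genotype matrix plus per-clone cell counts (or frequencies).  Noiseless bulk
VAFs follow as ``b_i = sum_j a_ij f_j`` normalized so the most abundant
variant reads 100%.  Three experiment families quantify how robust the
reconstruction is:

* **multinomial resampling** — redraw clone counts from
  ``Multinomial(n_cells, f)`` to emulate sampling a finite number of cells;
* **Gaussian perturbation** — add ``N(0, sd^2)`` noise to each bulk VAF
  (draws leaving [0, 100] are rejected and redrawn), emulating sequencing
  measurement error;
* **uniqueness experiment** — for every fixed-root topology on ``n`` clones,
  draw clone frequencies uniformly from the simplex, compute exact bulk
  VAFs, and count how many topologies fit the data exactly, with one or two
  timepoints.

All experiments are reproducible: each replicate draws from its own child
generator spawned from the global seed, so adding replicates never shifts
earlier draws.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .reconstruct import ReconstructionReport, rank_summary, reconstruct
from .solver import DEFAULT_TOL, VAFSample
from .trees import (
    WILDTYPE_ID,
    ClonalTree,
    Label,
    depth_order,
    enumerate_trees,
    tree_to_genotype_matrix,
)

logger = logging.getLogger("vaftree")


def _spawned_rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator at a fixed spawn key: counter-based, order-stable."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Single-cell ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleCellDataset:
    """Clone-by-mutation genotype table with clone abundances.

    Either integer per-clone cell ``counts`` (summing to ``n_cells``) or
    clone ``frequencies`` (summing to 1) must be given; counts imply
    frequencies.
    """

    allele_ids: tuple[Label, ...]
    genotypes: np.ndarray            # clones x alleles, binary
    counts: Optional[np.ndarray] = None
    frequencies: Optional[np.ndarray] = None
    n_cells: Optional[int] = None
    timepoint: str = ""

    def __post_init__(self) -> None:
        G = np.asarray(self.genotypes, dtype=np.int64)
        if G.ndim != 2 or G.shape[1] != len(self.allele_ids):
            raise ValidationError("genotypes must be a clones x alleles matrix")
        if not np.isin(G, (0, 1)).all():
            raise ValidationError("genotypes must be binary")
        if len({tuple(row) for row in G}) != G.shape[0]:
            raise ValidationError("clone genotype rows must be distinct")
        object.__setattr__(self, "genotypes", G)
        object.__setattr__(self, "allele_ids", tuple(self.allele_ids))
        if self.counts is not None:
            c = np.asarray(self.counts, dtype=np.int64)
            if c.shape != (G.shape[0],) or (c < 0).any():
                raise ValidationError("counts must be nonnegative, one per clone")
            total = int(c.sum())
            if total == 0:
                raise ValidationError("dataset contains no cells")
            if self.n_cells is not None and self.n_cells != total:
                raise ValidationError("n_cells does not match counts")
            object.__setattr__(self, "counts", c)
            object.__setattr__(self, "n_cells", total)
            object.__setattr__(self, "frequencies", c / total)
        elif self.frequencies is not None:
            f = np.asarray(self.frequencies, dtype=float)
            if f.shape != (G.shape[0],) or (f < 0).any():
                raise ValidationError("frequencies must be nonnegative, one per clone")
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValidationError("clone frequencies must sum to 1")
            object.__setattr__(self, "frequencies", f)
        else:
            raise ValidationError("either counts or frequencies are required")

    @property
    def n_clones(self) -> int:
        return self.genotypes.shape[0]

    @classmethod
    def from_tree(
        cls,
        tree: ClonalTree,
        counts: Optional[Sequence[int]] = None,
        frequencies: Optional[Sequence[float]] = None,
        timepoint: str = "",
    ) -> "SingleCellDataset":
        """Ancestor-closed genotypes of a clonal hierarchy, clones in depth order."""
        order = depth_order(tree)
        gm = tree_to_genotype_matrix(tree)
        return cls(
            allele_ids=order,
            genotypes=gm.A.T,    # clone rows carry their root-path mutations
            counts=None if counts is None else np.asarray(counts),
            frequencies=None if frequencies is None else np.asarray(frequencies),
            timepoint=timepoint,
        )


def bulk_vaf_from_sc(ds: SingleCellDataset) -> VAFSample:
    """Bulk VAFs implied by a single-cell clone table.

    ``b_i = sum_j a_ij f_j``, then normalized so the most abundant variant
    allele reads 100% (a purely leukemic sample).
    """
    raw = ds.genotypes.T @ ds.frequencies
    peak = raw.max()
    if peak <= 0:
        raise ValidationError("dataset carries no mutated alleles")
    return VAFSample(
        allele_ids=ds.allele_ids,
        b=raw * (100.0 / peak),
        timepoint=ds.timepoint,
    )


# ---------------------------------------------------------------------------
# Noise models
# ---------------------------------------------------------------------------

def multinomial_resample(
    ds: SingleCellDataset, n_reps: int, seed: int
) -> Iterator[SingleCellDataset]:
    """Redraw clone counts from ``Multinomial(n_cells, f)``, ``n_reps`` times."""
    if ds.n_cells is None or ds.n_cells < 1:
        raise ValidationError("resampling requires a dataset with cell counts")
    for i in range(n_reps):
        rng = _spawned_rng(seed, 1, i)
        counts = rng.multinomial(ds.n_cells, ds.frequencies)
        yield SingleCellDataset(
            allele_ids=ds.allele_ids,
            genotypes=ds.genotypes,
            counts=counts,
            timepoint=ds.timepoint,
        )


def perturb_vafs(
    sample: VAFSample,
    sd: float,
    n_reps: int,
    seed: int,
    policy: str = "redraw",
) -> Iterator[VAFSample]:
    """Add ``N(0, sd^2)`` noise (percent) to each allele's bulk VAF.

    Draws leaving [0, 100] are excluded: with ``policy="redraw"`` the
    offending allele is redrawn (replicate count preserved); with
    ``policy="replicate"`` the whole replicate is redrawn.  The output is
    deliberately *not* re-normalized — noise on the founder allele is
    precisely what destabilizes root identification.
    """
    if sd < 0:
        raise ValidationError("noise standard deviation must be nonnegative")
    if policy not in ("redraw", "replicate"):
        raise ValidationError(f"unknown perturbation policy {policy!r}")
    b = sample.b
    for i in range(n_reps):
        rng = _spawned_rng(seed, 2, i)
        if sd == 0:
            yield sample
            continue
        while True:
            new = b + rng.normal(0.0, sd, size=b.shape)
            if policy == "redraw":
                bad = (new < 0) | (new > 100)
                while bad.any():
                    new[bad] = b[bad] + rng.normal(0.0, sd, size=int(bad.sum()))
                    bad = (new < 0) | (new > 100)
                break
            if ((new >= 0) & (new <= 100)).all():
                break
        yield sample.replace(b=new)


# ---------------------------------------------------------------------------
# Replicated reconstruction experiments
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSummary:
    """Aggregate outcome of a replicated noise experiment."""

    n_reps: int
    frac_true_optimal: float
    frac_true_exact: float
    frac_optimum_unique: float
    histogram_n_compatible: dict[int, int]
    rank_distribution: dict[int, int]
    records: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for frac in (self.frac_true_optimal, self.frac_true_exact,
                     self.frac_optimum_unique):
            if not 0 <= frac <= 1:
                raise ValidationError("summary fractions must lie in [0, 1]")
        if sum(self.histogram_n_compatible.values()) != self.n_reps:
            raise ValidationError("histogram counts must sum to n_reps")


def robustness_experiment(
    truth: ClonalTree,
    ds_by_timepoint: Mapping[str, SingleCellDataset],
    noise: str,
    n_reps: int,
    seed: int,
    sd: float = 0.5,
    mode: str = "founder",
    relaxation_percent: float = 0.0,
    tol: float = DEFAULT_TOL,
    keep_records: bool = True,
) -> PerturbationSummary:
    """Replicate noisy bulk VAFs and summarize reconstruction outcomes.

    For each replicate the bulk VAFs of every timepoint are regenerated under
    the chosen noise model (``"resample"`` or ``"perturb"``), all candidate
    hierarchies are fitted jointly across timepoints, and the replicate
    records how many trees fit exactly, the true tree's rank, and whether the
    optimum is unique.
    """
    if noise not in ("resample", "perturb"):
        raise ValidationError(f"unknown noise model {noise!r}")
    tps = list(ds_by_timepoint)
    base_bulk = {tp: bulk_vaf_from_sc(ds_by_timepoint[tp]) for tp in tps}
    if mode == "wildtype" and WILDTYPE_ID not in truth.labels:
        truth = truth.with_wildtype_root()

    replicate_samples: list[list[VAFSample]] = [[] for _ in range(n_reps)]
    for k, tp in enumerate(tps):
        if noise == "resample":
            for i, ds in enumerate(
                multinomial_resample(ds_by_timepoint[tp], n_reps,
                                     seed=_child_seed(seed, 10 + k))
            ):
                replicate_samples[i].append(bulk_vaf_from_sc(ds))
        else:
            for i, s in enumerate(
                perturb_vafs(base_bulk[tp], sd, n_reps,
                             seed=_child_seed(seed, 10 + k))
            ):
                replicate_samples[i].append(s)

    hist: Counter[int] = Counter()
    ranks: Counter[int] = Counter()
    n_opt = n_exact = n_unique = 0
    records = []
    for i, samples in enumerate(replicate_samples):
        report = reconstruct(
            samples, mode=mode, relaxation_percent=relaxation_percent,
            tol=tol, normalize=False,
        )
        summary = rank_summary(report, truth)
        n_compatible = len(report.exact_fits)
        hist[n_compatible] += 1
        ranks[summary.rank] += 1
        n_opt += summary.is_optimal
        n_exact += summary.is_exact
        n_unique += summary.optimum_unique
        if keep_records:
            records.append({
                "replicate": i,
                "n_compatible": n_compatible,
                "true_rank": summary.rank,
                "true_exact": summary.is_exact,
                "true_optimal": summary.is_optimal,
                "optimum_unique": summary.optimum_unique,
            })
    logger.info(
        "%s experiment: %d reps, true optimal %.3f, true exact %.3f, "
        "optimum unique %.3f",
        noise, n_reps, n_opt / n_reps, n_exact / n_reps, n_unique / n_reps,
    )
    return PerturbationSummary(
        n_reps=n_reps,
        frac_true_optimal=n_opt / n_reps,
        frac_true_exact=n_exact / n_reps,
        frac_optimum_unique=n_unique / n_reps,
        histogram_n_compatible=dict(sorted(hist.items())),
        rank_distribution=dict(sorted(ranks.items())),
        records=records,
    )


def _child_seed(seed: int, k: int) -> int:
    # distinct deterministic child seeds below 2**31
    return int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Exhaustive uniqueness experiment
# ---------------------------------------------------------------------------

@dataclass
class UniquenessResult:
    """Distribution of exact-fit counts per generating topology.

    ``counts[g, d]`` is the number of fixed-root topologies exactly fitting
    dataset ``d`` generated from topology ``g`` (at all timepoints).
    """

    trees: list[ClonalTree]
    counts: np.ndarray           # topologies x datasets, integer
    timepoints: int

    def histogram(self, topology: Optional[int] = None) -> dict[int, int]:
        vals = self.counts if topology is None else self.counts[topology]
        c = Counter(int(v) for v in np.ravel(vals))
        return dict(sorted(c.items()))

    def fraction_at_most(self, k: int, topology: Optional[int] = None) -> float:
        """Fraction of datasets fitted exactly by at most ``k`` topologies."""
        vals = self.counts if topology is None else self.counts[topology]
        return float(np.mean(np.ravel(vals) <= k))


def uniqueness_experiment(
    n: int,
    n_datasets: int,
    timepoints: int = 1,
    seed: int = 0,
    tol: float = 1e-9,
) -> UniquenessResult:
    """How often do exact bulk data pin down the hierarchy?

    For each fixed-root topology on ``n`` clones, draws ``n_datasets`` clone
    frequency vectors per timepoint uniformly from the simplex (flat
    Dirichlet, independently per timepoint), computes the exact bulk VAFs,
    and counts how many of the topologies are compatible (non-negative
    back-substitution solution) with every timepoint.  The generating
    topology always fits its own data, so every count is at least 1.
    """
    if timepoints < 1:
        raise ValidationError("at least one timepoint is required")
    trees = list(enumerate_trees(n, fixed_root=1))
    mats = [tree_to_genotype_matrix(t) for t in trees]
    # For each topology: its genotype matrix permuted back to the canonical
    # allele-id order 1..n (for generating exact bulk VAFs), the permutation
    # taking an id-ordered b to the topology's depth order, and inv(A).
    perms = []    # depth position k -> id index of that allele
    members = []  # membership matrix M in id order: b = 100 * M @ f
    invs = []
    for gm in mats:
        q = np.array([int(a) - 1 for a in gm.allele_order])
        p = np.argsort(q)  # id index -> depth position
        perms.append(q)
        members.append(gm.A[np.ix_(p, p)].astype(float))
        invs.append(np.linalg.inv(gm.A.astype(float)))
    counts = np.zeros((len(trees), n_datasets), dtype=np.int64)
    for g, M in enumerate(members):
        rng = _spawned_rng(seed, 3, g)
        F = rng.dirichlet(np.ones(n), size=(n_datasets, timepoints))
        B = 100.0 * F @ M.T          # datasets x timepoints x alleles (id order)
        for inv_a, q in zip(invs, perms):
            X = B[..., q] @ inv_a.T  # back-substitution solutions, all at once
            compatible = (X >= -tol).all(axis=(1, 2))
            counts[g] += compatible
    logger.info(
        "uniqueness experiment n=%d: %d topologies x %d datasets x %d "
        "timepoint(s); pooled P(count<=2) = %.3f",
        n, len(trees), n_datasets, timepoints,
        float(np.mean(counts <= 2)),
    )
    return UniquenessResult(trees=trees, counts=counts, timepoints=timepoints)
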