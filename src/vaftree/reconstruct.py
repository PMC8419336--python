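"""End-to-end reconstruction of clonal hierarchies from bulk VAFs.

The pipeline normalizes each timepoint's VAF vector so the most abundant
mutation reads 100% (founder mode), enumerates every candidate rooted
labeled tree on the allele set, solves each tree's triangular system by
back-substitution, classifies trees whose solutions are non-negative at
every timepoint as *exact* fits, fits the remaining trees by constrained
weighted least squares, and ranks all candidates by combined residual.

Two rooting modes mirror the two biological scenarios:

* **founder mode** — a single founding mutation present in every leukemic
  cell; the root is the (post-normalization) most abundant allele, and the
  solved clone frequencies sum to 100.
* **wildtype mode** — several founding clones (or an unsequenced common
  founder); a healthy reference allele at 100% is prepended and every tree
  is rooted at it.  Optionally the data are *relaxed* by scaling mutated
  VAFs by ``(100 - x)/100``, which artificially admits ``x%`` healthy cells
  and restores feasibility of the true hierarchy under small errors.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .solver import (
    DEFAULT_TOL,
    TreeFit,
    VAFSample,
    back_substitute,
    constrained_fit,
    is_compatible,
)
from .trees import (
    DEFAULT_ENUMERATION_LIMIT,
    WILDTYPE_ID,
    ClonalTree,
    Label,
    canonical_key,
    enumerate_trees,
    tree_to_genotype_matrix,
)

logger = logging.getLogger("vaftree")


# ---------------------------------------------------------------------------
# Sample preprocessing
# ---------------------------------------------------------------------------

def normalize_vafs(sample: VAFSample) -> VAFSample:
    """Rescale so the most abundant mutation reads 100% (per timepoint)."""
    peak = float(sample.b.max())
    if peak <= 0:
        raise ValidationError(
            f"cannot normalize all-zero sample {sample.timepoint!r}"
        )
    return sample.replace(b=sample.b * (100.0 / peak))


def add_wildtype_root(
    samples: Sequence[VAFSample], wt_id: Label = WILDTYPE_ID
) -> list[VAFSample]:
    """Prepend the healthy reference allele at frequency 100 to each timepoint.

    The reference allele is present in all cells, so reconstruction can root
    every candidate tree at healthy cells.
    """
    out = []
    for s in samples:
        if wt_id in s.allele_ids:
            raise ValidationError(f"reference allele id {wt_id!r} already present")
        weights = (
            np.concatenate([[1.0], s.weights]) if s.weights is not None else None
        )
        out.append(
            VAFSample(
                allele_ids=(wt_id,) + s.allele_ids,
                b=np.concatenate([[100.0], s.b]),
                timepoint=s.timepoint,
                weights=weights,
                metadata=s.metadata,
            )
        )
    return out


def relax(
    samples: Sequence[VAFSample], x_percent: float, wt_id: Label = WILDTYPE_ID
) -> list[VAFSample]:
    """Artificially admit ``x_percent`` healthy cells.

    Every mutated-allele frequency is multiplied by ``(100 - x)/100``; a
    wild-type root allele, if already present, keeps frequency 100.  On exact
    data whose clone frequencies summed to 100, the reconstructed wild-type
    clone then takes frequency exactly ``x_percent``.
    """
    if not 0 <= x_percent < 100:
        raise ValidationError("relaxation percentage must lie in [0, 100)")
    factor = (100.0 - x_percent) / 100.0
    out = []
    for s in samples:
        scale = np.array([1.0 if a == wt_id else factor for a in s.allele_ids])
        out.append(s.replace(b=s.b * scale))
    return out


def _merge_allele_universe(samples: Sequence[VAFSample]) -> list[VAFSample]:
    """Align all timepoints on the union of alleles (absent alleles -> VAF 0)."""
    universe: list[Label] = []
    for s in samples:
        for a in s.allele_ids:
            if a not in universe:
                universe.append(a)
    out = []
    for s in samples:
        missing = [a for a in universe if a not in s.allele_ids]
        if not missing:
            b, w = s.aligned(universe)
            out.append(s.replace(allele_ids=tuple(universe), b=b,
                                 weights=w if s.weights is not None else None))
            continue
        warnings.warn(
            f"alleles {missing!r} absent at timepoint {s.timepoint!r}; "
            "reading their VAF as 0",
            stacklevel=3,
        )
        bmap = dict(zip(s.allele_ids, s.b))
        wmap = dict(zip(s.allele_ids, s.weights)) if s.weights is not None else None
        b = np.array([bmap.get(a, 0.0) for a in universe])
        w = (np.array([wmap.get(a, 1.0) for a in universe])
             if wmap is not None else None)
        out.append(s.replace(allele_ids=tuple(universe), b=b, weights=w))
    return out


# ---------------------------------------------------------------------------
# Fitting a single tree
# ---------------------------------------------------------------------------

def fit_tree(
    tree: ClonalTree,
    samples: Sequence[VAFSample],
    tol: float = DEFAULT_TOL,
    total: float = 100.0,
    rank_all: bool = True,
) -> TreeFit:
    """Fit one candidate hierarchy against every timepoint.

    Each timepoint is solved independently (clone frequencies may differ
    between diagnosis and relapse).  Compatible timepoints use the exact
    back-substitution solution (residual 0, tiny negative components clamped
    and the vector rescaled to its original sum); incompatible timepoints
    fall back to the constrained least-squares fit unless ``rank_all`` is
    False, in which case the tree is ranked at ``+inf``.
    """
    gm = tree_to_genotype_matrix(tree)
    x_by_tp: dict[str, np.ndarray] = {}
    res_by_tp: dict[str, float] = {}
    exact = True
    for s in samples:
        x = back_substitute(gm, s)
        if x.min() >= -tol:
            target = x.sum()
            x = np.clip(x, 0.0, None)
            if x.sum() > 0:
                x = x * (target / x.sum())
            residual = 0.0
        else:
            exact = False
            if rank_all:
                x, residual = constrained_fit(gm, s, total=total)
            else:
                residual = math.inf
        x_by_tp[s.timepoint] = x
        res_by_tp[s.timepoint] = residual
    combined = math.sqrt(sum(r * r for r in res_by_tp.values())) \
        if all(math.isfinite(r) for r in res_by_tp.values()) else math.inf
    return TreeFit(
        tree=tree,
        clone_order=gm.clone_order,
        x_by_timepoint=x_by_tp,
        residual_by_timepoint=res_by_tp,
        combined_residual=combined,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionReport:
    """Ranked fits of every candidate hierarchy against the data."""

    mode: str
    relaxation_percent: float
    fits: list[TreeFit]
    n_trees_enumerated: int
    samples: list[VAFSample]
    config_echo: dict = field(default_factory=dict)

    @property
    def exact_fits(self) -> list[TreeFit]:
        return [f for f in self.fits if f.exact]

    @property
    def best(self) -> TreeFit:
        return self.fits[0]


def reconstruct(
    samples: Sequence[VAFSample],
    mode: str = "founder",
    relaxation_percent: float = 0.0,
    tol: float = DEFAULT_TOL,
    total: float = 100.0,
    normalize: bool = True,
    rank_all: bool = True,
    enumeration_limit: int = DEFAULT_ENUMERATION_LIMIT,
    wt_id: Label = WILDTYPE_ID,
) -> ReconstructionReport:
    """Enumerate and rank every clonal hierarchy compatible with the data.

    Parameters
    ----------
    samples
        One :class:`VAFSample` per timepoint.  Timepoints are aligned on the
        union of their alleles; an allele absent at a timepoint is read as
        VAF 0 (with a warning).
    mode
        ``"founder"`` roots trees at the most abundant mutation (all tied
        maxima are enumerated); ``"wildtype"`` prepends a healthy reference
        allele at 100% and roots there.
    relaxation_percent
        Wildtype mode only: scale mutated VAFs by ``(100 - x)/100`` first.
    normalize
        Founder mode: rescale each timepoint so its maximum VAF is 100.
        Disable when feeding deliberately perturbed data whose founder
        allele should *not* be forced back to 100.
    rank_all
        When False, skip the least-squares fit for incompatible trees (they
        are ranked at ``+inf``); only the exact-fit search remains, which is
        much faster for large enumerations.
    """
    samples = list(samples)
    if not samples:
        raise ValidationError("at least one timepoint is required")
    tps = [s.timepoint for s in samples]
    if len(set(tps)) != len(tps):
        raise ValidationError(f"duplicate timepoint labels: {tps!r}")
    samples = _merge_allele_universe(samples)
    for s in samples:
        if s.b.max() <= 0:
            raise ValidationError(f"timepoint {s.timepoint!r} is all zero")

    if mode == "founder":
        if relaxation_percent:
            raise ValidationError("relaxation requires wildtype mode")
        if normalize:
            samples = [normalize_vafs(s) for s in samples]
        score = np.sum([s.b for s in samples], axis=0)
        peak = score.max()
        roots = [a for a, v in zip(samples[0].allele_ids, score)
                 if v >= peak - 1e-9]
    elif mode == "wildtype":
        if relaxation_percent:
            samples = relax(samples, relaxation_percent, wt_id=wt_id)
        if wt_id not in samples[0].allele_ids:
            samples = add_wildtype_root(samples, wt_id=wt_id)
        roots = [wt_id]
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    alleles = samples[0].allele_ids
    n = len(alleles)
    fits: list[TreeFit] = []
    n_enumerated = 0
    for root in roots:
        for tree in enumerate_trees(n, fixed_root=root, labels=alleles,
                                    limit=enumeration_limit):
            fits.append(fit_tree(tree, samples, tol=tol, total=total,
                                 rank_all=rank_all))
            n_enumerated += 1
    fits.sort(key=lambda f: (f.combined_residual, canonical_key(f.tree)))
    _assign_ranks(fits)
    logger.info(
        "reconstructed %d candidate hierarchies (%d exact) on %d alleles, "
        "%d timepoint(s), mode=%s",
        n_enumerated, sum(f.exact for f in fits), n, len(samples), mode,
    )
    return ReconstructionReport(
        mode=mode,
        relaxation_percent=relaxation_percent,
        fits=fits,
        n_trees_enumerated=n_enumerated,
        samples=samples,
        config_echo={
            "tol": tol,
            "total": total,
            "normalize": normalize,
            "rank_all": rank_all,
            "roots": roots,
            "enumeration_limit": enumeration_limit,
            "tie_rank_convention": "min (ties share the better rank)",
        },
    )


def _assign_ranks(fits: list[TreeFit], res_tol: float = DEFAULT_TOL) -> None:
    """Competition ranking: residual ties (within tolerance) share a rank."""
    rank = 0
    prev = None
    for i, f in enumerate(fits):
        if prev is None or f.combined_residual > prev + res_tol:
            rank = i + 1
            prev = f.combined_residual
        f.rank = rank


# ---------------------------------------------------------------------------
# Ranking the true hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSummary:
    """Where the true hierarchy lands in a reconstruction's ranking."""

    rank: int
    is_optimal: bool
    is_exact: bool
    optimum_unique: bool
    n_fits: int


def rank_summary(
    report: ReconstructionReport,
    true_tree: ClonalTree,
    res_tol: float = DEFAULT_TOL,
) -> RankSummary:
    """Rank of the true tree among all fitted candidates.

    The rank is 1-based with residual ties sharing the better rank;
    ``is_optimal`` means no candidate has a strictly smaller combined
    residual, and ``optimum_unique`` means exactly one candidate attains the
    minimum.  If the true tree's root was not among the enumerated roots
    (possible when noise displaces the most abundant allele) it is fitted
    directly and ranked against the list.
    """
    universe = set(report.samples[0].allele_ids)
    if set(true_tree.labels) != universe:
        raise ValidationError(
            f"true tree alleles {sorted(map(str, true_tree.labels))!r} do not "
            f"match the reconstruction's allele set {sorted(map(str, universe))!r}"
        )
    truth_fit = next(
        (f for f in report.fits if f.tree.parent == dict(true_tree.parent)), None
    )
    in_report = truth_fit is not None
    if truth_fit is None:
        cfg = report.config_echo
        truth_fit = fit_tree(
            true_tree, report.samples,
            tol=cfg.get("tol", DEFAULT_TOL), total=cfg.get("total", 100.0),
            rank_all=cfg.get("rank_all", True),
        )
    residuals = np.array([f.combined_residual for f in report.fits])
    r = truth_fit.combined_residual
    rank = 1 + int(np.sum(residuals < r - res_tol))
    pool = residuals if in_report else np.append(residuals, r)
    best = pool.min()
    return RankSummary(
        rank=rank,
        is_optimal=bool(r <= best + res_tol),
        is_exact=truth_fit.exact,
        optimum_unique=bool(np.sum(pool <= best + res_tol) == 1),
        n_fits=len(report.fits),
    )
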