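"""Synthetic patients emulating clonally resolved AML samples.

Real ground truth for this problem is a published single-cell cohort: a
handful of clones (2-7) related by a rooted mutation tree, heterozygous
mutations, clone frequencies on a simplex, and paired diagnosis/relapse
samples.  The generator reproduces those study conditions: a uniformly
random fixed-root labeled tree (via a uniform Prüfer sequence), flat-
Dirichlet clone frequencies per timepoint, a multinomial single-cell table
of ``n_cells`` sequenced cells, the implied bulk VAFs (founder normalized to
100%), and optional Gaussian VAF noise.

Every generator is a pure function of its seed: a single global seed fans
out to per-component child generators through numpy ``SeedSequence`` spawn
keys, so adding timepoints or replicates never shifts earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .robustness import SingleCellDataset, bulk_vaf_from_sc, perturb_vafs
from .solver import VAFSample
from .trees import ClonalTree, Label, WILDTYPE_ID, depth_order, prufer_to_tree, _root_edges

_TREE, _FREQ, _CELLS, _NOISE = 100, 101, 102, 103


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def mutation_labels(n: int) -> tuple[str, ...]:
    return tuple(f"m{i}" for i in range(1, n + 1))


def random_tree(
    n: int,
    seed: int = 0,
    mode: str = "founder",
    rng: Optional[np.random.Generator] = None,
) -> ClonalTree:
    """Uniformly random fixed-root labeled tree on ``n`` clones.

    Drawn as a uniform Prüfer sequence, which induces the uniform
    distribution over the ``n**(n-2)`` labeled trees with the given root.
    In founder mode the root is mutation ``m1``; in wildtype mode a healthy
    root :data:`WILDTYPE_ID` joins the ``n`` mutated clones and the tree is
    uniform over the ``(n+1)**(n-1)`` trees rooted there.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = rng if rng is not None else _rng(seed, _TREE)
    if mode == "founder":
        labels: tuple[Label, ...] = mutation_labels(n)
        root = labels[0]
    elif mode == "wildtype":
        labels = (WILDTYPE_ID,) + mutation_labels(n)
        root = WILDTYPE_ID
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    m = len(labels)
    if m == 1:
        return ClonalTree({labels[0]: None})
    seq = rng.integers(1, m + 1, size=max(m - 2, 0))
    edges = prufer_to_tree(seq.tolist(), m)
    parent_idx = _root_edges(edges, labels.index(root) + 1)
    return ClonalTree(
        {labels[c - 1]: (labels[p - 1] if p is not None else None)
         for c, p in parent_idx.items()}
    )


def random_frequencies(
    n: int,
    seed: int = 0,
    alpha: float = 1.0,
    min_clone_freq: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Clone frequencies drawn from Dirichlet(alpha, ..., alpha).

    ``alpha = 1`` is uniform on the simplex.  With ``min_clone_freq`` set,
    rejection-sample until every clone reaches that floor (so no clone is
    vanishingly rare).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    rng = rng if rng is not None else _rng(seed, _FREQ)
    if min_clone_freq is not None and n * min_clone_freq > 1 - 1e-12:
        raise ValidationError(
            f"min_clone_freq {min_clone_freq} infeasible for {n} clones"
        )
    while True:
        f = rng.dirichlet(np.full(n, float(alpha)))
        if min_clone_freq is None or f.min() >= min_clone_freq:
            return f


@dataclass(frozen=True)
class SyntheticPatient:
    """A fully specified in-silico patient with known ground truth."""

    truth: ClonalTree
    clone_order: tuple[Label, ...]
    frequencies_by_timepoint: dict[str, np.ndarray]
    sc_by_timepoint: dict[str, SingleCellDataset]
    bulk_by_timepoint: dict[str, VAFSample]
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(self.bulk_by_timepoint)

    def bulk_samples(self) -> list[VAFSample]:
        return list(self.bulk_by_timepoint.values())

    def to_json(self) -> str:
        """Deterministic serialization (same seed -> identical bytes)."""
        payload = {
            "seed": self.seed,
            "provenance": self.provenance,
            "truth": {str(c): (None if p is None else str(p))
                      for c, p in self.truth.parent.items()},
            "clone_order": [str(c) for c in self.clone_order],
            "timepoints": {
                tp: {
                    "frequencies": [repr(float(v)) for v in
                                    self.frequencies_by_timepoint[tp]],
                    "sc_counts": (None if self.sc_by_timepoint[tp].counts is None
                                  else self.sc_by_timepoint[tp].counts.tolist()),
                    "bulk_vaf": {str(a): repr(float(v)) for a, v in
                                 zip(self.bulk_by_timepoint[tp].allele_ids,
                                     self.bulk_by_timepoint[tp].b)},
                }
                for tp in self.timepoints
            },
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def simulate_patient(
    n: int,
    timepoints: Sequence[str] = ("diagnosis", "relapse"),
    n_cells: Optional[int] = 500,
    vaf_noise_sd: float = 0.0,
    seed: int = 0,
    alpha: float = 1.0,
    min_clone_freq: Optional[float] = None,
    mode: str = "founder",
    healthy_fraction: float = 0.0,
) -> SyntheticPatient:
    """Generate one synthetic patient end to end.

    Draws the true hierarchy once, then per timepoint: clone frequencies
    from the simplex, a single-cell table of ``n_cells`` multinomially
    sampled cells (``n_cells=None`` keeps the exact drawn frequencies), the
    implied bulk VAFs, and optional Gaussian VAF noise of ``vaf_noise_sd``
    percent.  In wildtype mode the healthy root clone receives
    ``healthy_fraction`` of the cells and the mutated clones share the rest.
    """
    if not timepoints:
        raise ValidationError("at least one timepoint is required")
    if vaf_noise_sd < 0:
        raise ValidationError("vaf_noise_sd must be nonnegative")
    if not 0 <= healthy_fraction < 1:
        raise ValidationError("healthy_fraction must lie in [0, 1)")
    truth = random_tree(n, seed=seed, mode=mode)
    order = depth_order(truth)
    n_clones = len(order)
    freqs: dict[str, np.ndarray] = {}
    scs: dict[str, SingleCellDataset] = {}
    bulks: dict[str, VAFSample] = {}
    for k, tp in enumerate(timepoints):
        if mode == "wildtype":
            f_mut = random_frequencies(
                n_clones - 1, alpha=alpha, min_clone_freq=min_clone_freq,
                rng=_rng(seed, _FREQ, k),
            )
            f = np.concatenate([[healthy_fraction],
                                (1.0 - healthy_fraction) * f_mut])
        else:
            f = random_frequencies(
                n_clones, alpha=alpha, min_clone_freq=min_clone_freq,
                rng=_rng(seed, _FREQ, k),
            )
        freqs[tp] = f
        if n_cells is not None:
            if n_cells < 1:
                raise ValidationError("n_cells must be >= 1")
            counts = _rng(seed, _CELLS, k).multinomial(n_cells, f)
            sc = SingleCellDataset.from_tree(truth, counts=counts, timepoint=tp)
        else:
            sc = SingleCellDataset.from_tree(truth, frequencies=f, timepoint=tp)
        scs[tp] = sc
        bulk = bulk_vaf_from_sc(sc)
        if vaf_noise_sd > 0:
            bulk = next(perturb_vafs(bulk, vaf_noise_sd, 1,
                                     seed=_child(seed, _NOISE, k)))
        bulks[tp] = bulk
    return SyntheticPatient(
        truth=truth,
        clone_order=order,
        frequencies_by_timepoint=freqs,
        sc_by_timepoint=scs,
        bulk_by_timepoint=bulks,
        seed=seed,
        provenance={
            "n": n, "timepoints": list(timepoints), "n_cells": n_cells,
            "vaf_noise_sd": vaf_noise_sd, "alpha": alpha,
            "min_clone_freq": min_clone_freq, "mode": mode,
            "healthy_fraction": healthy_fraction,
        },
    )


def _child(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0]
               % (2**31))
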