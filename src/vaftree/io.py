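"""File formats: VAF tables, single-cell clone tables, JSON reports, config.

VAF tables are TSV/CSV with columns ``mutation_id``, ``timepoint``,
``vaf_percent`` and optional ``ci_low``/``ci_high`` confidence bounds; the
weight of an allele defaults to 1 and is otherwise the reciprocal
half-width of its confidence interval.  Single-cell clone tables have one
row per clone: a ``timepoint`` column, a ``count`` column, and one binary
column per allele.  All frequencies are percentages (0-100); fractional
input is rejected at the boundary rather than silently rescaled.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reconstruct import ReconstructionReport
from .robustness import PerturbationSummary, SingleCellDataset
from .solver import VAFSample
from .trees import write_newick

PathLike = Union[str, Path]

SCHEMA_VERSION = 1
_VAF_REQUIRED = ("mutation_id", "timepoint", "vaf_percent")
_SC_REQUIRED = ("timepoint", "count")


def _read_table(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _sep_for(path: PathLike) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


# ---------------------------------------------------------------------------
# VAF tables
# ---------------------------------------------------------------------------

def read_vaf_table(path: PathLike) -> list[VAFSample]:
    """Read a per-timepoint VAF table into one sample per timepoint.

    Raises :class:`ValidationError` naming the offending line and column for
    malformed rows or frequencies outside [0, 100].
    """
    df = _read_table(path)
    missing = [c for c in _VAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    has_ci = "ci_low" in df.columns and "ci_high" in df.columns
    extra_cols = [c for c in df.columns
                  if c not in _VAF_REQUIRED + ("ci_low", "ci_high")]
    samples: list[VAFSample] = []
    for tp, group in df.groupby("timepoint", sort=False):
        ids, b, w = [], [], []
        meta: dict = {c: {} for c in extra_cols}
        for row in group.itertuples():
            line = row.Index + 2  # 1-based, after the header
            vaf = row.vaf_percent
            if not np.isfinite(vaf) or not 0 <= vaf <= 100:
                raise ValidationError(
                    f"{path} line {line}, column vaf_percent: value {vaf!r} "
                    "outside [0, 100]"
                )
            ids.append(str(row.mutation_id))
            b.append(float(vaf))
            if has_ci:
                half = (float(row.ci_high) - float(row.ci_low)) / 2.0
                if not np.isfinite(half) or half <= 0:
                    raise ValidationError(
                        f"{path} line {line}: confidence interval must have "
                        "positive width"
                    )
                w.append(1.0 / half)
            for c in extra_cols:
                meta[c][str(row.mutation_id)] = getattr(row, c)
        samples.append(VAFSample(
            allele_ids=tuple(ids),
            b=np.array(b),
            timepoint=str(tp),
            weights=np.array(w) if has_ci else None,
            metadata=meta if extra_cols else None,
        ))
    if not samples:
        raise ValidationError(f"{path}: table contains no rows")
    return samples


def write_vaf_table(samples: Sequence[VAFSample], path: PathLike) -> None:
    rows = []
    for s in samples:
        for i, a in enumerate(s.allele_ids):
            row = {"mutation_id": a, "timepoint": s.timepoint,
                   "vaf_percent": float(s.b[i])}
            if s.weights is not None:
                half = 1.0 / float(s.weights[i])
                row["ci_low"] = float(s.b[i]) - half
                row["ci_high"] = float(s.b[i]) + half
            if s.metadata:
                for c, m in s.metadata.items():
                    if a in m:
                        row[c] = m[a]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Single-cell clone tables
# ---------------------------------------------------------------------------

def read_sc_table(path: PathLike) -> list[SingleCellDataset]:
    """Read a clone table (one row per clone, binary allele columns)."""
    df = _read_table(path)
    missing = [c for c in _SC_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    allele_cols = [c for c in df.columns if c not in _SC_REQUIRED]
    if not allele_cols:
        raise ValidationError(f"{path}: no allele columns found")
    datasets = []
    for tp, group in df.groupby("timepoint", sort=False):
        G = group[allele_cols].to_numpy()
        if not np.isin(G, (0, 1)).all():
            raise ValidationError(f"{path}: allele columns must be binary 0/1")
        datasets.append(SingleCellDataset(
            allele_ids=tuple(allele_cols),
            genotypes=G.astype(np.int64),
            counts=group["count"].to_numpy(dtype=np.int64),
            timepoint=str(tp),
        ))
    if not datasets:
        raise ValidationError(f"{path}: table contains no rows")
    return datasets


def write_sc_table(datasets: Sequence[SingleCellDataset], path: PathLike) -> None:
    rows = []
    for ds in datasets:
        for j in range(ds.n_clones):
            row = {"timepoint": ds.timepoint,
                   "count": int(ds.counts[j]) if ds.counts is not None else 0}
            row.update({str(a): int(v)
                        for a, v in zip(ds.allele_ids, ds.genotypes[j])})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def report_to_dict(report: ReconstructionReport, top_k: Optional[int] = None) -> dict:
    fits = report.fits if top_k is None else report.fits[:top_k]
    return {
        "schema_version": SCHEMA_VERSION,
        "mode": report.mode,
        "relaxation_percent": report.relaxation_percent,
        "n_trees_enumerated": report.n_trees_enumerated,
        "n_exact": len(report.exact_fits),
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in report.config_echo.items()},
        "timepoints": [s.timepoint for s in report.samples],
        "trees": [
            {
                "rank": f.rank,
                "root": str(f.tree.root),
                "parent": {str(c): (None if p is None else str(p))
                           for c, p in f.tree.parent.items()},
                "exact": bool(f.exact),
                "combined_residual": float(f.combined_residual),
                "residual_by_timepoint": {
                    tp: float(r) for tp, r in f.residual_by_timepoint.items()},
                "x_by_timepoint": {
                    tp: {str(a): float(v) for a, v in f.x_as_dict(tp).items()}
                    for tp in f.x_by_timepoint
                },
            }
            for f in fits
        ],
    }


def write_report(
    report: ReconstructionReport,
    path: PathLike,
    top_k: Optional[int] = None,
    newick_dir: Optional[PathLike] = None,
) -> None:
    """Write the ranked reconstruction as JSON, optionally with Newick trees.

    Newick files (one per exact or top-``k`` tree) carry per-timepoint clone
    frequencies as comment annotations.
    """
    Path(path).write_text(json.dumps(report_to_dict(report, top_k), indent=1))
    if newick_dir is not None:
        newick_dir = Path(newick_dir)
        newick_dir.mkdir(parents=True, exist_ok=True)
        chosen = report.exact_fits or report.fits[: (top_k or 1)]
        if top_k is not None:
            chosen = report.fits[:top_k]
        for i, f in enumerate(chosen, start=1):
            freqs = {tp: f.x_as_dict(tp) for tp in f.x_by_timepoint}
            (newick_dir / f"tree_rank{f.rank}_{i}.nwk").write_text(
                write_newick(f.tree, frequencies=freqs) + "\n"
            )


def write_summary(summary: PerturbationSummary, path: PathLike) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "n_reps": summary.n_reps,
        "frac_true_optimal": summary.frac_true_optimal,
        "frac_true_exact": summary.frac_true_exact,
        "frac_optimum_unique": summary.frac_optimum_unique,
        "histogram_n_compatible": {str(k): v for k, v in
                                   summary.histogram_n_compatible.items()},
        "rank_distribution": {str(k): v for k, v in
                              summary.rank_distribution.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_replicates_tsv(summary: PerturbationSummary, path: PathLike) -> None:
    if not summary.records:
        raise ValidationError("summary carries no per-replicate records")
    pd.DataFrame(summary.records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: Optional[PathLike]) -> dict:
    """Flat key-value JSON config mirroring the CLI flags; CLI overrides."""
    if path is None:
        return {}
    cfg = json.loads(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a flat JSON object")
    return cfg
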