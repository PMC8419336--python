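"""Linear algebra of the clonal deconvolution problem.

Given the genotype matrix ``A`` of a candidate hierarchy and the bulk
variant-allele-frequency vector ``b`` (percent), the clone abundances ``x``
solve ``A x = b``.  Because ``A`` is unit upper triangular the solution is
unique and obtained by back-substitution; the data are *compatible* with the
hierarchy when that solution is componentwise non-negative.

When measurement error makes the data incompatible with every (or the true)
hierarchy, each candidate is instead fit by constrained weighted least
squares: minimize ``||W(Ax - b)||_2`` subject to ``x >= 0`` and
``sum(x) = total`` (total = 100 in percent space).  This is a convex
quadratic program; it is solved here by an active-set method (exact KKT
solves on the free variables) with a scipy SLSQP fallback, so the global
optimum is attained to machine precision on these small systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .errors import FitError, ValidationError
from .trees import ClonalTree, GenotypeMatrix, Label

#: The conventional exact-fit threshold on ``||Ax - b||``.  Kept as a
#: configurable constant; in practice exactness is decided by non-negativity
#: of the back-substitution solution (see `is_compatible`), which is
#: algebraically exact, because a residual below ~1e-16 is unreachable for
#: generic double-precision optimizer output.
EXACTNESS_EPSILON = 1e-15

#: Default feasibility tolerance on solution components (percent scale).
DEFAULT_TOL = 1e-9


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VAFSample:
    """Bulk variant allele frequencies of one sample (one timepoint).

    Frequencies are in percent (0-100).  Optional per-allele weights are the
    diagonal of the weighting matrix ``W`` in the weighted fit; they default
    to 1 and are typically ``1 / (confidence-interval half-width)``.
    """

    allele_ids: tuple[Label, ...]
    b: np.ndarray
    timepoint: str = ""
    weights: Optional[np.ndarray] = None
    metadata: Optional[dict] = None

    def __post_init__(self) -> None:
        ids = tuple(self.allele_ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate allele identifiers in sample")
        b = np.asarray(self.b, dtype=float)
        if b.ndim != 1 or b.shape[0] != len(ids):
            raise ValidationError("b must be a vector aligned to allele_ids")
        if len(ids) == 0:
            raise ValidationError("sample must contain at least one allele")
        if (b < -1e-9).any() or (b > 100 + 1e-7).any():
            raise ValidationError("VAFs must lie in [0, 100] percent")
        b = np.clip(b, 0.0, 100.0)  # absorb round-off at the boundaries
        object.__setattr__(self, "allele_ids", ids)
        object.__setattr__(self, "b", b)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != b.shape:
                raise ValidationError("weights must align with allele_ids")
            if (w <= 0).any():
                raise ValidationError("weights must be strictly positive")
            object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.allele_ids)

    def value(self, allele: Label) -> float:
        return float(self.b[self.allele_ids.index(allele)])

    def aligned(self, order: Sequence[Label]) -> tuple[np.ndarray, np.ndarray]:
        """Return (b, weights) reordered to ``order``; weights default to 1."""
        try:
            idx = [self.allele_ids.index(a) for a in order]
        except ValueError as exc:
            raise ValidationError(
                f"sample {self.timepoint!r} does not cover allele set {tuple(order)!r}"
            ) from exc
        if len(order) != self.n:
            raise ValidationError("allele set size mismatch")
        w = self.weights[idx] if self.weights is not None else np.ones(self.n)
        return self.b[idx], w

    def replace(self, **changes) -> "VAFSample":
        fields = dict(
            allele_ids=self.allele_ids, b=self.b, timepoint=self.timepoint,
            weights=self.weights, metadata=self.metadata,
        )
        fields.update(changes)
        return VAFSample(**fields)


@dataclass(eq=False)
class TreeFit:
    """One candidate hierarchy's fit against every timepoint.

    ``x_by_timepoint`` maps timepoint -> clone-frequency vector (percent)
    aligned to ``clone_order``; ``combined_residual`` aggregates the
    per-timepoint residuals ``||W(Ax - b)||_2`` as the root of their sum of
    squares.  ``exact`` means the back-substitution solution was feasible
    (non-negative) at every timepoint.
    """

    tree: ClonalTree
    clone_order: tuple[Label, ...]
    x_by_timepoint: dict[str, np.ndarray]
    residual_by_timepoint: dict[str, float]
    combined_residual: float
    exact: bool
    rank: Optional[int] = None

    def x_as_dict(self, timepoint: str) -> dict[Label, float]:
        x = self.x_by_timepoint[timepoint]
        return {lab: float(v) for lab, v in zip(self.clone_order, x)}


# ---------------------------------------------------------------------------
# Exact solution and compatibility
# ---------------------------------------------------------------------------

def back_substitute(gm: GenotypeMatrix, sample: VAFSample) -> np.ndarray:
    """Solve ``A x = b`` exactly for the unit-upper-triangular system.

    ``x[n-1] = b[n-1]`` and ``x[j] = b[j] - sum_{k>j} a_jk x[k]``; the
    solution is unique because ``det(A) = 1``.  Returns ``x`` aligned to
    ``gm.clone_order``.
    """
    b, _ = sample.aligned(gm.allele_order)
    return scipy.linalg.solve_triangular(
        gm.A.astype(float), b, lower=False, unit_diagonal=True
    )


def is_compatible(gm: GenotypeMatrix, sample: VAFSample, tol: float = DEFAULT_TOL) -> bool:
    """True iff ``A x = b`` has a (tolerance-)non-negative solution."""
    x = back_substitute(gm, sample)
    return bool(x.min() >= -tol)


def condition_number(gm: GenotypeMatrix) -> float:
    """l2 condition number of ``A``: ratio of extreme singular values.

    Bounds how strongly VAF measurement error is amplified into
    clone-frequency error.
    """
    return float(np.linalg.cond(gm.A.astype(float), 2))


def solution_sensitivity(
    gm: GenotypeMatrix, sample: VAFSample, sample_prime: VAFSample
) -> np.ndarray:
    """Per-clone solution difference ``x - x'`` for two data vectors.

    Since ``A(x - x') = b - b'`` and ``det(A) = 1``, Cramer's rule gives
    ``x_i - x_i' = det(A_i)`` with the i-th column replaced by ``b - b'``;
    in particular the last component satisfies ``x_n - x_n' = b_n - b_n'``.
    """
    return back_substitute(gm, sample) - back_substitute(gm, sample_prime)


# ---------------------------------------------------------------------------
# Constrained weighted least squares
# ---------------------------------------------------------------------------

def constrained_fit(
    gm: GenotypeMatrix, sample: VAFSample, total: float = 100.0
) -> tuple[np.ndarray, float]:
    """Globally minimize ``||W(Ax - b)||_2`` s.t. ``x >= 0``, ``sum(x) = total``.

    For compatible, normalized data the minimum is 0 and the solution matches
    back-substitution.  Returns ``(x, residual)`` with ``x`` aligned to
    ``gm.clone_order``.

    Raises
    ------
    FitError
        If both the active-set solver and the SLSQP fallback fail; the error
        names the tree (clone order) being fit.
    """
    b, w = sample.aligned(gm.allele_order)
    C = w[:, None] * gm.A.astype(float)
    d = w * b
    try:
        x = _active_set_eq_nnls(C, d, total)
    except FitError:
        x = _slsqp_fallback(C, d, total, gm)
    residual = float(np.linalg.norm(C @ x - d))
    return x, residual


def _solve_free(C: np.ndarray, d: np.ndarray, free: np.ndarray, total: float):
    """Equality-constrained LS on the free variables via the KKT system."""
    n = C.shape[1]
    k = int(free.sum())
    Cf = C[:, free]
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = Cf.T @ Cf
    K[:k, k] = 1.0
    K[k, :k] = 1.0
    rhs = np.concatenate([Cf.T @ d, [total]])
    sol = np.linalg.solve(K, rhs)
    x = np.zeros(n)
    x[free] = sol[:k]
    return x, float(sol[k])


def _active_set_eq_nnls(
    C: np.ndarray, d: np.ndarray, total: float, tol: float = 1e-10
) -> np.ndarray:
    """Lawson–Hanson-style active-set method with a sum equality constraint.

    Maintains a feasible iterate on the simplex ``{x >= 0, sum x = total}``;
    terminates at KKT optimality of the convex QP.
    """
    n = C.shape[1]
    x = np.full(n, total / n)
    free = np.ones(n, dtype=bool)
    scale = max(1.0, float(np.abs(C.T @ d).max()))
    for _ in range(6 * n + 10):
        xf, lam = _solve_free(C, d, free, total)
        if xf[free].min() >= -tol * total:
            x = np.clip(xf, 0.0, None)
            # dual feasibility on the clamped set: mu_i = g_i + lambda >= 0
            g = C.T @ (C @ x - d)
            mu = g + lam
            clamped = ~free
            if not clamped.any() or mu[clamped].min() >= -1e-8 * scale:
                return x
            worst = np.flatnonzero(clamped)[np.argmin(mu[clamped])]
            free[worst] = True
            continue
        # step from the feasible x toward xf until a free variable hits zero
        moving = free & (xf < x)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(moving & (xf < 0), x / (x - xf), np.inf)
        alpha = float(ratios.min())
        x = x + alpha * (xf - x)
        newly = free & (x <= tol * total)
        x[newly] = 0.0
        free &= ~newly
        if not free.any():  # numerical breakdown; the simplex is nonempty
            raise FitError("active set emptied out")
    raise FitError("active-set iteration limit reached")


def _slsqp_fallback(C: np.ndarray, d: np.ndarray, total: float, gm: GenotypeMatrix):
    n = C.shape[1]
    H = C.T @ C
    c = C.T @ d

    def fun(x):
        r = C @ x - d
        return 0.5 * float(r @ r)

    def jac(x):
        return H @ x - c

    res = scipy.optimize.minimize(
        fun, np.full(n, total / n), jac=jac, method="SLSQP",
        bounds=[(0.0, None)] * n,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - total,
                      "jac": lambda x: np.ones(n)}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    if not res.success:
        raise FitError(
            f"constrained fit failed for tree with clone order {gm.clone_order!r}: "
            f"{res.message}"
        )
    return np.clip(res.x, 0.0, None)
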