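"""Analytic hierarchy process: judgment matrices, priorities, consistency.

Within each sibling group of the indicator hierarchy, relative importance
is elicited as a positive reciprocal *judgment matrix* on the Saaty 1–9
scale (a_ij = how many grades item i dominates item j; a_ji = 1/a_ij).
Priority weights are the normalised principal eigenvector of that matrix;
internal coherence is judged by the consistency ratio

    CI = (lambda_max − n) / (n − 1),   CR = CI / RI(n),

where RI(n) is Saaty's mean consistency index of random reciprocal
matrices of order n.  CR < 0.1 is the conventional acceptance cut-off;
matrices of order 1–2 are consistent by construction.

When experts rate importance on a Likert scale instead of comparing pairs
directly, a group matrix is built from the per-indicator mean scores: the
difference between two means, in steps of a configurable grade width,
selects the Saaty grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

SAATY_MIN, SAATY_MAX = 1.0 / 9.0, 9.0

#: Saaty's random consistency index, orders 1..15
RANDOM_INDEX = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41,
                1.45, 1.49, 1.51, 1.48, 1.56, 1.57, 1.59)

CR_CUTOFF = 0.1

#: default Likert-mean difference corresponding to one Saaty grade
DEFAULT_GRADE_STEP = 0.5

_RECIPROCITY_TOL = 1e-12


class MatrixError(ValueError):
    """The given matrix is not a valid Saaty judgment matrix."""


@dataclass(frozen=True)
class JudgmentMatrix:
    """Positive reciprocal pairwise-comparison matrix over ordered ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        n = len(self.ids)
        if a.shape != (n, n):
            raise MatrixError(f"matrix shape {a.shape} does not match {n} ids")
        if not np.all(a > 0):
            raise MatrixError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=_RECIPROCITY_TOL):
            raise MatrixError("diagonal entries must equal 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-9):
            raise MatrixError("matrix is not reciprocal (a_ij * a_ji != 1)")
        if np.any(a < SAATY_MIN - 1e-9) or np.any(a > SAATY_MAX + 1e-9):
            raise MatrixError("entries must lie within the Saaty range [1/9, 9]")

    @property
    def order(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class AhpResult:
    """Priority weights with the consistency diagnostics of their matrix."""

    ids: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent: bool

    def weights_by_id(self) -> dict[str, float]:
        return {i: float(w) for i, w in zip(self.ids, self.weights)}

    def to_json_dict(self) -> dict:
        return {
            "weights": self.weights_by_id(),
            "lambda_max": self.lambda_max,
            "CI": self.ci,
            "RI": self.ri,
            "CR": self.cr,
            "consistent": self.consistent,
        }


def _half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def build_judgment_matrix(
    mean_scores: Mapping[str, float],
    step: float = DEFAULT_GRADE_STEP,
) -> JudgmentMatrix:
    """Group judgment matrix from per-indicator mean importance scores.

    For items i, j with mean difference d = m_i − m_j, the Saaty grade is
    g = min(9, 1 + round(|d| / step)); the entry is g when i dominates,
    1/g when j does, and 1 on a tie.  ``step`` is the score difference
    worth one grade (0.5 Likert units by default).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    ids = tuple(mean_scores)
    if len(ids) < 2:
        raise ValueError("need at least 2 siblings to compare")
    m = np.ones((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if j <= i:
                continue
            d = mean_scores[a] - mean_scores[b]
            g = min(9, 1 + _half_up(abs(d) / step))
            entry = 1.0 if g == 1 else (float(g) if d > 0 else 1.0 / g)
            m[i, j] = entry
            m[j, i] = 1.0 / entry
    return JudgmentMatrix(ids=ids, values=m)


def _power_iteration(a: np.ndarray, tol: float = 1e-12,
                     max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Principal eigenpair of a positive matrix (Perron–Frobenius)."""
    n = a.shape[0]
    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        av = a @ v
        nxt = av / av.sum()
        if np.max(np.abs(nxt - v)) < tol:
            v = nxt
            break
        v = nxt
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations"
        )
    lam = float((a @ v).sum() / v.sum())
    return v, lam


def priority_weights(
    matrix: JudgmentMatrix,
    method: str = "eigenvector",
) -> AhpResult:
    """Priority vector and consistency diagnostics.

    ``eigenvector`` (default, the classical AHP) takes the normalised
    principal eigenvector via power iteration; ``geometric_mean`` takes
    normalised row geometric means.  The two coincide exactly on
    consistent matrices.  lambda_max is estimated as the mean Rayleigh
    ratio (A w)_i / w_i, exact at the eigenvector.
    """
    a = matrix.values
    n = matrix.order
    if method == "eigenvector":
        if n == 1:
            w, lam = np.array([1.0]), 1.0
        else:
            w, lam = _power_iteration(a)
    elif method == "geometric_mean":
        gm = np.exp(np.mean(np.log(a), axis=1))
        w = gm / gm.sum()
        lam = float(np.mean((a @ w) / w))
    else:
        raise ValueError(f"unknown method {method!r}")
    ci, ri, cr, ok = _consistency_from_lambda(lam, n)
    return AhpResult(ids=matrix.ids, weights=w, lambda_max=lam,
                     ci=ci, ri=ri, cr=cr, consistent=ok)


def _consistency_from_lambda(lam: float, n: int) -> tuple[float, float, float, bool]:
    if n > len(RANDOM_INDEX):
        raise ValueError(
            f"no random index for order {n}; table covers 1..{len(RANDOM_INDEX)}"
        )
    if n <= 2:
        return 0.0, RANDOM_INDEX[n - 1], 0.0, True
    ci = (lam - n) / (n - 1)
    ri = RANDOM_INDEX[n - 1]
    cr = ci / ri
    return ci, ri, cr, cr < CR_CUTOFF


def consistency_ratio(matrix: JudgmentMatrix) -> tuple[float, float, float, bool]:
    """(CI, RI, CR, consistent) for a judgment matrix.

    Orders 1–2 are consistent by construction (CI = CR = 0); otherwise
    CI = (lambda_max − n)/(n − 1) and CR = CI/RI(n), accepted when
    CR < 0.1.
    """
    n = matrix.order
    if n <= 2:
        return _consistency_from_lambda(float(n), n)
    _, lam = _power_iteration(matrix.values)
    return _consistency_from_lambda(lam, n)


def aggregate_expert_matrices(
    matrices: Sequence[JudgmentMatrix],
) -> JudgmentMatrix:
    """Element-wise geometric mean of per-expert judgment matrices.

    The geometric mean is the standard group-AHP aggregator because it is
    the only one that preserves reciprocity; computed on logs so the
    result is reciprocal to machine precision.
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise MatrixError("matrices must share identical ids and order")
    logs = np.mean([np.log(m.values) for m in matrices], axis=0)
    # exact antisymmetry of logs -> exact reciprocity of the aggregate
    logs = (logs - logs.T) / 2.0
    return JudgmentMatrix(ids=ids, values=np.exp(logs))


# ---- CSV interface -----------------------------------------------------


def _parse_entry(text: str) -> float:
    text = text.strip()
    if "/" in text:
        return float(Fraction(text))
    return float(text)


def read_matrix_csv(path: str | Path) -> JudgmentMatrix:
    """Square CSV with ids on the first row and column; entries may be
    decimals or fraction strings like ``1/3``."""
    import csv

    with open(path, encoding="utf-8") as f:
        rows = [row for row in csv.reader(f) if row]
    if not rows:
        raise MatrixError(f"{path}: empty matrix file")
    ids = tuple(h.strip() for h in rows[0][1:])
    values = np.ones((len(ids), len(ids)))
    if len(rows) - 1 != len(ids):
        raise MatrixError(f"{path}: expected {len(ids)} data rows")
    for i, row in enumerate(rows[1:]):
        if row[0].strip() != ids[i]:
            raise MatrixError(
                f"{path} line {i + 2}: row id {row[0]!r} does not match "
                f"column id {ids[i]!r}"
            )
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = _parse_entry(cell)
            except (ValueError, ZeroDivisionError) as exc:
                raise MatrixError(f"{path} line {i + 2}: bad entry {cell!r}") from exc
    return JudgmentMatrix(ids=ids, values=values)


def write_matrix_csv(matrix: JudgmentMatrix, path: str | Path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["", *matrix.ids])
        for i, row_id in enumerate(matrix.ids):
            writer.writerow([row_id, *(repr(float(x)) for x in matrix.values[i])])
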