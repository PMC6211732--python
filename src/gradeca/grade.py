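"""Core grade-statistics machinery.

A nonnegative data matrix (rows = samples, columns = variables) is treated as
a discrete bivariate probability distribution by dividing through by its grand
total.  The *grade transformation* places rows and columns on the unit
interval proportionally to their marginal mass, turning the matrix into a
piecewise-constant copula density.  Everything else in the package — the
overrepresentation map, the Spearman-rho*/Kendall-tau seriation objectives,
the variance (differentiation) coefficients used for clustering, the total
variance ``tau_abs`` and the regularity index — is computed from that
representation.

Conventions
-----------
* ``p`` is the n x k probability matrix (sums to 1), ``p_i.``/``p_.j`` its
  marginals, ``S_i``/``T_j`` their cumulative breakpoints with S_0 = T_0 = 0
  and S_n = T_k = 1.
* The grade density on the rectangle R_ij = [S_{i-1},S_i) x [T_{j-1},T_j) is
  h_ij = p_ij / (p_i. * p_.j); h == 1 everywhere iff rows and columns are
  independent.
* rho* = 3 * sum_ij (S_{i-1}+S_i-1)(T_{j-1}+T_j-1) p_ij.
* tau  = 2 * sum_{i<r, j<s} (p_ij p_rs - p_rj p_is).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DataMatrix",
    "ProbabilityMatrix",
    "GradeDensityMap",
    "GradeCdf",
    "to_probability_matrix",
    "grade_density",
    "grade_transform",
    "rho_star",
    "tau",
    "tau_abs",
    "variance_coefficient",
    "tau_via_variance",
    "rho_via_variance",
    "regularity_index",
    "grade_summary",
]

#: absolute tolerance for "sums to one" style checks
SUM_TOL = 1e-9


def _as_ids(ids, n, prefix):
    if ids is None:
        return [f"{prefix}{i}" for i in range(n)]
    ids = [str(x) for x in ids]
    if len(ids) != n:
        raise ValueError(f"expected {n} {prefix}-identifiers, got {len(ids)}")
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate identifiers: {dup}")
    return ids


@dataclass(frozen=True)
class DataMatrix:
    """A labelled nonnegative matrix (rows = samples, columns = variables).

    Raises ``ValueError`` on negative or non-finite entries, naming the
    offending coordinates.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __init__(self, values, row_ids=None, col_ids=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"non-finite value at row {i}, column {j}")
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative value {values[i, j]} at row {i}, column {j}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", _as_ids(row_ids, values.shape[0], "row"))
        object.__setattr__(self, "col_ids", _as_ids(col_ids, values.shape[1], "col"))

    @classmethod
    def from_dataframe(cls, df) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def permute(self, row_perm=None, col_perm=None) -> "DataMatrix":
        """Return a copy with rows/columns reordered by the given permutations."""
        v = self.values
        rid, cid = self.row_ids, self.col_ids
        if row_perm is not None:
            row_perm = np.asarray(row_perm)
            v = v[row_perm]
            rid = [rid[i] for i in row_perm]
        if col_perm is not None:
            col_perm = np.asarray(col_perm)
            v = v[:, col_perm]
            cid = [cid[j] for j in col_perm]
        return DataMatrix(v, rid, cid)


@dataclass(frozen=True)
class ProbabilityMatrix:
    """A data matrix normalised to total mass 1, with marginals and grades.

    ``row_cum`` and ``col_cum`` hold the cumulative breakpoints including the
    leading zero, i.e. ``row_cum = (S_0, S_1, ..., S_n)`` with S_0 = 0 and
    S_n = 1.
    """

    p: np.ndarray
    row_marginals: np.ndarray
    col_marginals: np.ndarray
    row_cum: np.ndarray
    col_cum: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape

    def permute(self, row_perm=None, col_perm=None) -> "ProbabilityMatrix":
        v = self.p
        rid, cid = self.row_ids, self.col_ids
        if row_perm is not None:
            row_perm = np.asarray(row_perm)
            v = v[row_perm]
            rid = [rid[i] for i in row_perm]
        if col_perm is not None:
            col_perm = np.asarray(col_perm)
            v = v[:, col_perm]
            cid = [cid[j] for j in col_perm]
        return _probability_matrix_from_p(v, rid, cid)


def _probability_matrix_from_p(p, row_ids, col_ids) -> ProbabilityMatrix:
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    S = np.concatenate([[0.0], np.cumsum(pi)])
    T = np.concatenate([[0.0], np.cumsum(pj)])
    S[-1] = 1.0
    T[-1] = 1.0
    return ProbabilityMatrix(p, pi, pj, S, T, list(row_ids), list(col_ids))


def to_probability_matrix(m: DataMatrix | np.ndarray) -> ProbabilityMatrix:
    """Normalise a nonnegative matrix to a bivariate probability matrix.

    Rows or columns with zero marginal are rejected by name (the grade
    formulas divide by the marginals); a zero grand total is rejected.
    """
    if not isinstance(m, DataMatrix):
        m = DataMatrix(np.asarray(m, dtype=float))
    total = m.values.sum()
    if total <= 0:
        raise ValueError("matrix has zero grand total; cannot normalise")
    rowsum = m.values.sum(axis=1)
    colsum = m.values.sum(axis=0)
    if (rowsum == 0).any():
        ids = [m.row_ids[i] for i in np.flatnonzero(rowsum == 0)]
        raise ValueError(f"all-zero row(s): {ids}")
    if (colsum == 0).any():
        ids = [m.col_ids[j] for j in np.flatnonzero(colsum == 0)]
        raise ValueError(f"all-zero column(s): {ids}")
    return _probability_matrix_from_p(m.values / total, m.row_ids, m.col_ids)


@dataclass(frozen=True)
class GradeDensityMap:
    """Piecewise-constant copula density h_ij on the unit square.

    ``h[i, j]`` is the over/underrepresentation ratio on the rectangle
    ``[row_cum[i], row_cum[i+1]) x [col_cum[j], col_cum[j+1])``; values below
    1 are underrepresentation, above 1 overrepresentation.  The weighted sum
    ``sum_ij h_ij * dS_i * dT_j`` equals 1.
    """

    h: np.ndarray
    row_cum: np.ndarray
    col_cum: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    @property
    def rects(self):
        """Rectangles [S_{i-1},S_i) x [T_{j-1},T_j) as an (n, k, 4) array
        of (u0, u1, v0, v1)."""
        S, T = self.row_cum, self.col_cum
        n, k = self.h.shape
        out = np.empty((n, k, 4))
        out[..., 0] = S[:-1, None]
        out[..., 1] = S[1:, None]
        out[..., 2] = T[None, :-1]
        out[..., 3] = T[None, 1:]
        return out

    def integral(self) -> float:
        dS = np.diff(self.row_cum)
        dT = np.diff(self.col_cum)
        return float(dS @ self.h @ dT)


def grade_density(P: ProbabilityMatrix) -> GradeDensityMap:
    """Grade density h_ij = p_ij / (p_i. p_.j) on the unit-square rectangles."""
    h = P.p / np.outer(P.row_marginals, P.col_marginals)
    return GradeDensityMap(h, P.row_cum.copy(), P.col_cum.copy(),
                           list(P.row_ids), list(P.col_ids))


# ---------------------------------------------------------------------------
# one-dimensional grade transformation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradeCdf:
    """Left/right CDF limits of a one-dimensional distribution at its atoms.

    ``cdf_left[i] = F(support[i]-)`` and ``cdf_right[i] = F(support[i]+)``.
    Between atoms the CDF may rise continuously; ``grade_transform`` only
    needs the limits at the queried point.
    """

    support: np.ndarray
    cdf_left: np.ndarray
    cdf_right: np.ndarray

    @classmethod
    def from_sample(cls, sample: Sequence[float]) -> "GradeCdf":
        """Empirical CDF limits from a sample (atoms at the distinct values,
        mass proportional to multiplicity)."""
        x = np.sort(np.asarray(sample, dtype=float))
        support, counts = np.unique(x, return_counts=True)
        right = np.cumsum(counts) / len(x)
        left = right - counts / len(x)
        return cls(support, left, right)

    @classmethod
    def from_pmf(cls, support, probs) -> "GradeCdf":
        support = np.asarray(support, dtype=float)
        probs = np.asarray(probs, dtype=float)
        order = np.argsort(support)
        support, probs = support[order], probs[order]
        right = np.cumsum(probs)
        left = right - probs
        return cls(support, left, right)

    def limits_at(self, x: float) -> tuple[float, float]:
        """(F(x-), F(x+)) at an arbitrary point."""
        idx = np.searchsorted(self.support, x)
        if idx < len(self.support) and self.support[idx] == x:
            return float(self.cdf_left[idx]), float(self.cdf_right[idx])
        # not an atom: F is flat (or continuous) here; both limits equal the
        # mass strictly below x
        below = float(self.cdf_right[idx - 1]) if idx > 0 else 0.0
        return below, below


def grade_transform(cdf: GradeCdf, u: float, x: float) -> float:
    """Randomised grade (probability-integral) transform F*(u, x).

    Returns 1 if F(x+) <= u; (u - F(x-)) / (F(x+) - F(x-)) if
    F(x-) <= u < F(x+); and 0 if F(x-) > u.  For an atomless F this is the
    ordinary F(x) and the transformed variable is uniform on [0, 1]; the
    randomisation u spreads each atom over its mass interval so the output
    is uniform for any distribution.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must lie in [0, 1], got {u}")
    f_left, f_right = cdf.limits_at(x)
    if f_right <= u:
        return 1.0
    if f_left > u:
        return 0.0
    return (u - f_left) / (f_right - f_left)


# ---------------------------------------------------------------------------
# grade correlation coefficients
# ---------------------------------------------------------------------------

def _grade_centers(cum: np.ndarray) -> np.ndarray:
    """(S_{i-1} + S_i - 1) per cell — the centred grade coordinate scaled by 2."""
    return cum[:-1] + cum[1:] - 1.0


def rho_star(P: ProbabilityMatrix) -> float:
    """Grade Spearman correlation of the probability matrix.

    rho* = 3 sum_ij (S_{i-1}+S_i-1)(T_{j-1}+T_j-1) p_ij, in [-1, 1].
    """
    a = _grade_centers(P.row_cum)
    b = _grade_centers(P.col_cum)
    return float(3.0 * a @ P.p @ b)


def tau(P: ProbabilityMatrix) -> float:
    """Grade Kendall correlation: 2 sum_{i<r, j<s} (p_ij p_rs - p_rj p_is).

    Evaluated in O(nk) via row/column prefix sums rather than the quartic
    definition.
    """
    p = P.p
    # A[r] = sum of rows strictly above r
    A = np.cumsum(p, axis=0) - p
    # prefix over columns strictly left, suffix strictly right, of A per row
    cumA = np.cumsum(A, axis=1) - A
    suffA = A.sum(axis=1, keepdims=True) - cumA - A
    return float(2.0 * np.sum(p * (cumA - suffA)))


def tau_abs(P: ProbabilityMatrix) -> float:
    """Total absolute variance 2 sum_{i<r, j<s} |p_ij p_rs - p_rj p_is|.

    Upper-bounds |tau| over every row/column permutation of the matrix.  The
    pair sum for two rows u, v is evaluated in O(k log k) by sorting columns
    by the ratio u_j/(u_j+v_j): in that order all 2x2 determinants share a
    sign, so the absolute sum telescopes through prefix sums.  The pair loop
    runs over the shorter axis.
    """
    p = P.p if P.p.shape[0] <= P.p.shape[1] else P.p.T
    n, k = p.shape
    total = 0.0
    for i in range(n - 1):
        u = p[i]
        V = p[i + 1:]
        denom = u[None, :] + V
        with np.errstate(invalid="ignore", divide="ignore"):
            key = np.where(denom > 0, u[None, :] / denom, 0.5)
        order = np.argsort(key, axis=1, kind="stable")
        us = np.take_along_axis(np.broadcast_to(u, V.shape), order, axis=1)
        vs = np.take_along_axis(V, order, axis=1)
        # ascending u/v ratio => u_j v_s - u_s v_j <= 0 for j < s
        cu = np.cumsum(us, axis=1) - us
        cv = np.cumsum(vs, axis=1) - vs
        total += float(np.sum(us * cv - vs * cu))
    return 2.0 * total


def variance_coefficient(P: ProbabilityMatrix, r: int, i: int) -> float:
    """Differentiation coefficient ar(r:i) between normalised rows i < r.

    ar(r:i) = sum_{j<s} (p_ij p_rs - p_rj p_is) / (p_r. p_i.); it is the
    grade-Kendall concordance of the two row profiles and vanishes iff the
    normalised rows are identical in the concordance sense.
    """
    if not 0 <= i < r < P.p.shape[0]:
        raise ValueError(f"require 0 <= i < r < n, got i={i}, r={r}")
    u = P.p[i]
    v = P.p[r]
    cu = np.cumsum(u) - u
    cv = np.cumsum(v) - v
    num = float(np.sum(v * cu - u * cv))
    return num / (P.row_marginals[r] * P.row_marginals[i])


def _pairwise_ar(P: ProbabilityMatrix) -> np.ndarray:
    """Strict lower-triangular matrix of ar(r:i) for all row pairs i < r."""
    p = P.p
    n = p.shape[0]
    cum = np.cumsum(p, axis=1) - p
    M = cum @ p.T  # M[i, r] = sum_j cum_i[j] p_rj
    num = M.T - M  # num[r, i] = p_r . cum_i - p_i . cum_r
    w = np.outer(P.row_marginals, P.row_marginals)
    with np.errstate(invalid="ignore", divide="ignore"):
        ar = num / w
    return np.tril(ar, k=-1)


def tau_via_variance(P: ProbabilityMatrix) -> float:
    """tau expressed through the row-pair variance coefficients:
    tau = 2 sum_{i<r} p_i. p_r. ar(r:i).  Equals :func:`tau` identically."""
    ar = _pairwise_ar(P)
    w = np.outer(P.row_marginals, P.row_marginals)
    return float(2.0 * np.sum(np.tril(w * ar, k=-1)))


def rho_via_variance(P: ProbabilityMatrix) -> float:
    """rho* expressed through the row-pair variance coefficients:

    rho* = 3 sum_{i<r} (S_r + S_{r-1} - S_i - S_{i-1}) p_i. p_r. ar(r:i).
    Equals :func:`rho_star` identically.
    """
    ar = _pairwise_ar(P)
    S = P.row_cum
    g = S[1:] + S[:-1]  # S_i + S_{i-1}, 1-based i
    dist = g[:, None] - g[None, :]  # dist[r, i] = S_r + S_{r-1} - S_i - S_{i-1}
    w = np.outer(P.row_marginals, P.row_marginals)
    return float(3.0 * np.sum(np.tril(dist * w * ar, k=-1)))


def regularity_index(P: ProbabilityMatrix, tau_max: float) -> float:
    """Monotone regularity reg = tau_max / tau_abs(P) in [0, 1].

    ``tau_max`` must be the maximal tau over row/column permutations (from
    the GCA search or brute force).  Undefined for matrices with zero total
    variance (independent/constant), which raise ``ValueError``.
    """
    ta = tau_abs(P)
    if ta <= 1e-12:  # numerically zero total variance
        raise ValueError(
            "regularity index undefined: tau_abs = 0 "
            "(matrix has independent rows and columns)"
        )
    return tau_max / ta


def grade_summary(P: ProbabilityMatrix, tau_max: float | None = None) -> dict:
    """Flat record of the grade statistics of a probability matrix."""
    n, k = P.shape
    rec = {
        "rho": rho_star(P),
        "tau": tau(P),
        "tau_abs": tau_abs(P),
        "n": n,
        "k": k,
    }
    if tau_max is not None:
        try:
            rec["reg"] = regularity_index(P, tau_max)
        except ValueError:
            rec["reg"] = None
    return rec
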