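"""Independent brute-force oracles used by the test suite.

Everything here evaluates the defining sums/enumerations directly (quadruple
loops, exhaustive permutation or cut enumeration, per-block medians) and
deliberately shares no code with the package's fast implementations.
"""

import itertools

import numpy as np


def naive_rho(p):
    n, k = p.shape
    S = np.concatenate([[0.0], np.cumsum(p.sum(axis=1))])
    T = np.concatenate([[0.0], np.cumsum(p.sum(axis=0))])
    total = 0.0
    for i in range(n):
        for j in range(k):
            total += (S[i] + S[i + 1] - 1) * (T[j] + T[j + 1] - 1) * p[i, j]
    return 3.0 * total


def naive_tau(p):
    n, k = p.shape
    total = 0.0
    for r in range(1, n):
        for i in range(r):
            for s in range(1, k):
                for j in range(s):
                    total += p[i, j] * p[r, s] - p[r, j] * p[i, s]
    return 2.0 * total


def naive_tau_abs(p):
    n, k = p.shape
    total = 0.0
    for r in range(1, n):
        for i in range(r):
            for s in range(1, k):
                for j in range(s):
                    total += abs(p[i, j] * p[r, s] - p[r, j] * p[i, s])
    return 2.0 * total


def naive_ar(p, r, i):
    n, k = p.shape
    pi = p.sum(axis=1)
    total = 0.0
    for s in range(1, k):
        for j in range(s):
            total += p[i, j] * p[r, s] - p[r, j] * p[i, s]
    return total / (pi[r] * pi[i])


def exhaustive_perm_max(values, objective="rho"):
    """Global maximum of rho/tau over all row x column permutations of a raw
    nonnegative matrix; returns (best value, all values)."""
    p = values / values.sum()
    fn = naive_rho if objective == "rho" else naive_tau
    n, k = p.shape
    best = -np.inf
    vals = []
    for rp in itertools.permutations(range(n)):
        pr = p[list(rp)]
        for cp in itertools.permutations(range(k)):
            v = fn(pr[:, list(cp)])
            vals.append(v)
            best = max(best, v)
    return best, vals


def tau_of_aggregate(p, row_cuts, col_cuts):
    """tau of the block-sum table, via the naive quadruple loop."""
    r = np.add.reduceat(p, [0, *row_cuts], axis=0)
    agg = np.add.reduceat(r, [0, *col_cuts], axis=1)
    return naive_tau(agg)


def exhaustive_row_cuts(p, Kr, col_cuts, objective="tau"):
    """Best row segmentation by enumerating all C(n-1, Kr-1) cut placements."""
    n = p.shape[0]
    fn = naive_tau if objective == "tau" else naive_rho
    best_val, best_cuts = -np.inf, None
    for cuts in itertools.combinations(range(1, n), Kr - 1):
        r = np.add.reduceat(p, [0, *cuts], axis=0)
        agg = np.add.reduceat(r, [0, *col_cuts], axis=1)
        v = fn(agg)
        if v > best_val:
            best_val, best_cuts = v, cuts
    return best_cuts, best_val


def blockwise_medians(values, row_cuts, col_cuts=None):
    """Per-block medians computed cell-list by cell-list."""
    n, k = values.shape
    rbounds = [0, *row_cuts, n]
    if col_cuts is None:
        return np.array(
            [
                [
                    sorted(values[lo:hi, j])[len(values[lo:hi, j]) // 2]
                    if (hi - lo) % 2
                    else 0.5
                    * (
                        sorted(values[lo:hi, j])[(hi - lo) // 2 - 1]
                        + sorted(values[lo:hi, j])[(hi - lo) // 2]
                    )
                    for j in range(k)
                ]
                for lo, hi in zip(rbounds[:-1], rbounds[1:])
            ]
        )
    cbounds = [0, *col_cuts, k]
    out = np.empty((len(rbounds) - 1, len(cbounds) - 1))
    for a, (lo, hi) in enumerate(zip(rbounds[:-1], rbounds[1:])):
        for b, (cl, ch) in enumerate(zip(cbounds[:-1], cbounds[1:])):
            cells = sorted(values[lo:hi, cl:ch].ravel())
            m = len(cells)
            out[a, b] = cells[m // 2] if m % 2 else 0.5 * (cells[m // 2 - 1] + cells[m // 2])
    return out


def random_probability_matrix(rng, n, k):
    p = rng.random((n, k)) + 1e-3
    return p / p.sum()
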