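"""Synthetic expression matrices with known ground truth.

Two generators make every other module testable without downloads:

* :func:`generate_monotone` plants a latent monotone row/column ordering: the
  cell mean is ``exp(strength * a_i * b_j)`` for latent scores
  ``a_i = i/(n+1)``, ``b_j = j/(k+1)`` — a positive-dependence structure that
  a correct GCA run must recover after rows and columns are shuffled.
* :func:`generate_blocks` builds piecewise-constant block matrices for the
  GCCA segmentation tests.

Noise is multiplicative log-normal (``value * exp(noise * eps)``,
eps ~ N(0,1)), which keeps the matrix nonnegative and mimics the
right-skewed character of expression intensities without claiming to model
any platform's error structure.  All randomness flows through
``numpy.random.default_rng`` (PCG64), so a given seed reproduces a matrix
bit-for-bit on any platform.

The default desk-scale fixture is 32 rows x 200 columns — the shape of a
patients-by-probes expression table scaled down for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grade import DataMatrix

__all__ = ["SyntheticTruth", "generate_monotone", "generate_blocks"]

DEFAULT_N = 32
DEFAULT_K = 200


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated matrix bundled with its planted ground truth.

    ``matrix.values[true_row_order][:, true_col_order]`` restores the
    monotone (or block-ordered) arrangement the generator produced before
    shuffling.
    """

    matrix: DataMatrix
    true_row_order: np.ndarray
    true_col_order: np.ndarray
    row_blocks: np.ndarray | None = None
    col_blocks: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def unshuffled(self) -> DataMatrix:
        return self.matrix.permute(self.true_row_order, self.true_col_order)


def generate_monotone(
    n: int = DEFAULT_N,
    k: int = DEFAULT_K,
    strength: float = 6.0,
    noise: float = 0.3,
    seed: int = 0,
    shuffle: bool = True,
) -> SyntheticTruth:
    """Matrix with a planted monotone trend of given strength plus noise.

    ``strength`` scales the latent interaction (0 = independent rows and
    columns); ``noise`` is the log-normal sigma.  Rows and columns are then
    shuffled by seeded permutations recorded as the ground truth.
    """
    if n < 2 or k < 2:
        raise ValueError(f"need n, k >= 2, got {n}, {k}")
    if strength < 0 or noise < 0:
        raise ValueError("strength and noise must be nonnegative")
    rng = np.random.default_rng(seed)
    a = np.arange(1, n + 1) / (n + 1)
    b = np.arange(1, k + 1) / (k + 1)
    mean = np.exp(strength * np.outer(a, b))
    vals = mean * np.exp(noise * rng.standard_normal((n, k)))
    if shuffle:
        rperm = rng.permutation(n)
        cperm = rng.permutation(k)
    else:
        rperm = np.arange(n)
        cperm = np.arange(k)
    shuffled = vals[np.ix_(rperm, cperm)]
    m = DataMatrix(
        shuffled,
        [f"S{i}" for i in rperm],
        [f"G{j}" for j in cperm],
    )
    return SyntheticTruth(
        matrix=m,
        true_row_order=np.argsort(rperm),
        true_col_order=np.argsort(cperm),
        params={
            "n": n, "k": k, "strength": strength, "noise": noise,
            "seed": seed, "rng": "PCG64", "kind": "monotone",
        },
    )


def generate_blocks(
    row_sizes,
    col_sizes,
    block_means,
    noise: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Piecewise-constant block matrix (plus optional log-normal noise).

    ``block_means`` is a len(row_sizes) x len(col_sizes) nonnegative matrix;
    block labels (1-based, in order) are recorded as ground truth.  The
    matrix is emitted in block order (no shuffling) — segmentation tests cut
    an already-ordered matrix.
    """
    row_sizes = [int(s) for s in row_sizes]
    col_sizes = [int(s) for s in col_sizes]
    block_means = np.asarray(block_means, dtype=float)
    if block_means.shape != (len(row_sizes), len(col_sizes)):
        raise ValueError(
            f"block_means shape {block_means.shape} does not match "
            f"{len(row_sizes)} x {len(col_sizes)} blocks"
        )
    if (block_means < 0).any():
        raise ValueError("block means must be nonnegative")
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    rng = np.random.default_rng(seed)
    row_blocks = np.repeat(np.arange(1, len(row_sizes) + 1), row_sizes)
    col_blocks = np.repeat(np.arange(1, len(col_sizes) + 1), col_sizes)
    vals = block_means[np.ix_(row_blocks - 1, col_blocks - 1)].astype(float)
    if noise > 0:
        vals = vals * np.exp(noise * rng.standard_normal(vals.shape))
    n, k = vals.shape
    m = DataMatrix(vals, [f"S{i}" for i in range(n)], [f"G{j}" for j in range(k)])
    return SyntheticTruth(
        matrix=m,
        true_row_order=np.arange(n),
        true_col_order=np.arange(k),
        row_blocks=row_blocks,
        col_blocks=col_blocks,
        params={
            "row_sizes": row_sizes, "col_sizes": col_sizes, "noise": noise,
            "seed": seed, "rng": "PCG64", "kind": "blocks",
        },
    )
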