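"""Downstream case-study statistics.

Two operations sit on top of a GCCA segmentation of an expression matrix:

* :func:`differential_selection` — fold-difference gene filtering between two
  groups of row (patient) clusters: per gene the ratio of the group summary
  values (median of the member clusters' aggregated medians); genes below the
  difference-factor threshold (1.3 in the myeloma case study) are omitted.
* :func:`cluster_compatibility` — the percentage of items assigned the same
  cluster index by two clustering runs (e.g. GCA on the full matrix vs GCA on
  a CUR- or randomly-selected probe subset), per cluster and overall, with
  the complement reported as non-compatibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import AggregatedProfile

logger = logging.getLogger(__name__)

__all__ = [
    "GroupContrast",
    "ClusterAssignment",
    "DifferentialResult",
    "CompatibilityReport",
    "differential_selection",
    "cluster_compatibility",
]


@dataclass(frozen=True)
class GroupContrast:
    """Two disjoint groups of 1-based row-cluster labels and a difference
    factor threshold (>= 1)."""

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]
    threshold: float = 1.3
    summary: str = "median"  # or "mean"

    def __post_init__(self):
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b:
            raise ValueError("both groups must be non-empty")
        if a & b:
            raise ValueError(f"groups must be disjoint; shared: {sorted(a & b)}")
        if self.threshold < 1:
            raise ValueError(f"threshold must be >= 1, got {self.threshold}")
        if self.summary not in ("median", "mean"):
            raise ValueError(f"summary must be 'median' or 'mean', got {self.summary!r}")


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster label (1..K) per item identifier."""

    item_ids: tuple[str, ...]
    labels: tuple[int, ...]

    def __post_init__(self):
        if len(self.item_ids) != len(self.labels):
            raise ValueError("one label per item required")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item identifiers")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ClusterAssignment":
        items = tuple(mapping)
        return cls(items, tuple(int(mapping[i]) for i in items))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.item_ids, self.labels))


@dataclass(frozen=True)
class DifferentialResult:
    """Selected genes with their difference factors and directions.

    ``records`` holds (gene_id, ratio, direction) with direction "UP" when
    group A exceeds group B; ``excluded`` holds (gene_id, reason) for genes
    that could not be ratio-tested (nonpositive summary value).
    """

    records: tuple[tuple[str, float, str], ...]
    excluded: tuple[tuple[str, str], ...] = ()
    contrast: GroupContrast | None = None

    def gene_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=["gene", "ratio", "direction"])


def differential_selection(
    profiles: AggregatedProfile, contrast: GroupContrast
) -> DifferentialResult:
    """Select genes whose group-summary expression differs by at least the
    contrast's difference factor.

    ``profiles`` is the per-row-cluster median table (Kr x genes).  For each
    gene, a = summary over the group A clusters, b = over group B,
    ratio = max(a/b, b/a); genes with ratio >= threshold are kept (the
    boundary value survives: only ratios strictly below the factor are
    omitted), labelled UP when a > b and DOWN when a < b.  Genes with a
    nonpositive group summary are excluded with a logged reason.
    """
    Kr = profiles.values.shape[0]
    for lab in (*contrast.group_a, *contrast.group_b):
        if not 1 <= lab <= Kr:
            raise ValueError(f"cluster label {lab} outside 1..{Kr}")
    summ = np.median if contrast.summary == "median" else np.mean
    ia = [l - 1 for l in contrast.group_a]
    ib = [l - 1 for l in contrast.group_b]
    a = summ(profiles.values[ia], axis=0)
    b = summ(profiles.values[ib], axis=0)
    gene_ids = profiles.col_labels or [str(j) for j in range(profiles.values.shape[1])]

    records = []
    excluded = []
    for gid, av, bv in zip(gene_ids, a, b):
        if av <= 0 or bv <= 0:
            reason = f"nonpositive group summary (a={av:g}, b={bv:g})"
            logger.warning("differential_selection: excluding %s: %s", gid, reason)
            excluded.append((gid, reason))
            continue
        ratio = max(av / bv, bv / av)
        # equal summaries carry no direction and are never selected
        if ratio >= contrast.threshold and av != bv:
            records.append((gid, float(ratio), "UP" if av > bv else "DOWN"))
    return DifferentialResult(tuple(records), tuple(excluded), contrast)


@dataclass(frozen=True)
class CompatibilityReport:
    """Agreement between two cluster assignments, in percent."""

    overall: float
    per_cluster: dict = field(default_factory=dict)
    n_items: int = 0

    @property
    def non_compatible(self) -> float:
        return 100.0 - self.overall

    def to_dict(self) -> dict:
        return {
            "overall_compatible_pct": self.overall,
            "overall_non_compatible_pct": self.non_compatible,
            "per_cluster": {
                str(c): {"compatible_pct": v, "non_compatible_pct": 100.0 - v}
                for c, v in self.per_cluster.items()
            },
            "n_items": self.n_items,
        }


def cluster_compatibility(
    a: ClusterAssignment,
    b: ClusterAssignment,
    clusters=None,
    best_match: bool = False,
) -> CompatibilityReport:
    """Percentage of items receiving the same cluster index in both runs.

    Both assignments must cover the same item set; a mismatch is rejected
    listing the symmetric difference.  With ``clusters`` given, the
    comparison is restricted to items carrying one of those labels in either
    run (a symmetric restriction, so compatibility(a, b) == compatibility(b,
    a)).  ``best_match=True`` relabels ``b`` by the Hungarian assignment on
    the confusion matrix before comparing — useful when the two runs'
    contiguous indices are not aligned; the default compares raw indices, as
    both runs' labels already share the leftmost/topmost = 1 convention.
    """
    da, db = a.as_dict(), b.as_dict()
    if set(da) != set(db):
        diff = sorted(set(da) ^ set(db))
        raise ValueError(f"assignments cover different items; difference: {diff}")
    items = list(da)
    la = np.array([da[i] for i in items])
    lb = np.array([db[i] for i in items])

    if best_match:
        from scipy.optimize import linear_sum_assignment

        labs = sorted(set(la) | set(lb))
        idx = {l: i for i, l in enumerate(labs)}
        conf = np.zeros((len(labs), len(labs)))
        for x, y in zip(la, lb):
            conf[idx[x], idx[y]] += 1
        ri, ci = linear_sum_assignment(-conf)
        remap = {labs[c]: labs[r] for r, c in zip(ri, ci)}
        lb = np.array([remap[l] for l in lb])

    if clusters is not None:
        wanted = set(int(c) for c in clusters)
        keep = np.array([x in wanted or y in wanted for x, y in zip(la, lb)])
        la, lb = la[keep], lb[keep]
        items = [i for i, k in zip(items, keep) if k]
    if len(la) == 0:
        raise ValueError("no items in the requested clusters")

    match = la == lb
    overall = 100.0 * match.mean()
    per_cluster = {}
    for c in sorted(set(la) | set(lb)):
        mask = (la == c) | (lb == c)
        per_cluster[int(c)] = float(100.0 * match[mask].mean())
    return CompatibilityReport(float(overall), per_cluster, int(len(la)))
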