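"""Cluster-set comparisons: background subtraction, overlap matrices,
and site-in-cluster percentages.

Background subtraction removes, whole, any target cluster that shares at
least one base pair with a background cluster (clusters called from all
annotated genes, i.e. the genome's inherent gene clumping). The overlap
matrix counts overlapping cluster pairs between labeled sets, with the
diagonal holding each set's cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import SiteSet
from .scan import Cluster, ClusterSet

__all__ = [
    "clusters_overlap",
    "subtract_background",
    "overlap_matrix",
    "percent_in_clusters",
    "SubtractionResult",
    "OverlapMatrix",
]


def _overlap_len(a: Cluster, b: Cluster) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def clusters_overlap(a: Cluster, b: Cluster, min_reciprocal_overlap: float = 0.0) -> bool:
    """True iff the clusters share >=1 bp on the same chromosome.

    ``min_reciprocal_overlap`` optionally requires the shared length to be
    at least that fraction of *both* cluster lengths (0 disables, the
    default: any 1 bp overlap counts). Half-open abutment is not overlap.
    """
    ov = _overlap_len(a, b)
    if ov <= 0:
        return False
    if min_reciprocal_overlap > 0:
        if ov < min_reciprocal_overlap * (a.end - a.start):
            return False
        if ov < min_reciprocal_overlap * (b.end - b.start):
            return False
    return True


def _trees(cs: ClusterSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for c in cs:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c)
    return trees


@dataclass
class SubtractionResult:
    """Outcome of removing background-overlapping clusters, whole."""

    retained: ClusterSet
    removed: ClusterSet
    n_input: int
    n_removed: int
    n_retained: int


def subtract_background(
    target: ClusterSet,
    background: ClusterSet,
    min_reciprocal_overlap: float = 0.0,
) -> SubtractionResult:
    """Partition target clusters by >=1 bp overlap with any background cluster.

    Overlapping clusters are removed whole (never trimmed); the rest are
    retained unchanged. Idempotent: retained clusters never overlap the
    background, so subtracting again is a no-op.
    """
    trees = _trees(background)
    retained: list[Cluster] = []
    removed: list[Cluster] = []
    for c in target:
        hits = trees[c.chrom].overlap(c.start, c.end) if c.chrom in trees else ()
        hit = any(
            clusters_overlap(c, iv.data, min_reciprocal_overlap) for iv in hits
        )
        (removed if hit else retained).append(c)
    mk = lambda cl, suffix: ClusterSet(
        label=f"{target.label}{suffix}",
        source_site_label=target.source_site_label,
        clusters=cl,
        params=target.params,
        genome=target.genome,
    )
    return SubtractionResult(
        retained=mk(retained, "_minus_bkg"),
        removed=mk(removed, "_in_bkg"),
        n_input=len(target),
        n_removed=len(removed),
        n_retained=len(retained),
    )


@dataclass
class OverlapMatrix:
    """Pairwise cluster-overlap counts between labeled sets.

    Off-diagonal (i, j) counts overlapping cluster pairs between sets i
    and j (each pair once, so the matrix is symmetric); diagonal (i, i)
    is the cluster count of set i.
    """

    labels: list[str]
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def overlap_matrix(
    sets: list[ClusterSet], min_reciprocal_overlap: float = 0.0
) -> OverlapMatrix:
    """Count overlapping cluster pairs for every pair of sets."""
    if not sets:
        raise ValueError("need at least one ClusterSet")
    n = len(sets)
    counts = np.zeros((n, n), dtype=np.int64)
    trees = [_trees(s) for s in sets]
    for i in range(n):
        counts[i, i] = len(sets[i])
        for j in range(i + 1, n):
            c = 0
            for a in sets[i]:
                if a.chrom not in trees[j]:
                    continue
                for iv in trees[j][a.chrom].overlap(a.start, a.end):
                    if clusters_overlap(a, iv.data, min_reciprocal_overlap):
                        c += 1
            counts[i, j] = counts[j, i] = c
    return OverlapMatrix(labels=[s.label for s in sets], counts=counts)


def percent_in_clusters(sites: SiteSet, clusters: ClusterSet) -> tuple[int, float]:
    """Number and percentage of site points falling inside any cluster span.

    Returns the unrounded percentage; summaries round it to the nearest
    integer (half away from zero) for presentation.
    """
    if len(sites) == 0:
        raise ValueError("percentage undefined for an empty SiteSet")
    spans: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        spans.setdefault(c.chrom, []).append((c.start, c.end))
    n_in = 0
    for s in sites:
        for start, end in spans.get(s.chrom, ()):
            if start <= s.point < end:
                n_in += 1
                break
    return n_in, 100.0 * n_in / len(sites)
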