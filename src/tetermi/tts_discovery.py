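"""Transcription termination site (TTS) calling from PET 3' ends.

A TTS is a strand-specific cluster of mapped PET 3'-end bases.  Two 3' ends
on the same chromosome and strand belong to the same cluster when they
overlap or are separated by at most ``max_gap`` intervening bases (default
20).  Clusters are kept when their depth, normalized to tags per 10 million
mapped, reaches ``min_norm`` (default 20) in at least one cell type; the
cluster's peak is the base with the highest density of mapped 3' ends.
Clusters called independently per cell type are merged into one TTS when
they reciprocally overlap by at least ``min_reciprocal_overlap`` of both
cluster lengths (default 80%), taking the transitive closure across cell
types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import GenomicInterval

__all__ = [
    "TTSCluster",
    "cluster_3prime_ends",
    "cluster_end_array",
    "normalize_count",
    "attach_norm_counts",
    "filter_clusters",
    "peak_base",
    "merge_across_celltypes",
]


@dataclass
class TTSCluster:
    """A strand-specific cluster of PET 3' ends.

    ``member_bases``/``member_counts`` form the per-base 3'-end histogram
    (sorted unique bases with pooled counts across cell types).
    """

    interval: GenomicInterval
    peak: int
    member_bases: np.ndarray
    member_counts: np.ndarray
    counts_by_celltype: dict[str, int]
    norm_counts_by_celltype: dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return int(sum(self.counts_by_celltype.values()))

    def max_norm(self) -> float:
        return max(self.norm_counts_by_celltype.values(), default=0.0)


def normalize_count(raw: float, library_size: int) -> float:
    """Tag count per 10 million mapped tags: ``raw * 1e7 / library_size``."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return raw * 1e7 / library_size


def peak_base(cluster: TTSCluster) -> int:
    """The base with the highest 3'-end density; ties go to the smallest coordinate."""
    if cluster.member_bases.size == 0:
        raise ValueError("empty cluster histogram")
    return int(cluster.member_bases[int(np.argmax(cluster.member_counts))])


def _clusters_from_sorted(
    chrom: str,
    strand: str,
    bases: np.ndarray,
    counts: np.ndarray,
    max_gap: int,
    celltype: str,
) -> list[TTSCluster]:
    """Split sorted unique (bases, counts) at gaps of more than max_gap bases."""
    # adjacent bases p < q are linked iff q - p - 1 <= max_gap
    breaks = np.nonzero(np.diff(bases) > max_gap + 1)[0] + 1
    out: list[TTSCluster] = []
    for seg_b, seg_c in zip(np.split(bases, breaks), np.split(counts, breaks)):
        peak = int(seg_b[int(np.argmax(seg_c))])
        out.append(
            TTSCluster(
                interval=GenomicInterval(chrom, int(seg_b[0]), int(seg_b[-1]) + 1, strand),
                peak=peak,
                member_bases=seg_b,
                member_counts=seg_c,
                counts_by_celltype={celltype: int(seg_c.sum())},
            )
        )
    return out


def cluster_end_array(
    chrom: str,
    strand: str,
    bases: np.ndarray,
    max_gap: int = 20,
    celltype: str = "default",
) -> list[TTSCluster]:
    """Cluster a flat array of 3'-end bases from one chromosome/strand/cell type."""
    if bases.size == 0:
        return []
    uniq, counts = np.unique(np.asarray(bases, dtype=np.int64), return_counts=True)
    return _clusters_from_sorted(chrom, strand, uniq, counts, max_gap, celltype)


def cluster_3prime_ends(
    ends: Iterable[tuple[str, int, str]],
    max_gap: int = 20,
    celltype: str = "default",
) -> list[TTSCluster]:
    """Single-linkage clustering of (chrom, base, strand) 3' ends from one cell type.

    Clusters partition the input; each cluster's interval spans its minimum to
    maximum member base.  Clustering is strand-specific: the same base on
    opposite strands yields two clusters.
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for chrom, base, strand in ends:
        by_key.setdefault((chrom, strand), []).append(base)
    out: list[TTSCluster] = []
    for (chrom, strand) in sorted(by_key):
        out.extend(
            cluster_end_array(
                chrom, strand, np.asarray(by_key[(chrom, strand)]), max_gap, celltype
            )
        )
    return out


def attach_norm_counts(
    clusters: Sequence[TTSCluster], library_sizes: Mapping[str, int]
) -> None:
    """Fill ``norm_counts_by_celltype`` (tags per 10M mapped) in place."""
    for cl in clusters:
        cl.norm_counts_by_celltype = {
            ct: normalize_count(raw, library_sizes[ct])
            for ct, raw in cl.counts_by_celltype.items()
        }


def filter_clusters(
    clusters: Sequence[TTSCluster], min_norm: float = 20.0
) -> list[TTSCluster]:
    """Keep clusters whose normalized count reaches ``min_norm`` in >=1 cell type."""
    return [cl for cl in clusters if cl.max_norm() >= min_norm]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _linked(a: TTSCluster, b: TTSCluster, frac: float, reciprocal: bool) -> bool:
    ov = a.interval.overlap(b.interval)
    if ov <= 0:
        return False
    if reciprocal:
        return ov >= frac * len(a.interval) and ov >= frac * len(b.interval)
    return ov >= frac * min(len(a.interval), len(b.interval))


def merge_across_celltypes(
    per_celltype_clusters: Mapping[str, Sequence[TTSCluster]],
    min_reciprocal_overlap: float = 0.8,
    reciprocal: bool = True,
    return_components: bool = False,
):
    """Merge per-cell-type clusters that overlap by >=80% into single TTS.

    Same-strand clusters from different cell types are linked when their
    overlap reaches ``min_reciprocal_overlap`` of both cluster lengths
    (``reciprocal=False`` relaxes this to the shorter of the two); connected
    components under this relation become one merged TTS whose interval is
    the union span, whose histogram is the sum of member histograms, and
    whose peak is recomputed from the pooled histogram.  Per-cell-type counts
    are preserved.

    With ``return_components=True`` also returns, per cell type, the mapping
    from input cluster index to merged cluster index.
    """
    flat: list[TTSCluster] = []
    owner: list[tuple[str, int]] = []  # (celltype, index within that cell type)
    for ct in sorted(per_celltype_clusters):
        for i, cl in enumerate(per_celltype_clusters[ct]):
            flat.append(cl)
            owner.append((ct, i))
    uf = _UnionFind(len(flat))

    by_group: dict[tuple[str, str], list[int]] = {}
    for idx, cl in enumerate(flat):
        by_group.setdefault((cl.interval.chrom, cl.interval.strand), []).append(idx)
    for idxs in by_group.values():
        idxs.sort(key=lambda i: (flat[i].interval.start, flat[i].interval.end))
        for a_pos, i in enumerate(idxs):
            a = flat[i]
            for j in idxs[a_pos + 1:]:
                b = flat[j]
                if b.interval.start >= a.interval.end:
                    break
                if _linked(a, b, min_reciprocal_overlap, reciprocal):
                    uf.union(i, j)

    components: dict[int, list[int]] = {}
    for idx in range(len(flat)):
        components.setdefault(uf.find(idx), []).append(idx)

    merged: list[TTSCluster] = []
    comp_of_flat: dict[int, int] = {}
    for root in sorted(
        components,
        key=lambda r: (
            flat[r].interval.chrom,
            min(flat[i].interval.start for i in components[r]),
            flat[r].interval.strand,
        ),
    ):
        members = [flat[i] for i in components[root]]
        all_b = np.concatenate([m.member_bases for m in members])
        all_c = np.concatenate([m.member_counts for m in members])
        uniq, inv = np.unique(all_b, return_inverse=True)
        pooled = np.bincount(inv, weights=all_c).astype(np.int64)
        counts: dict[str, int] = {}
        norms: dict[str, float] = {}
        for m in members:
            for ct, raw in m.counts_by_celltype.items():
                counts[ct] = counts.get(ct, 0) + raw
            for ct, nv in m.norm_counts_by_celltype.items():
                norms[ct] = norms.get(ct, 0.0) + nv
        first = members[0]
        mc = TTSCluster(
            interval=GenomicInterval(
                first.interval.chrom,
                int(uniq[0]),
                int(uniq[-1]) + 1,
                first.interval.strand,
            ),
            peak=int(uniq[int(np.argmax(pooled))]),
            member_bases=uniq,
            member_counts=pooled,
            counts_by_celltype=counts,
            norm_counts_by_celltype=norms,
        )
        for i in components[root]:
            comp_of_flat[i] = len(merged)
        merged.append(mc)

    if not return_components:
        return merged
    index_maps: dict[str, dict[int, int]] = {ct: {} for ct in per_celltype_clusters}
    for flat_idx, (ct, i) in enumerate(owner):
        index_maps[ct][i] = comp_of_flat[flat_idx]
    return merged, index_maps
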