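"""Associate TTS clusters with genes and classify their location in the locus.

A cluster is tied to a gene through the linked 5' ends of its member
ditags: the gene wins when a plurality of member 5' points fall within
``promoter_halfwidth`` of its annotated TSS and the cluster lies within the
gene locus or at most ``downstream_limit`` bases past the annotated TTS in
the direction of transcription.  Associated TTS are then classified as
annotated (coinciding with the gene's annotated terminator), downstream,
5'-UTR, 3'-UTR or internal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import TE_FAMILIES, DitagRecord, GeneModel
from .tts_discovery import TTSCluster

__all__ = [
    "LOCATION_CLASSES",
    "TTSRecord",
    "associate_with_gene",
    "classify_location",
    "summarize_location_table",
    "location_table_shares",
]

LOCATION_CLASSES = (
    "five_prime_utr",
    "internal",
    "three_prime_utr",
    "annotated",
    "downstream",
)


@dataclass
class TTSRecord:
    """A TTS cluster joined to its host gene, location class and (optional) TE."""

    cluster: TTSCluster
    gene: str
    location_class: str
    te: str | None = None
    te_family: str | None = None
    te_orientation: str | None = None  # "sense" | "antisense"
    consensus_position: int | None = None
    ambiguous_promoter: bool = False
    name: str = ""

    @property
    def peak(self) -> int:
        return self.cluster.peak


def _direction(strand: str) -> int:
    return 1 if strand == "+" else -1


def _cluster_in_gene(
    cluster: TTSCluster, gene: GeneModel, downstream_limit: int
) -> bool:
    """Peak within the gene locus or <= downstream_limit past the annotated TTS."""
    peak = cluster.peak
    if cluster.interval.chrom != gene.locus.chrom:
        return False
    if gene.locus.contains(peak):
        return True
    d = (peak - gene.annotated_tts) * _direction(gene.strand)
    return 0 < d <= downstream_limit


def associate_with_gene(
    cluster: TTSCluster,
    ditags: Iterable[DitagRecord],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 500,
    downstream_limit: int = 5000,
) -> str | None:
    """Pick the host gene for a cluster from its member ditags' 5' points.

    A ditag is a member when its 3' point lies in the cluster interval on the
    cluster strand.  Each member votes for every gene whose annotated TSS is
    within ``promoter_halfwidth`` of its 5' point and which can contain the
    cluster; the gene with the most votes wins, ties broken toward the
    nearest TSS.  Returns ``None`` when no gene qualifies.
    """
    iv = cluster.interval
    candidates = [
        g
        for g in genes
        if g.locus.chrom == iv.chrom
        and g.strand == iv.strand
        and _cluster_in_gene(cluster, g, downstream_limit)
    ]
    if not candidates:
        return None
    votes: dict[str, int] = {}
    dist: dict[str, list[int]] = {}
    for d in ditags:
        c3, b3, s3 = d.three_prime
        if c3 != iv.chrom or s3 != iv.strand or not iv.contains(b3):
            continue
        c5, b5, _ = d.five_prime
        for g in candidates:
            dd = abs(b5 - g.annotated_tss)
            if c5 == g.locus.chrom and dd <= promoter_halfwidth:
                votes[g.id] = votes.get(g.id, 0) + 1
                dist.setdefault(g.id, []).append(dd)
    if not votes:
        return None
    best = min(votes, key=lambda gid: (-votes[gid], min(dist[gid]), gid))
    return best


def classify_location(
    tts_peak: int,
    gene: GeneModel,
    annotated_tts_set: Iterable[int] | None = None,
    cluster_interval=None,
    downstream_limit: int = 5000,
) -> str:
    """Classify a gene-associated TTS peak within its host locus.

    Precedence: *annotated* when the cluster overlaps an annotated terminator
    (any position in ``annotated_tts_set``, default the gene's annotated TTS);
    *downstream* when the peak is strictly past the annotated TTS by at most
    ``downstream_limit`` bases; *three_prime_utr*/*five_prime_utr* when the
    peak falls in an exonic UTR position (UTR extents come from the CDS
    bounds; genes without a CDS have no UTR classes); *internal* otherwise
    (introns and CDS exons).  Classification respects gene strand.
    """
    tts_set = set(annotated_tts_set) if annotated_tts_set is not None else {gene.annotated_tts}
    sgn = _direction(gene.strand)

    for t in tts_set:
        if cluster_interval is not None and cluster_interval.contains(t):
            return "annotated"
        if tts_peak == t:
            return "annotated"

    d_past = (tts_peak - gene.annotated_tts) * sgn
    if d_past > 0:
        if d_past <= downstream_limit:
            return "downstream"
        raise ValueError(
            f"peak {tts_peak} is {d_past} bases past the annotated TTS of {gene.id} "
            f"(limit {downstream_limit})"
        )
    if not gene.locus.contains(tts_peak):
        raise ValueError(f"peak {tts_peak} upstream of gene {gene.id}")

    in_exon = any(s <= tts_peak < e for s, e in gene.exon_blocks)
    if gene.cds is not None and in_exon:
        cs, ce = gene.cds
        if gene.strand == "+":
            if tts_peak >= ce:
                return "three_prime_utr"
            if tts_peak < cs:
                return "five_prime_utr"
        else:
            if tts_peak < cs:
                return "three_prime_utr"
            if tts_peak >= ce:
                return "five_prime_utr"
    return "internal"


_ROW_ORDER = list(LOCATION_CLASSES)
_COL_ORDER = ["non_te", "all_te", *TE_FAMILIES]


def summarize_location_table(records: Iterable[TTSRecord]) -> pd.DataFrame:
    """Count TTS by location class and TE family (plus non-TE and all-TE columns)."""
    counts = pd.DataFrame(0, index=_ROW_ORDER + ["sum"], columns=_COL_ORDER, dtype=int)
    for rec in records:
        row = rec.location_class
        if rec.te is None:
            counts.loc[row, "non_te"] += 1
            counts.loc["sum", "non_te"] += 1
        else:
            counts.loc[row, "all_te"] += 1
            counts.loc["sum", "all_te"] += 1
            fam = rec.te_family if rec.te_family in TE_FAMILIES else None
            if fam is not None:
                counts.loc[row, fam] += 1
                counts.loc["sum", fam] += 1
    return counts


def location_table_shares(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Family shares and per-column alternative-TTS fractions of a location table.

    The family share of a row is the family count divided by the sum of the
    eight named family counts in that row, as a percentage truncated to an
    integer.  The alternative fraction of a column is
    ``(total - annotated) / total`` (returned as a float proportion).
    """
    fam_cols = [c for c in counts.columns if c in TE_FAMILIES]
    row_sums = counts[fam_cols].sum(axis=1)
    shares = pd.DataFrame(0, index=counts.index, columns=fam_cols, dtype=int)
    for row in counts.index:
        denom = row_sums[row]
        if denom > 0:
            shares.loc[row] = (counts.loc[row, fam_cols] * 100 // denom).astype(int)
    body = counts.drop(index="sum", errors="ignore")
    totals = body.sum(axis=0)
    alt = pd.Series(np.nan, index=counts.columns, dtype=float)
    nz = totals > 0
    alt[nz] = (totals[nz] - body.loc["annotated", nz]) / totals[nz]
    return shares, alt
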