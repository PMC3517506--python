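"""Averaged ChIP-seq tag metaprofiles around anchor sets.

For each anchor the tags within ``halfwidth`` bases are binned by signed
offset (orientation flipped for minus-strand anchors so that downstream is
always positive), counts are normalized to tags per million mapped, and the
per-bin values are averaged over anchors.  Anchor sets of interest are the
TE-derived TTS, the non-TE TTS and the intragenic TE insertions that provide
no TTS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import GeneModel, TEAnnotation
from .gene_annotation import TTSRecord

__all__ = ["Metaprofile", "metaprofile", "stratify_anchors"]


@dataclass
class Metaprofile:
    """Mean normalized tag counts in fixed bins at signed offsets from anchors."""

    bin_offsets: np.ndarray  # left edge of each bin, relative to the anchor
    mean_norm_count: np.ndarray  # tags per million mapped, averaged over anchors
    n_anchors: int
    bin_size: int
    halfwidth: int


def _tags_by_chrom(tags: Iterable[tuple[str, int]] | Mapping[str, np.ndarray]):
    if isinstance(tags, Mapping):
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tags.items()}
    by: dict[str, list[int]] = {}
    for chrom, base in tags:
        by.setdefault(chrom, []).append(base)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by.items()}


def metaprofile(
    anchors: Sequence[tuple[str, int, str]],
    tags,
    library_size: int,
    halfwidth: int = 5000,
    bin_size: int = 10,
) -> Metaprofile:
    """Average normalized ChIP tag density in ``bin_size``-base windows around anchors.

    ``anchors`` are (chrom, base, strand) triples; ``tags`` either an iterable
    of (chrom, base) points or a mapping chrom -> position array.  Offsets run
    over ``[-halfwidth, halfwidth)``; for minus-strand anchors the offset of a
    tag at t from anchor a is ``a - t``, so profiles are oriented by
    transcription.  Counts are scaled by ``1e6 / library_size`` before
    averaging over anchors (mean across anchors, not pooled).
    """
    if not anchors:
        raise ValueError("anchor set is empty")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if 2 * halfwidth % bin_size:
        raise ValueError("bin_size must divide 2*halfwidth")
    by_chrom = _tags_by_chrom(tags)
    n_bins = 2 * halfwidth // bin_size
    acc = np.zeros(n_bins, dtype=float)
    for chrom, base, strand in anchors:
        arr = by_chrom.get(chrom)
        if arr is None or arr.size == 0:
            continue
        lo = np.searchsorted(arr, base - halfwidth - 1, side="left")
        hi = np.searchsorted(arr, base + halfwidth + 1, side="right")
        window = arr[lo:hi]
        off = (window - base) if strand == "+" else (base - window)
        off = off[(off >= -halfwidth) & (off < halfwidth)]
        if off.size:
            acc += np.bincount((off + halfwidth) // bin_size, minlength=n_bins)
    mean = acc * (1e6 / library_size) / len(anchors)
    offsets = np.arange(n_bins) * bin_size - halfwidth
    return Metaprofile(
        bin_offsets=offsets,
        mean_norm_count=mean,
        n_anchors=len(anchors),
        bin_size=bin_size,
        halfwidth=halfwidth,
    )


def stratify_anchors(
    tts_records: Iterable[TTSRecord],
    te_annotations: Sequence[TEAnnotation],
    genes: Sequence[GeneModel],
) -> dict[str, list[tuple[str, int, str]]]:
    """Split anchors into TE-TTS, non-TE-TTS and non-TTS intragenic TE sets.

    TTS anchors are cluster peaks oriented by the cluster strand; the anchor
    for a TE without a TTS is the element midpoint oriented by its host
    gene's strand.  The three sets are disjoint by construction.
    """
    te_tts: list[tuple[str, int, str]] = []
    non_te_tts: list[tuple[str, int, str]] = []
    tes_used: set[str] = set()
    for rec in tts_records:
        anchor = (rec.cluster.interval.chrom, rec.peak, rec.cluster.interval.strand)
        if rec.te is not None:
            te_tts.append(anchor)
            tes_used.add(rec.te)
        else:
            non_te_tts.append(anchor)

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.locus.chrom, []).append(g)
    non_tts_te: list[tuple[str, int, str]] = []
    for te in te_annotations:
        if te.id in tes_used:
            continue
        host = next(
            (
                g
                for g in genes_by_chrom.get(te.span.chrom, [])
                if g.locus.start <= te.span.start and te.span.end <= g.locus.end
            ),
            None,
        )
        if host is None:
            continue  # not intragenic
        mid = (te.span.start + te.span.end) // 2
        non_tts_te.append((te.span.chrom, mid, host.strand))
    return {"te_tts": te_tts, "non_te_tts": non_te_tts, "non_tts_te": non_tts_te}
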