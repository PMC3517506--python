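"""Decide which TTS are TE-derived and map them onto element consensus coordinates.

A TTS is TE-derived when its peak base lies at least ``min_into_te`` bases
(default 50, reflecting the distance between a polyadenylation signal and
the actual cleavage site) past the start of a TE insertion and less than
``max_past_end`` bases (default 15) past its end.  "Start" and "end" are
taken in the host gene's transcription direction by default, so an antisense
insertion's start is its genomic right edge for a plus-strand gene; a purely
genomic reading is available via ``coordinate_mode="genomic"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats_io import GeneModel, TEAnnotation

__all__ = [
    "ConsensusHit",
    "assign_te",
    "relative_orientation",
    "map_to_consensus",
    "consensus_density",
]


@dataclass(frozen=True)
class ConsensusHit:
    """A TTS peak mapped into a TE subfamily consensus sequence (1-based)."""

    te_id: str
    subfamily: str
    consensus_position: int
    consensus_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.consensus_position <= self.consensus_length):
            raise ValueError(
                f"consensus position {self.consensus_position} outside "
                f"[1, {self.consensus_length}]"
            )


def _te_ends_in_direction(te: TEAnnotation, gene_strand: str, mode: str) -> tuple[int, int, int]:
    """(first base, last base, direction sign) of the TE span for the 50/15 rule."""
    s, e = te.span.start, te.span.end
    if mode == "genomic" or gene_strand == "+":
        return s, e - 1, 1
    return e - 1, s, -1


def assign_te(
    peak: int,
    tes: Sequence[TEAnnotation],
    gene_strand: str = "+",
    min_into_te: int = 50,
    max_past_end: int = 15,
    coordinate_mode: str = "transcription",
) -> TEAnnotation | None:
    """Return the TE providing this TTS peak, or None.

    A TE qualifies when, measured in the host gene's transcription direction
    (or left-to-right for ``coordinate_mode="genomic"``), the peak is at
    least ``min_into_te`` bases past the element's first base and less than
    ``max_past_end`` bases past its last base.  When several TEs qualify, the
    one whose end is nearest the peak wins; the result is deterministic and
    independent of the order of ``tes``.
    """
    if coordinate_mode not in ("transcription", "genomic"):
        raise ValueError(f"unknown coordinate_mode {coordinate_mode!r}")
    best: tuple[int, int, str] | None = None
    best_te: TEAnnotation | None = None
    for te in tes:
        first, last, sgn = _te_ends_in_direction(te, gene_strand, coordinate_mode)
        into = (peak - first) * sgn
        past = (peak - last) * sgn
        if into >= min_into_te and past < max_past_end:
            key = (abs(peak - last), te.span.start, te.id)
            if best is None or key < best:
                best = key
                best_te = te
    return best_te


def relative_orientation(te: TEAnnotation, gene: GeneModel) -> str:
    """'sense' when the TE strand matches the host gene strand, else 'antisense'."""
    return "sense" if te.span.strand == gene.strand else "antisense"


def map_to_consensus(peak: int, te: TEAnnotation) -> ConsensusHit:
    """Map a genomic TTS peak to its position in the element consensus.

    The RepeatMasker alignment is treated as gapless (linear offset; the
    ``.out`` file carries no indel structure): for a plus-strand TE the
    consensus position is ``consensus_begin + (peak - span.start)``; for a
    minus-strand TE it is ``consensus_end - (peak - span.start)``.  Positions
    falling past either aligned consensus edge (for example peaks up to 15 bp
    past the element end) clamp to that edge.
    """
    offset = peak - te.span.start
    if te.span.strand == "+":
        pos = te.consensus_begin + offset
    else:
        pos = te.consensus_end - offset
    pos = min(max(pos, te.consensus_begin), te.consensus_end)
    return ConsensusHit(
        te_id=te.id,
        subfamily=te.subfamily,
        consensus_position=int(pos),
        consensus_length=te.consensus_length,
    )


def consensus_density(
    hits: Iterable[ConsensusHit],
    subfamily: str | None = None,
    bin: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized density of TTS positions along a subfamily consensus.

    Returns ``(bin_starts, density)`` where ``bin_starts`` are the 1-based
    left edges of ``bin``-base windows covering the consensus and ``density``
    sums to 1.
    """
    hits = [h for h in hits if subfamily is None or h.subfamily == subfamily]
    if not hits:
        raise ValueError("no consensus hits to bin")
    length = max(h.consensus_length for h in hits)
    n_bins = (length + bin - 1) // bin
    dens = np.zeros(n_bins, dtype=float)
    for h in hits:
        dens[(h.consensus_position - 1) // bin] += 1
    dens /= dens.sum()
    starts = np.arange(n_bins) * bin + 1
    return starts, dens
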