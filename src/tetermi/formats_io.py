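"""Readers and writers for the genomic text formats the pipeline touches.

All coordinates are normalized at the boundary to a single internal
convention: 0-based, half-open intervals; point features (tag ends, cluster
peaks) are stored as the 0-based index of the base itself.  RepeatMasker
``.out`` files (1-based, inclusive, with 'C' for the reverse strand) and any
other 1-based inputs are converted on read and restored on write.

Formats handled: BED6 (ChIP tag points), BED12 (gene models with exon block
structure and CDS extent), BEDPE (paired-end ditags, 5' point first),
RepeatMasker ``.out``, a BED6+1 dialect for TTS clusters, and a tab-separated
ground-truth sidecar used by the synthetic-data generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "DitagRecord",
    "GeneModel",
    "TEAnnotation",
    "TE_FAMILIES",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_ditags_bedpe",
    "write_ditags_bedpe",
    "read_genes_bed12",
    "write_genes_bed12",
    "read_chip_bed",
    "write_chip_bed",
    "write_tts_bed",
    "read_tts_bed",
]

#: The eight named TE families summarized throughout, plus a catch-all.
TE_FAMILIES = ("Alu", "ERV", "hAT", "L1", "L2", "MaLR", "MIR", "TcMar")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, base: int) -> bool:
        return self.start <= base < self.end


@dataclass(frozen=True)
class DitagRecord:
    """One paired-end ditag: the linked 5' and 3' end points of one mRNA.

    Each point is a (chrom, base, strand) triple.  A usable ditag has both
    points on the same chromosome and strand; others are flagged
    ``inter_locus`` and retained rather than silently dropped.
    """

    five_prime: tuple[str, int, str]
    three_prime: tuple[str, int, str]
    celltype: str = ""

    @property
    def inter_locus(self) -> bool:
        return (
            self.five_prime[0] != self.three_prime[0]
            or self.five_prime[2] != self.three_prime[2]
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with exon block structure and optional CDS extent.

    ``annotated_tss``/``annotated_tts`` are the transcribed first/last base
    (0-based), which sit at the strand-appropriate ends of the locus.
    """

    id: str
    locus: GenomicInterval
    exon_blocks: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        prev_end = self.locus.start - 1
        for s, e in self.exon_blocks:
            if not (self.locus.start <= s < e <= self.locus.end):
                raise ValueError(f"gene {self.id}: exon ({s},{e}) outside locus")
            if s <= prev_end:
                raise ValueError(f"gene {self.id}: exons unsorted or overlapping")
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.locus.start <= cs < ce <= self.locus.end):
                raise ValueError(f"gene {self.id}: CDS outside locus")

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def annotated_tss(self) -> int:
        return self.locus.start if self.strand == "+" else self.locus.end - 1

    @property
    def annotated_tts(self) -> int:
        return self.locus.end - 1 if self.strand == "+" else self.locus.start


@dataclass(frozen=True)
class TEAnnotation:
    """A RepeatMasker repeat interval with consensus alignment coordinates.

    ``consensus_begin``/``consensus_end`` are 1-based positions within the
    element's consensus sequence.  The genomic span may differ in length from
    the aligned consensus stretch because of indels; the discrepancy is
    recorded as ``indel_tolerance`` rather than assumed zero.
    """

    id: str
    span: GenomicInterval
    family: str
    subfamily: str
    consensus_begin: int
    consensus_end: int
    consensus_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.consensus_begin <= self.consensus_end <= self.consensus_length):
            raise ValueError(
                f"TE {self.id}: bad consensus coordinates "
                f"{self.consensus_begin}..{self.consensus_end}/{self.consensus_length}"
            )

    @property
    def indel_tolerance(self) -> int:
        """Genomic span length minus aligned consensus length (may be negative)."""
        return len(self.span) - (self.consensus_end - self.consensus_begin + 1)


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_FAMILY_CLASS = {
    "Alu": "SINE/Alu",
    "MIR": "SINE/MIR",
    "L1": "LINE/L1",
    "L2": "LINE/L2",
    "ERV": "LTR/ERV1",
    "MaLR": "LTR/ERVL-MaLR",
    "hAT": "DNA/hAT",
    "TcMar": "DNA/TcMar",
    "other": "Unknown",
}


def _family_from_class(repclass: str) -> str:
    fam = repclass.split("/", 1)[-1]
    # order matters: MaLR class strings contain "ERVL"
    if fam.startswith("Alu") or fam == "FLAM" or fam == "FRAM":
        return "Alu"
    if "MaLR" in fam:
        return "MaLR"
    if "ERV" in fam:
        return "ERV"
    if fam.startswith("L1"):
        return "L1"
    if fam.startswith("L2"):
        return "L2"
    if fam.startswith("MIR"):
        return "MIR"
    if "hAT" in fam:
        return "hAT"
    if "TcMar" in fam or "Tc1" in fam:
        return "TcMar"
    return "other"


def _paren(tok: str) -> int:
    return int(tok.strip("()"))


def read_repeatmasker_out(path: str | Path) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` file into :class:`TEAnnotation` records.

    Genomic coordinates are converted to 0-based half-open; strand ``C`` maps
    to ``-``.  For minus-strand records the parenthesised "(left)" field holds
    the distance of the alignment start from the consensus 3' end, so the
    repeat-coordinate columns come in the order (left), end, begin; the
    consensus length is recovered as ``end + left`` on both strands.
    """
    tes: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            # tolerate the two header lines RepeatMasker writes
            if toks[0] in ("SW", "score") or toks[0].startswith("#"):
                continue
            if len(toks) < 14:
                raise ValueError(
                    f"{path}:{lineno}: expected >=14 RepeatMasker columns, got {len(toks)}"
                )
            try:
                chrom = toks[4]
                qbegin, qend = int(toks[5]), int(toks[6])
                orient = toks[8]
                name = toks[9]
                repclass = toks[10]
                if orient == "+":
                    strand = "+"
                    cb, ce, left = int(toks[11]), int(toks[12]), _paren(toks[13])
                elif orient in ("C", "-"):
                    strand = "-"
                    left, ce, cb = _paren(toks[11]), int(toks[12]), int(toks[13])
                else:
                    raise ValueError(f"bad orientation {orient!r}")
                te_id = toks[14] if len(toks) > 14 else str(len(tes))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            tes.append(
                TEAnnotation(
                    id=f"te{te_id}" if te_id.isdigit() else te_id,
                    span=GenomicInterval(chrom, qbegin - 1, qend, strand),
                    family=_family_from_class(repclass),
                    subfamily=name,
                    consensus_begin=cb,
                    consensus_end=ce,
                    consensus_length=ce + left,
                )
            )
    return tes


def write_repeatmasker_out(tes: Sequence[TEAnnotation], path: str | Path) -> None:
    """Write TEs in the RepeatMasker ``.out`` column layout (with header)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching"
            "       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    repeat"
            "              class/family         begin  end (left)     ID\n"
        )
        for te in tes:
            left = te.consensus_length - te.consensus_end
            repclass = _FAMILY_CLASS.get(te.family, "Unknown")
            if te.span.strand == "+":
                orient = "+"
                rcols = f"{te.consensus_begin} {te.consensus_end} ({left})"
            else:
                orient = "C"
                rcols = f"({left}) {te.consensus_end} {te.consensus_begin}"
            fh.write(
                f"1000 0.0 0.0 0.0 {te.span.chrom} {te.span.start + 1} {te.span.end} "
                f"(0) {orient} {te.subfamily} {repclass} {rcols} {te.id}\n"
            )


# ---------------------------------------------------------------------------
# BEDPE ditags
# ---------------------------------------------------------------------------

def write_ditags_bedpe(ditags: Iterable[DitagRecord], path: str | Path) -> int:
    """Write ditags as BEDPE with the 5' point as the first mate.

    Returns the number of records written.
    """
    n = 0
    with open(path, "w") as fh:
        for i, d in enumerate(ditags):
            c5, b5, s5 = d.five_prime
            c3, b3, s3 = d.three_prime
            fh.write(
                f"{c5}\t{b5}\t{b5 + 1}\t{c3}\t{b3}\t{b3 + 1}\tditag{i}\t0\t{s5}\t{s3}\n"
            )
            n += 1
    return n


def read_ditags_bedpe(path: str | Path, celltype: str = "") -> list[DitagRecord]:
    """Read a BEDPE ditag file; one :class:`DitagRecord` per line.

    Mate order is significant: the first mate is the 5' point.  Records whose
    mates disagree on chromosome or strand are retained (``inter_locus`` is
    derived, not stored).
    """
    out: list[DitagRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 10:
                raise ValueError(f"{path}:{lineno}: expected >=10 BEDPE columns")
            try:
                five = (toks[0], int(toks[1]), toks[8])
                three = (toks[3], int(toks[4]), toks[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: coordinate parse failure: {exc}") from exc
            out.append(DitagRecord(five_prime=five, three_prime=three, celltype=celltype))
    return out


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------

def write_genes_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.locus.chrom, g.locus.start)):
            sizes = ",".join(str(e - s) for s, e in g.exon_blocks)
            starts = ",".join(str(s - g.locus.start) for s, e in g.exon_blocks)
            thick = g.cds if g.cds is not None else (g.locus.start, g.locus.start)
            fh.write(
                f"{g.locus.chrom}\t{g.locus.start}\t{g.locus.end}\t{g.id}\t0\t"
                f"{g.strand}\t{thick[0]}\t{thick[1]}\t0\t{len(g.exon_blocks)}\t"
                f"{sizes},\t{starts},\n"
            )


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end = toks[0], int(toks[1]), int(toks[2])
            name, strand = toks[3], toks[5]
            thick = (int(toks[6]), int(toks[7]))
            cds = None if thick[0] == thick[1] else thick
            sizes = [int(x) for x in toks[10].rstrip(",").split(",")]
            starts = [int(x) for x in toks[11].rstrip(",").split(",")]
            blocks = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            genes.append(
                GeneModel(
                    id=name,
                    locus=GenomicInterval(chrom, start, end, strand),
                    exon_blocks=blocks,
                    cds=cds,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# BED6 point tags (ChIP)
# ---------------------------------------------------------------------------

def write_chip_bed(tags: Iterable[tuple[str, int]], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for i, (chrom, base) in enumerate(tags):
            fh.write(f"{chrom}\t{base}\t{base + 1}\ttag{i}\t0\t+\n")
            n += 1
    return n


def read_chip_bed(path: str | Path) -> list[tuple[str, int]]:
    tags: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            tags.append((toks[0], int(toks[1])))
    return tags


# ---------------------------------------------------------------------------
# TTS BED (BED6 + peak column)
# ---------------------------------------------------------------------------

def write_tts_bed(records, path: str | Path) -> None:
    """Write TTS clusters/records as BED6+1, the extra column being the peak base.

    Accepts :class:`~tetermi.tts_discovery.TTSCluster` objects or objects with
    a ``cluster`` attribute.  Output is sorted by (chrom, start) and
    byte-deterministic.
    """
    rows = []
    for rec in records:
        cl = getattr(rec, "cluster", rec)
        name = getattr(rec, "name", None) or getattr(cl, "name", None)
        total = sum(cl.counts_by_celltype.values())
        rows.append(
            [cl.interval.chrom, cl.interval.start, cl.interval.end, name,
             total, cl.interval.strand, cl.peak]
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[5], r[3] or ""))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tpeak\n")
        for i, r in enumerate(rows):
            if r[3] is None:
                r[3] = f"tts{i}"  # default names follow sorted order
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_tts_bed(path: str | Path) -> list[tuple[GenomicInterval, int, str, int]]:
    """Read the BED6+1 TTS dialect back as (interval, peak, name, score) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.rstrip("\n").split("\t")
            iv = GenomicInterval(toks[0], int(toks[1]), int(toks[2]), toks[5])
            out.append((iv, int(toks[6]), toks[3], int(toks[4])))
    return out
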