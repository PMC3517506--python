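"""Synthetic genomes-in-miniature with planted transcription termination.

The generator emits the same data model the pipeline consumes from real
experiments — gene models with exon structure, RepeatMasker-style TE
annotations, per-cell-type PET ditag libraries and ChIP tag positions —
with a recoverable ground truth: every gene carries a set of planted
terminators (a subset inside TE spans, placed to satisfy the 50 bp / 15 bp
rule), each cell type draws every transcript's terminator from a planted
per-TTS probability vector, 3' ends get Gaussian positional jitter, and a
configurable fraction of tags are uniform background noise.

Genes come in three termination patterns so the downstream specificity
statistics have known answers: *specific* genes whose alternative TTS fire
in exactly one cell type, *uniform* genes whose single alternative TTS has
the same probability everywhere, and *variable* genes with per-cell-type
probabilities drawn independently.

All randomness flows from ``SimConfig.seed`` through per-stage
``numpy.random.default_rng`` streams, so identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import (
    DitagRecord,
    GeneModel,
    GenomicInterval,
    TEAnnotation,
    write_chip_bed,
    write_ditags_bedpe,
    write_genes_bed12,
    write_repeatmasker_out,
)

__all__ = [
    "SimConfig",
    "TrueTTS",
    "GroundTruth",
    "PETLibrary",
    "generate_gene_set",
    "generate_pet_library",
    "generate_chip_tags",
    "write_dataset",
    "write_ground_truth",
    "read_ground_truth",
]

# typical consensus lengths for fragments of each family (bases)
_CONSENSUS_LENGTHS = {
    "Alu": 311, "ERV": 1200, "hAT": 900, "L1": 6019,
    "L2": 3300, "MaLR": 1400, "MIR": 262, "TcMar": 1300,
}
_FAMILY_WEIGHTS = {
    "Alu": 0.35, "L1": 0.20, "MIR": 0.12, "L2": 0.08,
    "ERV": 0.07, "hAT": 0.07, "MaLR": 0.06, "TcMar": 0.05,
}
_SUBFAMILIES = {
    "Alu": ("AluY", "AluSx", "AluJb", "FLAM_C"),
    "ERV": ("ERVL-1", "ERV1-1"), "hAT": ("Charlie1",), "L1": ("L1PA2", "L1MB3"),
    "L2": ("L2a",), "MaLR": ("MLT1A",), "MIR": ("MIRb",), "TcMar": ("Tigger1",),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    The defaults describe the reference fixture: 200 genes on one synthetic
    chromosome, 8 cell types, one million ditags per cell type, alternative
    terminators planted with 2 bp 3'-end jitter and 2% uniform background
    noise over the gene locus.
    """

    n_genes: int = 200
    n_celltypes: int = 8
    genome_length: int = 4_000_000
    tts_per_gene: tuple[int, int] = (1, 3)
    te_fraction_of_tts: float = 0.6
    termination_prob_matrix: dict | None = None  # gene index -> (n_tts, n_ct) array
    jitter_sd: float = 2.0
    library_size: int = 1_000_000
    noise_rate: float = 0.02
    chip_enrichment_height: float = 5.0  # expected tags per anchor
    chip_enrichment_sd: float = 200.0
    chip_background: float = 0.001  # expected background tags per base
    seed: int = 0
    # secondary knobs
    celltypes: tuple[str, ...] | None = None
    chrom: str = "chrS"
    specific_gene_fraction: float = 0.25
    uniform_gene_fraction: float = 0.25
    tts_te_sense_prob: float = 0.75
    background_te_sense_prob: float = 0.35
    expression_sigma: float = 1.0
    promoter_jitter_sd: float = 20.0
    downstream_limit: int = 5000
    min_tts_separation: int = 300

    def __post_init__(self) -> None:
        for name in (
            "te_fraction_of_tts", "noise_rate", "specific_gene_fraction",
            "uniform_gene_fraction", "tts_te_sense_prob", "background_te_sense_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.specific_gene_fraction + self.uniform_gene_fraction > 1.0:
            raise ValueError("gene pattern fractions must sum to <= 1")
        if self.n_genes < 0 or self.n_celltypes < 1:
            raise ValueError("need n_genes >= 0 and n_celltypes >= 1")
        if self.library_size < 0:
            raise ValueError("library_size must be non-negative")
        if self.jitter_sd < 0 or self.chip_enrichment_sd <= 0:
            raise ValueError("dispersions must be non-negative")
        lo, hi = self.tts_per_gene
        if not 0 <= lo <= hi:
            raise ValueError(f"bad tts_per_gene range {self.tts_per_gene}")
        if self.termination_prob_matrix is not None:
            for gi, mat in self.termination_prob_matrix.items():
                arr = np.asarray(mat, dtype=float)
                if np.any(arr < 0) or np.any(arr > 1):
                    raise ValueError(f"gene {gi}: probabilities outside [0, 1]")
                if np.any(arr.sum(axis=0) > 1 + 1e-9):
                    raise ValueError(f"gene {gi}: per-cell-type TTS probabilities sum to > 1")

    @property
    def celltype_names(self) -> tuple[str, ...]:
        if self.celltypes is not None:
            if len(self.celltypes) != self.n_celltypes:
                raise ValueError("celltypes length must equal n_celltypes")
            return tuple(self.celltypes)
        return tuple(f"ct{i + 1:02d}" for i in range(self.n_celltypes))


@dataclass
class TrueTTS:
    """One planted terminator: where it is and how strongly each cell type uses it."""

    tts_id: str
    gene_id: str
    chrom: str
    position: int
    strand: str
    probs: np.ndarray  # per-cell-type termination probability
    te_id: str | None = None
    te_orientation: str | None = None
    planted_class: str = "internal"
    pattern: str = "variable"  # specific | uniform | variable
    is_canonical: bool = False


@dataclass
class GroundTruth:
    true_tts: list[TrueTTS]
    te_orientations: dict[str, str]
    expression_weights: np.ndarray  # (n_genes, n_celltypes), unnormalized
    celltypes: tuple[str, ...]
    gene_index: dict[str, int] = field(default_factory=dict)


@dataclass
class PETLibrary:
    """One cell type's ditag library as flat coordinate arrays (one chromosome)."""

    celltype: str
    chrom: str
    five: np.ndarray
    three: np.ndarray
    strand: np.ndarray  # '+'/'-' per tag
    gene_index: np.ndarray  # index into the gene list each tag was emitted from

    def __len__(self) -> int:
        return self.five.size

    def to_records(self) -> list[DitagRecord]:
        return [
            DitagRecord(
                five_prime=(self.chrom, int(f), str(s)),
                three_prime=(self.chrom, int(t), str(s)),
                celltype=self.celltype,
            )
            for f, t, s in zip(self.five, self.three, self.strand)
        ]

    def write_bedpe(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (f, t, s) in enumerate(zip(self.five, self.three, self.strand)):
                fh.write(
                    f"{self.chrom}\t{f}\t{f + 1}\t{self.chrom}\t{t}\t{t + 1}\t"
                    f"ditag{i}\t0\t{s}\t{s}\n"
                )


# ---------------------------------------------------------------------------
# gene / TE / truth generation
# ---------------------------------------------------------------------------

def _make_exons(rng, start: int, end: int) -> tuple[tuple[int, int], ...]:
    L = end - start
    n_ex = int(rng.integers(3, 7))
    sizes = rng.integers(150, 400, size=n_ex)
    while sizes.sum() + (n_ex - 1) * 100 > L:
        n_ex -= 1
        sizes = sizes[:n_ex]
    intron_total = L - int(sizes.sum())
    splits = rng.dirichlet(np.ones(n_ex - 1)) * intron_total
    introns = np.maximum(splits.astype(int), 100)
    # rescale if the floor pushed us over
    while introns.sum() > intron_total:
        introns[np.argmax(introns)] -= introns.sum() - intron_total
    exons = []
    pos = start
    for i in range(n_ex):
        exons.append((pos, pos + int(sizes[i])))
        pos += int(sizes[i]) + (int(introns[i]) if i < n_ex - 1 else 0)
    # stretch the last exon to the locus end
    last_s, _ = exons[-1]
    exons[-1] = (last_s, end)
    return tuple(exons)


def _place_tes(rng, gene: GeneModel, n_te: int, config: SimConfig, te_serial: int):
    """Place non-overlapping TE spans >=100 bp apart inside the locus."""
    placed: list[TEAnnotation] = []
    lo = gene.locus.start + 500
    hi = gene.locus.end - 500
    for _ in range(n_te):
        te = _try_place_te(rng, gene, placed, lo, hi, config, te_serial + len(placed))
        if te is not None:
            placed.append(te)
    return placed


def _try_place_te(rng, gene, placed, lo, hi, config, serial) -> TEAnnotation | None:
    for _ in range(30):
        fam = str(rng.choice(list(_FAMILY_WEIGHTS), p=list(_FAMILY_WEIGHTS.values())))
        clen = _CONSENSUS_LENGTHS[fam]
        te_len = int(rng.integers(200, min(350, clen) + 1))
        if hi - te_len <= lo:
            return None
        s = int(rng.integers(lo, hi - te_len))
        e = s + te_len
        if any(s < t.span.end + 100 and t.span.start - 100 < e for t in placed):
            continue  # overlaps or closer than 100 bp to an existing TE
        sub = str(rng.choice(_SUBFAMILIES[fam]))
        cb = int(rng.integers(1, clen - te_len + 2))
        ce = cb + te_len - 1
        sense = rng.random() < config.background_te_sense_prob
        strand = gene.strand if sense else ("-" if gene.strand == "+" else "+")
        return TEAnnotation(
            id=f"te{serial}",
            span=GenomicInterval(gene.locus.chrom, s, e, strand),
            family=fam,
            subfamily=sub,
            consensus_begin=cb,
            consensus_end=ce,
            consensus_length=clen,
        )
    return None


def _te_window(te: TEAnnotation, gene_strand: str) -> tuple[int, int]:
    """Genomic [lo, hi] of peaks satisfying the 50/15 rule, transcription-direction."""
    if gene_strand == "+":
        return te.span.start + 50, te.span.end - 1 + 14
    return te.span.start - 14, te.span.end - 1 - 50


def generate_gene_set(config: SimConfig):
    """Generate gene models, TE annotations and the planted ground truth.

    Returns ``(genes, tes, truth)``.  Gene loci are non-overlapping on one
    synthetic chromosome; each gene carries a canonical terminator at its
    annotated TTS plus 0 or more planted alternatives (a ``te_fraction_of_tts``
    share of them inside TE spans under the 50/15 rule), all separated by at
    least ``min_tts_separation`` bases.  Raises when the genes cannot fit in
    ``genome_length``.
    """
    rng = np.random.default_rng([config.seed, 0])
    cts = config.celltype_names
    genes: list[GeneModel] = []
    tes: list[TEAnnotation] = []
    truth = GroundTruth(
        true_tts=[],
        te_orientations={},
        expression_weights=np.ones((config.n_genes, config.n_celltypes)),
        celltypes=cts,
    )
    cursor = 1000
    te_serial = 0
    for gi in range(config.n_genes):
        L = int(rng.integers(4000, 8001))
        if cursor + L + config.downstream_limit + 2000 > config.genome_length:
            raise ValueError(
                f"gene {gi} does not fit: need > {cursor + L + config.downstream_limit + 2000} "
                f"bases but genome_length={config.genome_length}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        locus = GenomicInterval(config.chrom, cursor, cursor + L, strand)
        exons = _make_exons(rng, cursor, cursor + L)
        cds = (
            exons[0][0] + (exons[0][1] - exons[0][0]) // 2,
            exons[-1][1] - (exons[-1][1] - exons[-1][0]) // 2,
        )
        gene = GeneModel(id=f"g{gi:04d}", locus=locus, exon_blocks=exons, cds=cds)
        genes.append(gene)
        truth.gene_index[gene.id] = gi

        gene_tes = _place_tes(rng, gene, int(rng.integers(2, 5)), config, te_serial)
        te_serial += len(gene_tes)
        for te in gene_tes:
            truth.te_orientations[te.id] = (
                "sense" if te.span.strand == gene.strand else "antisense"
            )
        tes.extend(gene_tes)

        u = rng.random()
        if u < config.specific_gene_fraction:
            pattern = "specific"
        elif u < config.specific_gene_fraction + config.uniform_gene_fraction:
            pattern = "uniform"
        else:
            pattern = "variable"

        k = int(rng.integers(config.tts_per_gene[0], config.tts_per_gene[1] + 1))
        if pattern == "uniform":
            k = min(k, 1)
        placed_pos = [gene.annotated_tts]
        planted: list[tuple[int, TEAnnotation | None]] = []
        unused = list(gene_tes)
        for _ in range(k):
            use_te = rng.random() < config.te_fraction_of_tts
            pos = te = None
            if use_te:
                rng.shuffle(unused)
                for cand in list(unused):
                    wlo, whi = _te_window(cand, gene.strand)
                    for _try in range(10):
                        p = int(rng.integers(wlo, whi + 1))
                        if all(abs(p - q) >= config.min_tts_separation for q in placed_pos):
                            pos, te = p, cand
                            break
                    if pos is not None:
                        unused.remove(cand)
                        break
                if pos is None and config.te_fraction_of_tts >= 1.0:
                    continue  # cannot host another TE-TTS; keep the all-TE contract
            if pos is None and not use_te:
                for _try in range(50):
                    p = int(rng.integers(locus.start + 1000, locus.end - 400))
                    near_te = any(
                        t.span.start - 20 <= p < t.span.end + 20 for t in gene_tes
                    )
                    if not near_te and all(
                        abs(p - q) >= config.min_tts_separation for q in placed_pos
                    ):
                        pos = p
                        break
            if pos is None:
                continue
            placed_pos.append(pos)
            planted.append((pos, te))

        # per-cell-type termination probabilities for the alternatives
        n_alt = len(planted)
        explicit = (
            config.termination_prob_matrix is not None
            and gi in config.termination_prob_matrix
        )
        if explicit:
            probs = np.asarray(config.termination_prob_matrix[gi], dtype=float)
            if probs.shape != (n_alt, config.n_celltypes):
                raise ValueError(
                    f"gene {gi}: termination_prob_matrix shape {probs.shape} != "
                    f"({n_alt}, {config.n_celltypes})"
                )
        elif n_alt == 0:
            probs = np.zeros((0, config.n_celltypes))
        elif pattern == "specific":
            probs = np.zeros((n_alt, config.n_celltypes))
            c_star = int(rng.integers(config.n_celltypes))
            budget = rng.uniform(0.35, 0.7)
            shares = rng.dirichlet(np.ones(n_alt))
            probs[:, c_star] = budget * shares
        elif pattern == "uniform":
            p = rng.uniform(0.35, 0.65)
            probs = np.full((n_alt, config.n_celltypes), p)
        else:
            budget = rng.uniform(0.3, 0.7)
            shares = rng.dirichlet(np.ones(n_alt))
            base = budget * shares
            probs = base[:, None] * rng.uniform(0.2, 1.0, size=(n_alt, config.n_celltypes))
        if not explicit:
            # cap the generated alternatives so the canonical terminator keeps
            # at least 10% of transcripts in every cell type
            col = probs.sum(axis=0)
            over = col > 0.9
            if np.any(over):
                probs[:, over] *= 0.9 / col[over]

        for j, (pos, te) in enumerate(planted):
            truth.true_tts.append(
                TrueTTS(
                    tts_id=f"{gene.id}.t{j}",
                    gene_id=gene.id,
                    chrom=config.chrom,
                    position=pos,
                    strand=strand,
                    probs=probs[j].copy(),
                    te_id=te.id if te is not None else None,
                    te_orientation=(
                        truth.te_orientations[te.id] if te is not None else None
                    ),
                    planted_class=_planted_class(pos, gene),
                    pattern=pattern,
                )
            )
        truth.true_tts.append(
            TrueTTS(
                tts_id=f"{gene.id}.canonical",
                gene_id=gene.id,
                chrom=config.chrom,
                position=gene.annotated_tts,
                strand=strand,
                probs=1.0 - probs.sum(axis=0),
                planted_class="annotated",
                pattern=pattern,
                is_canonical=True,
            )
        )
        truth.expression_weights[gi] = rng.lognormal(
            0.0, config.expression_sigma, size=config.n_celltypes
        )
        cursor += L + config.downstream_limit + int(rng.integers(2000, 4001))
    return genes, tes, truth


def _planted_class(pos: int, gene: GeneModel) -> str:
    from .gene_annotation import classify_location

    return classify_location(pos, gene)


# ---------------------------------------------------------------------------
# PET library generation
# ---------------------------------------------------------------------------

def generate_pet_library(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    celltype: str,
    config: SimConfig,
) -> PETLibrary:
    """Draw one cell type's ditag library from the planted ground truth.

    Tags are apportioned over genes multinomially by the cell type's
    expression weights; each tag's 5' point sits at its gene's promoter with
    small Gaussian jitter and its 3' point is drawn from the gene's planted
    TTS probabilities, jittered by ``jitter_sd`` (rounded to an integer base,
    truncated at the gene's downstream boundary).  A ``noise_rate`` fraction
    of tags get uniform random 3' points within the gene locus.
    """
    cts = truth.celltypes
    if celltype not in cts:
        raise ValueError(f"unknown cell type {celltype!r}; have {cts}")
    c = cts.index(celltype)
    rng = np.random.default_rng([config.seed, 1, c])
    n_genes = len(genes)
    if n_genes == 0 or config.library_size == 0:
        empty = np.empty(0, dtype=np.int64)
        return PETLibrary(celltype, config.chrom, empty, empty.copy(),
                          np.empty(0, dtype="U1"), empty.copy())

    by_gene: dict[str, list[TrueTTS]] = {}
    for t in truth.true_tts:
        by_gene.setdefault(t.gene_id, []).append(t)

    w = truth.expression_weights[:, c].astype(float)
    w /= w.sum()
    n_per_gene = rng.multinomial(config.library_size, w)

    fives, threes, strands, gidx = [], [], [], []
    for gi, gene in enumerate(genes):
        n_g = int(n_per_gene[gi])
        if n_g == 0:
            continue
        tts_list = by_gene[gene.id]
        pos = np.array([t.position for t in tts_list], dtype=np.int64)
        p = np.array([t.probs[c] for t in tts_list], dtype=float)
        p = np.clip(p, 0, None)
        p /= p.sum()
        choice = rng.choice(pos.size, size=n_g, p=p)
        three = pos[choice].astype(np.int64)
        if config.jitter_sd > 0:
            three = three + np.rint(
                rng.normal(0.0, config.jitter_sd, size=n_g)
            ).astype(np.int64)
        if gene.strand == "+":
            lo3, hi3 = gene.locus.start, gene.locus.end - 1 + config.downstream_limit
        else:
            lo3, hi3 = gene.locus.start - config.downstream_limit, gene.locus.end - 1
        np.clip(three, lo3, hi3, out=three)
        n_noise = int(rng.binomial(n_g, config.noise_rate))
        if n_noise:
            idx = rng.choice(n_g, size=n_noise, replace=False)
            three[idx] = rng.integers(gene.locus.start, gene.locus.end, size=n_noise)
        five = np.full(n_g, gene.annotated_tss, dtype=np.int64)
        if config.promoter_jitter_sd > 0:
            off = np.rint(rng.normal(0.0, config.promoter_jitter_sd, size=n_g)).astype(np.int64)
            lim = int(3 * config.promoter_jitter_sd)
            five = five + np.clip(off, -lim, lim)
        fives.append(five)
        threes.append(three)
        strands.append(np.full(n_g, gene.strand, dtype="U1"))
        gidx.append(np.full(n_g, gi, dtype=np.int64))
    return PETLibrary(
        celltype=celltype,
        chrom=config.chrom,
        five=np.concatenate(fives) if fives else np.empty(0, dtype=np.int64),
        three=np.concatenate(threes) if threes else np.empty(0, dtype=np.int64),
        strand=np.concatenate(strands) if strands else np.empty(0, dtype="U1"),
        gene_index=np.concatenate(gidx) if gidx else np.empty(0, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# ChIP tag generation
# ---------------------------------------------------------------------------

def generate_chip_tags(
    anchors: Sequence[int],
    config: SimConfig,
    genome_length: int | None = None,
    enrichment_offset: int = 0,
) -> np.ndarray:
    """Sorted ChIP tag positions: uniform background plus per-anchor enrichment.

    The background contributes ``Poisson(chip_background * genome_length)``
    uniform tags; each anchor contributes ``Poisson(chip_enrichment_height)``
    tags at Gaussian offsets (sd ``chip_enrichment_sd``) around
    ``anchor + enrichment_offset``.
    """
    rng = np.random.default_rng([config.seed, 2])
    G = int(genome_length if genome_length is not None else config.genome_length)
    parts = []
    n_bg = int(rng.poisson(config.chip_background * G))
    if n_bg:
        parts.append(rng.integers(0, G, size=n_bg))
    for a in anchors:
        n = int(rng.poisson(config.chip_enrichment_height))
        if n:
            pos = np.rint(
                rng.normal(a + enrichment_offset, config.chip_enrichment_sd, size=n)
            ).astype(np.int64)
            parts.append(np.clip(pos, 0, G - 1))
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(parts).astype(np.int64))


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#celltypes=" + ",".join(truth.celltypes) + "\n")
        fh.write(
            "tts_id\tgene_id\tchrom\tposition\tstrand\tte_id\tte_orientation\t"
            "planted_class\tpattern\tcanonical\tprobs\n"
        )
        for t in truth.true_tts:
            probs = ",".join(f"{p:.6g}" for p in t.probs)
            fh.write(
                f"{t.tts_id}\t{t.gene_id}\t{t.chrom}\t{t.position}\t{t.strand}\t"
                f"{t.te_id or '.'}\t{t.te_orientation or '.'}\t{t.planted_class}\t"
                f"{t.pattern}\t{int(t.is_canonical)}\t{probs}\n"
            )


def read_ground_truth(path: str | Path) -> GroundTruth:
    true_tts: list[TrueTTS] = []
    celltypes: tuple[str, ...] = ()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#celltypes="):
                celltypes = tuple(line.strip().split("=", 1)[1].split(","))
                continue
            if line.startswith(("#", "tts_id")) or not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            true_tts.append(
                TrueTTS(
                    tts_id=toks[0],
                    gene_id=toks[1],
                    chrom=toks[2],
                    position=int(toks[3]),
                    strand=toks[4],
                    te_id=None if toks[5] == "." else toks[5],
                    te_orientation=None if toks[6] == "." else toks[6],
                    planted_class=toks[7],
                    pattern=toks[8],
                    is_canonical=bool(int(toks[9])),
                    probs=np.array([float(x) for x in toks[10].split(",")]),
                )
            )
    te_orient = {
        t.te_id: t.te_orientation for t in true_tts if t.te_id is not None
    }
    return GroundTruth(
        true_tts=true_tts,
        te_orientations=te_orient,
        expression_weights=np.empty((0, len(celltypes))),
        celltypes=celltypes,
    )


def write_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, tes, truth = generate_gene_set(config)
    paths: dict[str, Path] = {}
    paths["genes"] = outdir / "genes.bed12"
    write_genes_bed12(genes, paths["genes"])
    paths["repeats"] = outdir / "repeats.out"
    write_repeatmasker_out(tes, paths["repeats"])
    paths["truth"] = outdir / "truth.tsv"
    write_ground_truth(truth, paths["truth"])
    for ct in config.celltype_names:
        lib = generate_pet_library(genes, truth, ct, config)
        p = outdir / f"{ct}.bedpe"
        lib.write_bedpe(p)
        paths[f"ditags:{ct}"] = p
    anchors = [t.position for t in truth.true_tts]
    chip = generate_chip_tags(anchors, config)
    paths["chip"] = outdir / "chip.bed"
    write_chip_bed(((config.chrom, int(b)) for b in chip), paths["chip"])
    return paths
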