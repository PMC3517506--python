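"""End-to-end orchestration: discover -> associate -> TE-assign -> statistics.

The stage functions here are vectorized equivalents of the per-record
operations in the other modules, built to run whole multi-million-tag
libraries; unit semantics (clustering gap, filters, the 50/15 rule, the
utilization and specificity formulas) are identical.  ``run_pipeline``
executes every stage from input files into a run directory with a manifest
recording the configuration hash, input checksums and seed, so a run is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chromatin_profiles import metaprofile, stratify_anchors
from .formats_io import (
    GeneModel,
    TEAnnotation,
    read_chip_bed,
    read_ditags_bedpe,
    read_genes_bed12,
    read_repeatmasker_out,
    write_tts_bed,
)
from .gene_annotation import TTSRecord, classify_location, summarize_location_table
from .statistics import (
    cell_type_specificity,
    compare_utilization_groups,
    extrapolate_total,
    fit_log_trend,
    observed_expected_test,
    orientation_bias_test,
    rarefaction,
    specificity_eligible,
    transcribed_and_active,
    utilization,
)
from .synthetic_data import PETLibrary
from .te_assignment import assign_te, map_to_consensus, relative_orientation
from .tts_discovery import (
    TTSCluster,
    _clusters_from_sorted,
    filter_clusters,
    merge_across_celltypes,
    normalize_count,
)

__all__ = ["PipelineConfig", "AnalysisResult", "run_analysis", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, with the standard defaults."""

    max_gap: int = 20
    min_norm: float = 20.0
    min_reciprocal_overlap: float = 0.8
    reciprocal: bool = True
    promoter_halfwidth: int = 500
    downstream_limit: int = 5000
    min_into_te: int = 50
    max_past_end: int = 15
    te_coordinate_mode: str = "transcription"
    active_quantile: float = 0.75
    min_util: float = 0.2
    min_active_celltypes: int = 3
    metaprofile_halfwidth: int = 5000
    metaprofile_bin: int = 10
    rarefaction_target_celltypes: int = 210
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_reciprocal_overlap <= 1:
            raise ValueError("min_reciprocal_overlap must be in (0, 1]")
        if not 0 < self.active_quantile <= 1:
            raise ValueError("active_quantile must be in (0, 1]")
        for name in ("max_gap", "promoter_halfwidth", "downstream_limit",
                     "min_into_te", "max_past_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class AnalysisResult:
    clusters: list[TTSCluster]
    records: list[TTSRecord]
    utilization: pd.DataFrame  # rows (tts, celltype): terminated, passing, utilization
    gene_norm_counts: pd.DataFrame  # genes x celltypes, tags per 10M
    active: pd.DataFrame  # genes x celltypes bool
    specificity: pd.DataFrame  # per eligible TTS
    orientation_tests: pd.DataFrame
    obs_exp_tests: pd.DataFrame
    utilization_contrasts: pd.DataFrame
    rarefaction_tts: pd.DataFrame
    rarefaction_genes: pd.DataFrame
    log_fit: object | None
    extrapolation: dict
    location_counts: pd.DataFrame
    profiles: dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# vectorized stage helpers
# ---------------------------------------------------------------------------

def _library_groups(lib: PETLibrary) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Split a library into (chrom, strand) -> (five, three) arrays."""
    out = {}
    for strand in ("+", "-"):
        sel = lib.strand == strand
        if np.any(sel):
            out[(lib.chrom, strand)] = (lib.five[sel], lib.three[sel])
    return out


def library_from_records(records, celltype: str) -> PETLibrary:
    """Build a single-chromosome PETLibrary from DitagRecord objects."""
    usable = [d for d in records if not d.inter_locus]
    if not usable:
        e = np.empty(0, dtype=np.int64)
        return PETLibrary(celltype, "", e, e.copy(), np.empty(0, dtype="U1"), e.copy())
    chroms = {d.five_prime[0] for d in usable}
    if len(chroms) != 1:
        raise ValueError("library_from_records expects a single chromosome")
    return PETLibrary(
        celltype=celltype,
        chrom=next(iter(chroms)),
        five=np.array([d.five_prime[1] for d in usable], dtype=np.int64),
        three=np.array([d.three_prime[1] for d in usable], dtype=np.int64),
        strand=np.array([d.five_prime[2] for d in usable], dtype="U1"),
        gene_index=np.full(len(usable), -1, dtype=np.int64),
    )


def discover_tts(
    libraries: Mapping[str, PETLibrary], cfg: PipelineConfig
) -> tuple[list[TTSCluster], dict[str, np.ndarray]]:
    """Cluster, filter and merge per-cell-type 3' ends into TTS.

    Returns the merged clusters and, per cell type, the merged-cluster index
    of every tag (-1 for tags whose cluster failed the depth filter).
    """
    per_ct_clusters: dict[str, list[TTSCluster]] = {}
    tag_cluster: dict[str, np.ndarray] = {}
    keep_maps: dict[str, np.ndarray] = {}
    for ct in sorted(libraries):
        lib = libraries[ct]
        lib_size = max(len(lib), 1)
        clusters: list[TTSCluster] = []
        cl_of_tag = np.full(len(lib), -1, dtype=np.int64)
        for (chrom, strand), (five, three) in sorted(_library_groups(lib).items()):
            uniq, counts = np.unique(three, return_counts=True)
            segs = _clusters_from_sorted(chrom, strand, uniq, counts, cfg.max_gap, ct)
            cid_of_uniq = np.zeros(uniq.size, dtype=np.int64)
            if uniq.size > 1:
                cid_of_uniq[1:] = np.cumsum(np.diff(uniq) > cfg.max_gap + 1)
            cid_of_uniq += len(clusters)
            sel = np.flatnonzero((lib.strand == strand) & (lib.chrom == chrom))
            cl_of_tag[sel] = cid_of_uniq[np.searchsorted(uniq, three)]
            clusters.extend(segs)
        for cl in clusters:
            cl.norm_counts_by_celltype = {
                ct: normalize_count(cl.counts_by_celltype[ct], lib_size)
            }
        kept = filter_clusters(clusters, cfg.min_norm)
        old_to_new = np.full(len(clusters), -1, dtype=np.int64)
        kept_ids = {id(c) for c in kept}
        j = 0
        for i, cl in enumerate(clusters):
            if id(cl) in kept_ids:
                old_to_new[i] = j
                j += 1
        per_ct_clusters[ct] = kept
        tag_cluster[ct] = cl_of_tag
        keep_maps[ct] = old_to_new
    merged, index_maps = merge_across_celltypes(
        per_ct_clusters,
        min_reciprocal_overlap=cfg.min_reciprocal_overlap,
        reciprocal=cfg.reciprocal,
        return_components=True,
    )
    tag_comp: dict[str, np.ndarray] = {}
    for ct in sorted(libraries):
        imap = index_maps.get(ct, {})
        filt_to_comp = np.full(len(per_ct_clusters[ct]), -1, dtype=np.int64)
        for filt_idx, comp_idx in imap.items():
            filt_to_comp[filt_idx] = comp_idx
        cl = tag_cluster[ct]
        if keep_maps[ct].size == 0 or filt_to_comp.size == 0:
            tag_comp[ct] = np.full(cl.size, -1, dtype=np.int64)
            continue
        filt = np.where(cl >= 0, keep_maps[ct][cl], -1)
        tag_comp[ct] = np.where(filt >= 0, filt_to_comp[np.maximum(filt, 0)], -1)
    return merged, tag_comp


def _gene_of_tags(
    lib: PETLibrary, genes: Sequence[GeneModel], promoter_halfwidth: int
) -> np.ndarray:
    """Nearest promoter assignment: per tag the gene index, or -1."""
    out = np.full(len(lib), -1, dtype=np.int64)
    for strand in ("+", "-"):
        gsel = [
            (i, g.annotated_tss)
            for i, g in enumerate(genes)
            if g.strand == strand and g.locus.chrom == lib.chrom
        ]
        if not gsel:
            continue
        gsel.sort(key=lambda t: t[1])
        g_idx = np.array([i for i, _ in gsel], dtype=np.int64)
        tss = np.array([t for _, t in gsel], dtype=np.int64)
        sel = np.flatnonzero(lib.strand == strand)
        if sel.size == 0:
            continue
        five = lib.five[sel]
        pos = np.searchsorted(tss, five)
        left = np.clip(pos - 1, 0, tss.size - 1)
        right = np.clip(pos, 0, tss.size - 1)
        d_left = np.abs(five - tss[left])
        d_right = np.abs(five - tss[right])
        nearest = np.where(d_right < d_left, right, left)
        dist = np.minimum(d_left, d_right)
        hit = dist <= promoter_halfwidth
        out[sel[hit]] = g_idx[nearest[hit]]
    return out


def associate_clusters(
    merged: Sequence[TTSCluster],
    tag_comp: Mapping[str, np.ndarray],
    libraries: Mapping[str, PETLibrary],
    genes: Sequence[GeneModel],
    cfg: PipelineConfig,
) -> tuple[list[TTSRecord], dict[str, np.ndarray]]:
    """Assign each merged cluster its host gene by plurality of member 5' ends."""
    n_comp = len(merged)
    n_genes = len(genes)
    votes: dict[tuple[int, int], int] = {}
    gene_of_tag: dict[str, np.ndarray] = {}
    for ct in sorted(libraries):
        lib = libraries[ct]
        g = _gene_of_tags(lib, genes, cfg.promoter_halfwidth)
        gene_of_tag[ct] = g
        comp = tag_comp[ct]
        ok = (comp >= 0) & (g >= 0)
        if not np.any(ok):
            continue
        pair = comp[ok] * n_genes + g[ok]
        uniq, counts = np.unique(pair, return_counts=True)
        for p, c in zip(uniq, counts):
            key = (int(p) // n_genes, int(p) % n_genes)
            votes[key] = votes.get(key, 0) + int(c)

    by_comp: dict[int, list[tuple[int, int]]] = {}
    for (comp_i, gene_i), v in votes.items():
        by_comp.setdefault(comp_i, []).append((gene_i, v))

    records: list[TTSRecord] = []
    for comp_i in sorted(by_comp):
        cl = merged[comp_i]
        candidates = []
        for gene_i, v in by_comp[comp_i]:
            gene = genes[gene_i]
            if gene.strand != cl.interval.strand:
                continue
            if not _peak_in_gene(cl.peak, gene, cfg.downstream_limit):
                continue
            candidates.append((-v, abs(cl.peak - gene.annotated_tss), gene.id, gene_i))
        if not candidates:
            continue
        candidates.sort()
        gene = genes[candidates[0][3]]
        loc = classify_location(
            cl.peak, gene, cluster_interval=cl.interval,
            downstream_limit=cfg.downstream_limit,
        )
        records.append(
            TTSRecord(
                cluster=cl,
                gene=gene.id,
                location_class=loc,
                ambiguous_promoter=len(candidates) > 1,
                name=f"tts{comp_i:06d}",
            )
        )
    return records, gene_of_tag


def _peak_in_gene(peak: int, gene: GeneModel, downstream_limit: int) -> bool:
    if gene.locus.contains(peak):
        return True
    d = (peak - gene.annotated_tts) * (1 if gene.strand == "+" else -1)
    return 0 < d <= downstream_limit


def assign_tes_to_records(
    records: Sequence[TTSRecord],
    tes: Sequence[TEAnnotation],
    genes_by_id: Mapping[str, GeneModel],
    cfg: PipelineConfig,
) -> None:
    """Fill the TE fields of each record in place (50/15 rule, orientation, consensus)."""
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for te in tes:
        by_chrom.setdefault(te.span.chrom, []).append(te)
    starts: dict[str, np.ndarray] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: t.span.start)
        starts[chrom] = np.array([t.span.start for t in by_chrom[chrom]], dtype=np.int64)
    max_len = max((len(t.span) for t in tes), default=0)
    reach = max_len + cfg.max_past_end + 1
    for rec in records:
        gene = genes_by_id[rec.gene]
        chrom = rec.cluster.interval.chrom
        if chrom not in by_chrom:
            continue
        s_arr = starts[chrom]
        lo = int(np.searchsorted(s_arr, rec.peak - reach))
        hi = int(np.searchsorted(s_arr, rec.peak + reach))
        cands = by_chrom[chrom][lo:hi]
        te = assign_te(
            rec.peak, cands, gene_strand=gene.strand,
            min_into_te=cfg.min_into_te, max_past_end=cfg.max_past_end,
            coordinate_mode=cfg.te_coordinate_mode,
        )
        if te is None:
            continue
        rec.te = te.id
        rec.te_family = te.family
        rec.te_orientation = relative_orientation(te, gene)
        rec.consensus_position = map_to_consensus(rec.peak, te).consensus_position


def utilization_table(
    records: Sequence[TTSRecord],
    libraries: Mapping[str, PETLibrary],
    gene_of_tag: Mapping[str, np.ndarray],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Terminated/passing counts and utilization for every record x cell type."""
    gene_index = {g.id: i for i, g in enumerate(genes)}
    per_gene: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for ct in sorted(libraries):
        lib = libraries[ct]
        g = gene_of_tag[ct]
        order = np.argsort(g, kind="stable")
        gs = g[order]
        bounds = np.searchsorted(gs, np.arange(len(genes) + 1))
        per_gene[ct] = {}
        for gi in range(len(genes)):
            a, b = bounds[gi], bounds[gi + 1]
            if a < b:
                idx = order[a:b]
                per_gene[ct][gi] = (lib.five[idx], lib.three[idx])
    rows = []
    for rec in records:
        gi = gene_index[rec.gene]
        iv = rec.cluster.interval
        sgn = 1 if iv.strand == "+" else -1
        up_edge = iv.start if sgn == 1 else iv.end - 1
        down_edge = iv.end - 1 if sgn == 1 else iv.start
        for ct in sorted(libraries):
            tags = per_gene[ct].get(gi)
            if tags is None:
                rows.append((rec.name, ct, 0, 0, np.nan))
                continue
            five, three = tags
            upstream = (five - up_edge) * sgn < 0
            t3 = three[upstream]
            term = int(np.count_nonzero((t3 >= iv.start) & (t3 < iv.end)))
            npass = int(np.count_nonzero((t3 - down_edge) * sgn > 0))
            u = utilization(term, npass)
            rows.append((rec.name, ct, term, npass, np.nan if u is None else u))
    return pd.DataFrame(
        rows, columns=["tts", "celltype", "terminated", "passing", "utilization"]
    ).set_index(["tts", "celltype"])


def gene_norm_count_table(
    libraries: Mapping[str, PETLibrary],
    gene_of_tag: Mapping[str, np.ndarray],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Per-gene PET tag counts normalized to tags per 10 million mapped."""
    data = {}
    for ct in sorted(libraries):
        g = gene_of_tag[ct]
        counts = np.bincount(g[g >= 0], minlength=len(genes))
        lib_size = max(len(libraries[ct]), 1)
        data[ct] = counts * 1e7 / lib_size
    return pd.DataFrame(data, index=[g.id for g in genes])


def specificity_table(
    records: Sequence[TTSRecord],
    util: pd.DataFrame,
    active: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Cell-type specificity for each eligible TTS over its active cell types."""
    rows = []
    for rec in records:
        try:
            sub = util.loc[rec.name]
        except KeyError:
            continue
        utils_all = {
            ct: (None if np.isnan(u) else float(u))
            for ct, u in sub["utilization"].items()
        }
        act = {ct: bool(active.loc[rec.gene, ct]) for ct in sub.index}
        if not specificity_eligible(
            utils_all, act, min_util=cfg.min_util, min_active=cfg.min_active_celltypes
        ):
            continue
        # activity gates eligibility only; the specificity sum runs over every
        # cell type with a defined utilization
        vals = [u for u in utils_all.values() if u is not None]
        if len(vals) < 2 or max(vals) <= 0:
            continue
        rows.append(
            (
                rec.name, rec.gene, rec.location_class,
                rec.te if rec.te else ".",
                rec.te_orientation if rec.te_orientation else ".",
                max(vals), len(vals), cell_type_specificity(vals),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tts", "gene", "location_class", "te", "te_orientation",
            "max_utilization", "n_active_celltypes", "specificity",
        ],
    ).set_index("tts")


def _intragenic_tes(
    tes: Sequence[TEAnnotation], genes: Sequence[GeneModel]
) -> dict[str, GeneModel]:
    """Map TE id -> host gene for TEs fully inside a gene locus."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.locus.chrom, []).append(g)
    hosts: dict[str, GeneModel] = {}
    for te in tes:
        for g in by_chrom.get(te.span.chrom, []):
            if g.locus.start <= te.span.start and te.span.end <= g.locus.end:
                hosts[te.id] = g
                break
    return hosts


def family_bias_tables(
    records: Sequence[TTSRecord],
    tes: Sequence[TEAnnotation],
    genes: Sequence[GeneModel],
    util: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Orientation-bias, observed/expected and sense-vs-antisense utilization tests."""
    hosts = _intragenic_tes(tes, genes)
    te_by_id = {te.id: te for te in tes}
    tts_te_ids = {rec.te for rec in records if rec.te is not None}

    orient_rows, obsexp_rows, contrast_rows = [], [], []
    fam_genic: dict[str, int] = {}
    fam_tts: dict[str, int] = {}
    for te_id, host in hosts.items():
        fam = te_by_id[te_id].family
        fam_genic[fam] = fam_genic.get(fam, 0) + 1
    for rec in records:
        if rec.te is not None and rec.te_family:
            fam_tts[rec.te_family] = fam_tts.get(rec.te_family, 0) + 1
    total_genic = sum(fam_genic.values())
    total_tts = sum(fam_tts.values())

    families = sorted(set(fam_genic) | set(fam_tts))
    max_util_by_tts: dict[str, float] = {}
    if util is not None:
        mx = util["utilization"].groupby(level="tts").max()
        max_util_by_tts = mx.dropna().to_dict()

    for fam in families:
        s_tts = a_tts = s_other = a_other = 0
        sense_utils, anti_utils = [], []
        for rec in records:
            if rec.te is None or rec.te_family != fam:
                continue
            if rec.te_orientation == "sense":
                s_tts += 1
                if rec.name in max_util_by_tts:
                    sense_utils.append(max_util_by_tts[rec.name])
            else:
                a_tts += 1
                if rec.name in max_util_by_tts:
                    anti_utils.append(max_util_by_tts[rec.name])
        for te_id, host in hosts.items():
            te = te_by_id[te_id]
            if te.family != fam or te_id in tts_te_ids:
                continue
            if te.span.strand == host.strand:
                s_other += 1
            else:
                a_other += 1
        res = orientation_bias_test(s_tts, a_tts, s_other, a_other, family=fam)
        orient_rows.append(
            (fam, s_tts, a_tts, s_other, a_other,
             res.ratios[0], res.ratios[1], res.chi2, res.p)
        )
        if total_tts and 0 < fam_genic.get(fam, 0) < total_genic:
            frac = fam_genic[fam] / total_genic
            oe = observed_expected_test(fam_tts.get(fam, 0), total_tts, frac, family=fam)
            obsexp_rows.append(
                (fam, fam_tts.get(fam, 0), total_tts * frac, frac, oe.chi2, oe.p)
            )
        if sense_utils and anti_utils:
            stat, p = compare_utilization_groups(sense_utils, anti_utils)
            contrast_rows.append(
                (fam, len(sense_utils), len(anti_utils),
                 float(np.median(sense_utils)), float(np.median(anti_utils)), stat, p)
            )
    orient = pd.DataFrame(
        orient_rows,
        columns=["family", "sense_tts", "antisense_tts", "sense_other",
                 "antisense_other", "ratio_tts", "ratio_other", "chi2", "p"],
    )
    obsexp = pd.DataFrame(
        obsexp_rows,
        columns=["family", "observed", "expected", "genic_fraction", "chi2", "p"],
    )
    contrasts = pd.DataFrame(
        contrast_rows,
        columns=["family", "n_sense", "n_antisense", "median_sense",
                 "median_antisense", "U", "p"],
    )
    return orient, obsexp, contrasts


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def run_analysis(
    genes: Sequence[GeneModel],
    tes: Sequence[TEAnnotation],
    libraries: Mapping[str, PETLibrary],
    cfg: PipelineConfig | None = None,
    chip_tags=None,
    chip_library_size: int | None = None,
) -> AnalysisResult:
    """Run every analysis stage on in-memory inputs and collect the results."""
    cfg = cfg or PipelineConfig()
    merged, tag_comp = discover_tts(libraries, cfg)
    records, gene_of_tag = associate_clusters(merged, tag_comp, libraries, genes, cfg)
    genes_by_id = {g.id: g for g in genes}
    assign_tes_to_records(records, tes, genes_by_id, cfg)

    util = utilization_table(records, libraries, gene_of_tag, genes)
    gene_norm = gene_norm_count_table(libraries, gene_of_tag, genes)
    _, active = transcribed_and_active(
        gene_norm, active_quantile=cfg.active_quantile, min_norm=cfg.min_norm
    )
    spec = specificity_table(records, util, active, cfg)
    orient, obsexp, contrasts = family_bias_tables(records, tes, genes, util)

    te_ids_by_ct: dict[str, set] = {ct: set() for ct in libraries}
    gene_ids_by_ct: dict[str, set] = {ct: set() for ct in libraries}
    for rec in records:
        if rec.te is None:
            continue
        for ct in rec.cluster.counts_by_celltype:
            if ct in te_ids_by_ct:
                te_ids_by_ct[ct].add(rec.name)
                gene_ids_by_ct[ct].add(rec.gene)
    rare_tts = rarefaction(te_ids_by_ct, seed=cfg.seed)
    rare_genes = rarefaction(gene_ids_by_ct, seed=cfg.seed)
    log_fit = None
    extrap: dict = {}
    if len(libraries) >= 2 and rare_tts["mean"].iloc[-1] > 0:
        log_fit = fit_log_trend(rare_tts["k"], rare_tts["mean"])
        C = len(libraries)
        observed_total = rare_tts["mean"].iloc[-1]
        for target in (2 * C, cfg.rarefaction_target_celltypes):
            if target >= C:
                pred, ratio = extrapolate_total(log_fit, C, target, observed_total)
                extrap[target] = {"predicted": pred, "ratio": ratio}

    profiles = {}
    if chip_tags is not None and chip_library_size:
        anchors = stratify_anchors(records, tes, genes)
        for name, anc in anchors.items():
            if anc:
                profiles[name] = metaprofile(
                    anc, chip_tags, chip_library_size,
                    halfwidth=cfg.metaprofile_halfwidth, bin_size=cfg.metaprofile_bin,
                )

    return AnalysisResult(
        clusters=merged,
        records=records,
        utilization=util,
        gene_norm_counts=gene_norm,
        active=active,
        specificity=spec,
        orientation_tests=orient,
        obs_exp_tests=obsexp,
        utilization_contrasts=contrasts,
        rarefaction_tts=rare_tts,
        rarefaction_genes=rare_genes,
        log_fit=log_fit,
        extrapolation=extrap,
        location_counts=summarize_location_table(records),
    )


# ---------------------------------------------------------------------------
# file-level pipeline with manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(dataclasses.asdict(cfg), sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", float_format="%.6g")


def run_pipeline(
    cfg: PipelineConfig,
    genes_path: str | Path,
    repeats_path: str | Path,
    ditag_paths: Mapping[str, str | Path],
    outdir: str | Path,
    chip_path: str | Path | None = None,
) -> AnalysisResult:
    """Execute all stages from input files into ``outdir`` with a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = read_genes_bed12(genes_path)
    tes = read_repeatmasker_out(repeats_path)
    libraries = {}
    for ct in sorted(ditag_paths):
        recs = read_ditags_bedpe(ditag_paths[ct], celltype=ct)
        libraries[ct] = library_from_records(recs, ct) if recs else PETLibrary(
            ct, genes[0].locus.chrom if genes else "",
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
            np.empty(0, dtype="U1"), np.empty(0, dtype=np.int64),
        )
    chip = None
    chip_size = None
    if chip_path is not None:
        chip_points = read_chip_bed(chip_path)
        chip = chip_points
        chip_size = len(chip_points)

    result = run_analysis(genes, tes, libraries, cfg, chip, chip_size)

    write_tts_bed(result.records, outdir / "tts.bed")
    ann = pd.DataFrame(
        [
            (
                rec.name, rec.cluster.interval.chrom, rec.cluster.interval.start,
                rec.cluster.interval.end, rec.cluster.interval.strand, rec.peak,
                rec.gene, rec.location_class, rec.te or ".", rec.te_family or ".",
                rec.te_orientation or ".",
                rec.consensus_position if rec.consensus_position is not None else ".",
            )
            for rec in result.records
        ],
        columns=["tts", "chrom", "start", "end", "strand", "peak", "gene",
                 "location_class", "te", "te_family", "te_orientation",
                 "consensus_position"],
    ).set_index("tts")
    _write_tsv(ann, outdir / "tts_annotated.tsv", cfg)
    _write_tsv(result.utilization, outdir / "utilization.tsv", cfg)
    _write_tsv(result.specificity, outdir / "specificity.tsv", cfg)
    _write_tsv(result.orientation_tests, outdir / "orientation_bias.tsv", cfg)
    _write_tsv(result.obs_exp_tests, outdir / "obs_exp.tsv", cfg)
    _write_tsv(result.utilization_contrasts, outdir / "utilization_contrasts.tsv", cfg)
    _write_tsv(result.rarefaction_tts, outdir / "rarefaction_tts.tsv", cfg)
    _write_tsv(result.rarefaction_genes, outdir / "rarefaction_genes.tsv", cfg)
    _write_tsv(result.location_counts, outdir / "location_table.tsv", cfg)
    for name, prof in result.profiles.items():
        df = pd.DataFrame(
            {"offset": prof.bin_offsets, "mean_norm_count": prof.mean_norm_count}
        )
        _write_tsv(df.set_index("offset"), outdir / f"profile_{name}.tsv", cfg)

    inputs = {"genes": str(genes_path), "repeats": str(repeats_path)}
    inputs.update({f"ditags:{ct}": str(p) for ct, p in sorted(ditag_paths.items())})
    if chip_path is not None:
        inputs["chip"] = str(chip_path)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {k: _sha256(Path(v)) for k, v in inputs.items()},
        "seed": cfg.seed,
        "versions": {
            "tetermi": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
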