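"""Evaluation of pipeline output against a planted synthetic ground truth.

The generator plants terminators with known positions and per-cell-type
termination probabilities, so recovery can be scored exactly: a planted TTS
is *recovered* when a discovered TTS on the same strand has its peak within
a small tolerance of the planted base.  The expected utilization of a
recovered TTS is derived from the generative model itself: the planted
probability of terminating there, conditioned on the transcript reaching the
cluster, with the uniform background-noise tags apportioned between the
cluster and the downstream remainder of the locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel
from .gene_annotation import TTSRecord
from .synthetic_data import GroundTruth, SimConfig, TrueTTS

__all__ = [
    "match_records_to_truth",
    "recovery_stats",
    "expected_utilization",
    "utilization_envelope",
    "te_assignment_scores",
]


def match_records_to_truth(
    records: Sequence[TTSRecord],
    truth: GroundTruth,
    tolerance: int = 5,
) -> dict[str, TTSRecord]:
    """Map each planted TTS id to its best-matching discovered record.

    A record matches when it lies on the planted strand with its peak within
    ``tolerance`` bases of the planted position; among matches the deepest
    record (largest pooled tag count) wins.
    """
    by_strand: dict[str, list[TTSRecord]] = {}
    for rec in records:
        by_strand.setdefault(rec.cluster.interval.strand, []).append(rec)
    index: dict[str, tuple[np.ndarray, list[TTSRecord]]] = {}
    for strand, recs in by_strand.items():
        recs.sort(key=lambda r: r.peak)
        index[strand] = (np.array([r.peak for r in recs], dtype=np.int64), recs)

    matches: dict[str, TTSRecord] = {}
    for t in truth.true_tts:
        got = index.get(t.strand)
        if got is None:
            continue
        peaks, recs = got
        lo = int(np.searchsorted(peaks, t.position - tolerance))
        hi = int(np.searchsorted(peaks, t.position + tolerance, side="right"))
        cands = [r for r in recs[lo:hi] if r.cluster.interval.chrom == t.chrom]
        if cands:
            matches[t.tts_id] = max(cands, key=lambda r: r.cluster.total_count)
    return matches


def _expected_max_norm(t: TrueTTS, truth: GroundTruth, config: SimConfig) -> float:
    """Highest expected normalized depth (per 10M) of a planted TTS over cell types."""
    gi = truth.gene_index[t.gene_id]
    w = truth.expression_weights[gi] / truth.expression_weights.sum(axis=0)
    depth = w * t.probs * (1.0 - config.noise_rate)
    return float(depth.max() * 1e7)


def recovery_stats(
    records: Sequence[TTSRecord],
    truth: GroundTruth,
    config: SimConfig,
    min_expected_norm: float = 40.0,
    tolerance: int = 5,
) -> dict:
    """Recovery rate of planted TTS whose expected depth clears a threshold."""
    matches = match_records_to_truth(records, truth, tolerance)
    eligible = [
        t for t in truth.true_tts
        if _expected_max_norm(t, truth, config) >= min_expected_norm
    ]
    recovered = [t for t in eligible if t.tts_id in matches]
    errs = [abs(matches[t.tts_id].peak - t.position) for t in recovered]
    return {
        "n_eligible": len(eligible),
        "n_recovered": len(recovered),
        "recovery_rate": len(recovered) / len(eligible) if eligible else float("nan"),
        "peak_abs_error_mean": float(np.mean(errs)) if errs else float("nan"),
        "matches": matches,
    }


def expected_utilization(
    t: TrueTTS,
    rec: TTSRecord,
    gene: GeneModel,
    truth: GroundTruth,
    config: SimConfig,
    celltype_index: int,
) -> float | None:
    """Expected utilization of a recovered planted TTS under the generative model.

    Terminating mass is the planted probability plus the share of uniform
    noise tags falling inside the cluster interval; passing mass is the
    planted probability of every terminator strictly downstream of the
    cluster plus the noise share downstream within the locus.
    """
    iv = rec.cluster.interval
    sgn = 1 if gene.strand == "+" else -1
    down_edge = iv.end - 1 if sgn == 1 else iv.start
    nu = config.noise_rate
    L = len(gene.locus)
    w_iv = max(0, min(iv.end, gene.locus.end) - max(iv.start, gene.locus.start))
    if sgn == 1:
        L_down = max(0, gene.locus.end - iv.end)
    else:
        L_down = max(0, iv.start - gene.locus.start)
    p_down = sum(
        o.probs[celltype_index]
        for o in truth.true_tts
        if o.gene_id == t.gene_id and (o.position - down_edge) * sgn > 0
    )
    term = (1 - nu) * t.probs[celltype_index] + nu * w_iv / L
    passing = (1 - nu) * p_down + nu * L_down / L
    if term + passing <= 0:
        return None
    return term / (term + passing)


def utilization_envelope(
    records: Sequence[TTSRecord],
    util: pd.DataFrame,
    truth: GroundTruth,
    genes: Sequence[GeneModel],
    config: SimConfig,
    min_reads: int = 50,
    n_sigma: float = 3.0,
) -> dict:
    """Fraction of recovered (TTS, cell type) pairs inside the binomial envelope.

    For each recovered planted TTS and each cell type with at least
    ``min_reads`` informative reads, checks that the estimated utilization
    lies within ``n_sigma`` binomial standard deviations of the expected
    utilization derived from the planted probabilities.
    """
    genes_by_id = {g.id: g for g in genes}
    matches = match_records_to_truth(records, truth)
    cts = truth.celltypes
    n_in = n_tot = 0
    for t in truth.true_tts:
        rec = matches.get(t.tts_id)
        if rec is None or rec.gene != t.gene_id:
            continue
        gene = genes_by_id[t.gene_id]
        try:
            sub = util.loc[rec.name]
        except KeyError:
            continue
        for c, ct in enumerate(cts):
            if ct not in sub.index:
                continue
            row = sub.loc[ct]
            n = int(row["terminated"] + row["passing"])
            if n < min_reads:
                continue
            u_exp = expected_utilization(t, rec, gene, truth, config, c)
            if u_exp is None:
                continue
            u_obs = row["terminated"] / n
            tol = n_sigma * np.sqrt(u_exp * (1 - u_exp) / n) + 1e-9
            n_tot += 1
            if abs(u_obs - u_exp) <= tol:
                n_in += 1
    return {
        "n_checked": n_tot,
        "n_within": n_in,
        "coverage": n_in / n_tot if n_tot else float("nan"),
    }


def te_assignment_scores(
    records: Sequence[TTSRecord],
    truth: GroundTruth,
    tolerance: int = 5,
) -> dict:
    """Precision/recall of TE assignment over recovered planted TTS.

    A true positive is a recovered planted TE-TTS whose record is assigned
    the planted TE id; precision is taken over all recovered planted TTS that
    received any TE assignment, recall over all recovered planted TE-TTS.
    """
    matches = match_records_to_truth(records, truth, tolerance)
    tp = fp = fn = 0
    for t in truth.true_tts:
        rec = matches.get(t.tts_id)
        if rec is None:
            continue
        if t.te_id is not None:
            if rec.te == t.te_id:
                tp += 1
            else:
                fn += 1
                if rec.te is not None:
                    fp += 1
        elif rec.te is not None:
            fp += 1
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}
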