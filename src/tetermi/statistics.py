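"""Quantitative analyses of called TTS.

* **Utilization** of a TTS in a cell type is the fraction of transcripts
  that reach it and terminate there rather than reading through:
  ``utilization = reads_terminated / (reads_terminated + reads_passing)``.
* **Cell-type specificity** is the normalized mean shortfall of a TTS's
  utilization from its maximum across cell types: 0 when a terminator is
  used equally everywhere, 1 when it is used in a single cell type only.
* Orientation-bias and observed/expected contrasts use Pearson chi-squared
  tests on 2x2 tables with one degree of freedom (no continuity correction);
  sense-versus-antisense utilization contrasts use the Wilcoxon rank-sum
  test.
* **Rarefaction** counts the distinct TTS discovered over all combinations
  of k cell types; a logarithmic trend line ``y = a ln x + b`` extrapolates
  the total beyond the sampled cell types.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formats_io import DitagRecord, GeneModel
from .gene_annotation import TTSRecord

__all__ = [
    "UtilizationRecord",
    "SpecificityRecord",
    "LogTrendFit",
    "BiasTestResult",
    "count_terminated_passing",
    "utilization",
    "transcribed_and_active",
    "specificity_eligible",
    "cell_type_specificity",
    "orientation_bias_test",
    "observed_expected_test",
    "compare_utilization_groups",
    "rarefaction",
    "fit_log_trend",
    "predict_log_trend",
    "extrapolate_total",
]


@dataclass(frozen=True)
class UtilizationRecord:
    tts_id: str
    celltype: str
    reads_terminated: int
    reads_passing: int

    @property
    def utilization(self) -> float | None:
        return utilization(self.reads_terminated, self.reads_passing)


@dataclass(frozen=True)
class SpecificityRecord:
    tts_id: str
    max_utilization: float
    utilizations: tuple[float, ...]
    celltypes: int
    specificity: float


@dataclass(frozen=True)
class LogTrendFit:
    """Least-squares fit of ``y = a ln x + b``; r correlates fit with data."""

    a: float
    b: float
    r: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


@dataclass(frozen=True)
class BiasTestResult:
    """A 2x2 chi-squared contrast (df = 1)."""

    table: tuple[tuple[float, float], tuple[float, float]]
    chi2: float | None
    p: float | None
    family: str | None = None
    df: int = 1
    ratios: tuple[float, float] | None = None

    @property
    def defined(self) -> bool:
        return self.chi2 is not None


# ---------------------------------------------------------------------------
# utilization
# ---------------------------------------------------------------------------

def count_terminated_passing(
    tts: TTSRecord,
    ditags: Iterable[DitagRecord],
    celltype: str,
    gene: GeneModel,
) -> tuple[int, int]:
    """Count reads terminating in versus reading through a TTS cluster.

    Over the gene's ditags in ``celltype`` whose 5' point lies upstream of
    the cluster in the transcription direction: *terminated* are those whose
    3' point falls inside the cluster interval, *passing* those whose 3'
    point lies strictly downstream of it.  Ditags ending upstream of the
    cluster count in neither.
    """
    iv = tts.cluster.interval
    sgn = 1 if gene.strand == "+" else -1
    up_edge = iv.start if gene.strand == "+" else iv.end - 1
    down_edge = iv.end - 1 if gene.strand == "+" else iv.start
    n_term = n_pass = 0
    for d in ditags:
        if d.celltype and celltype and d.celltype != celltype:
            continue
        c5, b5, _ = d.five_prime
        c3, b3, _ = d.three_prime
        if c5 != iv.chrom or c3 != iv.chrom:
            continue
        if (b5 - up_edge) * sgn >= 0:  # 5' not upstream of the cluster
            continue
        if iv.contains(b3):
            n_term += 1
        elif (b3 - down_edge) * sgn > 0:
            n_pass += 1
    return n_term, n_pass


def utilization(reads_terminated: int, reads_passing: int) -> float | None:
    """Terminated over terminated-plus-passing; ``None`` when no reads reach the TTS."""
    denom = reads_terminated + reads_passing
    if denom <= 0:
        return None
    return reads_terminated / denom


def transcribed_and_active(
    norm_counts: pd.DataFrame,
    active_quantile: float = 0.75,
    min_norm: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag regions as transcribed and actively transcribed per cell type.

    ``norm_counts`` is regions x cell types of PET tag counts normalized per
    10 million mapped.  A region is *transcribed* in a cell type when its
    normalized count is at least ``min_norm``, and *active* when it is
    additionally among the top ``active_quantile`` most transcribed of the
    transcribed regions in that cell type (ties kept: every region tied with
    the cutoff value is active).
    """
    transcribed = norm_counts >= min_norm
    active = pd.DataFrame(False, index=norm_counts.index, columns=norm_counts.columns)
    for ct in norm_counts.columns:
        vals = norm_counts.loc[transcribed[ct], ct].to_numpy()
        if vals.size == 0:
            continue
        k = math.ceil(active_quantile * vals.size)
        cutoff = np.sort(vals)[::-1][k - 1]
        active[ct] = transcribed[ct] & (norm_counts[ct] >= cutoff)
    return transcribed, active


def specificity_eligible(
    utils: Mapping[str, float | None],
    active: Mapping[str, bool],
    min_util: float = 0.2,
    min_active: int = 3,
) -> bool:
    """Strong-TTS filter: utilization >= 20% somewhere and active in >= 3 cell types."""
    defined = [u for u in utils.values() if u is not None]
    if not defined or max(defined) < min_util:
        return False
    return sum(bool(v) for v in active.values()) >= min_active


def cell_type_specificity(utils: Sequence[float]) -> float:
    """Mean shortfall from the maximal utilization, normalized by the maximum.

    ``[sum over the C-1 non-maximal cell types of (max - u_i)] / (C-1) / max``.
    When several cell types tie at the maximum, one is excluded from the sum
    and the rest contribute shortfall 0.  Requires >= 2 defined utilizations
    and a positive maximum.
    """
    utils = [float(u) for u in utils]
    if len(utils) < 2:
        raise ValueError("specificity needs utilizations from >= 2 cell types")
    m = max(utils)
    if m <= 0:
        raise ValueError("specificity undefined when the maximal utilization is 0")
    i_max = utils.index(m)
    shortfall = sum(m - u for i, u in enumerate(utils) if i != i_max)
    return shortfall / (len(utils) - 1) / m


# ---------------------------------------------------------------------------
# chi-squared contrasts
# ---------------------------------------------------------------------------

def _pearson_2x2(table: np.ndarray) -> tuple[float | None, float | None]:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    if total <= 0 or np.any(rows == 0) or np.any(cols == 0):
        return None, None
    expected = np.outer(rows, cols) / total
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def orientation_bias_test(
    n_sense_tts: int,
    n_antisense_tts: int,
    n_sense_other: int,
    n_antisense_other: int,
    family: str | None = None,
) -> BiasTestResult:
    """Pearson chi-squared (df=1, no continuity correction) on orientation x TTS status.

    Also reports the sense/antisense ratios of the two groups (``inf`` when a
    group has no antisense members).  A zero marginal leaves the test
    undefined.
    """
    table = np.array(
        [[n_sense_tts, n_antisense_tts], [n_sense_other, n_antisense_other]], dtype=float
    )
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    chi2, p = _pearson_2x2(table)
    ratios = (
        n_sense_tts / n_antisense_tts if n_antisense_tts else math.inf,
        n_sense_other / n_antisense_other if n_antisense_other else math.inf,
    )
    return BiasTestResult(
        table=tuple(map(tuple, table)), chi2=chi2, p=p, family=family, ratios=ratios
    )


def observed_expected_test(
    family_tts_count: int,
    total_tts: int,
    family_genic_fraction: float,
    family: str | None = None,
) -> BiasTestResult:
    """Observed versus expected family TTS counts, chi-squared with df = 1.

    The expected count is ``total_tts * family_genic_fraction`` (the family's
    share of intragenic insertions); the statistic is the Pearson sum over
    the family/rest observed-expected pairs.
    """
    if not 0.0 < family_genic_fraction < 1.0:
        raise ValueError("family_genic_fraction must lie strictly between 0 and 1")
    obs = float(family_tts_count)
    exp = total_tts * family_genic_fraction
    rest_obs = total_tts - obs
    rest_exp = total_tts - exp
    chi2 = (obs - exp) ** 2 / exp + (rest_obs - rest_exp) ** 2 / rest_exp
    p = float(sps.chi2.sf(chi2, df=1))
    return BiasTestResult(
        table=((obs, exp), (rest_obs, rest_exp)), chi2=float(chi2), p=p, family=family
    )


def compare_utilization_groups(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of two groups.

    Uses exact enumeration for small tie-free samples (both n <= 20) and the
    tie-corrected normal approximation otherwise.  Returns ``(U, p)`` with U
    counted for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefaction(
    tts_ids_by_celltype: Mapping[str, set],
    max_exact: int = 12,
    n_subsample: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean (+/- SD) number of distinct TTS over all k-cell-type combinations.

    For every k from 1 to the number of cell types, enumerates all
    C-choose-k combinations (exactly for C <= ``max_exact``, by seeded
    subsampling of at most ``n_subsample`` combinations above that) and
    returns the mean and population standard deviation of the union sizes.
    """
    cts = sorted(tts_ids_by_celltype)
    if not cts:
        raise ValueError("need at least one cell type")
    sets = [frozenset(tts_ids_by_celltype[ct]) for ct in cts]
    C = len(cts)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, C + 1):
        n_comb = math.comb(C, k)
        if C <= max_exact or n_comb <= n_subsample:
            combos = itertools.combinations(range(C), k)
        else:
            combos = (
                tuple(rng.choice(C, size=k, replace=False)) for _ in range(n_subsample)
            )
        sizes = np.array(
            [len(frozenset().union(*(sets[i] for i in combo))) for combo in combos],
            dtype=float,
        )
        rows.append((k, sizes.mean(), sizes.std()))
    return pd.DataFrame(rows, columns=["k", "mean", "sd"])


def fit_log_trend(k: Sequence[float], y: Sequence[float]) -> LogTrendFit:
    """Least-squares fit of ``y = a ln x + b``; r is the fit/data correlation."""
    x = np.log(np.asarray(k, dtype=float))
    yv = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("all x identical; slope undefined")
    A = np.column_stack([x, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(A, yv, rcond=None)
    fitted = a * x + b
    if np.ptp(yv) == 0 or np.ptp(fitted) == 0:
        r = 1.0
    else:
        r = float(np.corrcoef(fitted, yv)[0, 1])
    return LogTrendFit(a=float(a), b=float(b), r=min(max(r, -1.0), 1.0))


def predict_log_trend(fit: LogTrendFit, x: float) -> float:
    return fit.a * math.log(x) + fit.b


def extrapolate_total(
    fit: LogTrendFit,
    observed_celltypes: int,
    target_celltypes: int,
    observed_total: float | None = None,
) -> tuple[float, float]:
    """Scale the observed distinct-TTS count to a larger number of cell types.

    Returns ``(predicted_total, ratio)`` where ``ratio`` is
    ``y(target) / y(observed)`` under the fitted trend and the prediction is
    the observed total scaled by that ratio (the trend value itself when no
    observed total is given).
    """
    if not 1 <= observed_celltypes <= target_celltypes:
        raise ValueError("need target >= observed >= 1")
    y_obs = predict_log_trend(fit, observed_celltypes)
    y_tgt = predict_log_trend(fit, target_celltypes)
    if y_obs == 0:
        raise ValueError("trend value at the observed point is 0; ratio undefined")
    ratio = y_tgt / y_obs
    if observed_total is None:
        return y_tgt, ratio
    return observed_total * ratio, ratio
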