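"""Stage-wise expression summaries and the statistical calls of the analysis.

Covers the log2(FPKM+1) box-plot summaries per TE class and stage, a
Wilcoxon rank-sum test with an exact small-sample path, Benjamini-Hochberg
adjustment, and the two threshold rules: ZGA genes (|log2FC| >= 1 at 8C/MII
with padj < 0.01) and knockdown DEGs (P <= 0.05, FPKM >= 1, |log2FC| >= 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import TYPE_CHECKING, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .te import TEAssociation, TEClass

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """FPKM values (features x samples) with a stage label per sample."""

    values: pd.DataFrame  # index: feature_id, columns: sample_id
    stage_of: dict[str, str]

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.stage_of]
        if missing:
            raise ValidationError(f"samples without stage label: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stage labels in order of first appearance across samples."""
        seen: list[str] = []
        for s in self.values.columns:
            st = self.stage_of[s]
            if st not in seen:
                seen.append(st)
        return seen

    def samples_for_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.stage_of[s] == stage]


@dataclass(frozen=True)
class DifferentialRecord:
    """One gene's differential-expression result (log2FC orientation per the
    source table: 8C/MII for ZGA tables, treatment/control for knockdown)."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float
    fpkm_group1: float
    fpkm_group2: float

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"{self.gene_id}: pvalue {self.pvalue} outside [0,1]")
        if not (0.0 <= self.padj <= 1.0):
            raise ValidationError(f"{self.gene_id}: padj {self.padj} outside [0,1]")


@dataclass(frozen=True)
class StageSummary:
    """Box-plot summary of pooled log2(FPKM+1) for one TE class at one stage."""

    te_class: "TEClass"
    stage: str
    n: int
    median: float
    q1: float
    q3: float
    mean: float

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValidationError(
                f"{self.stage}: quartiles out of order ({self.q1}, {self.median}, {self.q3})"
            )


# ---------------------------------------------------------------------------
# Stage summaries
# ---------------------------------------------------------------------------

def stage_class_summary(matrix: ExpressionMatrix,
                        associations: Iterable["TEAssociation"],
                        te_class: "TEClass") -> list[StageSummary]:
    """Per-stage pooled log2(FPKM+1) summaries for features of one TE class.

    Pools every per-feature per-sample value of the class members at each
    stage; quartiles use linear interpolation. Stages with zero samples are
    omitted with a warning.
    """
    members = [a.transcript_id for a in associations if te_class in a.classes]
    unknown = [m for m in members if m not in matrix.values.index]
    if unknown:
        raise ValidationError(f"association ids not in matrix: {unknown[:5]}")
    out: list[StageSummary] = []
    if not members:
        return out
    sub = matrix.values.loc[members]
    for stage in matrix.stages:
        samples = matrix.samples_for_stage(stage)
        if not samples:
            logger.warning("stage %s has zero samples; omitted", stage)
            continue
        pooled = np.log2(sub[samples].to_numpy(dtype=float) + 1.0).ravel()
        q1, med, q3 = np.percentile(pooled, [25, 50, 75])
        out.append(StageSummary(te_class, stage, pooled.size,
                                float(med), float(q1), float(q3), float(pooled.mean())))
    return out


def stage_values(matrix: ExpressionMatrix, feature_ids: Sequence[str],
                 stage: str) -> np.ndarray:
    """Pooled log2(FPKM+1) values of *feature_ids* over samples of *stage*."""
    samples = matrix.samples_for_stage(stage)
    sub = matrix.values.loc[list(feature_ids), samples]
    return np.log2(sub.to_numpy(dtype=float) + 1.0).ravel()


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney U)
# ---------------------------------------------------------------------------

class WilcoxonResult(NamedTuple):
    u: float
    pvalue: float
    method: str  # "exact" or "normal_approx"


_ALTERNATIVES = ("two_sided", "greater", "less")

#: exact enumeration is used up to this pooled sample size (no ties)
EXACT_MAX_N = 16


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #{x_i == y_j}, via pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[: len(x)].sum()
    return float(rx - len(x) * (len(x) + 1) / 2.0)


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided",
                      method: str = "auto") -> WilcoxonResult:
    """Wilcoxon rank-sum test of two independent samples.

    The exact p-value is computed by complete enumeration of rank
    assignments when the pooled size is <= 16 and there are no ties;
    otherwise a normal approximation with tie-corrected variance and a 0.5
    continuity correction is used. ``method`` may force either path.

    ``alternative="greater"`` tests whether *x* is stochastically larger
    than *y*.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_rank_sum: both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")
    if method not in ("auto", "exact", "normal"):
        raise ValidationError("method must be auto, exact or normal")

    n, m = x.size, y.size
    big_n = n + m
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < big_n
    u = _u_statistic(x, y)

    use_exact = method == "exact" or (method == "auto" and big_n <= EXACT_MAX_N
                                      and not has_ties)
    if use_exact and has_ties:
        # tied exact enumeration is intentionally not implemented
        use_exact = False

    if use_exact:
        ranks = np.arange(1, big_n + 1)
        offset = n * (n + 1) / 2.0
        us = np.array([sum(c) - offset for c in combinations(ranks, n)])
        total = us.size
        p_ge = np.count_nonzero(us >= u) / total
        p_le = np.count_nonzero(us <= u) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(u, float(p), "exact")

    mu = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return WilcoxonResult(u, 1.0, "normal_approx")
    sd = math.sqrt(var)
    if alternative == "greater":
        p = sps.norm.sf((u - mu - 0.5) / sd)
    elif alternative == "less":
        p = sps.norm.cdf((u - mu + 0.5) / sd)
    else:
        z = (abs(u - mu) - 0.5) / sd
        p = min(1.0, 2.0 * sps.norm.sf(z))
    return WilcoxonResult(u, float(min(max(p, 0.0), 1.0)), "normal_approx")


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``padj_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the sorted
    p-values; ties and the original order are preserved in the output.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


# ---------------------------------------------------------------------------
# Threshold calls
# ---------------------------------------------------------------------------

def call_zga_genes(records: Iterable[DifferentialRecord],
                   lfc_min: float = 1.0, padj_max: float = 0.01,
                   direction: str = "absolute") -> set[str]:
    """ZGA genes from an 8C/MII-oriented table: fold-change boundary
    inclusive (|log2FC| >= lfc_min), padj boundary strict (padj < padj_max).

    ``direction="up_only"`` restricts to log2FC >= lfc_min (upregulated at
    8C relative to MII).
    """
    if direction not in ("absolute", "up_only"):
        raise ValidationError("direction must be 'absolute' or 'up_only'")
    out = set()
    for r in records:
        fc = abs(r.log2fc) if direction == "absolute" else r.log2fc
        if fc >= lfc_min and r.padj < padj_max:
            out.add(r.gene_id)
    return out


def call_degs(records: Iterable[DifferentialRecord],
              p_max: float = 0.05, fpkm_min: float = 1.0,
              lfc_min: float = 1.0) -> set[str]:
    """Knockdown-vs-control DEGs: P <= p_max, max group FPKM >= fpkm_min,
    |log2FC| >= lfc_min — all boundaries inclusive."""
    return {
        r.gene_id
        for r in records
        if r.pvalue <= p_max
        and max(r.fpkm_group1, r.fpkm_group2) >= fpkm_min
        and abs(r.log2fc) >= lfc_min
    }
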