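"""Promoter-window SINE association and permutation enrichment of DEGs.

A gene is SINE-associated when a SINE annotation overlaps the window from
2 kb upstream to 1 kb downstream of its TSS. Enrichment of SINE-associated
genes in a query set (e.g. knockdown DEGs) is assessed against a null built
by repeatedly drawing equally sized gene sets uniformly without replacement
from the annotated-gene universe. Because the draws are uniform and without
replacement, the null intersection count is exactly hypergeometric, and the
closed-form hypergeometric upper tail is reported alongside the empirical
permutation p-value as an exact cross-check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .genomic_io import GeneModel, GenomicInterval, RepeatFeature
from .te import RepeatIndex, TEClass, TEConfig, map_repeat_class


# ---------------------------------------------------------------------------
# Promoter windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterWindowSpec:
    """Promoter window extent around the TSS, in gene orientation."""

    upstream_bp: int = 2000
    downstream_bp: int = 1000

    def __post_init__(self):
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValidationError("window extents must be non-negative")
        if self.upstream_bp + self.downstream_bp < 1:
            raise ValidationError("window must have positive total extent")


def promoter_window(gene: GeneModel,
                    spec: PromoterWindowSpec = PromoterWindowSpec(),
                    chrom_length: int | None = None) -> GenomicInterval:
    """The promoter window of a gene as a genomic interval.

    On the plus strand: ``[tss - upstream, tss + downstream)``. On the
    minus strand the window is mirrored so that "upstream" lies 5' of the
    gene: ``[tss - downstream + 1, tss + upstream + 1)``. The window is
    clipped at position 0 and at *chrom_length* when known; a window that
    is entirely off-chromosome is an error.
    """
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - spec.upstream_bp, tss + spec.downstream_bp
    else:
        start, end = tss - spec.downstream_bp + 1, tss + spec.upstream_bp + 1
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:
        raise ValidationError(
            f"{gene.gene_id}: promoter window entirely off chromosome"
        )
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def sine_associated_genes(genes: Sequence[GeneModel],
                          repeats: Iterable[RepeatFeature],
                          spec: PromoterWindowSpec = PromoterWindowSpec(),
                          te_config: TEConfig = TEConfig(),
                          chrom_lengths: Mapping[str, int] | None = None,
                          te_class: TEClass = TEClass.SINE) -> set[str]:
    """Genes with >= 1 repeat of *te_class* overlapping their promoter
    window by at least ``te_config.min_overlap_bp`` (strand-blind)."""
    class_repeats = [r for r in repeats
                     if map_repeat_class(r, te_config) is te_class]
    index = RepeatIndex(class_repeats)
    out = set()
    for gene in genes:
        cl = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        win = promoter_window(gene, spec, chrom_length=cl)
        for rep in index.query(win.chrom, win.start, win.end):
            if win.overlap_bp(rep.interval) >= te_config.min_overlap_bp:
                out.add(gene.gene_id)
                break
    return out


# ---------------------------------------------------------------------------
# Permutation enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentConfig:
    n_trials: int = 10_000
    seed: int = 0
    draw_size: int | None = None  # defaults to |query|
    sample_without_replacement: bool = True

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if not self.sample_without_replacement:
            raise ValidationError("trials sample without replacement by design")


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    null_counts: tuple[int, ...]
    empirical_p: float
    normal_approx_p: float
    null_mean: float
    null_sd: float
    upper5_threshold: int
    hypergeom_p: float
    universe_size: int
    n_sine_assoc_universe: int
    draw_size: int

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "normal_approx_p": self.normal_approx_p,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "upper5_threshold": self.upper5_threshold,
            "hypergeom_p": self.hypergeom_p,
            "universe_size": self.universe_size,
            "n_sine_assoc_universe": self.n_sine_assoc_universe,
            "draw_size": self.draw_size,
            "n_trials": len(self.null_counts),
        }
        if include_null:
            d["null_counts"] = list(self.null_counts)
        return d

    def to_json(self, path, include_null: bool = False) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_null=include_null), fh,
                      indent=2, sort_keys=True)
            fh.write("\n")


def null_upper_quantile(null_counts: Sequence[int], tail: float = 0.05) -> int:
    """Nearest-rank upper quantile: the ceil((1-tail)*N)-th smallest value.

    With ``tail=0.05`` this is the value the observed count must exceed to
    sit in the null's upper 5%.
    """
    counts = sorted(null_counts)
    if not counts:
        raise ValidationError("null_counts must be non-empty")
    if not (0.0 < tail < 1.0):
        raise ValidationError("tail must lie in (0, 1)")
    k = math.ceil((1.0 - tail) * len(counts))
    return int(counts[k - 1])


def permutation_enrichment(query: Iterable[str], universe: Iterable[str],
                           sine_set: Iterable[str],
                           config: EnrichmentConfig = EnrichmentConfig(),
                           ) -> EnrichmentResult:
    """Permutation test of SINE-associated-gene enrichment in *query*.

    Each trial draws ``draw_size`` genes (default: |query|) uniformly
    without replacement from *universe* and records how many fall in
    *sine_set*. The empirical p uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_trials)``, with ties counting
    toward significance. A normal upper-tail p at the null's moments and
    the exact hypergeometric upper tail are reported alongside. The query
    genes remain part of the sampling universe (plain random gene draws).
    Reproducible given ``config.seed``.
    """
    query = set(query)
    universe_list = sorted(set(universe))
    universe = set(universe_list)
    sine_set = set(sine_set)
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    if not sine_set <= universe:
        raise ValidationError("sine_set must be a subset of the universe")
    draw_size = config.draw_size if config.draw_size is not None else len(query)
    if not (1 <= draw_size <= len(universe_list)):
        raise ValidationError(
            f"draw_size {draw_size} must lie in [1, |universe|={len(universe_list)}]"
        )

    observed = len(query & sine_set)
    is_sine = np.fromiter((g in sine_set for g in universe_list), dtype=bool,
                          count=len(universe_list))
    rng = np.random.default_rng(config.seed)
    n = len(universe_list)
    null = np.empty(config.n_trials, dtype=np.int64)
    for i in range(config.n_trials):
        idx = rng.choice(n, size=draw_size, replace=False, shuffle=False)
        null[i] = int(is_sine[idx].sum())

    empirical_p = (1 + int((null >= observed).sum())) / (1 + config.n_trials)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if config.n_trials > 1 else 0.0
    if null_sd > 0:
        normal_p = float(sps.norm.sf(observed, loc=null_mean, scale=null_sd))
    else:
        normal_p = 1.0 if observed <= null_mean else 0.0
    hyper_p = float(sps.hypergeom.sf(observed - 1, n, len(sine_set), draw_size))

    return EnrichmentResult(
        observed=observed,
        null_counts=tuple(int(c) for c in null),
        empirical_p=empirical_p,
        normal_approx_p=normal_p,
        null_mean=null_mean,
        null_sd=null_sd,
        upper5_threshold=null_upper_quantile(null, 0.05),
        hypergeom_p=hyper_p,
        universe_size=n,
        n_sine_assoc_universe=len(sine_set),
        draw_size=draw_size,
    )
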