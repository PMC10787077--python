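"""Synthetic fixtures with the statistical structure the analysis assumes.

Generates gene models, RepeatMasker-style repeats with controllable SINE
density near promoters, assembled-transcript models spanning the lncRNA
filter boundaries, three-predictor coding verdicts, stage-structured
log-normal FPKM with TE-class-specific stage effects, and differential-
expression tables with a planted DEG set of controllable SINE-association
enrichment. Every generator is a pure function of (config, seed): one root
seed drives independent named substreams, so regenerating one layer never
perturbs another.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError, ValidationError
from .genomic_io import (
    CodingVerdicts,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    TranscriptModel,
    write_coding_verdicts,
    write_de_table,
    write_expression_table,
    write_gtf,
    write_rmsk,
)
from .stats import DifferentialRecord, ExpressionMatrix, benjamini_hochberg
from .te import TEClass
from .enrichment import PromoterWindowSpec, promoter_window

# named substreams; the offsets keep layers independent under one root seed
_STREAMS = {"genes": 11, "repeats": 23, "transcripts": 37, "expression": 53,
            "de": 71, "zga": 89}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


_REP_NAMES = {"SINE": ("PRE1", "Pre0_SS"), "LINE": ("L1MB7", "L1_SS"),
              "LTR": ("ERV1-1_SSc", "ERVL-SSc"), "DNA": ("hAT-Charlie", "MER5")}
_REP_FAMILIES = {"SINE": "tRNA", "LINE": "L1", "LTR": "ERVL", "DNA": "hAT"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome and transcriptome.

    Defaults follow the analysis design: a 2,000-gene universe, a planted
    10% gene subset whose promoters carry a SINE with probability 0.8
    against a 0.4 background, and a 200-gene DEG set drawn as that planted
    subset; SINE-class transcripts are elevated at the 4- and 8-cell
    stages, the zygotic genome activation window in pig.
    """

    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length_bp: int = 8_000_000
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (2000, 10_000)
    strand_prob_plus: float = 0.5
    # repeats
    repeat_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"SINE": 0.45, "LINE": 0.30, "LTR": 0.15, "DNA": 0.10})
    n_background_repeats: int = 4000
    repeat_length_range: tuple[int, int] = (100, 400)
    background_promoter_sine_prob: float = 0.4
    planted_fraction: float = 0.1
    planted_promoter_sine_prob: float = 0.8
    # transcripts
    n_lnc_transcripts: int = 300
    class_code_mix: Mapping[str, float] = field(
        default_factory=lambda: {"u": 0.25, "x": 0.10, "i": 0.10, "j": 0.15,
                                 "o": 0.10, "=": 0.20, "c": 0.10})
    exon_count_range: tuple[int, int] = (1, 6)
    transcript_length_range: tuple[int, int] = (150, 3000)
    noncoding_agreement_prob: float = 0.7
    # expression
    stages: tuple[tuple[str, int], ...] = (("GV", 3), ("MII", 3), ("2C", 3),
                                           ("4C", 3), ("8C", 3), ("MO", 3),
                                           ("BL", 3))
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.0
    te_stage_effect: Mapping[tuple[TEClass, str], float] = field(
        default_factory=lambda: {(TEClass.SINE, "4C"): 1.0,
                                 (TEClass.SINE, "8C"): 2.0})
    # differential expression
    deg_count: int = 200
    deg_lfc_mean: float = 2.5
    deg_lfc_sd: float = 0.8
    deg_up_prob: float = 0.6
    deg_from_sine_prob: float | None = None
    zga_count: int = 150

    def __post_init__(self):
        for name in ("strand_prob_plus", "background_promoter_sine_prob",
                     "planted_promoter_sine_prob", "noncoding_agreement_prob",
                     "deg_up_prob", "planted_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for mix_name in ("repeat_class_mix", "class_code_mix"):
            mix = getattr(self, mix_name)
            if any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
                raise ValidationError(f"{mix_name} weights must be non-negative, not all zero")


def _weighted_choice(rng: np.random.Generator, mix: Mapping[str, float], size: int
                     ) -> list[str]:
    keys = list(mix.keys())
    w = np.array([mix[k] for k in keys], dtype=float)
    return [keys[i] for i in rng.choice(len(keys), size=size, p=w / w.sum())]


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def generate_genes(config: SimConfig) -> list[GeneModel]:
    """Non-overlapping gene spans packed left-to-right per chromosome.

    Genes are assigned to chromosomes round-robin; spans start 10 kb into
    the chromosome so that every promoter window stays on-chromosome.
    """
    rng = _rng(config.seed, "genes")
    per_chrom = [0] * config.n_chroms
    for i in range(config.n_genes):
        per_chrom[i % config.n_chroms] += 1
    genes: list[GeneModel] = []
    gid = 0
    lo, hi = config.gene_length_range
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 10_000
        for _ in range(per_chrom[ci]):
            length = int(rng.integers(lo, hi + 1))
            # gaps exceed twice the default promoter upstream extent so that
            # promoter windows of neighbouring genes never overlap and a
            # promoter-planted repeat is attributable to exactly one gene
            gap = int(rng.integers(4100, 8001))
            end = pos + length
            if end + 10_000 > config.chrom_length_bp:
                raise GenerationError(
                    f"cannot place {config.n_genes} genes on "
                    f"{config.n_chroms} x {config.chrom_length_bp} bp chromosomes; "
                    "increase chrom_length_bp or n_chroms"
                )
            strand = "+" if rng.random() < config.strand_prob_plus else "-"
            gid += 1
            genes.append(GeneModel(f"G{gid:05d}", chrom, strand,
                                   GenomicInterval(chrom, pos, end, strand)))
            pos = end + gap
    return genes


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------

def generate_repeats(genes: Sequence[GeneModel], config: SimConfig
                     ) -> tuple[list[RepeatFeature], set[str]]:
    """RepeatMasker-style repeats with two promoter-SINE rates.

    A randomly chosen planted subset (``planted_fraction`` of the genes)
    receives a SINE inside its promoter window with probability
    ``planted_promoter_sine_prob``; the remaining genes with
    ``background_promoter_sine_prob``. Additional repeats are scattered
    uniformly with classes drawn from ``repeat_class_mix``. Returns the
    repeats and the planted subset's gene ids (the test oracle).
    """
    rng = _rng(config.seed, "repeats")
    n_planted = math.ceil(config.planted_fraction * len(genes))
    gene_ids = [g.gene_id for g in genes]
    planted = set(rng.choice(gene_ids, size=n_planted, replace=False)) if n_planted else set()
    spec = PromoterWindowSpec()
    lo, hi = config.repeat_length_range
    repeats: list[RepeatFeature] = []

    for gene in genes:
        p = (config.planted_promoter_sine_prob if gene.gene_id in planted
             else config.background_promoter_sine_prob)
        if rng.random() >= p:
            continue
        win = promoter_window(gene, spec, chrom_length=config.chrom_length_bp)
        length = int(rng.integers(lo, hi + 1))
        if win.length > length:
            start = int(rng.integers(win.start, win.end - length + 1))
        else:
            start = win.start
        name = _REP_NAMES["SINE"][int(rng.integers(0, 2))]
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(RepeatFeature(
            GenomicInterval(gene.chrom, start, start + length, strand),
            rep_name=name, rep_class="SINE", rep_family=_REP_FAMILIES["SINE"]))

    classes = _weighted_choice(rng, dict(config.repeat_class_mix),
                               config.n_background_repeats)
    for rc in classes:
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, config.chrom_length_bp - length))
        name = _REP_NAMES.get(rc, (rc, rc))[int(rng.integers(0, 2))]
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(RepeatFeature(
            GenomicInterval(chrom, start, start + length, strand),
            rep_name=name, rep_class=rc,
            rep_family=_REP_FAMILIES.get(rc, rc)))
    return repeats, planted


# ---------------------------------------------------------------------------
# Transcripts and coding verdicts
# ---------------------------------------------------------------------------

def _build_exons(rng: np.random.Generator, chrom: str, strand: str,
                 spliced_length: int, n_exons: int, chrom_length: int
                 ) -> tuple[GenomicInterval, ...]:
    # split the spliced length into n_exons positive parts
    if n_exons > spliced_length:
        n_exons = spliced_length
    if n_exons == 1:
        parts = [spliced_length]
    else:
        cuts = sorted(rng.choice(np.arange(1, spliced_length), size=n_exons - 1,
                                 replace=False))
        parts = [b - a for a, b in zip([0] + list(cuts), list(cuts) + [spliced_length])]
    introns = [int(rng.integers(50, 501)) for _ in range(n_exons - 1)]
    span = sum(parts) + sum(introns)
    start = int(rng.integers(1000, chrom_length - span - 1000))
    exons = []
    pos = start
    for i, p in enumerate(parts):
        exons.append(GenomicInterval(chrom, pos, pos + p, strand))
        pos += p + (introns[i] if i < len(introns) else 0)
    return tuple(exons)


def generate_lnc_transcripts(config: SimConfig
                             ) -> tuple[list[TranscriptModel], list[CodingVerdicts]]:
    """Assembled-transcript models plus three-predictor coding verdicts.

    Class codes, exon counts and spliced lengths are drawn from the
    configured mixes. When ``n_lnc_transcripts >= 20`` the first four
    transcripts pin the filter boundaries: spliced lengths 199 and 200,
    and exon counts 1 and 2 (class codes still come from the mix). Verdicts
    are unanimous non-coding with probability ``noncoding_agreement_prob``.
    """
    rng = _rng(config.seed, "transcripts")
    n = config.n_lnc_transcripts
    codes = _weighted_choice(rng, dict(config.class_code_mix), n)
    elo, ehi = config.exon_count_range
    llo, lhi = config.transcript_length_range
    boundary = [(199, 2), (200, 2), (400, 1), (400, 2)]
    transcripts: list[TranscriptModel] = []
    verdicts: list[CodingVerdicts] = []
    for i in range(n):
        code = codes[i]
        if n >= 20 and i < len(boundary):
            length, n_exons = boundary[i]
        else:
            length = int(rng.integers(llo, lhi + 1))
            n_exons = int(rng.integers(elo, ehi + 1))
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        strand = "+" if rng.random() < config.strand_prob_plus else "-"
        exons = _build_exons(rng, chrom, strand, length, n_exons,
                             config.chrom_length_bp)
        tid = f"TX{i + 1:05d}"
        transcripts.append(TranscriptModel(tid, f"XLOC_{i + 1:05d}", chrom,
                                           strand, exons, class_code=code))
        if rng.random() < config.noncoding_agreement_prob:
            flags = (True, True, True)
        else:
            coding_tool = int(rng.integers(0, 3))
            flags = tuple(j != coding_tool for j in range(3))
        verdicts.append(CodingVerdicts(tid, flags))
    return transcripts, verdicts


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(transcripts: Sequence[TranscriptModel],
                        associations: Sequence,
                        config: SimConfig) -> ExpressionMatrix:
    """Stage-structured log-normal FPKM with TE-class stage effects.

    ``FPKM = exp(N(lognormal_mu, lognormal_sigma)) * 2^(sum of applicable
    te_stage_effect terms)`` per feature and sample; the effect applies to
    every (class, stage) pair the feature's TE classes match.
    """
    import pandas as pd

    rng = _rng(config.seed, "expression")
    classes_of = {a.transcript_id: a.classes for a in associations}
    samples, stage_of = [], {}
    for stage, reps in config.stages:
        for r in range(1, reps + 1):
            sid = f"{stage}_{r}"
            samples.append(sid)
            stage_of[sid] = stage
    values = np.empty((len(transcripts), len(samples)))
    for fi, t in enumerate(transcripts):
        cls = classes_of.get(t.transcript_id, frozenset())
        for si, sid in enumerate(samples):
            eff = sum(v for (c, s), v in config.te_stage_effect.items()
                      if c in cls and s == stage_of[sid])
            base = math.exp(rng.normal(config.lognormal_mu, config.lognormal_sigma))
            values[fi, si] = base * 2.0 ** eff
    df = pd.DataFrame(values, index=[t.transcript_id for t in transcripts],
                      columns=samples)
    df.index.name = "feature_id"
    return ExpressionMatrix(values=df, stage_of=stage_of)


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def generate_de_table(genes: Sequence[GeneModel], sine_set: set[str],
                      config: SimConfig, *,
                      deg_gene_ids: Sequence[str] | None = None,
                      deg_count: int | None = None,
                      stream: str = "de",
                      ) -> tuple[list[DifferentialRecord], set[str]]:
    """A DE table with a planted DEG set; all other genes are null.

    Planted genes get |log2FC| = max(1, |N(deg_lfc_mean, deg_lfc_sd)|),
    p ~ U(0, 1e-4) and a group FPKM >= 1, so they clear the DEG thresholds;
    null genes get log2FC ~ N(0, 0.3) and p ~ U(0, 1). padj is
    Benjamini-Hochberg over all rows. When *deg_gene_ids* is omitted the
    DEG set is sampled: each DEG comes from *sine_set* with probability
    ``deg_from_sine_prob`` (uniformly from the whole universe when that is
    None).
    """
    rng = _rng(config.seed, stream)
    gene_ids = [g.gene_id for g in genes]
    n_deg = deg_count if deg_count is not None else config.deg_count
    if n_deg > len(gene_ids):
        raise GenerationError(f"deg_count {n_deg} exceeds n_genes {len(gene_ids)}")

    if deg_gene_ids is not None:
        degs = set(deg_gene_ids)
        if not degs <= set(gene_ids):
            raise ValidationError("deg_gene_ids must be a subset of the gene set")
    elif config.deg_from_sine_prob is None:
        degs = set(rng.choice(gene_ids, size=n_deg, replace=False))
    else:
        sine_pool = [g for g in gene_ids if g in sine_set]
        other_pool = [g for g in gene_ids if g not in sine_set]
        rng.shuffle(sine_pool)
        rng.shuffle(other_pool)
        degs = set()
        for _ in range(n_deg):
            take_sine = rng.random() < config.deg_from_sine_prob
            pool = sine_pool if (take_sine and sine_pool) else other_pool
            if not pool:
                pool = sine_pool
            degs.add(pool.pop())

    records = []
    pvals = []
    rows = []
    for gid in gene_ids:
        if gid in degs:
            mag = max(1.0, abs(rng.normal(config.deg_lfc_mean, config.deg_lfc_sd)))
            lfc = mag if rng.random() < config.deg_up_prob else -mag
            p = float(rng.uniform(0.0, 1e-4))
            f1 = max(1.0, float(rng.lognormal(1.0, 0.8)))
            f2 = f1 / 2.0 ** lfc
        else:
            lfc = float(rng.normal(0.0, 0.3))
            p = float(rng.uniform())
            f1 = float(rng.lognormal(0.5, 1.0))
            f2 = f1 / 2.0 ** lfc
        rows.append((gid, lfc, f1, f2))
        pvals.append(p)
    padj = benjamini_hochberg(pvals)
    for (gid, lfc, f1, f2), p, q in zip(rows, pvals, padj):
        records.append(DifferentialRecord(gid, lfc, p, q, f1, f2))
    return records, degs


# ---------------------------------------------------------------------------
# Full fixture
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    repeats: list[RepeatFeature]
    planted_genes: set[str]
    transcripts: list[TranscriptModel]
    verdicts: list[CodingVerdicts]
    expression: ExpressionMatrix
    de_records: list[DifferentialRecord]
    planted_degs: set[str]
    zga_records: list[DifferentialRecord]
    planted_zga: set[str]


def simulate_all(config: SimConfig = SimConfig()) -> SimResult:
    """Generate the complete fixture.

    The knockdown DEG set is the planted promoter-SINE-enriched gene
    subset, so the end-to-end enrichment test has known ground truth; the
    ZGA table plants an independent uniformly drawn gene set.
    """
    from .te import TEConfig, classify_transcripts

    genes = generate_genes(config)
    repeats, planted = generate_repeats(genes, config)
    transcripts, verdicts = generate_lnc_transcripts(config)
    associations = classify_transcripts(transcripts, repeats, TEConfig())
    expression = generate_expression(transcripts, associations, config)
    de_records, planted_degs = generate_de_table(
        genes, set(), config, deg_gene_ids=sorted(planted)[: config.deg_count])
    zga_records, planted_zga = generate_de_table(
        genes, set(), config, deg_count=config.zga_count, stream="zga")
    return SimResult(config, genes, repeats, planted, transcripts, verdicts,
                     expression, de_records, planted_degs, zga_records,
                     planted_zga)


def write_fixture(result: SimResult, outdir) -> dict[str, Path]:
    """Write the fixture directory consumed by the pipeline CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in {
        "genes_gtf": "genes.gtf", "transcripts_gtf": "transcripts.gtf",
        "rmsk": "repeats.rmsk.tsv", "verdicts": "coding_verdicts.tsv",
        "expression": "expression.tsv", "stage_map": "stage_map.tsv",
        "de_table": "de_table.tsv", "zga_table": "zga_table.tsv",
        "truth": "truth.json"}.items()}

    gene_tx = [TranscriptModel(f"{g.gene_id}.t1", g.gene_id, g.chrom, g.strand,
                               (g.span,), class_code="=") for g in result.genes]
    write_gtf(gene_tx, paths["genes_gtf"])
    write_gtf(result.transcripts, paths["transcripts_gtf"])
    write_rmsk(result.repeats, paths["rmsk"])
    write_coding_verdicts(result.verdicts, paths["verdicts"])
    write_expression_table(result.expression, paths["expression"],
                           stage_map_path=paths["stage_map"])
    write_de_table(result.de_records, paths["de_table"])
    write_de_table(result.zga_records, paths["zga_table"])
    truth = {
        "seed": result.config.seed,
        "planted_genes": sorted(result.planted_genes),
        "planted_degs": sorted(result.planted_degs),
        "planted_zga": sorted(result.planted_zga),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
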