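"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals;
conversions to and from 1-based closed GTF happen only at the I/O boundary.
The UCSC rmsk table and BED are already 0-based half-open and pass through
unchanged.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, SchemaError, ValidationError
from .stats import DifferentialRecord, ExpressionMatrix

logger = logging.getLogger(__name__)

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

#: attribute key under which gffcompare-style class codes are expected
DEFAULT_CLASS_CODE_ATTR = "class_code"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    Empty and negative-length intervals are rejected at construction, so a
    valid interval always has ``length >= 1``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty/inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Width of the intersection with *other*; 0 on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: exons on one chromosome and strand, plus the
    gffcompare-style class code describing its relation to the reference
    annotation (u = intergenic, x = antisense, i = intronic, j = novel
    isoform, o = other exonic overlap)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    class_code: str = "."

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for e in exons:
            if e.chrom != self.chrom:
                raise ValidationError(
                    f"{self.transcript_id}: exon on {e.chrom}, transcript on {self.chrom}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with a strand-aware transcription start site.

    On the plus strand the TSS is ``span.start``; on the minus strand it is
    ``span.end - 1``, the 5'-most base in 0-based coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: gene strand must be + or -")

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker annotation record (rmsk table row)."""

    interval: GenomicInterval
    rep_name: str
    rep_class: str
    rep_family: str = ""

    def __post_init__(self):
        if not self.rep_class:
            raise ValidationError(f"repeat {self.rep_name}: empty rep_class")


@dataclass(frozen=True)
class CodingVerdicts:
    """Non-coding calls from three coding-potential predictors for one
    transcript; True means the predictor called the transcript non-coding."""

    transcript_id: str
    verdicts: tuple[bool, bool, bool]

    def __post_init__(self):
        if len(self.verdicts) != 3:
            raise ValidationError(
                f"{self.transcript_id}: exactly three predictor verdicts required, "
                f"got {len(self.verdicts)}"
            )

    @property
    def all_noncoding(self) -> bool:
        return all(self.verdicts)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gtf(path, class_code_attr: str = DEFAULT_CLASS_CODE_ATTR):
    """Parse exon features from a GTF file.

    Returns ``(transcripts, genes)``. GTF's 1-based closed coordinates are
    converted to 0-based half-open. Transcripts are grouped by
    ``transcript_id`` with exons sorted by start; genes are derived as the
    union span of their transcripts. The class code is taken from the
    attribute *class_code_attr* when present, else ".".
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gid, chrom, strand, code)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates")
            if end1 < start1:
                raise FormatError(f"{path}: line {lineno}: end {end1} < start {start1}")
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            try:
                tid = attr["transcript_id"]
                gid = attr["gene_id"]
            except KeyError as e:
                raise FormatError(f"{path}: line {lineno}: missing attribute {e}")
            code = attr.get(class_code_attr, ".")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if tid in meta:
                g, c, s, old_code = meta[tid]
                if c != chrom:
                    raise ValidationError(f"{tid}: exons on multiple chromosomes")
                if s != strand:
                    raise ValidationError(f"{tid}: mixed strands within one transcript")
                if old_code == "." and code != ".":
                    meta[tid] = (g, c, s, code)
            else:
                meta[tid] = (gid, chrom, strand, code)
            exons.setdefault(tid, []).append(iv)

    transcripts = [
        TranscriptModel(tid, gid, chrom, strand, tuple(sorted(ivs, key=lambda e: e.start)),
                        class_code=code)
        for tid, ivs in exons.items()
        for gid, chrom, strand, code in (meta[tid],)
    ]

    genes = derive_genes(transcripts)
    return transcripts, genes


def derive_genes(transcripts: Sequence[TranscriptModel]) -> list[GeneModel]:
    """Union-span gene models from transcripts grouped by ``gene_id``."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = []
    for gid, txs in by_gene.items():
        chroms = {t.chrom for t in txs}
        strands = {t.strand for t in txs}
        if len(chroms) > 1:
            raise ValidationError(f"gene {gid}: transcripts on multiple chromosomes")
        if len(strands) > 1:
            raise ValidationError(f"gene {gid}: transcripts on both strands")
        start = min(t.span.start for t in txs)
        end = max(t.span.end for t in txs)
        strand = strands.pop()
        genes.append(
            GeneModel(gid, chroms.pop(), strand,
                      GenomicInterval(txs[0].chrom, start, end, strand))
        )
    return genes


def write_gtf(transcripts: Iterable[TranscriptModel], path,
              source: str = "telncrna",
              class_code_attr: str = DEFAULT_CLASS_CODE_ATTR) -> None:
    """Write exon lines in GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'{class_code_attr} "{t.class_code}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# UCSC rmsk
# ---------------------------------------------------------------------------

# column offsets after the optional leading bin column
_RMSK_GENONAME, _RMSK_GENOSTART, _RMSK_GENOEND = 4, 5, 6
_RMSK_STRAND, _RMSK_REPNAME, _RMSK_REPCLASS, _RMSK_REPFAMILY = 8, 9, 10, 11


def read_rmsk(path) -> list[RepeatFeature]:
    """Read a UCSC rmsk table (tab-separated, plain or gzip).

    Both the 17-column dialect (leading ``bin``) and the 16-column dialect
    are accepted; the layout is auto-detected per row from the column count.
    ``genoStart`` is already 0-based and ``genoEnd`` exclusive. Rows with
    ``genoEnd <= genoStart`` are skipped with a logged warning.
    """
    repeats: list[RepeatFeature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 17:
                off = 1
            elif len(fields) == 16:
                off = 0
            else:
                raise FormatError(
                    f"{path}: line {lineno}: rmsk rows have 16 or 17 columns, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[off + _RMSK_GENOSTART])
                end = int(fields[off + _RMSK_GENOEND])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates")
            if end <= start:
                logger.warning(
                    "%s: line %d: genoEnd %d <= genoStart %d, row skipped",
                    path, lineno, end, start,
                )
                continue
            strand = fields[off + _RMSK_STRAND]
            repeats.append(
                RepeatFeature(
                    GenomicInterval(
                        fields[off + _RMSK_GENONAME], start, end,
                        strand if strand in ("+", "-") else ".",
                    ),
                    rep_name=fields[off + _RMSK_REPNAME],
                    rep_class=fields[off + _RMSK_REPCLASS],
                    rep_family=fields[off + _RMSK_REPFAMILY],
                )
            )
    return repeats


def write_rmsk(repeats: Iterable[RepeatFeature], path, with_bin: bool = True) -> None:
    """Write repeats in the UCSC rmsk tab-separated dialect."""
    with open(path, "w") as fh:
        for i, r in enumerate(repeats):
            row = [
                "1000", "0", "0", "0",
                r.interval.chrom, str(r.interval.start), str(r.interval.end), "0",
                r.interval.strand if r.interval.strand != "." else "+",
                r.rep_name, r.rep_class, r.rep_family,
                "1", str(r.interval.length), "0", str(i),
            ]
            if with_bin:
                row.insert(0, "0")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

def read_stage_map(path) -> dict[str, str]:
    """Two-column TSV (sample_id, stage) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "stage"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["sample_id"], df["stage"]))


def read_expression_table(path, stage_map: dict[str, str] | str | Path) -> ExpressionMatrix:
    """FPKM table (feature_id then one column per sample) plus its stage map.

    *stage_map* may be a ``sample_id -> stage`` mapping or a path to a
    two-column TSV. Every sample column must have a stage.
    """
    if not isinstance(stage_map, dict):
        stage_map = read_stage_map(stage_map)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "feature_id":
        raise SchemaError(f"{path}: first column must be 'feature_id', got {df.columns[0]!r}")
    if df["feature_id"].duplicated().any():
        dups = df["feature_id"][df["feature_id"].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate feature_id(s): {dups[:5]}")
    values = df.set_index("feature_id").astype(float)
    unmapped = [s for s in values.columns if s not in stage_map]
    if unmapped:
        raise SchemaError(f"{path}: samples missing from stage map: {unmapped}")
    return ExpressionMatrix(values=values,
                            stage_of={s: stage_map[s] for s in values.columns})


def write_expression_table(matrix: ExpressionMatrix, path, stage_map_path=None) -> None:
    df = matrix.values.copy()
    df.insert(0, "feature_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if stage_map_path is not None:
        with open(stage_map_path, "w") as fh:
            fh.write("sample_id\tstage\n")
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.stage_of[s]}\n")


_DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj", "fpkm_group1", "fpkm_group2"]


def read_de_table(path) -> list[DifferentialRecord]:
    """Differential-expression result table (one row per gene)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_DE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id rows")
    return [
        DifferentialRecord(
            gene_id=str(r.gene_id), log2fc=float(r.log2fc),
            pvalue=float(r.pvalue), padj=float(r.padj),
            fpkm_group1=float(r.fpkm_group1), fpkm_group2=float(r.fpkm_group2),
        )
        for r in df.itertuples(index=False)
    ]


def write_de_table(records: Iterable[DifferentialRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.log2fc!r}\t{r.pvalue!r}\t{r.padj!r}\t"
                f"{r.fpkm_group1!r}\t{r.fpkm_group2!r}\n"
            )


def read_coding_verdicts(path) -> list[CodingVerdicts]:
    """Verdict TSV: transcript_id then three boolean non-coding flags."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"transcript_id", "tool1", "tool2", "tool3"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df["transcript_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate verdict rows")

    def to_bool(v: str) -> bool:
        s = str(v).strip().lower()
        if s in ("true", "1", "noncoding", "nocoding", "yes"):
            return True
        if s in ("false", "0", "coding", "no"):
            return False
        raise FormatError(f"{path}: unrecognized verdict value {v!r}")

    return [
        CodingVerdicts(str(r.transcript_id),
                       (to_bool(r.tool1), to_bool(r.tool2), to_bool(r.tool3)))
        for r in df.itertuples(index=False)
    ]


def write_coding_verdicts(verdicts: Iterable[CodingVerdicts], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\ttool1\ttool2\ttool3\n")
        for v in verdicts:
            fh.write(v.transcript_id + "\t" + "\t".join(str(b) for b in v.verdicts) + "\n")


def write_bed(intervals: Iterable[GenomicInterval], path,
              names: Sequence[str] | None = None) -> None:
    """BED6: 0-based half-open, name '.' unless given, score 0, strand col 6."""
    intervals = list(intervals)
    if names is not None and len(names) != len(intervals):
        raise ValidationError("names must match intervals in length")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >= 3 columns")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_report_tsv(records: Iterable[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous dict records as TSV; None becomes ".", floats keep
    full precision."""
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else []

    def fmt(v):
        if v is None:
            return "."
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(fmt(rec.get(c)) for c in columns) + "\n")
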