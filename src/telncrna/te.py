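"""TE-class association of transcripts from exon-repeat overlap.

Transcripts are classified into four retrotransposon-centric classes —
SINE, LINE, ERV, OTHER_REPEAT — according to the RepeatMasker annotations
overlapping their exons. UCSC rmsk tables annotate endogenous retroviruses
under repClass "LTR" (families ERV1/ERVK/ERVL), which maps to the ERV
class here. Membership is non-exclusive by default: a transcript counts in
every class whose repeats its exons overlap. Overlap is strand-blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .genomic_io import RepeatFeature, TranscriptModel


class TEClass(Enum):
    SINE = "SINE"
    LINE = "LINE"
    ERV = "ERV"
    OTHER_REPEAT = "OTHER_REPEAT"


#: sentinel accepted in ``class_map_overrides`` to drop a repeat class
EXCLUDE = "EXCLUDE"

#: tie-break priority for exclusive (dominant-class) assignment
_CLASS_PRIORITY = (TEClass.SINE, TEClass.LINE, TEClass.ERV, TEClass.OTHER_REPEAT)


@dataclass(frozen=True)
class TEConfig:
    min_overlap_bp: int = 1
    class_map_overrides: Mapping[str, "TEClass | str"] = field(default_factory=dict)
    excluded_rep_classes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.min_overlap_bp < 1:
            raise ValidationError("min_overlap_bp must be >= 1")
        object.__setattr__(self, "excluded_rep_classes",
                           frozenset(self.excluded_rep_classes))


@dataclass(frozen=True)
class TEAssociation:
    """Per-transcript TE association: distinct overlapping repeats and total
    exonic overlap per class; ``classes`` is every class with count >= 1."""

    transcript_id: str
    per_class_counts: Mapping[TEClass, int]
    per_class_overlap_bp: Mapping[TEClass, int]
    classes: frozenset[TEClass]

    def __post_init__(self):
        expected = frozenset(c for c, n in self.per_class_counts.items() if n >= 1)
        if self.classes != expected:
            raise ValidationError(
                f"{self.transcript_id}: classes inconsistent with per_class_counts"
            )

    def dominant_class(self) -> "TEClass | None":
        """Class with the largest overlap_bp; ties broken SINE > LINE > ERV >
        OTHER_REPEAT. None for transcripts with no TE association."""
        if not self.classes:
            return None
        return max(
            self.classes,
            key=lambda c: (self.per_class_overlap_bp[c],
                           -_CLASS_PRIORITY.index(c)),
        )


def map_repeat_class(rep: "RepeatFeature", config: TEConfig = TEConfig()
                     ) -> "TEClass | None":
    """Map a RepeatMasker repClass string to a TE class.

    repClass beginning "SINE" -> SINE, beginning "LINE" -> LINE, exactly
    "LTR" -> ERV, anything else -> OTHER_REPEAT. Overrides take precedence;
    returns None for excluded repeat classes.
    """
    rc = rep.rep_class
    if rc in config.class_map_overrides:
        mapped = config.class_map_overrides[rc]
        return None if mapped == EXCLUDE else TEClass(mapped)
    if rc in config.excluded_rep_classes:
        return None
    if rc.startswith("SINE"):
        return TEClass.SINE
    if rc.startswith("LINE"):
        return TEClass.LINE
    if rc == "LTR":
        return TEClass.ERV
    return TEClass.OTHER_REPEAT


class RepeatIndex:
    """Per-chromosome interval index over repeat features."""

    def __init__(self, repeats: Iterable["RepeatFeature"]):
        self._trees: dict[str, IntervalTree] = {}
        for rep in repeats:
            tree = self._trees.setdefault(rep.interval.chrom, IntervalTree())
            tree.addi(rep.interval.start, rep.interval.end, rep)

    def query(self, chrom: str, start: int, end: int) -> list["RepeatFeature"]:
        """Repeats with >= 1 bp overlap with [start, end) on *chrom*."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]


def overlap_exons(transcript: "TranscriptModel",
                  repeats: "RepeatIndex | Iterable[RepeatFeature]",
                  ) -> list[tuple["RepeatFeature", int]]:
    """Every repeat with total exonic overlap >= 1 bp, with its overlap.

    Exons are non-overlapping, so the total is a plain sum of per-exon
    intersection widths. Repeat strand is ignored. Results are ordered by
    repeat start coordinate.
    """
    if not isinstance(repeats, RepeatIndex):
        repeats = RepeatIndex(repeats)
    totals: dict[int, int] = {}
    by_key: dict[int, "RepeatFeature"] = {}
    for exon in transcript.exons:
        for rep in repeats.query(transcript.chrom, exon.start, exon.end):
            bp = min(exon.end, rep.interval.end) - max(exon.start, rep.interval.start)
            if bp > 0:
                key = id(rep)
                totals[key] = totals.get(key, 0) + bp
                by_key[key] = rep
    out = [(by_key[k], bp) for k, bp in totals.items()]
    out.sort(key=lambda t: (t[0].interval.start, t[0].interval.end, t[0].rep_name))
    return out


def classify_transcript(transcript: "TranscriptModel",
                        repeats: "RepeatIndex | Iterable[RepeatFeature]",
                        config: TEConfig = TEConfig()) -> TEAssociation:
    """TE association of one transcript.

    A repeat contributes to its class when its total exonic overlap is at
    least ``config.min_overlap_bp``; distinct repeat copies are counted
    separately. A transcript may belong to several classes at once.
    """
    counts: dict[TEClass, int] = {c: 0 for c in TEClass}
    bps: dict[TEClass, int] = {c: 0 for c in TEClass}
    for rep, bp in overlap_exons(transcript, repeats):
        if bp < config.min_overlap_bp:
            continue
        cls = map_repeat_class(rep, config)
        if cls is None:
            continue
        counts[cls] += 1
        bps[cls] += bp
    classes = frozenset(c for c, n in counts.items() if n >= 1)
    return TEAssociation(transcript.transcript_id, counts, bps, classes)


def classify_transcripts(transcripts: Sequence["TranscriptModel"],
                         repeats: "RepeatIndex | Iterable[RepeatFeature]",
                         config: TEConfig = TEConfig()) -> list[TEAssociation]:
    if not isinstance(repeats, RepeatIndex):
        repeats = RepeatIndex(repeats)
    return [classify_transcript(t, repeats, config) for t in transcripts]


def tabulate_te_distribution(associations: Sequence[TEAssociation],
                             feature_set: Iterable[str],
                             exclusive: bool = False) -> dict[TEClass, int]:
    """Count features of *feature_set* per TE class.

    Non-exclusive by default (a two-class feature increments two cells);
    with ``exclusive=True`` each TE-associated feature counts once, under
    its dominant class.
    """
    by_id = {a.transcript_id: a for a in associations}
    table: dict[TEClass, int] = {c: 0 for c in TEClass}
    for fid in feature_set:
        if fid not in by_id:
            raise ValidationError(f"feature {fid!r} has no TE association record")
        a = by_id[fid]
        if exclusive:
            dom = a.dominant_class()
            if dom is not None:
                table[dom] += 1
        else:
            for c in a.classes:
                table[c] += 1
    return table


# ---------------------------------------------------------------------------
# TSV serialization of association records
# ---------------------------------------------------------------------------

def associations_to_records(associations: Iterable[TEAssociation]) -> list[dict]:
    recs = []
    for a in associations:
        rec: dict = {
            "transcript_id": a.transcript_id,
            "classes": ",".join(sorted(c.value for c in a.classes)) or None,
        }
        for c in TEClass:
            rec[f"count_{c.value}"] = a.per_class_counts.get(c, 0)
            rec[f"bp_{c.value}"] = a.per_class_overlap_bp.get(c, 0)
        recs.append(rec)
    return recs


def read_associations(path) -> list[TEAssociation]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        counts = {c: int(getattr(r, f"count_{c.value}")) for c in TEClass}
        bps = {c: int(getattr(r, f"bp_{c.value}")) for c in TEClass}
        classes = frozenset(c for c, n in counts.items() if n >= 1)
        out.append(TEAssociation(str(r.transcript_id), counts, bps, classes))
    return out
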