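"""Candidate lncRNA filtering.

Novel transcripts from a reference-guided assembly are kept as lncRNA
candidates when their gffcompare class code is one of {u, x, i, j, o},
their spliced length is at least 200 nt and they have at least two exons;
candidates must then be called non-coding by all three coding-potential
predictors. Length is interpreted as spliced (exonic) length, the
conventional reading of the >= 200 nt lncRNA definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .genomic_io import CodingVerdicts, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_CLASS_CODES = frozenset("uxijo")


@dataclass(frozen=True)
class LncFilterThresholds:
    allowed_class_codes: frozenset[str] = DEFAULT_CLASS_CODES
    min_length: int = 200
    min_exons: int = 2
    require_all_noncoding: bool = True

    def __post_init__(self):
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")
        if self.min_exons < 1:
            raise ValidationError("min_exons must be >= 1")
        if not self.allowed_class_codes:
            raise ValidationError("allowed_class_codes must be non-empty")
        object.__setattr__(self, "allowed_class_codes",
                           frozenset(self.allowed_class_codes))


@dataclass(frozen=True)
class FilterDecision:
    transcript_id: str
    kept: bool
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kept != (len(self.failed_rules) == 0):
            raise ValidationError(
                f"{self.transcript_id}: kept flag inconsistent with failed_rules"
            )


def filter_candidates(transcripts: Sequence[TranscriptModel],
                      thresholds: LncFilterThresholds = LncFilterThresholds(),
                      ) -> list[FilterDecision]:
    """Structural filter: class code, spliced length, exon count.

    Every rule is evaluated (no short-circuiting), so ``failed_rules``
    lists all violated rules for each rejected transcript.
    """
    decisions = []
    for t in transcripts:
        failed = []
        if t.class_code not in thresholds.allowed_class_codes:
            failed.append("class_code")
        if t.spliced_length < thresholds.min_length:
            failed.append("length")
        if len(t.exons) < thresholds.min_exons:
            failed.append("exons")
        decisions.append(FilterDecision(t.transcript_id, not failed, tuple(failed)))
    return decisions


def apply_coding_consensus(decisions: Sequence[FilterDecision],
                           verdicts: Iterable[CodingVerdicts],
                           require_all_noncoding: bool = True,
                           keep_missing: bool = False) -> list[FilterDecision]:
    """Keep only transcripts called non-coding by all three predictors.

    Transcripts already rejected stay rejected unchanged. A kept transcript
    without a verdict row is rejected with rule ``coding_missing`` (and a
    warning) unless *keep_missing* is set. With
    ``require_all_noncoding=False`` the consensus step is a no-op.
    """
    by_tid: dict[str, CodingVerdicts] = {}
    for v in verdicts:
        if v.transcript_id in by_tid:
            raise ValidationError(f"duplicate verdict rows for {v.transcript_id}")
        by_tid[v.transcript_id] = v

    if not require_all_noncoding:
        return list(decisions)

    out = []
    for d in decisions:
        if not d.kept:
            out.append(d)
            continue
        v = by_tid.get(d.transcript_id)
        if v is None:
            if keep_missing:
                out.append(d)
            else:
                logger.warning("no coding verdicts for kept transcript %s; rejected",
                               d.transcript_id)
                out.append(FilterDecision(d.transcript_id, False, ("coding_missing",)))
        elif v.all_noncoding:
            out.append(d)
        else:
            out.append(FilterDecision(d.transcript_id, False,
                                      d.failed_rules + ("coding",)))
    return out


def kept_ids(decisions: Iterable[FilterDecision]) -> set[str]:
    return {d.transcript_id for d in decisions if d.kept}


def decisions_to_records(decisions: Iterable[FilterDecision]) -> list[dict]:
    return [
        {"transcript_id": d.transcript_id, "kept": d.kept,
         "failed_rules": ",".join(d.failed_rules) if d.failed_rules else None}
        for d in decisions
    ]
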