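"""End-to-end orchestration: ingest -> lncRNA filter -> TE classification ->
stage summaries and tests -> ZGA/DEG calling -> promoter-SINE enrichment.

Stages whose inputs are absent are skipped when nothing downstream needs
them. All randomness is confined to the enrichment stage and surfaced in
the run manifest; a rerun with the same config and seed produces
byte-identical reports apart from the manifest timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .catalog import (LncFilterThresholds, apply_coding_consensus,
                      decisions_to_records, filter_candidates, kept_ids)
from .enrichment import (EnrichmentConfig, PromoterWindowSpec,
                         permutation_enrichment, promoter_window,
                         sine_associated_genes)
from .errors import StageError, ValidationError
from .genomic_io import (read_coding_verdicts, read_de_table,
                         read_expression_table, read_gtf, read_rmsk,
                         write_bed, write_report_tsv)
from .stats import (benjamini_hochberg, call_degs, call_zga_genes,
                    stage_class_summary, stage_values, wilcoxon_rank_sum)
from .te import (TEClass, TEConfig, associations_to_records,
                 classify_transcripts, tabulate_te_distribution)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; unset optional paths cause the
    dependent stages to be skipped."""

    outdir: str = "telncrna_out"
    transcripts_gtf: str | None = None
    genes_gtf: str | None = None
    rmsk: str | None = None
    verdicts: str | None = None
    expression: str | None = None
    stage_map: str | None = None
    de_table: str | None = None
    zga_table: str | None = None

    filter_thresholds: LncFilterThresholds = field(default_factory=LncFilterThresholds)
    te_config: TEConfig = field(default_factory=TEConfig)
    window: PromoterWindowSpec = field(default_factory=PromoterWindowSpec)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    zga_lfc_min: float = 1.0
    zga_padj_max: float = 0.01
    zga_direction: str = "absolute"
    deg_p_max: float = 0.05
    deg_fpkm_min: float = 1.0
    deg_lfc_min: float = 1.0
    exclusive_classes: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "filter_thresholds" in kwargs:
            ft = dict(kwargs["filter_thresholds"])
            if "allowed_class_codes" in ft:
                ft["allowed_class_codes"] = frozenset(ft["allowed_class_codes"])
            kwargs["filter_thresholds"] = LncFilterThresholds(**ft)
        if "te_config" in kwargs:
            kwargs["te_config"] = TEConfig(**kwargs["te_config"])
        if "window" in kwargs:
            kwargs["window"] = PromoterWindowSpec(**kwargs["window"])
        if "enrichment" in kwargs:
            kwargs["enrichment"] = EnrichmentConfig(**kwargs["enrichment"])
        return cls(**kwargs)

    def snapshot(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, frozenset):
                return sorted(v)
            if isinstance(v, dict):
                return {str(k): enc(x) for k, x in v.items()}
            return v

        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> {"status", counts...}
    started: str = ""
    finished: str = ""

    def record(self, stage: str, status: str, **counts) -> None:
        self.stages[stage] = {"status": status, **counts}

    def to_dict(self) -> dict:
        return {"version": self.version, "config": self.config,
                "seeds": self.seeds, "stages": self.stages,
                "started": self.started, "finished": self.finished}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage whose inputs are available; see module docstring.

    Raises :class:`StageError` on the first stage failure, after writing a
    manifest with a FAILED entry for that stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot())
    manifest.started = _now()
    manifest.seeds["enrichment"] = config.enrichment.seed
    current = "ingest"
    try:
        # ingest ------------------------------------------------------------
        transcripts, genes = ([], [])
        if config.transcripts_gtf:
            transcripts, derived = read_gtf(config.transcripts_gtf)
        universe_genes = []
        if config.genes_gtf:
            _, universe_genes = read_gtf(config.genes_gtf)
        repeats = read_rmsk(config.rmsk) if config.rmsk else []
        manifest.record("ingest", "ok", transcripts_in=len(transcripts),
                        genes_in=len(universe_genes), repeats_in=len(repeats))

        # lncRNA filter -----------------------------------------------------
        current = "filter"
        kept = set()
        if transcripts:
            decisions = filter_candidates(transcripts, config.filter_thresholds)
            if config.verdicts:
                verdicts = read_coding_verdicts(config.verdicts)
                decisions = apply_coding_consensus(
                    decisions, verdicts,
                    require_all_noncoding=config.filter_thresholds.require_all_noncoding)
            kept = kept_ids(decisions)
            write_report_tsv(decisions_to_records(decisions),
                             outdir / "filter_decisions.tsv")
            (outdir / "lncrna_kept.txt").write_text(
                "".join(f"{t}\n" for t in sorted(kept)))
            manifest.record("filter", "ok", transcripts_in=len(transcripts),
                            lncrna_kept=len(kept))
        else:
            manifest.record("filter", "skipped", reason="no transcripts GTF")

        # TE classification -------------------------------------------------
        current = "classify"
        associations = []
        if transcripts and config.rmsk:
            associations = classify_transcripts(transcripts, repeats,
                                                config.te_config)
            write_report_tsv(associations_to_records(associations),
                             outdir / "te_associations.tsv")
            table = tabulate_te_distribution(
                associations, kept, exclusive=config.exclusive_classes)
            write_report_tsv(
                [{"te_class": c.value, "n_features": n} for c, n in table.items()],
                outdir / "te_class_counts.tsv")
            manifest.record("classify", "ok",
                            te_associated=sum(1 for a in associations if a.classes),
                            **{f"kept_{c.value}": n for c, n in table.items()})
        else:
            manifest.record("classify", "skipped", reason="needs transcripts and rmsk")

        # stage summaries + Wilcoxon ----------------------------------------
        current = "summarize"
        if config.expression and config.stage_map and associations:
            matrix = read_expression_table(config.expression, config.stage_map)
            summary_rows, test_rows = [], []
            for te_class in TEClass:
                members = [a.transcript_id for a in associations
                           if te_class in a.classes
                           and a.transcript_id in matrix.values.index]
                for s in stage_class_summary(matrix, associations, te_class):
                    summary_rows.append({
                        "te_class": te_class.value, "stage": s.stage, "n": s.n,
                        "median": s.median, "q1": s.q1, "q3": s.q3, "mean": s.mean})
                if not members:
                    continue
                stages = matrix.stages
                for a, b in zip(stages, stages[1:]):
                    res = wilcoxon_rank_sum(stage_values(matrix, members, b),
                                            stage_values(matrix, members, a))
                    test_rows.append({"te_class": te_class.value,
                                      "stage_a": a, "stage_b": b,
                                      "u": res.u, "pvalue": res.pvalue,
                                      "method": res.method})
            if test_rows:
                adj = benjamini_hochberg([r["pvalue"] for r in test_rows])
                for r, q in zip(test_rows, adj):
                    r["padj"] = q
            write_report_tsv(summary_rows, outdir / "stage_summaries.tsv")
            write_report_tsv(test_rows, outdir / "stage_tests.tsv")
            manifest.record("summarize", "ok", n_summaries=len(summary_rows),
                            n_tests=len(test_rows))
        else:
            manifest.record("summarize", "skipped",
                            reason="needs expression, stage map and associations")

        # ZGA calling -------------------------------------------------------
        current = "zga"
        if config.zga_table:
            zga_records = read_de_table(config.zga_table)
            zga = call_zga_genes(zga_records, config.zga_lfc_min,
                                 config.zga_padj_max, config.zga_direction)
            (outdir / "zga_genes.txt").write_text(
                "".join(f"{g}\n" for g in sorted(zga)))
            manifest.record("zga", "ok", table_rows=len(zga_records),
                            zga_genes=len(zga))
        else:
            manifest.record("zga", "skipped", reason="no ZGA table")

        # DEG calling -------------------------------------------------------
        current = "degs"
        degs: set[str] = set()
        if config.de_table:
            de_records = read_de_table(config.de_table)
            degs = call_degs(de_records, config.deg_p_max,
                             config.deg_fpkm_min, config.deg_lfc_min)
            by_id = {r.gene_id: r for r in de_records}
            n_up = sum(1 for g in degs if by_id[g].log2fc > 0)
            (outdir / "deg_genes.txt").write_text(
                "".join(f"{g}\n" for g in sorted(degs)))
            manifest.record("degs", "ok", table_rows=len(de_records),
                            degs=len(degs), up=n_up, down=len(degs) - n_up)
        else:
            manifest.record("degs", "skipped", reason="no DE table")

        # promoter enrichment ------------------------------------------------
        current = "enrich"
        if degs and universe_genes and config.rmsk:
            sine_set = sine_associated_genes(universe_genes, repeats,
                                             config.window, config.te_config)
            if not sine_set:
                raise StageError("enrich", "empty SINE set")
            universe = {g.gene_id for g in universe_genes}
            query = degs & universe
            if not query:
                raise StageError("enrich", "no DEGs found in the gene universe")
            result = permutation_enrichment(query, universe, sine_set,
                                            config.enrichment)
            result.to_json(outdir / "enrichment.json")
            write_report_tsv(
                [{"trial": i, "null_count": c}
                 for i, c in enumerate(result.null_counts)],
                outdir / "null_counts.tsv")
            windows = [promoter_window(g, config.window) for g in universe_genes]
            write_bed(windows, outdir / "promoter_windows.bed",
                      names=[g.gene_id for g in universe_genes])
            manifest.record("enrich", "ok", observed=result.observed,
                            draw_size=result.draw_size,
                            upper5_threshold=result.upper5_threshold,
                            empirical_p=result.empirical_p,
                            hypergeom_p=result.hypergeom_p,
                            n_sine_assoc_universe=result.n_sine_assoc_universe,
                            universe_size=result.universe_size)
        else:
            manifest.record("enrich", "skipped",
                            reason="needs DEGs, gene universe and rmsk")
    except StageError as e:
        manifest.record(e.stage, "FAILED", error=str(e))
        manifest.finished = _now()
        manifest.write(outdir / "manifest.json")
        raise
    except Exception as e:
        manifest.record(current, "FAILED", error=str(e))
        manifest.finished = _now()
        manifest.write(outdir / "manifest.json")
        raise StageError(current, str(e)) from e

    manifest.finished = _now()
    manifest.write(outdir / "manifest.json")
    return manifest
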