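"""Synthetic-data generators: determinism, planted structure, boundaries."""

import dataclasses

import numpy as np
import pytest

from telncrna.catalog import (apply_coding_consensus, filter_candidates,
                              kept_ids)
from telncrna.enrichment import sine_associated_genes
from telncrna.errors import GenerationError
from telncrna.genomic_io import read_gtf, read_rmsk
from telncrna.simulate import (SimConfig, generate_de_table,
                               generate_expression, generate_genes,
                               generate_lnc_transcripts, generate_repeats,
                               simulate_all)
from telncrna.stats import call_degs
from telncrna.te import TEClass, TEAssociation


BASE = SimConfig(seed=5, n_genes=300, n_chroms=2, chrom_length_bp=2_500_000,
                 n_background_repeats=300, n_lnc_transcripts=80)


class TestGenes:
    def test_non_overlapping_and_count(self):
        genes = generate_genes(BASE)
        assert len(genes) == 300
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.span)
        for spans in by_chrom.values():
            spans.sort(key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start

    def test_deterministic_per_seed(self):
        assert generate_genes(BASE) == generate_genes(BASE)
        other = generate_genes(dataclasses.replace(BASE, seed=6))
        assert other != generate_genes(BASE)

    def test_infeasible_packing_raises(self):
        config = dataclasses.replace(BASE, n_genes=5000, chrom_length_bp=100_000)
        with pytest.raises(GenerationError, match="chrom_length"):
            generate_genes(config)


class TestRepeats:
    def test_degenerate_rates_recover_planted_set_exactly(self):
        config = dataclasses.replace(BASE, planted_promoter_sine_prob=1.0,
                                     background_promoter_sine_prob=0.0,
                                     n_background_repeats=0)
        genes = generate_genes(config)
        repeats, planted = generate_repeats(genes, config)
        assert len(planted) == 30  # ceil(0.1 * 300)
        assert sine_associated_genes(genes, repeats) == planted

    def test_equal_rates_give_equal_group_frequencies(self):
        # planted vs background SINE-association rates within 3 SE when
        # the planted probability equals the background probability
        rates_p, rates_b = [], []
        for seed in range(50):
            config = dataclasses.replace(BASE, seed=seed, n_genes=200,
                                         planted_promoter_sine_prob=0.4,
                                         background_promoter_sine_prob=0.4,
                                         n_background_repeats=0)
            genes = generate_genes(config)
            repeats, planted = generate_repeats(genes, config)
            sine = sine_associated_genes(genes, repeats)
            background = {g.gene_id for g in genes} - planted
            rates_p.append(len(sine & planted) / len(planted))
            rates_b.append(len(sine & background) / len(background))
        n_p = 50 * 20
        n_b = 50 * 180
        se = np.sqrt(0.4 * 0.6 * (1 / n_p + 1 / n_b))
        assert abs(np.mean(rates_p) - np.mean(rates_b)) < 3 * se

    def test_no_sine_anywhere_means_no_sine_associated_genes(self):
        config = dataclasses.replace(BASE, planted_promoter_sine_prob=0.0,
                                     background_promoter_sine_prob=0.0,
                                     repeat_class_mix={"LINE": 1.0})
        genes = generate_genes(config)
        repeats, _ = generate_repeats(genes, config)
        assert repeats  # background LINEs exist
        assert sine_associated_genes(genes, repeats) == set()


class TestTranscripts:
    def test_boundary_transcripts_present(self):
        transcripts, _ = generate_lnc_transcripts(BASE)
        lengths = {t.spliced_length for t in transcripts[:4]}
        exon_counts = {len(t.exons) for t in transcripts[:4]}
        assert {199, 200} <= lengths
        assert {1, 2} <= exon_counts

    def test_unanimous_verdicts_add_no_extra_filtering(self):
        config = dataclasses.replace(BASE, noncoding_agreement_prob=1.0)
        transcripts, verdicts = generate_lnc_transcripts(config)
        structural = filter_candidates(transcripts)
        combined = apply_coding_consensus(structural, verdicts)
        assert kept_ids(combined) == kept_ids(structural)

    def test_reference_matching_codes_keep_nothing(self):
        config = dataclasses.replace(BASE, class_code_mix={"=": 1.0})
        transcripts, _ = generate_lnc_transcripts(config)
        assert kept_ids(filter_candidates(transcripts)) == set()

    def test_deterministic(self):
        a, _ = generate_lnc_transcripts(BASE)
        b, _ = generate_lnc_transcripts(BASE)
        assert a == b


def sine_assoc(tid):
    counts = {c: 0 for c in TEClass}
    bps = {c: 0 for c in TEClass}
    counts[TEClass.SINE] = 1
    bps[TEClass.SINE] = 100
    return TEAssociation(tid, counts, bps, frozenset({TEClass.SINE}))


class TestExpression:
    def test_stage_effect_shifts_log2_mean(self):
        config = dataclasses.replace(
            BASE, n_lnc_transcripts=500,
            te_stage_effect={(TEClass.SINE, "8C"): 2.0})
        transcripts, _ = generate_lnc_transcripts(config)
        assocs = [sine_assoc(t.transcript_id) for t in transcripts]
        matrix = generate_expression(transcripts, assocs, config)
        log2p1 = np.log2(matrix.values + 1)
        mean_8c = log2p1[matrix.samples_for_stage("8C")].to_numpy().mean()
        mean_2c = log2p1[matrix.samples_for_stage("2C")].to_numpy().mean()
        assert mean_8c - mean_2c == pytest.approx(2.0, abs=0.2)

    def test_no_effect_leaves_stages_exchangeable(self):
        config = dataclasses.replace(BASE, n_lnc_transcripts=200,
                                     te_stage_effect={})
        transcripts, _ = generate_lnc_transcripts(config)
        assocs = [sine_assoc(t.transcript_id) for t in transcripts]
        matrix = generate_expression(transcripts, assocs, config)
        log2p1 = np.log2(matrix.values + 1)
        means = [log2p1[matrix.samples_for_stage(s)].to_numpy().mean()
                 for s in matrix.stages]
        # per-stage means are iid with SE ~ 0.06 here; 0.3 is a ~5 SE range
        assert max(means) - min(means) < 0.3

    def test_deterministic(self):
        transcripts, _ = generate_lnc_transcripts(BASE)
        assocs = [sine_assoc(t.transcript_id) for t in transcripts]
        a = generate_expression(transcripts, assocs, BASE)
        b = generate_expression(transcripts, assocs, BASE)
        assert a.values.equals(b.values)


class TestDeTable:
    def test_planted_degs_recovered_at_default_thresholds(self):
        for seed in range(20):
            config = dataclasses.replace(BASE, seed=seed, deg_count=30)
            genes = generate_genes(config)
            records, planted = generate_de_table(genes, set(), config)
            called = call_degs(records)
            recovered = len(called & planted) / len(planted)
            assert recovered >= 0.95

    def test_null_only_table_calls_few_degs(self):
        config = dataclasses.replace(BASE, deg_count=0)
        genes = generate_genes(config)
        records, planted = generate_de_table(genes, set(), config)
        assert planted == set()
        called = call_degs(records)
        # null genes must additionally clear the |lfc|>=1 (3.3 sigma) and
        # FPKM gates, so chance calls are far below 5% of the table
        assert len(called) < 0.02 * len(records)

    def test_planted_sine_probability_one(self):
        config = dataclasses.replace(BASE, deg_count=30, deg_from_sine_prob=1.0)
        genes = generate_genes(config)
        sine_set = {g.gene_id for g in genes[:100]}
        records, planted = generate_de_table(genes, sine_set, config)
        assert planted <= sine_set and len(planted) == 30

    def test_deg_count_exceeding_genes_raises(self):
        config = dataclasses.replace(BASE, deg_count=10_000)
        genes = generate_genes(config)
        with pytest.raises(GenerationError):
            generate_de_table(genes, set(), config)


class TestFixtureRoundTrip:
    def test_files_round_trip_through_readers(self, small_sim, fixture_dir):
        transcripts, _ = read_gtf(fixture_dir / "transcripts.gtf")
        by_id = {t.transcript_id: t for t in transcripts}
        assert len(transcripts) == len(small_sim.transcripts)
        for t in small_sim.transcripts:
            b = by_id[t.transcript_id]
            assert [(e.start, e.end) for e in b.exons] == \
                   [(e.start, e.end) for e in t.exons]
            assert b.class_code == t.class_code and b.strand == t.strand
        repeats = read_rmsk(fixture_dir / "repeats.rmsk.tsv")
        assert [(r.interval.start, r.interval.end, r.rep_class)
                for r in repeats] == \
               [(r.interval.start, r.interval.end, r.rep_class)
                for r in small_sim.repeats]
        _, genes = read_gtf(fixture_dir / "genes.gtf")
        by_gid = {g.gene_id: g for g in genes}
        for g in small_sim.genes:
            assert by_gid[g.gene_id].tss == g.tss

    def test_simulate_all_deterministic(self, small_sim):
        again = simulate_all(small_sim.config)
        assert again.planted_genes == small_sim.planted_genes
        assert again.de_records == small_sim.de_records
        assert again.expression.values.equals(small_sim.expression.values)
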