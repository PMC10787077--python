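import numpy as np
import pytest

from telncrna.genomic_io import (GenomicInterval, RepeatFeature,
                                 TranscriptModel)
from telncrna.simulate import SimConfig, simulate_all, write_fixture


def make_transcript(tid="T1", chrom="chr1", strand="+", exons=((100, 200),),
                    class_code="u", gene_id=None):
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return TranscriptModel(tid, gene_id or f"g_{tid}", chrom, strand, ivs,
                           class_code=class_code)


def make_repeat(chrom="chr1", start=0, end=100, rep_class="SINE",
                rep_name=None, strand="+"):
    return RepeatFeature(GenomicInterval(chrom, start, end, strand),
                         rep_name=rep_name or rep_class.lower(),
                         rep_class=rep_class, rep_family=rep_class)


def brute_force_overlap_bp(transcript, repeat):
    """Per-base membership count over the exon union — the overlap oracle."""
    if repeat.interval.chrom != transcript.chrom:
        return 0
    exonic = set()
    for e in transcript.exons:
        exonic.update(range(e.start, e.end))
    return sum(1 for pos in range(repeat.interval.start, repeat.interval.end)
               if pos in exonic)


def random_overlap_fixture(rng, chrom_len=10_000):
    """One random transcript plus random repeats on a short chromosome."""
    n_exons = int(rng.integers(1, 6))
    starts = np.sort(rng.choice(np.arange(0, chrom_len - 100, 10),
                                size=n_exons, replace=False))
    exons = []
    prev_end = 0
    for s in starts:
        s = max(int(s), prev_end + 1)
        e = s + int(rng.integers(1, 300))
        if e > chrom_len:
            break
        exons.append((s, e))
        prev_end = e
    if not exons:
        exons = [(0, 100)]
    t = make_transcript(exons=tuple(exons))
    classes = ["SINE", "LINE", "LTR", "DNA", "Simple_repeat"]
    repeats = []
    for _ in range(int(rng.integers(1, 30))):
        s = int(rng.integers(0, chrom_len - 1))
        e = s + int(rng.integers(1, 400))
        repeats.append(make_repeat(start=s, end=min(e, chrom_len),
                                   rep_class=classes[int(rng.integers(0, 5))]))
    return t, repeats


SMALL_SIM = SimConfig(seed=3, n_genes=500, n_chroms=2,
                      chrom_length_bp=4_000_000, n_background_repeats=500,
                      n_lnc_transcripts=60, deg_count=50, zga_count=40)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_all(SMALL_SIM)


@pytest.fixture(scope="session")
def fixture_dir(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(small_sim, outdir)
    return outdir
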