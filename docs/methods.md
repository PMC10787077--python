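# Methods

## Coordinates and formats

All intervals are held internally as 0-based half-open `[start, end)`;
conversions happen only at I/O boundaries. GTF (1-based closed) exon
coordinates become `(start−1, end)` on read and are restored on write;
UCSC `rmsk` tables and BED are already 0-based half-open and pass through
unchanged. Both the 16-column and the 17-column (leading `bin`) `rmsk`
dialects are accepted, auto-detected per row; rows with
`genoEnd ≤ genoStart` are skipped with a warning rather than aborting, to
tolerate table noise. The transcription start site of a minus-strand gene
is `span.end − 1`, the 5′-most base in 0-based space; the literature
rarely states this convention, so it is fixed here and used consistently
by the promoter-window code.

## lncRNA candidate filter

The filter chain keeps transcripts with a gffcompare class code in
{u, x, i, j, o}, spliced length ≥ 200 nt, and ≥ 2 exons, then requires a
unanimous non-coding call from three coding-potential predictors.
"Length" is interpreted as spliced (exonic) length, matching the standard
≥ 200 nt lncRNA definition; the genomic span would make the threshold
nearly vacuous for multi-exon transcripts. All structural rules are
evaluated for every transcript (no short-circuiting), so rejection
records list every violated rule. A kept transcript with no verdict row
is rejected with rule `coding_missing` (the consensus rule demands three
explicit calls); a permissive flag can keep it instead. Single-exon
transcripts are rejected by default even though genuine single-exon
lncRNAs exist — fidelity to the filter being reproduced outweighs recall
here, and `min_exons` is configurable.

## TE classification

RepeatMasker `repClass` strings map as: prefix `SINE` → SINE, prefix
`LINE` → LINE, exactly `LTR` → ERV (endogenous retroviruses are annotated
under repClass LTR, families ERV1/ERVK/ERVL, in UCSC tables), everything
else → other-repeat. The map accepts per-class overrides and exclusions
(e.g. dropping `Simple_repeat`/`Low_complexity`); by default nothing is
excluded and the minimum exonic overlap is 1 bp, i.e. "other repeat" is
taken literally. Membership is **non-exclusive**: a transcript carrying
both a SINE and a LINE counts in both classes, and per-class tallies of a
feature set therefore need not sum to the number of features. An
exclusive mode assigns each transcript its dominant class (largest total
overlap, ties broken SINE > LINE > ERV > other). Overlap is strand-blind,
the conventional choice for repeat-content classification. Repeat queries
use a per-chromosome interval tree; equality with a per-base brute-force
count is part of the test suite.

## Expression summaries and tests

Box summaries pool per-feature, per-sample log₂(FPKM+1) values of a TE
class at each stage, with linear-interpolation quartiles and no
expression floor; the pseudo-count of 1 is the conventional choice. Stage
comparisons use a Wilcoxon rank-sum test with
U = #{(i,j): xᵢ > yⱼ} + ½·#{xᵢ = yⱼ}. For pooled sample size ≤ 16 with no
ties the p-value is exact by complete enumeration of the C(n+m, n) rank
assignments; otherwise a normal approximation with tie-corrected variance

    Var(U) = nm/12 · [ (N+1) − Σ(t³−t) / (N(N−1)) ],  N = n+m

and a 0.5 continuity correction is used. Exact enumeration under ties is
deliberately not implemented: ties push the test onto the normal path,
which carries the tie correction. Benjamini–Hochberg adjustment is the
standard step-up `min_{j≥i} min(1, p₍ⱼ₎·m/j)`; note that re-applying BH
to already-adjusted values is *not* a no-op in general (the m/j factors
re-inflate non-tied values), which is why the tests assert the fixed
point only on fully monotonized output.

## Threshold calls

ZGA genes (8C/MII-oriented tables): |log₂FC| ≥ 1 **and** padj < 0.01 —
the fold-change boundary inclusive, the padj boundary strict, both
configurable, with an `up_only` mode restricting to log₂FC ≥ 1 for the
reading under which ZGA candidates are the upregulated transcripts.
Knockdown DEGs: p ≤ 0.05, max(group₁ FPKM, group₂ FPKM) ≥ 1 and
|log₂FC| ≥ 1, all boundaries inclusive. "FPKM ≥ 1" does not name a group,
so requiring expression in at least one condition is the permissive
standard reading adopted here.

## Promoter-SINE enrichment

The promoter window spans 2 kb upstream to 1 kb downstream of the TSS in
gene orientation: `[tss−2000, tss+1000)` on the plus strand and the
mirror image `[tss−999, tss+2001)` on the minus strand, clipped to the
chromosome. A gene is SINE-associated when ≥ 1 SINE-class repeat overlaps
its window by at least the configured minimum (1 bp).

The permutation null draws `draw_size` genes (default: the query size)
uniformly **without replacement** from the gene universe per trial —
query genes are not excluded from the universe, matching a plain
random-gene-set design — and records the intersection with the
SINE-associated set. The empirical p-value uses the add-one estimator
(1 + #{null ≥ obs}) / (1 + N), ties counting toward significance; its
smallest attainable value at N = 10,000 trials is ≈ 1.0e-4. The "5%
threshold" is the nearest-rank 95th percentile of the null counts, the
value the observed count must exceed. Because the design makes the null
exactly hypergeometric, the closed-form tail P(X ≥ obs) for
X ~ Hypergeom(|U|, |S|, draw) is computed as an exact reference, and a
normal upper tail at the null's empirical moments is reported as well;
the three are reported side by side rather than silently picking one.
The gene universe defaults to all genes in the parsed annotation and is a
parameter. No GC- or position-matched null is provided — the design being
reproduced uses plain random draws.

## Synthetic data

The generator emulates the data shapes the analysis consumes, not
sequences or reads. Defaults define the study conditions: 2,000 genes on
4 × 8 Mb chromosomes; a planted 10% gene subset whose promoters carry a
SINE with probability 0.8 against a 0.4 background (the planted subset
doubles as the 200-gene DEG set, giving the end-to-end run known ground
truth); ~4,000 additional repeats scattered with class mix SINE 0.45 /
LINE 0.30 / LTR 0.15 / DNA 0.10; 300 assembled transcripts whose class
codes, lengths (150–3,000 nt) and exon counts (1–6) span both sides of
every filter boundary — lengths 199/200 and exon counts 1/2 are
guaranteed present — with unanimous non-coding verdicts at probability
0.7; seven stages (GV, MII, 2C, 4C, 8C, morula, blastocyst) × 3
replicates of log-normal FPKM.

Specific numerical choices:

- **Inter-gene gaps are 4.1–8 kb**, strictly more than twice the 2 kb
  upstream window extent, so promoter windows of neighbouring genes never
  overlap and a promoter-planted SINE is attributable to exactly one gene;
  this makes the degenerate configuration (planted probability 1,
  background 0, no scattered repeats) recover the planted set *exactly*.
- **Baseline log-FPKM is N(3.0, 1.0)** (median FPKM ≈ 20). With FPKM well
  above the +1 pseudo-count, a TE-class stage effect of e log₂ units
  multiplies FPKM by 2^e and shifts the mean log₂(FPKM+1) by ≈ e (the
  default SINE effects are +1 at 4C and +2 at 8C, emulating elevated
  SINE-class expression across the zygotic genome activation window). At a
  much lower baseline the pseudo-count compresses the shift visibly.
- **Planted DE genes** get |log₂FC| = max(1, |N(2.5, 0.8)|), upregulated
  with probability 0.6, p ~ U(0, 1e-4) and a group FPKM ≥ 1, so the DEG
  caller recovers them; null genes get log₂FC ~ N(0, 0.3) and p ~ U(0,1).
  padj is BH over the whole table.
- **Determinism.** One root seed spawns independent named substreams
  (genes, repeats, transcripts, expression, DE, ZGA), so changing, say,
  the number of enrichment trials never perturbs the genome layout. Every
  generator is a pure function of its config.

What the generator does **not** emulate: genomic sequence (no FASTA, no
motif content), overlapping or nested gene models, assembly artifacts,
fragment-level quantification noise models, correlated repeats
(clustering, age structure), or realistic chromosome counts and sizes.
Passing tests therefore demonstrate the correctness and calibration of
the statistics under the generative model's assumptions — not that real
embryo data satisfy those assumptions.

## Problem sizes in the test and acceptance runs

The shared pipeline fixture uses 500 genes / 50 planted DEGs / 60
transcripts — large enough that the planted enrichment is detectable with
high margin — while the enrichment-specific checks run at the design
scale (universe 2,000, planted set 200) across 100 seeded replicates with
1,000-trial nulls, and the null-calibration check uses 500 random query
sets × 1,000 trials. The acceptance script runs the full default
conditions with a 10,000-trial null.

## Known limitations

- GTF parsing consumes `exon` features only and derives gene spans from
  transcripts; explicit `gene`/`transcript` feature lines are ignored, and
  annotation dialects that encode class codes elsewhere need the attribute
  key parameter.
- Exact Wilcoxon enumeration is combinatorial; `method="exact"` should not
  be forced beyond pooled sizes around 20.
- The enrichment draws are uniform over genes; no correction for gene
  length, GC content or genomic clustering of SINEs is attempted.
- Multi-transcript genes on both strands are rejected rather than
  resolved; the gene universe is whatever the provided annotation defines.
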