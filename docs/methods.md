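# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `pilnc`, in the spirit of a statistical-software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model and I/O

All coordinates are 0-based half-open internally; GTF I/O converts to and
from the format's 1-based inclusive convention, FASTA is uppercased on read
and wrapped at 60 columns on write, and bedGraph signals are
piecewise-constant with uncovered bases reading as 0 (so "positive DNase
signal over the promoter" is well defined even with sparse tracks).
Readers/writers are line-oriented and round-trip exactly; they are written
directly rather than through a genomics library because the pipeline also
needs to construct and interrogate all of these objects in memory, and the
formats involved are simple text.

## Novel lncRNA discovery

The cascade applies its three filters in a fixed order, and the
`FilterReport` enforces the conservation identity
`n_input = removed_overlap + removed_short + removed_coding + retained` on
every run. Filter 1 is exon-vs-exon overlap (≥ 1 nt): against
protein-coding exons on the same strand only, and against annotated lncRNA
exons on either strand. Filter 2 drops spliced length < 200 nt. Filter 3
drops transcripts with positive coding score.

The coding score is an ORF-coverage statistic: the longest ATG..stop open
reading frame over the three forward frames (stop codon included; open-ended
ORFs without a stop do not count), divided by transcript length, minus a
threshold τ = 0.35. The surrogate deliberately replaces SVM-based coding
classifiers: it is transparent, dependency-free and exactly testable against
a brute-force ORF enumeration, and the API accepts externally computed
scores when a full classifier is available. Forward frames only are scanned
because the input is the strand-oriented spliced transcript. τ = 0.35 was
chosen so that a transcript must devote roughly a third of its length to a
single ORF before being called coding — long enough to exclude the short
spurious ORFs of genuine lncRNAs, low enough that real mRNAs (typically
> 50% CDS) score positive.

Position classes are assigned with the fixed priority
pseudogenic/TE-related (span overlap ≥ 1 nt, either strand; pseudogene
outranks TE when both overlap) > antisense > cis > intergenic. The
antisense test uses the protein-coding transcript's span intron-inclusively
(natural antisense transcripts include intronic overlaps); an exon-only
variant is a keyword switch. The cis distance is measured between closest
transcript boundaries, strand-agnostic, with the 500-nt cutoff as a
parameter.

## Poly(A) classification

RPKM = count × 10⁹ / (total_mapped_reads × length). Transcripts with
RPKM < 0.1 in every library of the design are set aside as low-expressed
before any ratio is computed (global floor first). The PA/NPA ratio is
computed from replicate-mean RPKM within one tissue and condition, with an
ε = 10⁻⁶ guard on the denominator — the guard changes no call for any
nonzero denominator and sends "expressed in PA, zero in NPA" to poly(A)+,
which is the only sensible limit. Replicates are averaged before the ratio;
a per-replicate majority vote would be an easy variant but the averaged
form matches how two-replicate designs are usually summarized.

## Differential expression

The two-group test is a negative-binomial Wald test built from scratch:

- **Size factors** by median-of-ratios against the geometric-mean reference
  (transcripts with any zero count are excluded from the reference).
- **Dispersion** is a single α pooled across transcripts by method of
  moments on within-group residuals: α̂ = Σ(v − m) / Σ m², clipped to
  [10⁻⁸, 10], under the variance model Var = μ + αμ². With two replicates
  per group no per-transcript estimate is usable, but thousands of
  transcripts pin the common α tightly.
- **Statistic**: log₂ fold change of normalized group means with a 0.5
  pseudo-count, delta-method standard error, two-sided normal p-value.
  All-zero transcripts report FC = 1, p = 1, flagged.
- **Significance** is the published rule: FC > 2 or FC < 0.5 **and**
  p < 0.05 (raw); a BH-adjusted column is emitted alongside.

The six clusters are a pure function of the per-tissue calls: both-tissue
induction/repression (1/4), roots only (2/5), shoots only (3/6);
opposite-direction transcripts are reported as `discordant` rather than
forced into a cluster, and never-significant ones as `unassigned`.
Expression is poly(A)-aware: poly(A)+ and bimorphic transcripts are tested
on PA libraries, poly(A)− transcripts on NPA libraries.

AS events are called from exon chains alone: retained intron (intron of one
isoform inside an exon of the other), A3SS/A5SS (overlapping introns
sharing exactly one boundary, donor/acceptor resolved by strand), exon
skipping (internal exon inside an intron of the other isoform). Detection
is symmetric in the isoform pair.

## Enrichment statistics

GO-style over-representation is the upper-tail hypergeometric on a flat
term → gene map with BH correction across terms — no DAG propagation, by
design: the pipeline's enrichment questions are desk-scale comparisons, and
a flat map keeps the statistic exact and auditable. Ratio comparisons use
the Pearson χ² on a 2×2 table without continuity correction (df = 1),
flagging any expected cell < 1.

## P1BS scanning with exact p-values

The PWM is built from the published degenerate consensus `GNATATNC` with
pseudocounts (pc = 0.05 default): allowed letters share 1 − 4·pc equally
and every letter receives pc, so `N` positions are exactly uniform. Scores
are log₂-odds against a uniform background (an input-derived 0-order
background is a parameter).

Exact hit p-values come from a dynamic program: per-position scores are
discretized to a common lattice (bin width = widest per-position range /
1000) and the full distribution of the 8-mer score under the background is
obtained by convolving positions. Because scanning uses the *same*
discretized scores, the DP tail equals exhaustive 4⁸ enumeration up to
floating-point addition (the suite checks < 10⁻⁹). At the published 10⁻³
cutoff only exact consensus instantiations are hits (16 words,
p = 16/4⁸ ≈ 2.4 × 10⁻⁴; any single defined-position mismatch jumps to
≈ 4.6 × 10⁻³).

Promoters are 2 kb upstream of the first ATG of the spliced transcript
(genes; falling back to the TSS if no ATG exists) or of the TSS (lncRNAs),
truncated and flagged at chromosome edges; minus-strand windows are
reverse-complemented so the promoter always reads 5′→3′ toward its anchor.
Hits report the paper-style offset: the window's most-5′ base, negative,
relative to the anchor. One wrinkle worth knowing: `GNATATNC` is its own
reverse complement, so every site is reported on both strands at the same
offset; consumers that want occurrence counts should count unique offsets
(the pipeline's PHR1 stage does).

A PHR1 target requires all three evidence layers: ≥ 1 promoter hit, a
significant Pi-starvation response, and positive mean DNase signal over the
promoter. The motif-count/fold-change trend reports per-count mean log₂FC
with a normal-approximation 95% CI and a strict-monotonicity flag.

## miRNA targets and mimics

The complementarity scorer is a declared, transparent scheme (the reference
tool's internals are unpublished): antiparallel alignment of the full miRNA
against any transcript window, penalties mismatch = 1, G:U wobble = 0.5,
bulged base = 2, all doubled at miRNA positions 2–8; at most two bulged
bases; semi-global DP with a bounded gap dimension, ties resolved to the
leftmost site. A perfect site scores 0 and the published score ≤ 5 cutoff
retains sites with up to ~5 non-seed mismatch-equivalents.

A target mimic is detected structurally, not by score: the site must pair
the miRNA with an exact 3-nt unpaired insertion in the *target* opposite
the junction of miRNA positions 10–11 (the configuration that blocks
cleavage), perfect Watson–Crick pairing across the seed (positions 2–8),
and ≤ 3 mismatches elsewhere — G:U wobbles count as mismatches here
(strict reading; the looser variant would only widen the detected set).
Bulge-free perfect complements are cleavage targets, never mimics.

ceRNA edges require target score ≤ 5 and expression Pearson r ≤ −0.5 over
the 8 matched samples; the cutoff is interpreted as anti-correlation
(≤ −0.5) since the network's premise is repression by cleavage, and a
whitelist lets validated targets bypass the correlation gate (flagged), as
printed target tables often retain canonical pairs with weak correlations.

## Synthetic data: what it emulates, and what it does not

The generator lays out a single chromosome with two-exon coding genes
(2.4 kb span, ORF from the TSS — simulated genes carry no 5′UTR, so ATG-
and TSS-anchored promoters coincide by construction), annotated lncRNAs,
pseudogenes and TE genes, and novel lncRNAs planted into known position
classes (55% antisense, 13% cis, ~6% each pseudogenic/TE, remainder
intergenic — echoing the antisense-dominated breakdown such studies
report). Non-coding transcript bodies are filled with A/C/T-only sequence
in their own orientation: with no ATG in any forward frame their ORF score
is exactly −τ, making coding-filter truth deterministic. Planted miRNA
sites (which reintroduce G) are followed by a 12-mer carrying stops in all
three frames so they cannot seed a long ORF.

Counts are NB(μ, α) with variance μ + αμ², α = 0.1 (typical two-replicate
bulk RNA-seq overdispersion) and base mean 200; library totals are uniform
in [0.8, 1.2] × 10⁶ to exercise RPKM normalization. Differential expression
multiplies the P− mean by the fold (default 5; up-regulated transcripts
additionally scale by 1.4^(motif count), which makes the motif-count/fold
trend strictly increasing in expectation). Poly(A)+ transcripts have PA
means 8× their NPA means (and conversely): with two replicates at α = 0.1
the log-ratio noise is ≈ 0.33, so a planted 4× separation would leave a
~2% per-transcript chance of crossing the 2×/0.5× decision boundary,
whereas 8× (comfortably inside the "at least 4×" design) puts planted
poly(A)+/− calls ≥ 4 SD from the boundary — planted plus/minus classes are
then recovered exactly, while planted *bimorphic* transcripts sit between
two thresholds and retain an irreducible few-percent misclassification.
The default planted fold of 5 reflects the same arithmetic: detection
requires the *observed* FC to clear 2, and at fold 4 with two replicates
the per-tissue miss rate (~1.6%) plus the false-call rate in the other
tissue (~3%) would leave tissue-restricted clusters hovering at the edge of
a 95% diagonal; a 5-fold planted effect is both realistic for Pi-starvation
marker responses and keeps the planted-pattern diagonal safely above it.
The statistical acceptance checks for the test itself (type-I error,
4-fold recovery) are run at base mean 100 and fold 4 on dedicated count
simulations, independent of these generator defaults.

Promoters carry 0–4 planted P1BS words (exact consensus instantiations, on
either strand, ≥ 14 nt apart, offsets recorded); after planting, promoters
are rescanned and accidental consensus matches are mutated away so planted
counts are exact truth. The DNase track is a constant positive value over
the promoters of designated PHR1 targets (a 70% random subset of
motif-and-DE transcripts) and absent elsewhere. miRNA cleavage sites are
near-perfect reverse complements (0–2 non-seed mismatches), mimic sites are
the exact 3-nt-bulge construction, and negatives are shuffled sites.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: assembly noise and fragmented transcripts, 5′UTRs
(real ATG anchors differ from TSSs), per-transcript expression
heterogeneity and mean–dispersion trends, correlated replicates, partially
degenerate or clustered motif occurrences, DNase signal that varies
continuously, and miRNA sites embedded in structured UTR contexts. The
suite demonstrates correctness of the algorithms under the stated model,
not field performance.

Determinism: all randomness flows from one `numpy` Generator seeded by the
config; identical seeds produce byte-identical outputs, and `write()`
refuses to overwrite existing files.

## Problem sizes

Defaults were chosen so the full test suite runs in about a minute and the
acceptance script in a few seconds: 150 coding genes, 200 novel lncRNAs on
a ~1.7 Mb chromosome for the end-to-end study; 2,000 null and 600 planted
transcripts for DE calibration; the engineered filter-cascade dataset
reproduces the reference per-stage totals at full printed size (22,972
candidates) since the cascade itself is cheap.

## Known limitations

- The Wald test's normal approximation with two replicates is slightly
  anti-conservative (measured type-I ≈ 0.05–0.07 at nominal 0.05); an exact
  conditional NB test would tighten this at the cost of speed.
- The coding surrogate scans forward frames only and knows nothing of
  similarity to known proteins; supply external scores for real data.
- The mimic detector fixes the bulge opposite the miRNA 10–11 junction;
  naturally occurring mimics with shifted bulges would be missed.
- GO enrichment ignores term hierarchy; parent terms must be materialized
  in the flat map if their aggregation is wanted.
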