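# Methods

This note documents the statistical models, the synthetic experiment that
serves as ground truth, and the numerical and design choices behind
`clipforge`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Bin-level significance: the zero-truncated negative binomial

Coverage bins with at least one fragment are modelled as a zero-truncated
negative binomial (ZTNB): with an untruncated NB of mean `mu` and size
`size` (variance `mu + mu^2/size`),

    f(k) = NB(k; mu, size) / (1 - NB(0; mu, size)),   k >= 1.

Fitting only non-zero bins avoids modelling the unmappable/unexpressed zero
class. The likelihood is maximised over `(log mu, log size)` with
Nelder-Mead from a moment start; the zero-truncated Poisson limit
(`size -> inf`, solved by Brent's method on `lam/(1-e^-lam) = mean`) is
always evaluated as a boundary candidate and wins when its likelihood is at
least as high — note a truncated sample can show variance below its mean
while an interior ZTNB still fits best, so the interior fit is attempted
regardless. A bin's score is the conditional upper tail
`P(X >= k | X >= 1) = sf(k-1)/(1-pmf(0))`, computed from the survival
function in one numerically stable step; significance is declared at
BH-adjusted p < alpha (default 0.05, configurable — the bin caller's
internal threshold is a protocol choice, not a published constant).

A single genome-wide ZTNB is deliberately simple: between-gene expression
differences and the exon/intron coverage contrast widen the fitted
dispersion, which makes the caller conservative for weak sites in poorly
covered introns. The downstream fold-enrichment test, not the bin caller,
carries the specificity of the pipeline; the per-gene upper-quartile filter
and the region-level thresholds were designed around exactly this division
of labour.

## Fold enrichment and selection

For a candidate region, `FE = (n_ip/T_ip) / (max(n_input,1)/T_input)` with
library totals `T`; the pseudocount only enters the ratio, never the test
table, so a zero-Input region keeps a finite FE without distorting the
exact test. The p-value uses the Yates-corrected chi-square on
`[[n_ip, T_ip-n_ip], [n_input, T_input-n_input]]`, switching to the
two-sided Fisher exact test when any of the four observed or four expected
cells is below 5. BH runs per IP replicate across all candidates of the
run. Selection requires `log2 FE > 2` and `FDR < 0.05` in both replicates,
all strict inequalities. The summit is the leftmost position of maximal
combined IP1+IP2 per-base FPM inside the region.

The per-gene quartile filter compares the significant bin's **own** FPM in
the IP sample against Q3 (linear interpolation between order statistics) of
the host gene's Input FPM over all bins overlapping the gene span; bins at
exactly Q3 survive, bins outside any gene are untouched. The protocol
sentence this implements can also be read as comparing the bin's Input FPM;
that reading is available via `comparator="input"` but the IP reading is
the default, because the filter's purpose is to demand that the IP signal
stands above the gene's own background.

## Motif statistics

Sequences are handled as sense-strand RNA (reverse complement for
minus-strand hosts, T->U). Over-representation is a presence/absence
two-sided Fisher test on 100-nt summit-centred windows against 10
length-matched control windows per peak drawn uniformly from expressed
(Input CPM > 0) precursor spans, BH-corrected across the motif catalogue.
This replaces a rank-based motif tool: the adjusted p plays the role of its
E-value and should be read as an approximation of it, not a reproduction.

The positional profile tests, for each offset d in -50..+50, the 10-nt
window **centred** on summit+d (RNA coordinates) for motif containment,
peaks versus controls, with Bonferroni correction over the 101 offsets and
a Haldane-Anscombe-corrected log2 odds ratio capped at +/-8 for display.
Centring the window on the offset makes the profile of a summit-planted
motif symmetric around 0; indexing windows by their left edge would shift
the whole profile by half a window width, which is why the centred
convention was chosen. Sliding step is 1 nt. Control windows are not
purged of real-peak overlap (an option exists for sensitivity analysis).

## Differential binding

WT-selected peaks are the consensus; each is re-counted in the four IP
libraries and scaled to the mean library size. A single common dispersion
`phi` (variance `m + phi m^2`) is estimated by moment matching on the
replicate pairs — `E[(x1-x2)^2/2] = m + phi m^2` pooled over peaks and
conditions, clipped at zero — because a 2-vs-2 design cannot identify
per-peak dispersions. The test conditions on the pooled count `s = A + B`
of the two condition sums: under the null both sums are NB with mean `s/2`
and size `2/phi`, and the two-sided p adds the conditional probabilities of
all outcomes no more likely than the observed one (the Poisson limit
`phi = 0` reduces exactly to Binomial(s, 1/2)). Peaks at FDR < 0.05 are
Gain (KO > WT) or Loss (WT > KO). The construction is symmetric, so
swapping condition labels swaps Gain and Loss and leaves every p-value
unchanged — asserted exactly in the tests.

Gene-set overlap (targets vs DEG classes) is a two-sided Fisher test on the
2x2 partition of a gene universe. The universe defaults to genes passing
the expression filter of the DEG analysis plus the DEG table itself; the
reported percentage (bound share of a class) is universe-independent, the
p-value is not.

## The synthetic experiment

The generator emulates a small stranded CLIP experiment end to end: a toy
genome of two 600-kb chromosomes plus a 16-kb mitochondrial-like contig;
60 protein-coding genes (3-6 exons, CDS and both UTRs), 10 lncRNAs — one
with a 6-kb first intron and the highest lncRNA abundance, standing in for
an intron-retaining nuclear lncRNA — and 6 rRNA/tRNA blacklist genes plus
2 mitochondrial genes. Expression is lognormal (sigma 0.3, a
post-expression-filter transcriptome rather than the full dynamic range);
exonic bins get a x3 coverage boost. Per-bin fragment counts are NB with
size 100 (phi = 0.01, concordant IP duplicates from one lysate);
fragment lengths are uniform 30-60 nt (CLIP footprint scale), strand equals
the host gene strand. The Input library is sampled twice as deep as the IPs
(`input_scale = 2`), as Input libraries typically are.

Binding sites are single 200-bp bins fully inside genes with at least
median expression, constrained to overlap an exon — at the simulated depth
only exonic-level coverage makes a planted site identifiable, mirroring the
coverage dependence of real CLIP (real MATR3 binding is intron-dominated;
the toy does not emulate that, see limitations). Sites are planted at
enrichment levels E in {2, 4, 8, 16}, three per level; the (E-1)-fold extra
IP fragments all span the planted summit, because real CLIP fragments
contain the crosslink footprint — this is what makes the computed coverage
summit coincide with the binding site. The UUCUU consensus (DNA template
TTCTT, reverse-complemented for minus-strand hosts) is written centred on
the summit for 90% of planted peaks. Two sticky transcripts receive
Input-level IgG coverage (IgG is otherwise at 8% depth). In the knockout,
the lncRNA is silenced, half the peaks (ko_fate = loss) revert to E = 1,
and a 10% tranche of gain peaks (E = 1 in wild type) switch on.

What passing tests show — and what they do not: the simulator draws from
the same NB family the caller fits, places non-overlapping genes, and has
no mappability artefacts, PCR duplicates, crosslinking biases or antisense
transcription. Recovery of planted truth therefore validates the
statistical machinery and the filter plumbing, not performance on real
libraries.

## Problem sizes and determinism

Every random draw descends from a single integer seed
(`numpy.random.default_rng` with structured seed sequences), and identical
configuration plus seed reproduces byte-identical FASTA/GTF/BED outputs.
Test and acceptance runs use desk-scale sizes chosen as the package's
standard validation workload: full simulations of ~1.2 Mb / ~45k fragments
per IP library; ZTNB recovery on 50,000 draws; null calibration on 50-200
columns of 2,000 ZTNB bins; planted-peak recovery pooled over three
simulations; loss recovery pooled over two WT/KO pairs; Fisher-oracle
equivalence on all 2x2 tables with grand total <= 16 plus 400 random
tables.

## Known limitations

- The global ZTNB ignores covariates (expression, mappability); weak
  intronic sites on lowly expressed genes are systematically missed.
- The quartile filter's alternative (Input-side) reading is implemented but
  untested against real data.
- The presence/absence motif test ignores occurrence counts per window and
  motif positional weight matrices.
- The differential test uses one common dispersion; with more replicates a
  per-peak (tagwise) estimate would be preferable.
- Gain peaks are detectable only when they reach the WT-selected consensus;
  a union consensus (WT + KO selections) would be needed to study gains
  systematically.
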