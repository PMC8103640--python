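# Methods

This note documents the models and procedures medsweep implements, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where practice leaves
the procedure under-determined.

## Two-population sweep scan

### Estimators

Fst is the Weir & Cockerham (1984) variance-component estimator θ̂ for
r = 2 diploid subpopulations. Per biallelic site, with n_i called
individuals, alt frequency p_i and observed heterozygote frequency h_i in
population i, the among-population (a), among-individual (b) and
within-individual (c) components are computed from n̄, n_c, p̄, s² and h̄ as
in the original derivation. A window's estimate is the ratio of sums
θ̂_w = Σa / Σ(a+b+c) — the "weighted" form that classical Fst tooling
reports — rather than an average of per-site ratios, which is biased for
low-information sites. Windows with a zero denominator are undefined and
never ranked. Negative θ̂_w values are retained by default (clamping to 0
is available) so that the ranking of outlier windows is not distorted.

Nucleotide diversity uses the unbiased per-site form
π = 2·c_ref·c_alt / (n(n−1)) over called alleles, summed over a window's
SNPs and divided by the window span in bp. The per-bp normalization cancels
in the log₂(π_control/π_tolerance) ratio; it is stated so per-window values
are reproducible. The ratio is undefined when either π is 0, and the
ratio screen ranks only strictly positive values (windows where the
tolerance population lost diversity relative to control), matching the
convention of plotting only positive ratios in this kind of scan.

### Missing data and window policy

Allele counts are per-site, per-population over called genotypes only. A
site enters the Fst sums only when both populations have ≥ 2 called
individuals; a site enters a population's π only when that population has
≥ 2 called alleles. Windows are 40 kb sliding by 20 kb (both configurable),
0-based half-open internally and in BED output, starts at multiples of the
step, truncated terminal windows kept but flagged. A window needs
≥ `min_snps` (default 10) usable sites to be ranked; this suppresses
noise-dominated windows and is configurable because no universal value is
right for every SNP density.

### Screening and regions

Each statistic's screen selects the top floor(q·N) windows (q = 0.05
default) among defined values, plus any windows tied with the boundary
value; when floor(q·N) = 0 nothing is selected and a warning is emitted.
The two screens combine by intersection by default — a window must be an
outlier in both differentiation and diversity loss — with union available;
selected windows that overlap or abut merge into maximal regions. A gene is
a candidate if its 1-based span overlaps a region by at least one bp.

## Synthetic genotypes

Background sites follow the Balding–Nichols model: ancestral frequency
p ~ Uniform(0.05, 0.95) (bounded away from the edges so sampled sites are
polymorphic with high probability), and each population's frequency is
Beta(p(1−F)/F, (1−p)(1−F)/F), whose expected Weir–Cockerham Fst is ≈ F.
F = 0 short-circuits to both populations sharing p exactly. Genotypes are
Binomial(2, frequency) — Hardy–Weinberg within populations, no inbreeding,
no linkage: sites are exchangeable draws, which is exactly what the
estimator's sampling theory assumes and what a recovery test should use.

Sweeps are deterministic frequency distortions, not coalescent histories.
Inside a sweep interval the tolerance-population frequency moves toward its
nearer extreme e ∈ {0,1}: p ← e + (p−e)/pi_reduction, shrinking expected
heterozygosity ≈ pi_reduction-fold; the control frequency moves a fraction
`divergence_boost` toward the opposite extreme, raising divergence. The
construction keeps truth exact and runtime trivial; the scan is being
tested on signal shape and ranking, not on evolutionary realism (no
hitchhiking gradients, no recombination structure — a real sweep's flanks
decay smoothly, these have sharp edges).

The frozen sweep-recovery experiment uses one 4 Mb chromosome, 40k SNPs,
7 vs 7 diploids (mirroring a top-7/bottom-7 accession split), background
F = 0.15, and three 80 kb sweeps with pi_reduction = 10 and
divergence_boost = 0.25. The boost value was calibrated so sweep-window Fst
is ≈ 3× the background level — a strong but not degenerate signal. Sweep
width matters structurally: the three sweeps overlap ~13 of 200 windows,
against a top-5% budget of 10 windows per statistic; wider plants would
exceed what the screen can select and make full recovery impossible by
construction.

## K-mer genome size

Reads are decomposed into canonical k-mers (lexicographic minimum of the
window and its reverse complement; k odd so no window is its own reverse
complement), windows containing N skipped. The estimate is
total k-mers / major-peak depth: at depth c, a genome of G distinct
positions contributes ≈ G·c k-mer observations peaking at multiplicity c,
so the ratio recovers G. With read length L the effective peak sits near
c·(L−k+1)/L.

The major peak can be taken over the raw histogram (the literal formula) or
after a first-local-minimum cutoff that excises the low-multiplicity error
spike; sequencing errors inflate the literal total, so both modes exist and
the cutoff mode is the default peak-finder. Heterozygous genomes put
haplotype-specific k-mers in a secondary mode near half depth; when a
secondary local maximum ≥ 20% of the major peak sits near half or double
the chosen peak, the estimate is flagged ambiguous rather than silently
resolved. Counting is chunked (per-read numpy encoding folded into a
running map every ~2M k-mers); inputs are assumed to fit in memory at the
scales this package targets — no on-disk partitioning is implemented.
Heterozygosity and repeat mixture modeling are out of scope; the histogram
exports in the two-column format those models consume.

## Synteny and 4DTv

Anchors (similarity gene pairs, e-value filtered upstream) are ranked by
gene order per chromosome. Within each chromosome pair, an O(n²) dynamic
program finds the longest chain with rank_a strictly increasing and rank_b
strictly increasing (+) or decreasing (−), breaking when either rank gap
exceeds `max_gap` (default 25 intervening genes, the collinearity-tool
convention; only the 5-gene block minimum is externally fixed). Chains are
extracted greedily by descending length, each anchor joining at most one
block; chains shorter than `min_block` = 5 are discarded. Full
weighted-interval optimization is unnecessary at gene-order scale.

A codon column is a comparable fourfold-degenerate site iff both codons are
gap/N-free, share their first two bases, and that prefix belongs to a
fourfold family of the standard code (TC*, CT*, CC*, CG*, AC*, GT*, GC*,
GG*). Requiring the shared prefix (rather than independent degeneracy) is
the stricter and unambiguous reading. 4DTv is the uncorrected transversion
fraction at those sites — no multiple-hit correction, so expected 4DTv
saturates at 0.5(1−e^(−4βT)) under K80 with total transversion parameter
βT. Pairs with fewer than `min_sites` = 10 comparable sites are reported
undefined rather than noisy. Peak detection histograms values on [0,1]
(bin 0.01), smooths with a 3-bin moving average, reports local maxima
ranked by height (plateaus refined to the raw-histogram mode), and flags
distributions whose maximum is < 1.5× the median smoothed bin as not well
separated. Binning and smoothing are configurable since no convention is
canonical.

## Retention/loss

Best-hit rows sort by target (chromosome, start); targets without a
reference partner are NA. The absent region for an NA gene is the reference
interval strictly between the spans of the reference partners of the
nearest paired neighbours (consecutive NA runs share flanks); partners on
different reference chromosomes leave the region undefined ("split
flanks"), and an NA gene at a chromosome end searches from its single
partner's span to the chromosome end. Regions never overlap the flanking
partners' spans.

The search is a built-in six-frame translated local alignment: the region
is translated in all six frames, stop codons split frames into segments,
and the target protein is aligned locally against each segment under
BLOSUM62 with affine gaps (open 11, extend 1). A best hit with identity
≥ 50% and query coverage ≥ 50% (both configurable; no external convention
fixes them) calls the gene `present_unannotated`; a completed search below
thresholds calls it `lost_in_reference`; undefined or all-N regions are
`unresolved`. A hit clearing identity but not coverage is flagged
`partial` — intron-containing or stop-disrupted copies can truncate
coverage in an unspliced aligner, and flagging is safer than silently
calling loss. An external spliced-alignment tool can replace the built-in
search through the same call interface.

## Enrichment and motifs

Enrichment is the one-sided hypergeometric upper tail
P(X ≥ k | N, K, n), computed via the survival function in log space, with
Benjamini–Hochberg step-up correction across tested terms and the rich
factor k/K reported per term. The universe defaults to all annotated genes
in the supplied map; annotation is taken as given (no GO-graph
propagation). Motifs are IUPAC strings expanded to character classes and
scanned on the forward strand and, optionally, as the reverse-complement
pattern (palindromic motifs are not double-counted); overlapping mode
counts every start position. The MYB-core filter keeps genes with strictly
more than `min_count` = 2 occurrences ("more than two"), with a flag for
≥ semantics since the phrase is ambiguous; the motif itself is a required
configurable (default CNGTT, a common MYB-core consensus) because no
single catalogue entry is canonical. Promoters default to the 2 kb
strand-aware upstream window.

## Pipeline

`run_sweep_pipeline` executes read → windows → Fst/π → ratio → top-5% →
regions → genes → enrichment, writing every stage artifact plus the
resolved configuration and a manifest (version, seed, config hash, record
counts). Outputs contain no timestamps, so identical configurations produce
byte-identical files; wall times go to the stderr log. Validation checks
formats and ID consistency up front (population IDs ⊆ VCF samples; GFF
falls back from `gene` to `mRNA` features with a warning) and failures exit
with code 2 before any computation.

## What passing tests do and do not show

The generators share the estimators' own sampling assumptions
(exchangeable unlinked sites, Hardy–Weinberg, uniform read starts, uniform
substitution errors, gap-free codon alignments, single-exon genes). Tests
therefore demonstrate correctness of the implementations and recovery under
the generating model — not robustness to linkage, inbreeding, alignment
error, indels, splicing, GC-biased coverage, or ascertainment, none of
which the synthetic data contains. Known limitations: the k-mer counter is
in-memory; the translated aligner is unspliced; 4DTv is uncorrected for
multiple hits; the scan has no kinship or structure correction.
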