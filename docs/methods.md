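# Methods

This note documents the models, conventions and numerical choices behind
`dsbrna`, and what the synthetic-data generators do and do not emulate.

## Coordinate and cut-geometry conventions

All coordinates are 0-based half-open internally; SAM input is converted
at the I/O boundary (pysam already exposes 0-based coordinates), BED is
native. AsiSI recognises the palindromic 8-mer `GCGATCGC` and cleaves
`GCGAT^CGC` on each strand, leaving a 2-nt 3′ overhang on the central
`AT`. We fix, for a motif starting at `m`:

- `overhang = [m+3, m+5)` — the `AT` dinucleotide;
- `cut_anchor = m+4` — a single coordinate inside the overhang used as
  the origin ("0") of every site-anchored profile.

The literature describes the cut qualitatively; a single-point numeric
convention was needed and this one is used consistently everywhere
(scanning, windows, profiles, the simulator), so all offsets are
internally coherent. Because the motif is its own reverse complement,
one forward-strand scan is strand-complete; `N` bases never match.

## Analysis windows

Site-anchored windows use 10-bp bins covering 5 kb either side of the
cut anchor (`WindowSpec(half_width=5000, bin_size=10)`): 500 bins per
side, 1000 per site, tiled without gaps and clipped (with a flag) at
chromosome ends. Bin offsets are reported relative to the cut anchor,
negative upstream.

## Small-RNA stage

**Trimming.** Library construction appends the 3′ adapter
`TGGAATTCTCGGGTGCCAAGG` and ligates 4 degenerate nucleotides to each
side of the insert (a ligation-bias reduction). The trimmer cuts at the
leftmost exact occurrence of the full adapter, or at an adapter prefix
of ≥ 10 nt that reaches the read's 3′ end (the adapter ran off the
sequenced length); it then removes 4 nt from each side and discards
inserts shorter than 15 nt. Exact matching was chosen because the
simulated reads are error-free; the 15-nt floor leaves margin below the
19–26-nt analysis range. Discards are tallied, never raised.

**Classification.** Reads are assigned to the first annotation class
they overlap by ≥ 1 bp, in the fixed order miRNA → tRNA → snRNA →
snoRNA → scRNA → Y RNA → sRNA; everything else is *residual*, and only
residual reads enter the site-level analysis. The order encodes
"miRNA hairpins first", then the remaining small-RNA gene classes; ties
beyond that are broken by this fixed order since no natural priority
exists among them.

**Counting.** A read counts for a site iff it overlaps
`[anchor − 5 kb, anchor + 5 kb)` by ≥ 1 bp (any-overlap; a containment
flag is exposed). Reads overlapping two site windows count once per
site, so column sums can exceed the residual library size when windows
overlap — flagged with a warning, not an error.

**Signed coverage.** Per bin: (plus-strand read-bases − minus-strand
read-bases) × 10⁶ / residual-library-size; minus-strand coverage
plots below the axis. The averaged profile is the mean over sites at
each bin offset.

**NB window test.** The undamaged (0 h) time point is contrasted with
all damage time points pooled. Size factors are median-of-ratios over
sites with nonzero counts in every sample. Per site, a moment
dispersion `α = max(0.01, (s² − μ)/μ²)` is computed from the normalised
counts *across all samples, with no group structure*: a genuine group
shift then also inflates the variance the effect is tested against.
This deliberately conservative estimator keeps the empirical type-I
error at nominal 0.05 within [0.03, 0.07] at the study's small
replicate numbers (2–8 per group), where pooling within-group variances
makes the normal-reference Wald test anticonservative (~0.08 measured).
The Wald statistic is `log2((μ_d + ½)/(μ_c + ½)) / SE` with the
delta-method SE from the NB variance `μ + αμ²`; p-values are two-sided
normal, BH-adjusted values are reported alongside, and the volcano
table plots −log10 of the *unadjusted* p against log2FC (when every
adjusted p is ≈ 1, the raw-p volcano still shows the spread). Sites
with all-zero counts get log2FC = 0, p = 1 and a flag.

## Transcription-matched controls

Break-proximal signal is compared against undamaged loci of similar
transcriptional activity. For each cut site's host gene, candidate
controls are non-cut genes within ± 0.25 of it in both
`log10(TPM + 0.01)` and `log10(length)`; one is drawn uniformly at
random (seeded), without replacement across sites by default. If no
candidate qualifies — or every qualifying candidate is rejected because
its anchor window would leave the chromosome or contain a recognition
motif — the tolerance doubles (logged) until a match exists. The control
anchor sits at the cut site's TSS distance along the control gene,
measured along the gene's strand (downstream positive). The 0.25-log10
box, the 0.01 TPM pseudocount and the doubling fallback are package
choices (no numeric tolerance exists in the literature for "similar");
all three are exposed as parameters. By construction no matched anchor
lies within the half-width of any recognition motif, mirroring an
empty-vector control that can never have been cut.

## DRIP stage

**Fragments.** The sequenced fragment is
`[min(mate starts), max(mate ends))`. Interchromosomal pairs, pairs
with inconsistent read1/read2 flags, unpaired records and fragments
longer than 2500 bp are dropped and tallied by reason.

**Enrichment.** Coverage is *fragment-base* coverage (not midpoint
counts; a flag would be trivial to add but base coverage matches how
hybrid-containing DNA is read out). Per repair class, per bin: mean
over that class's sites of binned coverage × 10⁶ / library fragments;
enrichment is `log2((damaged + c)/(undamaged + c))` with `c` = 1
fragment-base per million — finite everywhere, exactly 0 where both
conditions are empty. Libraries are depth-normalised *before* the
ratio. Note a composition effect: enriching cut-site windows dilutes
the per-million background, so uncut loci sit slightly below 0
(≈ −0.04 log2 at the default geometry); this mirrors real
per-million-normalised IP data.

**Overhang fine structure.** Per-nucleotide coverage at offsets
−radius..+radius from the cut anchor, summed over sites. The overhang
occupies offsets −1 and 0; the dip statistic divides mean overhang
coverage by mean coverage over the 10 flanking positions each side. 0
means every fragment end respects the cut; ≈ 1 means fragments ignore
it.

**Metagene.** Genes are stratified into TPM quantiles (default 4);
coverage around TSS and TES (flank 2 kb, 50-bp bins) is strand-aware
(upstream negative; a minus-strand gene's upstream flank maps to higher
genomic coordinates) and normalised per million fragments.

## qPCR quantifications

- `%ssDNA = 100 / (2^(ΔCT−1) + 0.5)`, ΔCT = digested − undigested mean
  cycles. The −1 and 0.5 constants come from the originating assay's
  geometry (one strand of a resected duplex protects the amplicon) and
  are implemented verbatim; ΔCT = 0 gives exactly 100 %, the function is
  strictly decreasing, and ΔCT < 0 triggers a "super-unity" warning
  rather than an error.
- ΔΔCT: `ΔCT = mean(target) − mean(reference)` per condition; the fold
  is `2^−(ΔCT − ΔCT_control)`; the control condition returns exactly 1.
- Percent input: `100 × 2^(ct_input − log2(input_fraction) − ct_ip)`;
  the formula is standard IP practice (not specified in the source
  analysis), so `input_fraction` is a required argument. ChIP
  efficiency is the target/H3 percent-input ratio.
- Laser stripes: damage-stripe intensity over a background stripe in
  the same nucleus, first time point scaled to exactly 1.
- Reporter efficiency: GFP-positive proportion over the control
  condition's proportion; control exactly 1.

Replicates aggregate by arithmetic mean of CTs; no outlier rejection.

## Synthetic data: what it emulates, and what it does not

Default geometry: 3 chromosomes × 1 Mb, 40 planted motifs of which 12
are cut, split 3 HR / 3 NHEJ / 6 unspecified by largest-remainder
scaling of the canonical 25:25:49 proportions. This is a deliberate
~30× scale-down of the real system (~1220 recognition sites, 99 cut,
3 Gb genome) sized so profiles are well-populated and generation takes
well under a minute. Motifs are planted ≥ 25 kb apart (site windows
never bleed into each other) and ≥ 10 kb from chromosome ends; the
random background is rescrubbed until the motif occurs *only* at
planted positions, so the scanner's census against truth is exact.
Positions are drawn uniformly under the separation constraint (sorted
uniforms plus fixed spacing).

Small-RNA libraries: 70 % annotated small-RNA gene reads (miRNA-
dominated mixture), 30 % uniform residual background, plus an optional
planted 21–23-nt species within ±500 nt of cut anchors at
`planted_dsb_fold` × background density. Raw FASTQ reads are 4 random
nt + insert + 4 random nt + adapter, truncated to 75 nt, so the trimmer
provably inverts the construction. Annotation intervals are kept ≥ 1 kb
clear of motif anchors so planted break-derived reads always classify
as residual.

DRIP libraries: undamaged fragments uniform with lengths
~ U(300, 1000); damaged fragments add extras around cut sites drawn
with the length-biased, overlap-conditioned distribution of background
fragments overlapping the ±span window, which makes the planted
coverage ratio uniformly `enrichment_fold` across the span (uniform
fragment *centres* would taper toward the span edges and bias the
recovered log2 low). With probability `adherence`, a damaged fragment
overlapping a cut is truncated at the cut — mirroring the in-vitro
digestion of the damaged template — so at adherence 1 the 2-nt overhang
has exactly zero coverage. Mates are emitted directly as 75-nt
alignment records (no aligner in the loop), matching 2 × 75 bp
sequencing.

Count-level simulator (`simulate_region_counts`): NB counts with the
study design — 2 replicates at 0 h versus 2 replicates × 4 damage time
points — at μ = 50, α = 0.05, with an optional fold shift planted in
the damage group of one site. It is used where many-seed repetition
matters (type-I calibration, null/planted detection rates); the full
read-level path (simulate → trim → classify → size-filter → count →
test) is exercised at fewer seeds.

qPCR: ΔCT is set by inverting the %ssDNA formula
(`ΔCT = 1 + log2(100/f − 0.5)`); undigested CTs ~ N(22, σ), digested
CTs add ΔCT plus independent N(0, σ) noise; σ = 0 round-trips exactly.

Not emulated: sequencing errors, PCR duplicates, mappability and
multimapping, chromatin accessibility of cutting, transcription-coupled
hybrid formation. Passing tests therefore validate the *computations*
on data with the assumed statistical structure; they do not revalidate
the upstream biology or the behaviour of aligners.

## Problem sizes and determinism

All generators are deterministic given their seed; derived seeds are
spawned with `numpy.random.SeedSequence` and kept below 2³¹. The
acceptance script runs at: census and matching on the default genome;
oracle agreement on 20 × 10³-element instances; null/planted detection
on 100 seeds × 12 sites; type-I error on 50 seeds × 200 sites; DRIP
recovery on 3 libraries of 2 × 10⁵ fragments (at 10⁴ fragments the
3-HR-site geometry leaves a sampling sd of ~0.3 on the in-span mean
log2, too coarse to characterise the estimator; 2 × 10⁵ × 3 brings it
to ~0.05); overhang dips on 3 × 10⁴ fragments; resection on 100 seeds ×
4 fractions. The whole script completes in well under a minute of CPU.

## Known limitations

- The NB test is a self-contained Wald test in the DESeq2 family, not a
  bit-compatible reimplementation of any published tool (no dispersion
  shrinkage across sites, no LFC moderation). At the study's replicate
  numbers its calibration is verified empirically instead.
- Adapter trimming is exact-match; reads with sequencing errors inside
  the adapter would be discarded rather than rescued.
- `match_control_sites` enumerates candidates per cut site
  (O(sites × genes)); fine for 10²–10⁴ genes, not tuned beyond that.
- The overhang dip statistic is undefined (NaN) when the flanking
  coverage is zero.
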