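# Methods

## The measurement model

TimEX-seq infers replication timing from DNA copy number. Cells in G1 carry
two copies of every locus; cells in S carry between two and four, in
proportion to how early the locus replicates. The per-locus ratio of
read depth in an S-phase library to a G1 library is therefore a surrogate
for replication time, spanning a theoretical range of 1 (latest) to 2
(earliest) after scaling. Allele specificity comes from restricting to
reads that cover phased heterozygous SNPs, which split the signal into a
maternal and a paternal track at the cost of roughly a ten-fold reduction
in usable reads.

A profile is built per homolog as:

1. sum allele depths of SNPs into 500 bp bins (bins without a SNP are
   flagged uncovered, never zero-filled);
2. normalize each track to its genome-wide total of SNP-containing reads;
3. smooth with a Gaussian kernel, sigma = 100 kb, truncated at 4 sigma,
   with weights renormalized over covered bins only so that SNP deserts do
   not dilute the average;
4. divide the smoothed S track by the smoothed G1 track and multiply by
   1.4, which maps typical values into roughly 0.9–2.1.

The high-resolution, non-allele-specific variant uses 1 kb bins, drops raw
ratios above 2.4, smooths at sigma = 20 kb and finally indexes the covered
values affinely onto [1, 2] (a robust flag switches the anchors to the
0.1/99.9 percentiles).

## Asynchronously replicated domains

The maternal-minus-paternal difference track is scanned by a gap-tolerant
island finder: maximal runs of covered bins at or beyond ±0.02 are merged
across gaps up to 250 kb and kept if they span at least 50 kb; opposite
signs never merge. Each island's statistical support is a Pearson
chi-square (1 df, no continuity correction) on the 2×2 table of raw summed
reads (maternal/paternal × S/G1) inside the island, followed by
Benjamini–Hochberg correction across all candidate islands genome-wide and
a 5% FDR cut. Cores are re-called inside each domain with threshold 0.1
and gap 50 kb. Mean differences convert to minutes as
`diff × 480 / 1.2` (480-minute S phase; the observed 0.9–2.1 value range
spans 1.2× the theoretical range, and we apply the factor as a division,
with a switch for the opposite convention).

A caveat worth stating plainly: the chi-square is evaluated on the same
reads that the island finder used for selection, so p-values of
noise-selected islands are anti-conservative. On unselected null data the
test is exactly calibrated (the null-calibration tests verify a median of
zero significant calls), but in spiked simulations the pooled empirical
FDR of the procedure lands above the nominal 5% (about 10–20% under the
benchmark geometry). We implement the published procedure as described
rather than repairing it (e.g. by data splitting), and report both the
false/true and the false/total FDR variants.

## Synthetic data

The generator produces what the method assumes rather than what a
sequencer produces:

- **SNP positions.** Haplotype-like density blocks of 100 kb–1 Mb, each
  with a characteristic spacing drawn uniformly from 500 bp–5 kb; gaps are
  jittered ±25% around the block spacing and clamped to the bounds, so any
  100 kb window stays within the configured density range.
- **Timing landscape.** A stationary Gaussian field mapped through the
  normal CDF onto [1, 2], autocorrelated at `timing_domain_scale`
  (default 1.5 Mb, the scale of mammalian timing domains: the lag at which
  the underlying field's autocorrelation falls to exp(−1/2)).
- **Depths.** Per SNP, per homolog: G1 ~ Poisson(λ), S ~ Poisson(λ·t/t̄)
  with t the local timing value and t̄ its genome mean. The default study
  condition is λ = 12.5 per homolog per fraction, i.e. ~25× site depth per
  fraction at a heterozygous SNP, matching the coverage the method was
  designed around.
- **Spike-in asynchrony.** Inside each spiked region on one homolog the
  per-SNP total (S+G1) count is inflated to `round(total·(1+e))` with all
  extra reads assigned to S; every SNP of both homologs is then passed
  through a binomial resampler, Binomial(total, S/total). For benchmark
  baselines both homolog "controls" are resampled from the same observed
  track (`control_pair`), so their contrast carries resampling noise only —
  this is what makes the island chi-square calibrated on null data, and it
  mirrors how the original simulation constructed its controls.

What the generator deliberately omits: mappability and GC bias, phasing
errors, alignment artifacts, and the extra-binomial variance of real
libraries. Passing benchmarks therefore demonstrate correctness of the
statistical machinery under the stated noise model, not performance on
real sequencing data; on real data the per-island information content is
lower and detection thresholds correspondingly worse.

## The spike-in power study

Spiked regions must not overlap, so a 200 Mb genome cannot host 150
regions of 2 Mb; each (size, excess) condition instead accumulates
independent replicate genomes, each carrying spikes over at most 25% of
its length, until the requested region count (default 150) is reached.
Metrics per condition:

- **detection rate** — spiked regions overlapped (≥1 bp) by a significant
  domain, over all spiked regions;
- **empirical FDR** — significant islands overlapping no spiked region,
  reported both relative to the true-overlapping count (the convention the
  original figure legend prints) and relative to all significant islands;
- **distortion** — per max-overlap-matched pair, detected/true ratios of
  size and of timing differential. The "true" differential of a region is
  measured by running the identical profile pipeline on the noise-free
  expected counts, which isolates what smoothing and detection do to the
  signal. Sizes are overestimated by the kernel smear (~0.2 Mb per side at
  sigma = 100 kb), so the size ratio sits near 1.2 for 2 Mb regions and
  grows as regions shrink; the differential ratio stays within ~10% of
  unity for regions ≥ 500 kb.

Note on units: a spike of excess e multiplies the in-region S/G1 ratio by
roughly (1+2e) when S ≈ G1, so the induced profile differential is ~2.8e,
not the 1.2e that the nominal "e × 480 minutes" label suggests; recovered
delays are therefore compared against the induced differential, and the
nominal conversion `excess_to_minutes` is provided as the separate
bookkeeping quantity it is.

Problem sizes were chosen so the full study (one 2 Mb condition plus
ascending excess sweeps at 1 Mb and 500 kb, 150 regions each) completes in
about a minute on one CPU; per-cell Monte-Carlo error on a detection rate
near 0.9 with n = 150 is ±2.5 points (1 SE).

## Ripples, fractions and interval statistics

Sub-domain "ripples" are exposed by subtracting the sigma = 100 kb smooth
from the sigma = 20 kb smooth of a high-resolution profile; candidate
peaks are maximal positive runs of the residual, scored by area (sum of
residual over the run), and the top 10% by area are kept. The genome is
partitioned into S1–S5 quintiles by sorting covered bins on profile value
(descending, ties broken by genomic order) and cutting into equal-count
groups. Overlap between peak sets is the fraction of intervals in one set
touched (≥1 bp) by the other; the coverage-based random expectation
multiplies the two fractional covers and a partial-overlap factor of 3,
exactly as the source analysis printed it (we note that formula mixes a
per-peak fraction with a coverage product; the empirical alternative —
re-placing intervals uniformly inside a stated territory with widths
preserved — is implemented in `randomize_intervals` and is what the
bootstrap enrichment and SV tests use).

Nascent-strand peak post-processing follows the published recipe: peaks
are re-centred into 400 bp windows (merging overlapping windows, which is
why the count drops by roughly half), optionally truncated to the top
100,000 by score, and associated to feature windows (CpG intervals as
given, 1 kb on TSSs, 400 bp on G4/DHS midpoints) by ≥1 bp overlap.
Enrichment folds divide the observed association percentage by its mean
over uniform re-placements (100 iterations by default; the add-one
correction is not applied here because the fold, not a p-value, is
reported).

The structural-variant analysis measures allelic asynchrony as the
maternal/paternal profile ratio in 5 kb sub-windows (inverted below 1),
averaged over 500 kb windows sliding every 100 kb; windows are classed by
the largest overlapping SV (none, ≥10 kb, ≥50 kb, ≥100 kb). Significance
re-places the SVs uniformly (widths preserved) and reports the add-one
corrected fraction of randomizations whose SV-window mean reaches the
observed one (the original analysis used the raw fraction over 100,000
randomizations; the correction only matters at small counts). Log-ratio
and absolute-difference differentials are available behind a flag.

## Numerical and design notes

- Coordinates are 0-based half-open everywhere internally; 1-based only in
  the allele-depth TSV (VCF convention).
- Smoothing uses overlap-add convolution; equality with a direct
  O(n·k) evaluation is enforced to 1e-9 relative error in the tests.
- Division-by-zero G1 bins are masked, not errors — SNP deserts make them
  routine.
- Zero marginals in a contingency table return p = 1 with a warning.
- All randomness flows from explicit seeds through per-stage child
  streams, so each pipeline stage is independently reproducible; every
  generator is byte-identical under a fixed seed.
- The island finder treats opposite-sign bins as gap content; islands are
  bounded by their first and last qualifying bins.
- Empirical FDR with no true-overlapping detection is reported as NaN and
  flagged rather than raising.

## Known limitations

- Real-data catalogues (domain counts per individual, real association
  percentages, real NS correlations) require the original sequencing data
  and annotation snapshots and are out of scope; the corresponding
  machinery is exercised on synthetic fixtures.
- The selection/test coupling discussed above means FDR control of the
  domain caller should not be taken at face value on real data either.
- The Poisson/binomial noise model bounds the realism of power estimates
  from above; detection limits quoted for the original data are broader
  than what this generator reproduces at the same nominal depth.
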