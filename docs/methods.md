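# Methods

## The MACC statistic

Chromatin digested with micrococcal nuclease (MNase) at several enzyme
concentrations releases fragments at rates that depend on local
accessibility: open chromatin yields fragments already under light
digestion, while protected chromatin requires heavy digestion.  For a
titration with concentrations c₁…cₖ (defaults 1.5, 6.25, 25, 100
units), fragment midpoints are counted in 100-bp non-overlapping bins,
each concentration's column is scaled to counts per million (CPM), and
the per-bin accessibility score is the ordinary least-squares slope of
CPM frequency against x = −ln c:

    MACC(b) = slope of { (−ln cⱼ, CPMⱼ(b)) : j = 1…k }

High frequency at low concentration — open chromatin — gives a
positive score.  The log base is configurable; any base rescales all
scores by one constant, so comparisons are unaffected.  The fit is
unweighted across the four points.

Steps around the fit:

* **Hotspot filter.** Per library, positions whose fragment-start
  count has Z ≥ 7 against the mean/SD over all covered positions are
  masked and their fragments discarded.  The reference population is
  all positions with ≥ 1 start in that sample; with uniform coverage
  (SD = 0) nothing is masked and a warning is emitted.
* **Fragment selection.** Fragments are assigned to bins by midpoint
  (each fragment lands in exactly one bin).  The MACC size window is
  100–200 bp; nucleosome-resolution read-frequency profiles use
  140–160 bp.  Both are parameters.
* **GC correction.** The expected score as a function of bin GC is
  estimated by LOWESS (span 0.3) over all scored bins and removed,
  re-centering on the global mean: corrected = raw − fitted + mean.
  Bins with no GC value (all-N sequence, or no FASTA) pass through and
  are flagged; with fewer than 100 GC-bearing bins the correction
  refuses and warns.  Filtering precedes normalization; the order is a
  configuration choice and is logged.
* **Validation transforms.** `median_shift` subtracts each sample's
  genome-wide median (MACC is a relative quantity; the shift makes
  cross-sample Δ comparisons robust to composition differences), and
  `double_x_reads` doubles raw X-linked counts before renormalization
  to mimic equal X copy number — since CPM normalization cancels any
  uniform per-column scaling, autosomal slopes are unchanged.

Coordinates are 0-based half-open everywhere (BED convention).

## Differential accessibility

Replicates are scored separately and compared with a moderated
two-sample t statistic per bin.  The per-bin pooled variance s²
(df = n₁ + n₂ − 2) is shrunk toward a prior s₀² with weight d₀
estimated by method of moments on log s²: under the scaled-F model
var(log s²) = ψ′(df/2) + ψ′(d₀/2), inverted for d₀ (Newton on the
trigamma), and the moderated statistic is referred to a t distribution
with df + d₀ degrees of freedom.  The test matches limma's eBayes to
machine precision on shared input (checked in the test suite via
Rscript).  Per-bin p-values are used unadjusted at p < 0.01 for the
category tables, mirroring the study's reporting; a BH-FDR column is
emitted alongside.

Significant bins are classified by midpoint with precedence
TSS/TTS-proximal (±500 bp of gene ends, strand-aware) → enhancer
(±500 bp of centers) → gene body → unannotated; the precedence keeps
regulatory windows distinct from bodies where they overlap.
Genome-fraction normalization divides each category's count by its
merged, non-double-counted bp share under the same precedence.
Chromosome summaries report type-7 quartiles, the 1.58·IQR/√n notch
convention, and two-sided Mann–Whitney tests for X vs autosomes and
between conditions.

## Profiles

Bin values are anchored at bin centers and sampled on a 10-bp offset
grid by linear interpolation; per-offset means across anchors carry a
pointwise 95% normal-approximation CI (mean ± 1.96·sd/√n, sites
weighted equally), and averaged curves are smoothed with a short
running window (default 10 bp — effectively light at the 10-bp grid).
Minus-strand anchors contribute mirrored rows; anchors whose flank
leaves the chromosome are dropped and counted.  Metagene profiles
rescale each body to 100 positions with fixed-bp flanks.  Heatmap
rows are per-gene scaled-body signal ordered by ChIP occupancy
(descending) or by Δ (strongest decrease first), ties stable.
Score-based splits (high/low halves, quartiles) put boundary ties in
the lower group; the low half takes the extra element at odd n.

## Start-seq and qPCR

Observed TSS are the argmax of stranded 5′-end signal within ±250 bp
of the annotated start (ties to the lower coordinate; silent genes
excluded) — a simplified stand-in for the published redefinition
procedure, flagged as such.  Differential Start-RNA abundance uses
CPM-normalized log(x+1) counts with the same moderated statistic;
"positive regulation" is a significant decrease after clamp RNAi.
Regulation summaries round percentages to one decimal.

qPCR enrichment assumes perfect per-cycle doubling (efficiency
configurable): percent input = 100·2^((Ct_input − log₂(1/f)) − Ct_IP)
with input fraction f (default 1%, a log₂ 100 dilution adjustment);
log₂ fold enrichment is the log ratio of target to internal-control
percent input per replicate, averaged with SEM over (typically three)
biological replicates, with a two-sided t-test between conditions.
Technical-replicate Cts are averaged before the power transform.
ΔCt relative abundance is 2^(Ct_ref − Ct_target).

## Synthetic study design

The generator emulates the study's conditions so every stage can be
tested against known truth: a 3 × 1 Mb genome (one X, two autosomes),
~300 genes, enhancer centers, peaks with lognormal occupancy (2×
density on X), CES on the X in subgroups A/B/C at 176:43:45 scaled by
0.25 by default (full scale 264 sites), and a ~5% repeat mask.

Per bin, expected normalized frequency is linear in centered
x = −ln c:

    μ_b(c) = β_b + (a_b + g(GC_b)) · (x_c − x̄)

with lognormal baseline β_b (log-SD 0.2), a smoothed Gaussian slope
field a_b (SD 0.10) elevated near peaks by an exponential bump
(amplitude 0.25, decay 1 kb, truncated at 3 decay lengths), and a
smooth GC artifact g(GC) = 0.08·sin(2π·GC) acting on the *slope* so
the score — not just the coverage — is GC-confounded, as in real
MNase data; the recorded truth is a_b, making the MACC estimand equal
the true slope by construction.  Slopes are clipped so every expected
frequency stays positive.  Clamp RNAi removes the peak bump (a
distance-decaying loss); msl2 RNAi subtracts 0.20 only within 200 bp
of CES centers.  Counts are Poisson at the configured depth (2 × 10⁶
fragments per concentration by default; negative-binomial and
noise-free options exist); fragment lengths are Normal(150, 15)
truncated to [100, 250] bp with midpoints uniform within the bin.
Start-seq counts are negative binomial (dispersion 0.05) around
lognormal baselines with 10% of TSS perturbed ±4-fold under clamp
RNAi, decreases X-biased (62% vs 50%); these fractions and the
replicate-noise magnitudes are configuration placeholders — the study
they emulate reports no variance components, so defaults were chosen
once as plausible for nascent-RNA counts.  qPCR Cts invert the
percent-input model with Gaussian cycle noise (SD 0.1).

All randomness flows from one recorded seed through CRC32-keyed
substreams, so outputs are byte-identical across processes.

What the generator does **not** emulate: sequence-level MNase cut
bias, nucleosome phasing, mappability, duplicate reads, chromatin
contacts, or ChIP-seq coverage.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model,
not robustness to those real-data artifacts.

## Numerical and design notes

* Problem sizes: recovery runs use the default 3 × 1 Mb genome
  (30,000 bins); calibration/power use a 1 Mb genome (10,000 bins,
  depth 7 × 10⁵); the bundled demo pipeline uses 3 × 200 kb at depth
  2 × 10⁵ so an end-to-end run takes seconds.
* The power benchmark injects a balanced ± perturbation of 3× the RMS
  per-bin replicate noise SD; balancing the signs preserves library
  composition, which a one-sided injection would shift (CPM is
  relative), and the RMS matches the variance scale the moderated
  test shrinks toward.
* Because CPM normalization is relative, condition-wide perturbations
  leak a small compositional offset into all bins; the median-shift
  transform is applied before locality analyses for exactly this
  reason.
* LOWESS uses `delta` ≈ 0.5% of the GC range for speed; the
  correction is idempotent to smoother tolerance.
* Degenerate inputs: zero-variance bins give p = 1 at Δ = 0; all-equal
  scores collapse score splits to one group with a warning; zero-total
  library columns, empty anchor sets after edge filtering, and
  infeasible feature packings raise typed errors.
* bedGraph (not bigWig) is the native track format to stay text-only;
  adjacent equal values are merged on write and round-trip at six
  decimals.

## Known limitations

The obsTSS and Start-seq significance machinery are this package's
own definitions (the original delegates to external protocols);
results carry that caveat in metadata.  The per-bin differential
design (replicates as units, concentrations pooled into one slope) is
likewise this package's definition.  Real-genome inputs (BED/SAM
fragments, FASTA, GTF/BED12) are supported through the readers, but
behavior on full-size genomes is bounded by memory (dense per-bin
arrays) rather than streaming.
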