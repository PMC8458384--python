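# Methods

## Signal model

Aligned single-end reads are represented by their genomic footprints
(BED6). Each read is replaced by a fixed 200-bp interval anchored at its
5′ end and extended in read orientation — the standard fragment-length
surrogate for short single-end ChIP-seq libraries — then clipped to the
chromosome. Density is the number of extended reads overlapping each
50-bp bin (≥ 1 bp), scaled to reads per million mapped reads (rpm). By
default the normalising depth is the number of reads supplied, but it can
be overridden when a subsample is quantified against full library depth.

Region signal is Σ over bins of (bin value × overlapping bp / 50). The
pro-rata edge handling is a deliberate choice: it makes signal exactly
additive over any partition of a region and equal to length × density for
constant tracks. The units are rpm·bins; only ranks and differences of
this quantity are ever interpreted, so the unit convention is harmless.

ChIP and input tracks are each normalised to their own depth; no further
depth-ratio matching is applied before subtraction, and negative net
signals are kept (they rank last) rather than floored.

## Enhancer stitching

Reads overlapping ENCODE-style blacklist regions are removed before any
track is built. Peak calls from multiple upstream peak-calling parameter
sets are unioned (overlapping or abutting calls merge — two call sets of
the same mark describe one enhancer landscape). Peaks fully contained in
a TSS ± 2,000 bp promoter region are excluded from stitching; we treat
that region as the half-open 4-kb window `[TSS − 2000, TSS + 2000)`,
consistent with the 4-kb promoter windows used for annotation. Excluded
peaks are dropped from the enhancer universe entirely rather than
re-entering as singleton enhancers — ROSE variants exist with either
behaviour; they still contribute signal wherever a promoter window is
quantified. The remaining peaks are stitched transitively whenever the
same-chromosome gap (next start − previous end, half-open arithmetic) is
≤ 12,500 bp; a gap of exactly 12,500 stitches. Stitching never crosses
chromosomes. Ids are assigned in genomic order with chromosomes sorted by
name, so output is deterministic.

## Super-enhancer cutoff

Net signals are sorted ascending and both axes scaled to [0, 1]
(rank i → i/(n−1); signal min–max). The cutoff is the index maximising
(scaled rank − scaled signal): for a convex ranked curve this is exactly
where a slope-1 line is tangent, and the discrete argmax is robust where
a numerical derivative of an empirical step curve is not. Ties break to
the largest index, within an absolute tolerance of 1e-12 on the scaled
difference — this absorbs float rounding so that an exactly linear curve
(every point equidistant from the diagonal) yields zero SEs rather than
an arbitrary rounding-dependent cutoff. Enhancers with net signal
strictly above the cutoff signal are SEs; membership is therefore
downward-closed in rank and invariant to positive rescaling of all
signals. Fewer than two enhancers, or all-equal signals, raise a
degenerate-data error (CLI exit code 3): no cutoff is definable.

## Gene assignment

Active genes are the top floor(2N/3) of all N genes ranked by raw ChIP
rpm in TSS ± 500 bp (promoter windows clipped at chromosome edges). Raw
ChIP rather than input-subtracted signal is used for this ranking — the
ranking only gates eligibility, and subtraction would add input noise to
a threshold decision; the subtracted alternative is a one-line change.
Boundary ties break lexicographically by gene name. Every stitched
enhancer (typical and SE alike) is assigned to the active gene on its
chromosome whose TSS is nearest the enhancer centre (floor midpoint);
equidistant ties break to the lexicographically smaller name, and
enhancers on chromosomes without active genes stay unassigned. The
"SE-associated gene set" used for cross-sample comparison is the set of
assigned genes over enhancers flagged super.

## Peak annotation and direct targets

Promoters are 4-kb windows centred on the TSS (clipped at position 0);
gene bodies run from 2 kb downstream of the TSS in transcription
direction to the TES and exist only for genes longer than 2 kb. A peak
receives the first category in the fixed precedence SE > typical
enhancer > promoter > gene body with ≥ 1 bp overlap, else intergenic —
so categories partition the peak set and the order matters whenever
features overlap (the test suite demonstrates count changes under
reordering).

For the direct/indirect split of differential genes, a gene's regulatory
region is defined as promoter ∪ gene body ∪ every stitched enhancer
assigned to it — the most inclusive reading consistent with the feature
catalog; it is a function argument, not a constant, so narrower
definitions are easy to evaluate. Genes absent from the gene table are
reported as unmatched and excluded from denominators.

## Correlation screen and histoscore

For each gene g against the driver d over n samples:
r = Pearson(d, g), t = r·sqrt((n−2)/(1−r²)), and the two-sided P value is
the Student-t tail with n − 2 df (scipy's implementation; tests verify it
against direct quadrature of the t density to 1e-9). Exactly collinear
genes are reported at the smallest positive float rather than P = 0;
zero-variance genes have undefined r and are reported but excluded from
the ranking, which is descending in r. No multiple-testing correction is
applied by default; Benjamini–Hochberg q values are an optional column.

Histoscore = intensity (integer 0–3) × percent positively stained cells,
range [0, 300]; staining in ≤ 1% of cells is not positive and scores 0.

## Synthetic landscapes

The generator's defaults define the study conditions: a 2 × 5 Mb genome,
50 genes (3–15 kb), 30 typical enhancers (0.8–1.5 kb), 5 SE clusters of
3–7 constituents (span 10–60 kb, intra-cluster gaps 2–12.4 kb, always
below the stitch distance), one 10-kb blacklist region per chromosome,
and 200k ChIP + 200k input reads of 75 bp. Typical enhancers receive 500
reads each and SE constituents 1,000 each, which puts roughly an order of
magnitude more net signal in an SE region than in a typical enhancer —
the separation that makes the hockey-stick cutoff meaningful. The
remaining reads are uniform background (~16 reads/kb), with 1% of
background deliberately placed inside blacklist regions to exercise the
filter. The input library is background only.

Placement divides each chromosome into equal slots, one element per slot
at a random offset with a 13-kb margin to either edge, which guarantees
≥ 25 kb between planted regions and > 2 kb clearance between enhancer
edges and every TSS window; layouts violating these invariants are
rejected before any file is written. Because the active-gene rule is a
relative threshold, the generator plants 150 promoter reads at exactly
floor(2N/3) randomly chosen genes, making the active set deterministic
ground truth (a planted promoter beats Poisson background with
overwhelming probability); each planted enhancer's intended gene is then
the nearest planted-active TSS to its centre, mirroring the assignment
rule. Peak calls are the planted constituents with ±25 bp uniform edge
jitter — peak calling itself is upstream of this package. TF peaks are
planted in the promoters of a configurable fraction of each differential
gene list (defaults 0.6 down / 0.4 up), and expression is generated as
g = ρ·d + sqrt(1−ρ²)·ε against a standard-normal driver for 10 correlated
genes (ρ ∈ [0.4, 0.9]) over 23 samples, null genes independent.

What the simulator does not model: fragment-size variation, GC and
mappability bias, copy-number variation, overlapping genes, diffuse
enhancer signal outside called peaks, and biological covariance structure
in expression beyond single-driver correlation. Passing tests therefore
demonstrate algorithmic correctness and calibration under idealised
sampling noise, not robustness to every artefact of real chromatin data.

A note on planted-correlation recovery: conditional on one 23-sample
driver realization, the realized sample correlations shift coherently
with the driver's sample variance, so recovery of a planted ρ is checked
as an average over driver realizations (16 independent draws × 200
genes), where the estimator is nearly unbiased.

## Problem sizes and numerics

Tests and the acceptance script run the full pipeline at the default
scale above (about 3 s per landscape), 500-instance randomized
equivalence checks for stitching against a naive O(n²) transitive-merge
oracle, per-bp pileup oracles at 1e-9 relative tolerance, and a
5,000-gene null screen for P-value calibration. All outputs are
byte-stable: every tie in ranking, assignment and cutoff selection has a
deterministic break, output headers carry parameters and input checksums
but no timestamps, and all simulator randomness flows from a single
integer seed.

## Known limitations

- WIG ingest supports only the full-chromosome fixedStep blocks this
  package writes (start=1, step=span), not general WIG.
- BAM/SAM input is out of scope; reads arrive as BED6 footprints.
- Stitched-enhancer tables re-read from disk lose constituent structure
  (regions, flags and assignments are preserved — sufficient for
  annotation).
- The tangent cutoff presumes an approximately convex ranked curve; on
  strongly non-convex curves the argmax rule still returns the point of
  maximum diagonal distance, which may not be a tangency.
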