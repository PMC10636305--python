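# Methods

## The assay, in brief

A multi-enzyme conformation-capture library reports pairwise chromatin
contacts as ligation junctions between restriction fragment ends.  Because
three 4-bp cutters are used, the genome is fragmented every ~85 bp on an
i.i.d. sequence (analytically 256/3 bp, since each distinct 4-mer occurs
with density 4⁻⁴ per position), and contact coordinates — always the
ligated cut positions — are dense enough to support 100 bp analysis.  PCR
copies of a molecule are recognised by the sonication shear-break
coordinate, which acts as a UMI: the deduplication key is
(viewpoint, distal chromosome, distal fragment, distal cut coordinate,
distal strand, sonication end), matched exactly, with side1 added to the
key for anchor-free (Hi-C style) tables where no constant bait exists.
Matching is exact (no ±1 bp tolerance): the shear coordinate is a mapped
alignment endpoint, and a tolerance would make deduplication
order-dependent.  Chance UMI collisions between genuine molecules are
merged — that is what any UMI assay observes — and the simulator's
ground-truth ledger counts distinct UMI keys for the same reason.

## Loop calling

For one viewpoint, every 100 bp bin starting at *s* scores
M = unique distal contact ends in [s−200, s+300) — a 500 bp window, an odd
multiple of the step, so windows are centred.  M_norm rescales M to a
library of 10,000 unique cis contacts for cross-library display.

The expectation N is MACS-style local: the read density over centred spans
of total width 5, 10, 20 and 50 kb (half-widths 2.5/5/10/25 kb), each with
the ±1 kb zone around the bin excluded and truncated at region edges, is
computed and the **maximum** density over spans — times the window width —
is N.  Taking the maximum is the conservative choice: a bin must beat its
worst-case neighbourhood, which absorbs both sharp local elevation and
broad domain-scale elevation.  Net span reads are floored at 0.5
(configurable) so N never vanishes; an empty background yields N ≈ 0.005
and p = 1 for M = 0.

Significance is the exact Poisson upper tail P(X ≥ M), X ~ Poisson(N),
through the regularised incomplete gamma function.  Bins within 5 kb of the
viewpoint are not tested (self-ligation/re-ligation zone; the background
definition itself starts at 5 kb).  The per-profile threshold is Bonferroni:
p < α / (number of tested bins), α = 0.05.  Significant bins are merged
into loops when their windows are closer than 500 bp (one window); the
summit is the leftmost minimal-p bin and loop strength is log2(M/N) there.
With replicates, loops are anchored on the first replicate's intervals and
kept only if a significant interval in *every* replicate overlaps by ≥1 bp
("reproducible"); any overlap is accepted because requiring identical
summits at 100 bp granularity would discard genuinely reproduced loops that
differ by one bin.

### Restriction-structure correction of the expectation

Contacts can only be observed at cut sites, and each cut site "collects"
the contact activity of the chromatin around it — up to half of each
flanking fragment, capped at 300 bp per side (the sonication fragment
scale, beyond which a locus cannot be linked to its tagging cut by a read).
A window's expected count is therefore proportional to its **taggable
mass**, not its base-pair width: windows bordering under-digested gaps
carry less mass, windows with favourable fragment phasing carry more (±17%
s.d. on an i.i.d. genome, with ~1.8× outliers).  When a fragment map is
supplied (`fragment_map=` on `evaluate_profile`, `call_loops` and
`distal_interactivity`), densities are computed per mass-bp and each bin's
N scales with its own window mass, removing this structural variance;
without a map the expectation is purely bp-based.  The correction is in the
same spirit as the assay itself — single-enzyme 4C's loop detection is
biased by restriction-site placement, and the expectation should not
re-introduce that bias at the calling stage.

### Alternative background

`distance_model_background` fits mean M against log10 distance-to-viewpoint
(40 log-spaced distance bins, monotone-decreasing isotonic regression,
count-weighted) and evaluates the curve per bin.  This reproduces the
behaviour of conventional callers that normalise by genomic distance
globally; it over-corrects sharp local structure and is provided for
algorithm comparison, not as the default.

## Differential and allele-specific tests

Differential looping between conditions A and B conditions on the two
library sizes T_A, T_B (total unique cis contacts of the analysed region):
under no change, a loop's A-share of reads is Binomial(M_A + M_B,
T_A/(T_A+T_B)); the two-sided exact binomial p-value is BH-adjusted across
loops.  Log2 fold changes of library-normalised counts carry a 0.5
pseudocount (p-values do not).  The allele-specific test is the same
conditional binomial with the allele-resolved library sizes as the null
proportion; loops with zero counts on both alleles are omitted with a
warning.

ROC evaluation is rank-based (Mann–Whitney): AUC is the probability that a
random positive bin outscores a random negative bin, ties counting ½.

## Matrix analytics

Contact matrices are sparse upper-triangular at a chosen resolution;
observed/expected uses the per-diagonal mean.  Iterative balancing is
deliberately not applied: all quantitative targets here are
simulation-based and the per-diagonal mean is the smallest faithful
expectation.  Where a known strong loop would inflate its own diagonal's
mean (short chromosomes have few pixels per diagonal), the loop pixels can
be excluded from the expectation (`expected_by_distance(exclude=...)`);
`stripe_residual` does this automatically for the loop list it is given.

* **Distal interactivity / hotspots**: D(bin) counts contact ends in the
  bin's 500 bp window whose partner is ≥10 kb away (both ends of a
  long-range contact contribute).  "Distal" = 10 kb clears the strong
  short-range decay and ligation-artefact regime; it is configurable.  E
  comes from the same 5–50 kb max-over-scales background applied to the D
  track; S = −log10 p; bins with p < 3×10⁻⁷ (a stringent genome-wide
  Bonferroni-scale threshold) are flagged and adjacent flagged bins merged.
* **Insulation**: diamond(i) = mean count over pairs (a, b) with
  i−w ≤ a < i < b ≤ i+w; score = log2(diamond / chromosome mean of
  diamonds), so scores average ~0.  Defaults r = 1 kb, w = 25 bins (25 kb),
  the sub-TAD scale.  Boundaries are plateau-aware local minima (midpoint
  bin of an equal-minimum run — a noise-free block junction produces a
  two-bin plateau whose midpoint is exactly the junction) with prominence
  above 0.1 (configurable) relative to the maximal score within w bins.
* **APA**: element-wise mean of (2k+1)² observed/expected neighbourhoods
  around loop pixels (k = 10), loops closer than k+2 bins to the diagonal
  or k bins to the edge skipped.  Center fold enrichment = mean central 3×3
  over mean lower-left-corner 3×3 (the corner nearest the diagonal, i.e.
  the shortest-distance background); Z standardises each cell against the
  non-central cells.
* **Stripe residual**: FE_loop / (FE_a1 · FE_a2), where FE_a is the D/E
  interactivity fold at the hotspot bin nearest the anchor (within 1 kb;
  else the anchor's own bin) and FE_loop is either supplied or measured as
  the loop pixel's central 3×3 mean O/E.  Residual ≈ 1 means the loop pixel
  is what two independently "sticky" anchors would produce by chance
  colocalisation; >1 indicates loop-specific structure.  A matrix-band
  variant of the anchor strength (`anchor_fe="band"`) is exposed for
  comparison since the 1D and band definitions can differ on real data.
* **Loop asymmetry**: for the corner pixel (i, j), each anchor's stripe is
  a ±1-bin band extending 10 bins (default) from the corner into the loop
  (interior) and past the partner (exterior), on O/E; asymmetry =
  exterior/interior.  Values well below 1 mean the partner anchor blocks
  the stripe — the signature of insulating elements.

## The simulator

The simulator is the package's ground-truth instrument, not a fixture.  A
seeded PCG64 generator (`numpy.random.default_rng`) drives everything, so a
seed fully determines the output across platforms.

The underlying contact probability is defined **per base pair** of
chromatin: power-law decay d^(−α) (α = 1 by default — the typical
intra-TAD regime; real decay is log-linear overall without one published
exponent, so α is configurable), multiplied by loop folds on anchor
windows, hotspot marginal folds h_i·h_j, and a same-domain ratio.  The
assay then restricts observation to cut sites: each cut samples with weight
equal to its taggable catchment (half of each flanking fragment, capped at
300 bp per side) times the per-bp factors at its coordinate.  Features act
on the underlying probability *before* cut-site restriction, so injected
folds are recovered as folds regardless of local fragment phasing.
Sonication ends are uniform within ±300 bp of the ligated cut; orientations
are multinomial over (in–in, in–out, out–in, out–out); PCR duplicates are
exact record copies appended so that duplicates ≈ rate × reads; trans
contacts (4C mode, multi-chromosome maps) pick a uniform partner on another
chromosome.

What the simulator emulates: restriction-constrained coordinates, distance
decay, point loops, marginal hotspots, block domains, UMI structure and PCR
duplication.  What it does not: sequencing error and mappability, GC /
tagmentation bias, fragment-level ligation competition, cell-cycle or
population heterogeneity, and trans-chromosomal structure.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not performance on real libraries.

## Problem sizes and defaults used by the test suite

Viewpoint analyses use a 2 Mb i.i.d. genome (~23k cut sites) with 100k
molecules per replicate — around the unique-contact scale of a deep single
viewpoint.  Matrix analyses use a 300–400 kb genome (a TAD-sized region;
the all-pairs weight table grows quadratically in cut sites) with 300–600k
molecules, APA at 500 bp resolution with six injected loops, insulation on
constructed block matrices.  Null calibration runs 20 seeded two-replicate
null libraries for the loop caller (at most one run in twenty may show any
Bonferroni-significant reproducible loop) and 20 for the hotspot caller
(zero hotspots at 3×10⁻⁷ in all).  Acceptance checks of injected-parameter
recovery: loop sensitivity ≥ 0.9 at 8-fold (two replicates), summit
strength within ±0.4 log2 of truth for folds 2/4/8, APA centre fold within
10% of an injected 6-fold (20 seeds), insulation boundaries exactly at
constructed junctions, stripe residuals ≈ 1 under the multiplicative null
and ≈ the injected fold above it.

## Known limitations

* The bait-side sonication end is not part of the UMI key (only the distal
  side), so two molecules sharing the distal end and shear but differing on
  the bait side would be merged in 4C mode.
* The background is single-pass: previously called loop bins are not
  excluded when estimating N, which biases strength slightly downward next
  to very strong loops.
* Reproducibility is anchored on the first replicate's intervals; loops
  found only in later replicates are not reported.
* Hot pixels can saturate the UMI space (601 shear positions × strands per
  cut pair); deduplicated counts of extreme features are compressed, which
  is a property of UMI assays generally, not of this implementation.
* Insulation requires the diamond fully inside the chromosome; the first
  and last w bins carry no score.
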