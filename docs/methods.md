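# Methods

This note documents the models and procedures implemented in `blisskit`,
their assumptions, the parameters that matter, and the numerical and design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

A break-mapping library tags each free DSB end in situ with an adapter whose
sequenced prefix is `UMI (8–12 nt) + sample barcode [+ optional
restriction-site anchor]`, followed by genomic sequence read away from the
break. After alignment, the 5′-most aligned base of a read (relative to the
read) is the DSB-proximal base. A *unique DSB end* is a (location, strand,
UMI) triple; reads sharing all three are PCR duplicates. Multiple UMIs at
one location are independent break events in different cells or alleles —
the basis of recurrent-break quantification.

## Prefix scanning (`adapter_scan`)

The prefix grammar is mismatch-only (`[m,0,0]`): indels are disallowed
because they make the downstream position of the genomic sequence ambiguous,
at the cost of discarding a bounded fraction of reads. Defaults: barcode
tolerance 1, anchor tolerance 1, UMI extracted verbatim (any 8-mer is a
legal UMI; UMI tolerance is only meaningful relative to other UMIs and is
applied at deduplication). Minimum Phred is 30 per base.

*Quality scope.* Whether the Phred rule applies to every base of the read or
only to the prefix region is configurable (`quality_scope="prefix"` default,
`"read"` strict). The strict rule discards most of a typical modern library;
the prefix-only default protects exactly the bases whose miscalls corrupt
the UMI/barcode assignment.

*Fixed-UMI audit.* For libraries built with a known constant UMI before a
restriction anchor (e.g. HindIII `AAGCTT`), `audit_fixed_umi` selects the
stretch before the first anchor occurrence (anchor matched within 1
mismatch) and histograms its Hamming distance to the fixed UMI. Under
independent per-base substitution errors at rate ε the histogram is
Binomial(8, ε); the test suite checks this against the analytic law.

## Deduplication (`umi_dedup`)

Reads are grouped per (sample, chromosome, strand). Neighbourhoods form by
single-linkage chaining: consecutive sorted positions at most `window` (8) nt
apart join. Single linkage was chosen because it is deterministic,
order-independent, and the only parameter-free reading of "nearby
locations"; whether chaining should instead use fixed windows is not
determinable from the assay description, and the choice only matters for
pathological read spreads wider than the window. Neighbourhoods never cross
strands: plus and minus events at a cut are distinct DSB ends, which the
overhang analysis requires.

The event location is the most frequent read position in the neighbourhood
(tie → leftmost). UMIs within a neighbourhood are merged greedily in order
of descending read count (ties lexicographic): each UMI joins the most
frequent already-kept UMI within Hamming distance `umi_max_mismatch` (2), or
is kept as a new representative. This directional-adjacency-style greedy
rule is deterministic and testable; the suite proves it identical to a
brute-force O(n²) implementation on thousands of random instances.
Coordinates are 0-based half-open everywhere except at SAM boundaries.

The Hamming comparisons against the kept set are vectorised (numpy byte
matrices) so recurrent cut sites carrying thousands of UMIs remain
tractable.

*Known limitation.* With u UMIs at one location and an 8-nt UMI alphabet,
the expected number of spurious merges grows as C(u,2)·277/4⁸ (277 = size of
the Hamming-≤2 ball); at u ≈ 200 per strand roughly 8 % of events merge
away. This is inherent to error-tolerant UMI collapsing, not to this
implementation, and is visible in the simulator's truth tables.

## Saturation model (`dsb_quant.estimate_dsb_per_cell`)

Unique DSB ends per cell as a function of sequencing depth r follows the
hyperbola

    DSB(r) = DSB_max · r / (k + r),

with DSB_max the number of breaks per cell at saturation and k the
half-saturation read count. The curve passes through the origin and
saturates; each depth point contributes `unique_umi_reads / (2 · n_cells)`
on the assumption that one break yields two unique reads (one per end). The
fit is nonlinear least squares (`scipy.optimize.curve_fit`); the 95 % CI on
DSB_max comes from the linearised covariance, with a nonparametric bootstrap
option (the CI procedure is a package choice; either is defensible at ≥ 6
depth points). At least 3 depth points are required. Recovery calibration:
with 6 depths reaching ~94 % of saturation (max depth 16·k) and 5 %
multiplicative noise, DSB_max is recovered within 10 % in ≥ 95 % of 200
simulated fits (checked in the acceptance suite); depth series that stop far
from the plateau identify DSB_max correspondingly worse.

## Threshold sweeps, enrichment, telomeres, accessibility

*UMI-threshold sweep.* Per chromosome and threshold t ∈ 1..10, count
locations with t ≤ UMIs ≤ 500 (the cap suppresses collapsed repeats),
normalise by each sample's total unique ends, and average the
treated/control ratio over chromosomes with equal weight (chromosomes
missing from either sample are excluded and reported). Fold changes are also
computed on locations exclusive to each sample.

*TSS fraction.* ±5 kb windows around all TSSs are merged before overlap
testing, so duplicated or overlapping annotations cannot double-count; the
fraction of unique DSB locations inside the merged footprint is reported per
UMI threshold, with an empty event set reported as missing rather than 0.

*Expression stratification.* Deciles are computed over genes with nonzero
expression, ties broken by stable gene-id order. Per decile the UMI-weighted
percentage of all sequenced ends within ±1 kb of the decile's TSSs is
reported; gene-body densities (ends per kb) are summarised for the top and
bottom deciles, and a binned positional profile around the TSS is produced.

*Telomere screen.* Prefix-trimmed reads are matched at the read start
against the six phase patterns of the C-rich telomeric strand —
`[#A, #AA, #TAA, #CTAA, #CCTAA, #CCCTAA]-CCCTAA` — longest variable part
first, one assignment per read.

*Accessibility comparison.* Fixed-width genome bins (default 100 kb)
accumulate UMI-weighted densities of the DSB and accessibility (e.g.
restriction-digest) event sets; association is reported as Spearman rank
correlation, undefined (NaN) when a binned density is constant.

## Guide homology score (`crispr_offtarget`)

Candidate loci are DSB clusters: plus/minus events within the dedup window
paired per chromosome, ranked by total unique UMIs, top 5,000 kept. The
cluster center is the UMI-weighted mean position rounded down.

Within ±50 nt of a center, every PAM occurrence (IUPAC patterns, both
strands; NGG+NAG for SpCas9, 5′ TTTN or the all-PAMs pattern NNNN for Cpf1)
anchors a candidate protospacer. The 20-nt spacer is aligned globally
against the candidate segment with match +3, mismatch −1, gap −5
(`Bio.Align.PairwiseAligner`; the spacer must align fully, genomic flanking
bases are free). The candidate segment extends 3 nt beyond the nominal
protospacer away from the PAM so gapped alignments can be found; gap
placement at spacer termini is thereby permitted on the genomic side, a
choice the scoring weights make nearly irrelevant (a terminal gap costs the
same −5 anywhere). Score facts that pin the implementation: perfect match
60; 4 mismatches 44 (≥ cutoff 41), 5 mismatches 40; 2 gaps 44, 3 gaps 36;
legacy PAM-inclusive mode adds +3 per matched PAM base (max 69 for a 3-nt
PAM). Ties among equal-scoring candidates resolve to the candidate closest
to the cluster center, then genomic order, then + strand.

Clusters scoring ≥ 41 become hits, annotated with *signal* = unique DSB ends
per 10⁵ unique library ends and sorted by signal. Position numbering in all
mismatch reporting is PAM-proximal = 1 (spacer 3′ end for a 3′ PAM, 5′ end
for a 5′ PAM).

*Overhang profiling.* The histogram of signed offsets (minus-strand end −
plus-strand end) near a cut; blunt cuts mode at 0, 5′ overhangs at the
overhang length. Two pairing rules are provided — all cross-strand pairs
weighted by UMI products (default) and modal-position difference — because
the per-read pairing rule is not uniquely determined by the assay
description.

*Site enumeration.* `enumerate_mismatch_sites` scans both strands of a
genome exhaustively (vectorised shifted comparisons) for perfect-PAM sites
with ≤ 1 spacer mismatch, reporting per-position counts — the denominator
for per-position detection fractions. It is intended for desk-scale genomes
(tested at 10 Mb, ~3 s); genome-scale scanning is better served by dedicated
tools.

*ROC.* Standard threshold-sweep ROC over validated/non-validated labels
(scikit-learn), with the Youden-optimal cutoff reported; ties resolve to the
more specific (higher) cutoff.

## Mismatch-tolerance model (`mismatch_model`)

The cutting frequency of a guide g with a single mismatch at position x is
modelled on the log scale as

    log f(g, x) = log f(g) + log t(x′) + a(g) + ε,   x′ ∈ [x − β, x + β],

where t(x) is the nuclease's position-dependent mismatch tolerance (a
property of the protein), a(g) a per-guide effect on the ratio, ε
experimental noise (taken additive on the log scale, the natural scale for
rate ratios), and the wobble window [x − β, x + β] (β = 0.5) absorbs local
stretch/compression of the guide–DNA heteroduplex. t(x) is a third-order
(cubic) B-spline on (1, 20) with uniform interior knots (default 8,
configurable; 16 interior knots make the basis rich enough to interpolate
all 20 positions, used in the exactness tests).

The fit minimises the squared error of observed log-ratios
log(f(g,x)/f(g)) against log t(x′) + a(g) plus λ·Σ|c| on the spline
coefficients (λ = 0.3). Optimisation is proximal gradient descent:
backtracking line-search gradient steps on the smooth part with the standard
soft-threshold step for the lasso term — the natural form of gradient
descent for an L1-penalised objective, with deterministic initialisation
(flat curve, zero guide effects).

*Wobble mechanism.* Two readings of the wobble are implemented: averaging
the spline over the window (default) and hard assignment of the
within-window position minimising the residual. The hard assignment
co-adapts with the curve during fitting and systematically narrows fitted
peaks (normalised-curve RMSE roughly doubles in recovery simulations), so
window averaging is the default; the hard mode remains available.

*Identifiability.* The model has one gauge freedom (scale of t ↔ shift of
a). The reported curve is normalised to max 1 on a fine grid, the shift
absorbed into a(g); cubic B-splines with a clamped knot vector reproduce
constants, so the shift is exact. A guard requires ≥ 2 guides or ≥ 10
observations. Ratios at 0 are floored at 10⁻⁶ before taking logs.

## Synthetic data (`simulate`)

The generator emulates the assay's data model: a seeded genome of
configurable length and GC content (default 0.41, human-like) with planted
cleavage sites (protospacer+PAM sequences embedded at recorded coordinates;
overlaps are an error); per site, breaks ~ Binomial(n_cells,
break_frequency); each break exposes two ends with independent UMIs (plus
end at the cut position, minus end offset by the site's 5′-overhang length);
PCR copies per molecule ~ 1 + Poisson(mean − 1); independent per-base
substitution errors over the whole read, prefix included. Reads are emitted
both as FASTQ and as a perfect-alignment BED so no aligner is needed in
tests; truth tables record every read's origin. The single-mismatch
cutting-frequency generator emits a saturated panel (three alternative bases
per position per guide) with a guide activity scale that cancels from
normalised ratios, an optional ratio-level per-guide offset, and log-normal
noise.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: non-uniform error profiles along the read,
chimeric or multi-mapping reads, mappability structure, chromatin-dependent
ligation efficiency, UMI ligation bias, and genome-scale repeat content.
Claims about those require real libraries.

## Problem sizes used in the test and acceptance suites

Chosen so the full suite runs in well under a minute of CPU for the unit
tests plus ~20 s for the acceptance tests: dedup oracle equivalence on 100
instances of 50–400 reads plus two 2,000-read instances; saturation recovery
over 200 fits at 6 depths; off-target end-to-end on a 10-Mb genome with
8,000 cells, a planted on-target, eight off-targets spanning a 1,000-fold
frequency range and a 120-site single-mismatch panel; tolerance recovery
over 100 simulated 2-guide saturated panels.
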