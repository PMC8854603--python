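# Methods

This note documents the models behind each stage, the defaults that
matter, what the simulators do and do not emulate, and the numerical
choices made where the design was open.

## Marker karyotypes and event inference

**Model.** A genome is a set of chromosomes, each an ordered list of
oriented marker blocks; every marker occurs once genome-wide and carries a
fixed bp length. Rearrangements are whole-chromosome fusions (concatenate
two chromosomes, either end orientation) and fissions (split between two
markers). Marker, not base, resolution is deliberate: event calling is a
synteny-level problem, and bp coordinates are needed only to classify
operands as micro- (< 20 Mb) or macrochromosomes (≥ 20 Mb, the avian
convention; the boundary value counts as macro).

**Adjacency encoding.** Every junction between consecutive markers is an
unordered pair of signed marker extremities (tail/head). Signed ends make
the two possible fusion junction orientations distinct characters. A
fusion creates exactly one adjacency; a fission destroys exactly one.

**Branch assignment.** Each adjacency observed in any tip or in the
ancestral genome is a binary presence/absence character. Fitch small
parsimony runs on the rooted tree with the root state fixed to the
ancestral state, implemented as a two-state dynamic programme that also
*counts* optimal labelings: characters with more than one minimum-change
labeling are flagged ambiguous rather than silently resolved (the
traceback then prefers the parent state). Plain Fitch — parallel gains
allowed — is used rather than Dollo parsimony because recurrent
independent fusions of the same chromosome pair are a real phenomenon the
encoding must be able to represent. An adjacency gain is reported as a
fusion, a loss as a fission, on the branch where the state changes.

**Simulator.** Events are Poisson per branch (rate × branch length), or
exactly `n_events` placed multinomially by branch length; operands are
uniform among available chromosomes and junctions, the neutral default in
the absence of a mechanistic model. Fissions drawn when every chromosome
is single-marker are logged as skipped. Replaying the log along any
root-to-tip path reproduces the tip genome exactly (tested invariant).
Events that cancel along one path (an adjacency gained then lost) are
invisible to any inference; with the default ancestor (~38 chromosomes,
280 markers) and 38 events such collisions are rare, and the recovery
check conditions on the parsimony solution being unique, as it almost
always is under these conditions.

## Coverage differentiation and strata

**Windows.** Non-overlapping windows (default 100 kb). A trailing partial
window longer than half a window stands alone; otherwise it merges into
the previous window, so the last window is at most 1.5× nominal.
(Configurable step size provides true sliding windows if wanted.)

**Coverage model.** Female read depth over a fully differentiated
(hemizygous) Z region is half the autosomal depth; the ratio track is
window depth divided by the genome-wide autosomal median. Windows with
ratio ≤ 0.65 are hemizygous, ≥ 0.85 PAR-like; intermediate windows join
the nearer classified window, and an all-intermediate track is returned
as a single flagged ambiguous segment. The thresholds sit roughly
midway between the expected ratios (0.5 and 1.0) with a wider hemizygous
band because mapping losses bias ratios downward in real data.

**Alignment filter.** Z–W local alignments are kept iff length ≥ 65 bp
and identity in [60 %, 96 %]. Short and low-identity alignments are noise;
near-perfect ones are usually unmasked simple repeats. The stated
exclusion conditions are strict inequalities, so the boundary values are
kept. Identity is on the 0–100 scale throughout. Note the > 96 % cut also
removes genuine PAR alignments; the PAR is therefore delimited by the
coverage classifier, not by the identity track.

**Windowed identity.** Per window, the length-weighted mean identity of
overlapping records, with record length apportioned by overlap fraction;
windows without aligned bp are missing and are skipped by the
segmentation (then absorbed into the flanking segment on output).

**Changepoint segmentation.** Exact least-squares partition into k
piecewise-constant segments by O(K n²) dynamic programming (fine for the
≤ 10⁴ windows this is meant for), choosing k ≤ `max_segments` by
`n·log(SSE/n) + penalty·(2k−1)·log(n)`. The default penalty multiplier is
2: plain BIC (multiplier 1) is known to overfit changepoint models and
splits long strata on sampling noise. Segments are labelled S0, S1, … by
increasing mean identity, the standard convention that older strata are
more diverged. Cost is non-increasing in `max_segments` and boundaries
are mirror-symmetric (tested invariants).

## k-mer satellites

**Counting.** Canonical k-mers (lexicographic min of k-mer and reverse
complement), k odd so no k-mer is self-complementary, k ≤ 31 (2-bit
packing into 64-bit codes; counting is vectorised and processes ~10⁶
reads in seconds). Non-ACGT symbols invalidate only the windows
containing them. A `min_count` floor supports very large spectra by
discarding rare k-mers (default keeps everything, so small-scale
invariants are exact).

**Selection.** Default k = 21 for discovery — the monomer length is an
*output* (the cycle length), not the choice of k. `max_male_count = 0`
implements strict female specificity; it is configurable because real
male libraries contain contamination.

**Monomer assembly.** Selected k-mers, in both orientations, form a graph
on (k−1)-overlaps; a perfect tandem monomer is a simple cycle. The search
is depth-first with backtracking and bounded work; among closing cycles
it keeps those covering the most canonical k-mers in the fewest nodes
(a perfect tandem uses every circular k-mer and nothing twice). Canonical
k-mer sets occasionally admit several monomer preimages — a segment
replaced by its reverse complement can chain through coincidentally
present junction k-mers — in which case all equally supported spellings
are reported (`alternatives`, `ambiguous`), the lexicographically least
first. Monomers are reported in canonical rotation (least string over all
rotations of both strands). Disjoint satellites come back as separate
cycles ranked by summed count; inputs with no cycle return an explicit
no-monomer result with the longest simple path as a diagnostic.

**Copy number.** In a perfect array of C copies each circular k-mer
occurs C times per genome copy, so C = median(count)/k-mer depth; the
median resists array-edge effects and sequencing errors. Base depth
relates to k-mer depth by the edge factor (R−k+1)/R for read length R;
passing `read_length` applies it. The estimator is within ~1 % on
error-free simulated arrays at ≥ 20×.

## Hi-C insulation

**Filtering and balancing.** Entries below `min_count` (default 10, at
100-kb bins) are zeroed first, then the matrix is balanced to unit row
sums by symmetric iterative proportional fitting (tolerance 1e−5 on the
max row-sum deviation). IPF shares its doubly-stochastic fixed point with
Knight–Ruiz; it is used for the simpler contract. Rows emptied by
filtering are masked, never balanced into non-finite values.

**Insulation score.** The diamond statistic anchored at junctions:
d(i) = mean of m[i−w..i−1, i..i+w−1], the contacts crossing the junction
upstream of bin i, and IS(i) = log2(d(i)/⟨d⟩) over defined bins. With
this anchoring a boundary between bins i−1 and i gives a *unique*
insulation minimum at i (the first bin of the downstream domain); the
bin-centred variant that excludes bin i produces an exact two-bin tie at
every boundary and cannot localise it uniquely. Bins within w of the
ends, masked bins, and d = 0 bins are NaN. Default bin size 100 kb and
w = 2 bins, i.e. a 200-kb insulation window. The log-ratio form makes the
profile invariant to global matrix rescaling.

**Boundaries and the breakpoint test.** Boundaries are strict local
insulation minima with prominence ≥ 0.1 (scipy peak finding on the
negated profile); on simulated matrices with contrast ≤ 0.5 and ≥ 100
bins recall is 1, with occasional extra minima under Poisson noise.
Whether rearrangement breakpoints sit at low insulation is a one-sided
Mann–Whitney/Wilcoxon rank-sum test (H₁: breakpoint IS below background),
exact when n₁·n₂ ≤ 10⁴ and tie-free, else the tie-corrected normal
approximation. The background defaults to all defined non-breakpoint
bins; TAD-interior or matched-random backgrounds can be supplied instead.

## Dosage and repeats

**TPM.** count/length scaled to 10⁶ per sample; replicate means per
(tissue, sex). Columns sum to 10⁶ exactly (tested).

**M:F ratios.** Per gene, (male + ε)/(female + ε) with ε = 0.1 TPM on
replicate means; genes under 1 TPM in both sexes are dropped; the class
summary is the *median* across genes (robust to zeros; the aggregation
is exposed in the API). TPM ratios are compositional: because libraries
are normalised to a fixed total, a sex-linked class can only show its
copy-number ratio when the transcriptome is dominated by autosomal genes,
as real transcriptomes are. The simulated study condition therefore uses
2000 autosomal genes against 200 per sex-linked class, under which the
recovered ratios are within ~4 % of the copy-number expectation (2 for
hemizygous, 1 for autosomal).

**Gametolog concordance.** Per Z–W pair, Spearman correlation of
log(1+TPM) across tissues; pooled correlation on the log scale and the
OLS slope of W on Z on the TPM scale (so halved W expression reads as
slope 0.5); pairs with mean W above Z are flagged upregulated.

**TE content and retention.** Repeat intervals are resolved per base by
priority satellite > LTR > CR1 > other-TE (declared, since annotations
overlap); percentages per stratum sum to 100 with unannotated bases as
"none". Gene retention is surviving/ancestral × 100 on externally
supplied counts — no gene annotation is performed here.

## What the simulators do and do not emulate

The generators reproduce the *statistical structure* each analysis
assumes: marker-level rearrangements, i.i.d. per-site substitution
(Jukes–Cantor-like, no indels — the downstream statistic is windowed
percent identity only), uniform error-free reads with per-copy weighting
(default 100 bp, 30×), perfect tandem arrays with optional per-copy
mutation, Poisson contact counts with power-law distance decay and
per-boundary attenuation (matrix-level only, no read-level Hi-C), and
negative-binomial counts with copy-scaled means (dispersion 0 gives the
deterministic limit). They do not emulate assembly error, mapping bias,
GC/coverage coupling, TE sequence evolution, or gene conversion between
gametologs — so passing recovery tests demonstrates correctness of the
inference logic under its stated model, not robustness to every artefact
of real data. All randomness in a run flows from one integer seed;
sub-stage seeds are derived deterministically.

The acceptance script runs each stage at deliberately modest problem
sizes — a 6.5-Mb Z, 2.5-Mb coverage tracks, a ~550-kb female genome at
30× for the satellite stage, 150-bin contact matrices — chosen so the
whole recomputation completes in well under a minute on one CPU while
keeping every recovery band (3 s.e. identity bands, ±1 window boundaries,
5 % copy-number error, 10 % dosage ratios) statistically meaningful.

## Known limitations

- Event inference sees only net adjacency changes; same-path gain+loss
  pairs are invisible, and heavily saturated histories would need a
  rearrangement-distance model (DCJ), which is out of scope.
- Stratum labels order by identity, so two strata with equal divergence
  would be ordered arbitrarily; the segmentation itself is unaffected.
- The monomer assembler targets single-monomer tandem arrays; higher-order
  repeat structure collapses to its elementary cycle.
- The balancing contract (equal row sums) treats the matrix as one
  chromosome; trans contacts are out of scope.
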