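# Methods

This note records the models implemented in `dsb3d`, the conventions and
defaults behind them, what the synthetic-data generator does and does not
emulate, and the numerical choices made where more than one convention is in
use in the field.

## Contact-matrix model and balancing

A contact matrix is a bin table (uniform bins, 0-based half-open
coordinates, short terminal bins allowed) plus sparse upper-triangle pixels
of raw counts. Balancing is iterative correction (ICE): multiplicative
per-bin weights `w` are iterated until every non-filtered bin's balanced
marginal (with the first `ignore_diags = 2` diagonals masked, where
short-range ligation artifacts dominate) equals the common mean within
`tol = 1e-5`. The update divides each bias by the square root of its
normalized marginal; the square root damps the period-2 oscillation the raw
update exhibits on symmetric matrices, and converges to the same fixed
point. Weights are normalized so the mean balanced marginal is 1, making
balanced values invariant to sequencing depth. Bins with zero coverage, or
with log10 coverage more than `mad_max = 5` median absolute deviations below
the median, are filtered to missing and stay missing downstream. Iteration
is capped at `max_iter = 1000`; non-convergence raises an error carrying the
last residual.

## Expected, O/E, P(s) and insulation

The cis expected model is the per-chromosome mean balanced value per
diagonal over non-filtered elements; diagonals with no valid element are
undefined (NaN), never zero. Observed/expected divides each balanced value
by the expected at its separation, so each diagonal's mean O/E is exactly 1
— this identity is asserted in the tests at 1e-9.

P(s) pools diagonal means across chromosomes (weighted by valid-element
counts) into geometric separation bins, 8 per decade by default, and the
derivative d log P / d log s is taken by central finite differences on the
binned curve with no further smoothing. The curve is normalized to unit sum;
together with the balancing normalization this makes both P(s) shape and
derivative invariant to total count scale. The resolution at which the
expected is computed is a free parameter: the tests use 25-kb bins, which
resolve three decades of separation on a 50-Mb chromosome; pushing to finer
bins changes only the smallest separations.

Insulation is a reconstruction, since no single convention is canonical: for
each bin the mean balanced signal in the `w × w` diamond crossing it
(`w = window / bin_size`, default window 100 kb) is divided by the
chromosome-wide mean diamond score and log2-transformed. Bins within `w` of
a chromosome end are undefined. Users comparing against other toolkits
should expect convention-level differences (window shape, normalization
span).

## Compartments, flips and saddles

EV1 is the leading eigenvector (largest eigenvalue) of the symmetrized
centered O/E matrix (O/E − 1) per chromosome, with missing rows/columns
removed before decomposition and re-inserted as NaN, scaled by the square
root of the (non-negative) leading eigenvalue, and sign-phased so its
correlation with gene density is non-negative. Centering by subtracting 1
rather than row-centering follows the standard compartment callers; this is
a reconstruction in the sense that the choice of centering is
convention, not physics. A chromosome with fewer than 10 valid bins yields
no EV1 (warning). EV1 exactly 0 is left unassigned — strict inequalities
define A (EV1 > 0, gene dense) and B (EV1 < 0). A zero phasing correlation
keeps the arithmetic sign and warns.

Flip detection compares per-bin labels between two conditions. The
replicate-consistency flag is true where every (condition-1 replicate,
condition-2 replicate) pair shows the same assigned transition; the headline
transition class comes from pooled-condition labels when pooled results are
passed, otherwise from the replicate consensus. Summary fractions are over
consistently assigned bins and sum to 1 there. This split — pooled tracks
for the headline, replicates for consistency — reflects how replicate
experiments are normally reported.

Saddles rank bins by EV1 genome-wide (per-chromosome trimming is available
as an option), drop the outer 0.2 percentiles, split the rest into 30
equal-count quantile groups (sizes differ by at most one bin), and average
cis O/E between group pairs. Saddle strength at extent k is the mean of the
k×k A–A (or B–B) corner over the mean of the two anti-diagonal corners;
it is invariant to uniform scaling of O/E and equals 1 exactly on a uniform
map.

## Pileups, enrichment scores and the matched null

Pairwise pileups snip O/E windows centered on the bins containing each cis
site pair (default 25-kb bins, ±1-Mb flank, hence 81×81). Windows crossing
the diagonal (separation ≤ 2·flank) or a chromosome end are dropped and
counted; windows whose center cell is missing are dropped; other missing
cells are skipped per cell. The cluster enrichment score is the mean linear
O/E of the central 5×5-bin block (total width 125 kb, i.e. a 2-bin Chebyshev
radius) divided by the mean over cells with center Chebyshev distance
beyond the block and at most 1 Mb (ties at the radius included). Ratios are
computed on linear O/E; log2 is used only for display matrices, with a
`log_ratio` flag for sensitivity analysis. The "5×5 central bins" block is
read as 125 kb total width; descriptions that phrase the same block as a
"25-kb radius" are reconciled to this 2-bin-radius reading.

The matched control null re-draws, 100 times by default, one control locus
per cut site under three constraints: at least 125 kb from every cut motif,
identical per-chromosome counts, and identical compartment label (from the
undamaged-control EV1) — implemented by sampling within (chromosome, label)
strata without replacement. Each resample's score is computed through the
identical pair → pileup → score path. Resamples use independent RNG streams
spawned from one seed and the resampled catalogs are retained so the
constraints can be asserted post hoc.

Oriented CTCF pileups rotate minus-strand snippets by 180° so all motifs
point rightward; the "flame" line score is the mean O/E along the central
row/column on each side of the center minus the off-line background mean.
Convergent loop aggregation pairs + anchors with downstream − anchors at
25 kb–1 Mb separation and scores the central 5×5 block against the 25–100-kb
ring; near-diagonal windows are retained because loops live there by
construction. Anchored differential tracks subtract control from damage O/E
along one anchor row, with an optional mask over the local diagonal
neighborhood.

Downsampling thins pixel counts by a multivariate hypergeometric draw, so
the requested total is hit exactly and two complementary halves pool back to
the original matrix; pooling sums pixels on identical bin tables.

## Junction model

A junction record carries the last read base aligned to the bait
(`bait_end`, 1-based) and the first aligned to the prey (`prey_start`). With
`gap = prey_start − bait_end`: `gap = 1` is blunt; `gap ≤ 0` is a
microhomology of `1 − gap` bases (the overlap aligned to both references);
`gap ≥ 2` is an insertion of the intervening read bases. Classification is
by the coordinate gap alone, matching coordinate-based pipelines; flanking
micro-matches around an insertion do not reclassify it. MH buckets split at
6 nt with lengths ≥ 6 in the upper bucket, so "MH 1–5" and "MH ≥ 6"
partition; the boundary is a parameter. Frequencies are binned at 100 kb
and normalized per bait-only read and per 1,000 total events (junctions +
bait-only reads); both scales are always emitted since figure conventions
vary. Differential tables keep bins with ≥ 10 raw events summed over the
two conditions (the filter's scope is ambiguous between one and both
conditions; combined was chosen and is a parameter), report log2 fold
changes with a 0.5-raw-event pseudocount (display only), and test the
genome-wide shift with a paired Wilcoxon signed-rank across retained bins —
paired because the two conditions share one bait and bin grid; an unpaired
variant is available. Insertion mapping searches the 20–30-nt insert and its
reverse complement exactly, prey flank before bait flank, sense before
antiparallel; a chance 20-mer hit in a 1-kb flank has probability ≈ 2 kb ×
4⁻²⁰ ≈ 2×10⁻⁹ and is ignored. Prey annotation is a precedence rule:
Promoter (TSS ± 3 kb) over Gene Body over Intergenic.

## Synthetic data: what it emulates and what it does not

The Hi-C generator draws Poisson counts around the intensity

    p_ij ∝ s^(−α) · (1 + κ·c_i·c_j) · loop(i,j; λ) · cluster(i,j; β)

with s the bin separation, c a ±1 plaid of alternating blocks (default 10
bins), flips switching configured B bins to A in the damage condition only,
and focal boosts at convergent anchor pairs (λ) and cut-site pairs (β,
damage only). Defaults: α = 1 (the classic genome-wide decay slope),
κ = 0.3 (clearly resolvable plaid at moderate depth), toy genome 4 × 50 Mb,
expected total N = 10⁶ (tests raise it to 10⁷–2×10⁷ where recovery
tolerances demand depth). The focal boost is flat over a square of
half-width 2 bins — exactly the 5×5 block the enrichment scores measure —
so the planted β/λ is, by construction, the value an ideal estimator
reports; a Gaussian-edged bump is available (`focal_shape="gaussian"`), in
which case the score measures the bump's 5×5 average rather than its peak.
Poisson (not negative-binomial) noise is the default; the generator's
purpose is recovery testing, for which overdispersion adds nothing but
variance.

The junction generator composes each read as bait prefix + (nothing |
insertion) + prey suffix, forcing the k bases before the junction identical
in both references for an MH-k event and forcing the bases flanking the
shared stretch to differ, so the maximal-overlap class of every read is
exactly the requested one; insertions are copied from the antiparallel prey
flank so the mapper can locate them. Default class mixture 0.18 / 0.69 /
0.13 (blunt / MH / insertion) with MH lengths 1–8 on a decreasing weight
profile, insert lengths uniform on 20–30 nt, and 85% of preys drawn within
±400 bp of a cut site.

What the generator does **not** emulate: trans contacts (intensities are
cis-only; trans pixels are simply absent), TAD-scale insulation structure,
distance-dependent noise beyond Poisson, copy-number or mappability biases,
restriction-fragment effects, resection-length distributions, sequencing
errors in reads, or PCR duplicates (assumed removed upstream). Passing
recovery tests therefore demonstrates the correctness of the estimators on
data satisfying the model's assumptions, not robustness to every artifact of
real libraries.

The "mouse-like" cut-site preset plants 97 sites across 19 chromosomes with
per-chromosome counts (12, 11, 11, 8, 8, 7, 5, 5, 4, 4, 4, 3, 3, 3, 2, 2,
2, 2, 1) — a synthetic stand-in chosen so the number of same-chromosome
pairs is exactly 304, the invariant the pipeline's pair accounting relies
on. A real ranked cut-site table can be supplied as BED and used unchanged.

## Numerical choices and degenerate inputs

- Genomic positions map to bins by integer division; a position in a
  terminal short bin maps to that bin.
- Eigendecomposition uses `numpy.linalg.eigh` on the symmetrized matrix;
  residual NaN inside a retained submatrix (masked diagonals) is zeroed
  before decomposition.
- Quantile assignment uses a stable argsort, so EV1 ties break by bin order.
- All-zero bins get missing weights; fully filtered diagonals give NaN
  expected; a zero expected under non-zero observations is an error rather
  than an infinite O/E.
- Empty pileups (no usable snippet), empty resampling strata, empty
  convergent-pair sets and empty event-filtered differential tables raise
  errors naming the condition, never return silent zeros.
- Simulation seeds: replicate and resample streams are spawned from a single
  `SeedSequence`, making every output reproducible from one integer and
  independent across replicates.

## Problem sizes

The test and reproduction runs use 50-Mb chromosomes (2–4 of them), 25-kb
bins for pileup/loop/scaling analyses (2,000 bins per chromosome), 250-kb
bins for compartment analyses, 10⁷–2×10⁷ simulated contacts, 100 null
resamples, and 10,000-junction libraries. These sizes were chosen so every
recovered estimate sits well inside its tolerance while a full run stays in
the minutes range on a laptop core; all of them scale up linearly by
configuration if tighter recovery is wanted.

## Known limitations

- The insulation and eigenvector centering conventions are reconstructions
  of common-toolkit behavior, as discussed above.
- The expected model is cis-only; no trans expected, no distance-smoothed
  expected (out of scope).
- `cooler`/HDF5 binary files are not read or written; use `cooler dump`
  text exports.
- The Wilcoxon p-value for identical tables is reported as exactly 1 (the
  signed-rank statistic is undefined for all-zero differences).
- Junction classification trusts the upstream aligner's coordinates; the
  optional reference cross-check validates but does not re-align.
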