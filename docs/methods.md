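# Methods

This note documents the models, conventions and numerical choices behind
`nucleoform`, and what validation on its synthetic generators does and
does not establish about real data.

## Coordinates and the contact-matrix model

All genomic coordinates are 0-based half-open (BED convention). A genome
is tiled by fixed-size bins of width *b* per chromosome, in a stated
chromosome order that defines a contiguous global bin index; the last
bin of a chromosome may be short. Contact maps are symmetric and stored
as their upper triangle (i ≤ j); raw maps hold integer counts, balanced
maps nonnegative reals. A set of masked bins travels with the matrix and
no stored entry may touch a masked bin. The interchange format is a
5-column triplet TSV (`chrom1 start1 chrom2 start2 count`) plus a
two-column chrom.sizes file; readers fold lower-triangle rows and sum
duplicates, so the representation is canonical regardless of row order
or orientation.

Typical bin sizes in this line of work are 10 kb for per-chromosome maps
and 50 kb genome-wide; those are the package defaults where a bin size
is needed, but any positive size is accepted.

### Masking

Two masking modes, applied in either order and accumulated as a union:
explicit BED regions (the primary mode — repeat-rich intervals with poor
read mapping, such as a sex-chromosome repeat block, are masked before
normalization), and a coverage rule that masks bins whose raw marginal
falls below a fraction (default 0.05) of the median marginal of nonzero
bins. All-zero bins are always masked by the coverage rule, since
balancing is undefined for them. Whether a real study masked additional
low-coverage bins beyond its stated repeat region is usually
unreported; the coverage rule is this package's proxy, not a
reproduction of any particular pipeline.

### ICE balancing

Normalization is iterative correction (ICE), the community standard for
"normalized" Hi-C maps: find per-bin biases `b_i > 0` such that
`M*_ij = M_ij / (b_i b_j)` has equal genome-wide marginals on all
unmasked bins. The iteration divides by the relative marginal each round
and stops when `max_i |m_i / mean(m) − 1| < tol` (default 1e-5, max 200
iterations; non-convergence is an error that reports the final
residual). Biases are rescaled to geometric mean 1 over unmasked bins,
which fixes the otherwise arbitrary overall scale of the balanced
matrix; masked bins carry NaN biases. Diagonal entries participate in
marginals with weight 1 (keeping the balancing operator standard) but
are excluded from every downstream statistic, because self-pair counts
are dominated by self-ligation artifacts. An unmasked bin with zero
marginal is an error instructing the caller to mask first. The test
suite checks the balanced output against an independently coded naive
fixed-point iteration run to 1e-12.

## Hi-C summary statistics

**Compactness** of unmasked bin *i* is the sum of balanced cis contacts
over unmasked neighbours within `W/b` bins on both sides (default
W = 200 kb), diagonal excluded. Edge bins sum over the neighbours that
exist; no padding or rescaling is applied, so first/last bins of a
chromosome have roughly half the interior value on a uniform matrix (the
acceptance checks use exactly this 40c vs 20c analytic case at 10-kb
bins). Compactness is computed per bin rather than aggregated per
chromosome because genotype comparisons need a distribution per
chromosome, and it is linear in the matrix, so the geometric-mean-1 bias
convention only sets a common scale factor within a map. Comparisons
between maps therefore compare distributions whose absolute scale
depends on that convention and on sequencing depth — the Mann–Whitney
contrast is rank-based exactly for this reason.

**Contact decay.** `P(s)` is the mean balanced contact over all unmasked
cis pairs at separation `s = k·b`, pooled across chromosomes by
valid-pair-weighted averaging (per-chromosome curves are also attached).
Pairs with both bins unmasked count toward the denominator even when the
observed contact is zero. The decay exponent is the ordinary
least-squares slope of `log10 P` vs `log10 s` over grid points with
positive P and nonzero pair count inside the fit range; at least three
points are required. Defaults: `s_min = 2b` (the first diagonal is the
noisiest and s = b is excluded by the diagonal rule anyway),
`s_max = 2.5 Mb` — an upper limit commonly used for per-autosome decay
fits. The log base does not affect the slope. Whether a given study
fitted per autosome or on pooled autosomes is usually unstated; both
modes are exposed and neither is claimed to reproduce any published
value.

**Trans decomposition.** Per unmasked bin: cis sum, trans sum (diagonal
excluded) and trans fraction `trans/(cis+trans)`, NaN where the
denominator is zero. On raw integer matrices cis + trans equals the
off-diagonal marginal exactly, which the tests assert integer-for-
integer. Fractions are the default contrast (absolute balanced sums are
also emitted), since fractions are invariant to the balanced-scale
convention.

**Genotype comparison** takes two per-bin profiles on the same bin grid
and reports, per chromosome, `median(B) − median(A)` and a two-sided
Mann–Whitney U over bins defined in both genotypes.

### Mann–Whitney U

U counts pairs with `x_i < y_j` plus half the ties (so `alternative=
'less'` — x stochastically smaller — corresponds to large U). With at
most 16 pooled observations and no ties the p-value is exact, from the
full null distribution of U computed by the textbook counting recurrence
(worst case C(16,8) = 12,870 labelings); otherwise a normal
approximation with tie correction and a 0.5 continuity correction is
used, and p is clamped to (0, 1]. The 16-observation threshold keeps the
exact path cheap while covering the regimes where the approximation is
poorest. scipy's implementation serves as an independent cross-check in
the tests, not as the implementation.

## DEG filtering and overlap enrichment

The filter implements the rule "FDR smaller than q and fold change more
than F" with q = 0.01, F = 3 by default: up-regulated means
`padj < q` and `log2FC ≥ log2 F`, down-regulated the mirror image.
Boundary behaviour is deliberate: equality passes on the fold change
(the fold rule is "at least") but fails on padj (the FDR rule is a
strict "smaller than"); rows with missing padj never pass. The fold
threshold is interpreted on the linear scale because DE tools report
log2 values while threshold statements are usually phrased linearly.

Overlap enrichment builds the 2×2 table
`((k, |A|−k), (|B|−k, N−|A|−|B|+k))` and computes the one-sided
hypergeometric upper tail (the enrichment question, the default) or the
two-sided Fisher p; the universe size N must be supplied explicitly
because published analyses rarely print it, and no attempt is made to
reproduce any published overlap p-value without it. Gene ids absent from
an explicitly given universe are dropped with a logged count, since id
mismatches between annotation versions are routine. The tests verify the
tail against exact integer arithmetic for every configuration with
N ≤ 25 and against literal draw enumeration for small N.

## Nuclear morphology

The measurement chain is maximum z-projection → threshold (Otsu by
default, or fixed) → hole filling → 8-connected labelling → discard
components below `min_area` or touching the border (partial nuclei are
unmeasurable) → per-object area, perimeter, centroid, equivalent
diameter. Hole filling precedes measurement because nucleolar voids in
DAPI images would otherwise corrupt the perimeter. The circularity index
is `C = 4πA/P²`, the standard definition (1 for a circle). The perimeter
uses the Crofton (line-intercept) estimator: the naive chain/boundary
estimators inflate a rasterized disk's perimeter enough to bias C by
~10–25%, which the test suite demonstrates explicitly
(chain estimator: C ≈ 0.91 on a disk; Crofton: C ≈ 0.99). Both area and
equivalent diameter are emitted because "nuclear size" can reasonably
mean either. Group comparisons use the two-sided Mann–Whitney U; groups
below 3 records are rejected and groups below ~45 nuclei (a typical
per-genotype sample in this kind of study) trigger a logged warning.

## Synthetic generators

The generators define the conditions under which the pipeline is
validated.

**Hi-C maps.** Expected cis contact between bins at separation s bins is
proportional to `s^−α` (α > 0; the diagonal carries no mass since every
statistic excludes it). Expected trans contact is uniform over all
inter-chromosomal bin pairs at `territory_strength × (cis expectation at
s_ref = 10 bins)`; s_ref is arbitrary but fixed, and the uniform-trans
choice is the simplest model consistent with chromosome-territory
phenomenology — it contains no arm-level or compartment structure, which
is a stated limitation. Short terminal bins have expectations scaled by
(bin length / b) per axis, modelling edge effects rather than dropping
them. Masked-region expectations are zeroed before the whole expectation
is rescaled so that its grand total equals `depth`, and realized counts
are independent Poisson draws (the sequencing-sampling model). Default
depth is 2×10⁶ expected pairs — chosen as the scale at which a
5-Mb/10-kb map has O(10) counts per near-diagonal pair, comparable to a
reasonably deep experiment for a genome this size; real studies often do
not print their depth, so this is a package default, not a reproduction.

**Gene sets.** Two sets with exact sizes and exact overlap, drawn
uniformly from an indexed universe; composing the generator with overlap
counting is the identity on (|A|, |B|, k), which makes the enrichment
stage testable against planted truth.

**Nucleus images.** Non-overlapping ellipses (overlap is an error, to
keep truth unambiguous) rendered at pixel-center resolution on a
16-bit gray scale, with optional seeded Gaussian noise clipped to the
gray range. Ground truth per ellipse: area πab exactly, perimeter by
Ramanujan's approximation `π(a+b)(1 + 3h/(10+√(4−3h)))`,
`h = ((a−b)/(a+b))²` (relative error < 1e-6 for the aspect ratios used
here), circularity from those. For a 2:1 ellipse this gives C ≈ 0.841.

All three generators are deterministic given their seed parameter; the
pipeline derives per-stage seeds from one root seed via
`numpy.random.SeedSequence`.

What passing on synthetic data does **not** show: real Hi-C maps have
TADs, loops, compartments and distance-dependent artifacts absent from
the power-law model; real nuclei are not ellipses and real images have
uneven illumination and clumping; real DEG tables have correlated
p-values. The generators validate the *operations* (masking, balancing,
summation, testing arithmetic), not biological inference.

## Pipeline

One YAML config drives up to three stages (hic, deg, morphology), each
either consuming files or simulating inputs. Validation is strict:
unknown keys and type errors are rejected with all problems listed, and
the written `report.json` contains the fully resolved config, so every
applied default is recorded. The first genotype/group listed is the
reference (A side) of comparisons. Reruns with the same config and seed
are byte-identical on all numeric TSV outputs. Stage failure aborts with
a nonzero status after writing a report naming the stage.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations for
single-CPU runs: decay-exponent recovery uses a 5-Mb chromosome at 10-kb
bins and depth 2×10⁶ over 10 seeds per α ∈ {0.8, 1.0, 1.2} (mean fitted
slope within ±0.05 of −α, correct rank order); the genotype contrast
uses a two-chromosome genome (2.5 + 2.0 Mb, 10-kb bins, depth 10⁶) with
Δα = 0.3 for the planted effect and ten independent same-α pairs for
null calibration; ICE convergence is checked on random sparse maps up to
500 bins with the exact oracle on ≤10-bin cases. These sizes are the
package's validation conditions, chosen to exercise every code path at
meaningful statistical power.

## Known limitations

- No TAD/compartment/loop analysis, and the generator plants none; the
  decay exponent and compactness are global summaries only.
- The uniform trans background cannot represent preferential
  chromosome–chromosome adjacency.
- Compactness absolute values depend on the balanced-scale convention;
  only within-map distributions and rank-based contrasts are
  interpretable across genotypes.
- Published overlap p-values cannot be reproduced without the original
  universe and reference-set sizes; the enrichment machinery is
  validated on planted truth instead.
- Segmentation is global-threshold only; touching nuclei are not split
  (the generator forbids overlap accordingly).
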