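# Methods

This note documents the models, parameter choices and numerical decisions
behind `xi_origami`, in the order the pipeline applies them.

## Synthetic chromosome architecture

Contact matrices are simulated per chromosome from a multiplicative
expectation

    E[i, j] ∝ (|i − j| + 1)^(−α) · (1 + ε·[same compartment]) · (1 − δ·[crosses boundary])

with distance measured in bins (the `+1` keeps the self-diagonal finite),
decay exponent α = 1 by default, compartment strength ε, and megadomain
strength δ.  A pair "crosses the boundary" when the first bin starts before
and the second at/after the boundary coordinate (73 Mb by default — the
position of the *Dxz4* locus on mm9 chrX).  The expectation is scaled so the
unmasked upper-triangle total equals the requested read depth and counts are
drawn independently per pair from a Poisson; Poisson is the minimal noise
model for Hi-C pair counts, while gene-level counts (below) need explicit
overdispersion.  A fixed fraction of bins (default 0.14, matching the
bottom-~14% mappability masking the analysis applies) is unmappable: zeroed
and masked, drawn uniformly but never at the boundary bin so the megadomain
statistic stays well defined.

Regime presets fix (ε, δ): the compartment-less wild-type Xi (0, 0), the
SMCHD1-null Xi with S1/S2 checkerboard plus megadomains (0.4, 0.4), the
Xist-deleted Xi with megadomains only (0, 0.4), and an active-X-like A/B
pattern (0.4, 0).  Compartment labels alternate over contiguous runs; when a
target compartment count is given, exactly that many segments tile the
chromosome (random cuts, ≥10 bins each — on a 166-Mb chromosome 25 segments
average 6.6 Mb); otherwise run lengths are uniform on 10–40 bins.

Coverage tracks place a per-bin mean of `base·(1 + enrichment)` in S1 bins
and `base` elsewhere, add Gaussian noise per 500-bp step, and render as
bedGraph.  Negative values are allowed, as in input-subtracted signal.

What the generator does **not** emulate: loop-level structure, TAD
hierarchies (insulation boundaries in the simulations arise only from
compartment transitions), distance-dependent overdispersion of real Hi-C,
copy-number or mappability autocorrelation, and read-level artefacts.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated generative model, not robustness to every property of real
libraries.

## Synthetic allelic expression

Per gene, the Xa (cas) read count in a sample is negative binomial with
mean `xa_mean` (log-normal across genes, median 500) and dispersion 0.1;
the Xi (mus) count has mean `xa_mean · silencing_ratio`, times a
reactivation multiplier (default 5) in mutant+Aza samples of planted
reactivated genes.  The two alleles of a gene share a per-sample Gamma
factor (shape 1/d, scale d), so each marginal is exactly NB(mean, d) while
the within-sample allelic ratio carries near-binomial noise — alleles of one
gene share library and expression-level variation, which is what makes a
two-clone allelic contrast informative at all.  With fully independent
draws the %mus noise floor is ~√(2d) ≈ 45% of the mean and a 2-clone Welch
t at p < 0.1 has ~50% power even for a five-fold effect; the shared-factor
model restores the power a paired-allele design actually has.

Planted gene classes: escapees (10%, silencing ratio uniform 0.15–0.5),
inactive genes (5%, zero expression), low-count genes (5%, ~5 reads),
miscalled-SNP genes (3%, spurious ~20% mus skew in the pure-cas control
samples), and reactivated genes planted among subject genes with baseline
ratio uniform on 0.02–0.06 — a five-fold release is only measurable when
the baseline is quantifiable at realistic depth; remaining subject genes
have baseline ratio 0.002–0.06.  The design is 2 genotypes × 2 treatments ×
2 clones plus two pure-cas control samples.  A `noiseless` mode replaces
sampling with rounded means for exact-recovery tests.

## Matrix preprocessing

Masking ranks bins by raw marginal and masks the bottom `ceil(q·n)` (default
q = 0.14), ties to the lower index, all-zero rows always; re-masking is
idempotent.  Down-sampling draws a multivariate hypergeometric over
upper-triangle cells, so totals are exact and expectations proportional.
ICE iterates `W ← W/(s_i s_j)` with `s` the marginals scaled to unit mean
until the unmasked-marginal CV < 1e-6 (default cap 200 iterations), then
rescales so the mean unmasked entry is preserved; the iteration count is
recorded.  O/E divides by per-diagonal means over unmasked pairs; diagonals
with zero expectation give NA.

The Pearson map correlates O/E (or residual) rows pairwise over unmasked
columns, excluding the two self-columns, with pairwise-complete deletion of
NA cells; it is computed from value and finite-indicator matrix products
with closed-form self-column downdates (no Python loops), pinned to a
brute-force loop oracle in the tests.  Pairs with <3 complete observations
and constant rows give NA.

## Compartment calling

PC1/PC2 are the leading eigenvectors of the correlation map restricted to
unmasked bins; explained variance is the eigenvalue over the sum of positive
eigenvalues.  Each PC's sign is fixed so that its correlation with a
reference track (in practice Xist density or another S1/A-enriched feature)
is non-negative; |r| < 0.05 raises an orientation warning.  Both PCs are
reported with their reference correlations because PC-to-structure
assignment is sample-dependent: with megadomains present the large-scale
split competes with the checkerboard for the leading eigenvector.

Two numerical choices matter at 100-kb resolution and ~5×10⁶ contacts:

1. **Variance-stabilized residuals.**  The raw O/E ratio at distances where
   the expected count falls below one is 0 or enormous, and those cells
   dominate row correlations.  The compartment stage therefore correlates
   Pearson residuals, (observed − expected)/√expected, which have roughly
   unit variance at every distance and weight each distance by its
   information content.  The plain O/E map remains available and is used
   for the whole-chromosome PCs and the permutation null.
2. **Per-megadomain eigendecomposition.**  When a boundary is declared, the
   eigenvectors are computed independently inside each megadomain and
   stitched (`compute_compartments_blockwise`) — the per-arm practice of
   standard compartment analysis, which prevents the block split from
   mixing into the compartment eigenvector when eigenvalues are close.
   Without these two choices the 25-compartment recovery at the default
   depth succeeds in only about half of the seeds; with them it recovers
   25/25 segments with 100% bin agreement in all tested seeds.

Sign-run segmentation takes maximal constant-sign runs over unmasked bins
(zero counts as positive); interior masked gaps are bridged when the
flanking signs agree and split at the gap midpoint when they disagree; runs
shorter than `min_run_bins` (default 3, i.e. 300 kb at the 100-kb calling
resolution — one- or two-bin noise flips must not inflate compartment
counts) are merged into the longer neighbour until stable.  Segment count ×
mean size equals the segmented extent by construction.

The no-structure null for PC1 explained variance permutes contacts within
each genomic-distance diagonal (among unmasked positions, mirrored to keep
symmetry) and re-runs balancing, O/E, and the correlation-map
eigendecomposition per permutation.  Both features matter: shuffling across
diagonals would homogenize the strongly distance-dependent noise scale, and
skipping the re-balance would miss the weak shared row factors ICE itself
introduces; a joint row/column permutation would leave the spectrum
unchanged entirely.

## Insulation and boundaries

The raw insulation score of bin i is the mean of unmasked cells in the
square `[i−w, i) × (i, i+w]` with w = 500 kb; bins within w of an end, masked
bins, and windows more than half masked score NA.  Normalized scores are
log2 of raw over the "iqrMean" — the mean of raw scores lying within the
chromosome's interquartile range — making them invariant to global scaling;
this reading of the iqrMean flag is pinned by the oracle test.  The delta
vector at bin i is the mean normalized score over `(i, i+d]` minus that over
`[i−d, i)` with d = 400 kb; boundaries sit at negative-to-positive zero
crossings (the called bin is the lower-scoring of the two crossing bins),
with strength = following local delta maximum − preceding local minimum, and
calls at or below the noise threshold (default 0) dropped.  Per-region
boundary scores take the minimum normalized score over overlapping bins
(boundaries are insulation minima); set comparisons use the rank-sum test.
Border/boundary matching uses a 1-bin slack by default.

## Megadomain statistic

A bin pair (i < j) is long-range when `(j−i)·bin_size` exceeds 10 Mb
(about twice the largest X-linked TAD) and crossing when bin i starts
before and bin j at/after the 73-Mb boundary; the boundary bin belongs to
the distal domain.  The fraction is contact-weighted by default (a
pair-counted mode exists), is invariant to global scaling, and decreases
monotonically in the simulator's boundary strength.  Replicate contrasts
use the unpaired one-sided Welch t with means ± SD reported; identical
zero-variance groups return t = 0, one-sided p = 0.5 by convention.

## Classification cascade and tests

The cascade order is fixed: activity (FPKM > 0 in every sample) →
assessability (mus+cas ≥ 13 in every sample, inclusive) → miscalled-SNP
exclusion (%mus > 9.09% in any pure-cas control sample — the value of 1 read
in 11) → escapee (within-clone Xi/Xa read ratio mus/cas strictly > 0.1 in at
least one WT reference clone) → subject to XCI (the remainder).  Each gene
records the first filter it failed; statuses partition the assessable set.
"13 allele-specific reads" is read as the per-sample mus+cas total, and the
escapee ratio is computed from the same allelic counts (both readings
documented here because the upstream definitions leave them open).

Reactivation requires mean %mus in the test condition ≥ 3× the baseline
mean (a baseline of exactly 0 passes when the test mean is positive) AND a
one-sided Welch t p < 0.1 across clones; with two clones per condition the
test is valid but low-powered, and zero-variance degenerate cases fall back
to a deterministic mean comparison.  Paired cumulative-distribution
comparisons use the Wilcoxon signed-rank on per-gene differences of
clone-averaged %mus (the paired analogue of the rank-sum; all-zero
differences give p = NA), unpaired ones the rank-sum.  Class enrichment
intersects an external class annotation with the subject set and compares
%mus of the target class against the rest (unpaired, one-sided).  Sample
clustering is average-linkage on Euclidean distances over the subject-gene
%mus matrix with listwise NA deletion.

## Coverage arithmetic

Tracks are piecewise-constant over 0-based half-open intervals; integrals
are exact via a breakpoint-interpolated cumulative.  Smoothing records the
mean over a centred 1-kb window every 500 bp (window clipped at chromosome
ends, dividing by the clipped width).  fpm normalization scales total mass
to 10⁶; input subtraction is a documented simple windowed difference of
fpm-normalized IP and input.  Scaling to a reference equalizes integrals
over a region (the chromosome-sum equalization used for Xist coverage in
two genotypes expressing Xist equally); Δ tracks subtract pointwise over the
union of breakpoints.  Binned densities are length-weighted means (
resolution-independent).  The S1-vs-S2 test partitions bins by compartment
sign and applies the one-sided rank-sum, reporting box-plot summaries
(median, quartiles, 1.5·IQR whiskers).  Metaprofiles average fixed-step
(100 bp) window means over ±10 kb around peak summits, dropping summits
within a flank of a chromosome end.

## Problem sizes and determinism

The tests and the acceptance script run at the sizes of the synthetic study
conditions: compartment recovery on the full 166-Mb chromosome at 100-kb
bins (10 seeds in the test suite, 3 in the acceptance script), regime
contrasts at 200-kb bins with 100 (tests) or 30 (script) permutations, the
coverage chain on a 40-Mb chromosome at 200-kb bins (so each compartment
group holds well over 50 bins) with 100/20 seeds, and reactivation
performance over 50/10 tables of 100 genes.  Every random draw flows from
an explicit seed; identical seeds give byte-identical simulated data,
reports and tables (the pipeline report embeds the config hash and library
versions).

## Known limitations

Pearson maps, eigenvectors and insulation assume a single chromosome held
densely in memory (fine to ~5,000 bins).  The miscalled-SNP filter needs
pure-cas control samples and is skipped with a warning otherwise.  TAD
coordinates are consumed as input regions — there is no TAD caller — and
the insulation boundary caller with noise threshold 0 is deliberately
permissive, so border-overlap fractions on synthetic data vary with seed.
The generator's planted effects are block-constant; real S1/S2 strength
varies along the chromosome.
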