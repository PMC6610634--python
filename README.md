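# xi-origami

Analysis toolkit for the chromosome architecture and allelic expression of
the inactive X chromosome (Xi), built around the question of how the
non-canonical SMC protein SMCHD1 shapes Xi folding and silencing in
post-XCI cells.

In hybrid mouse cells carrying a *mus* Xi and a *cas* Xa, allele-resolved
Hi-C, Xist CHART-seq, H3K27me3/H2AK119ub ChIP-seq and allele-specific
RNA-seq together describe a layered Xi: two megadomains separated by the
*Dxz4* locus (~73 Mb, mm9), an underlying S1 (Xist-rich) / S2 (Xist-poor)
compartment pattern that SMCHD1 normally merges, attenuated TADs, and a
silenced gene complement with a minority of escapees.  This package
implements the downstream analysis chain for all of those layers, plus a
synthetic-data generator that plants each structure with known ground truth
so every stage can be validated by parameter recovery.

## What it computes

* **Contact-matrix preprocessing** (`hic_balance`): mappability masking of
  the lowest-coverage bins (bottom ~14% of marginals), exact depth-matching
  by multivariate-hypergeometric down-sampling, iterative correction (ICE)
  with mean preservation, observed/expected and variance-stabilized
  residual maps, and bin-by-bin Pearson correlation maps with the two
  self-columns excluded.
* **Compartments** (`compartments`): PC1/PC2 of the correlation map
  (whole-chromosome or per-megadomain), sign-oriented against a reference
  track so that positive values mark the Xist-rich S1 (or A-like)
  compartment; sign-run segmentation with masked-gap bridging and a
  minimum-run merge; feature correlations; profile clustering.
* **Insulation** (`insulation`): Crane-style sliding-square scores
  (500-kb square, 400-kb delta span, iqrMean normalization, noise
  threshold 0), delta-vector boundary calls with strengths, rank-sum
  comparisons of boundary sets, and S1/S2-border/TAD-boundary overlap.
* **Megadomains** (`megadomains`): the fraction of long-range (>10 Mb)
  contacts that cross the megadomain boundary, and its replicate-level
  one-sided Welch t contrast.
* **Allelic expression** (`allelic_expression`): %mus = 100·mus/(mus+cas)
  and the classification cascade — active (FPKM > 0 in all samples) →
  allele-assessable (≥13 allele-specific reads in all samples) →
  miscalled-SNP filter (%mus > 9.09% in pure-cas controls) → escapee
  (Xi/Xa > 10% in ≥1 WT clone) → subject to XCI — followed by the
  reactivation call (≥3-fold %mus gain with one-sided Welch t p < 0.1),
  cumulative-distribution comparisons, class-intersection tests, and
  sample clustering.
* **Coverage tracks** (`coverage_tracks`): windowed smoothing (1-kb windows
  every 500 bp), chromosome-sum-equalized scaling, difference (Δ) tracks,
  per-region and per-bin densities, the S1-vs-S2 density rank-sum test, and
  peak-summit-centered metaprofiles.
* **Synthetic data** (`synthetic`): contact matrices with power-law
  distance decay, a planted compartment checkerboard of strength ε, a
  megadomain boundary of strength δ, unmappable bins, and Poisson noise at
  a target depth; compartment-following coverage tracks; and allelic count
  tables with planted escapees, miscalled SNPs, Class I labels, and a
  reactivation effect under combined SMCHD1-loss + Aza treatment.

## Worked example

```python
import xi_origami as xo
from xi_origami.pipeline import compartment_stage

truth = xo.make_architecture_truth(
    "SMCHD1_KO", chrom_length_bp=166_000_000, bin_size_bp=100_000,
    n_compartments=25, read_depth=5_000_000, seed=0)
matrix = xo.simulate_contact_matrix(truth)
balanced = xo.ice_balance(xo.mask_low_coverage(matrix, 0.14))
reference = xo.BinnedSignal(truth.binning,
                            (truth.compartment_labels > 0).astype(float))
profile, segments = compartment_stage(balanced, reference, truth.boundary_bin)
called = segments.labels()
ok = ~truth.unmappable_bins & (called != 0)
print(segments.n_compartments,
      round(segments.mean_size_bp / 1e6, 2),
      round((called[ok] == truth.compartment_labels[ok]).mean(), 4))
```

prints

```
25 6.64 1.0
```

— the chain recovers all 25 planted compartments (mean size 6.64 Mb on the
166-Mb chromosome) with 100% bin-label agreement at a depth of 5 million
contacts and 14% unmappable bins.

The numbered scripts under `analysis/` run each stage as a narrative
analysis (simulation, compartment recovery, insulation boundaries,
megadomain strength, coverage deltas, allelic classification) and write
their tables under `results/`.  A one-shot orchestration of everything is

```bash
xi-origami run configs/demo.yaml --out results/pipeline
```

which emits a JSON report plus figure-ready TSV/BED/bedGraph files and is
byte-reproducible under a fixed seed.

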