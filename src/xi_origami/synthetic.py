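"""Synthetic data with planted Xi architecture and allelic expression.

The generator emulates the study conditions the analysis modules are built
for, with ground truth retained for parameter-recovery tests:

* contact matrices with power-law distance decay, a planted S1/S2 (or A/B)
  checkerboard of strength epsilon, a megadomain boundary of strength delta,
  unmappable bins, and Poisson counting noise scaled to a target read depth;
* coverage tracks whose per-bin mean follows the compartment labels plus
  Gaussian noise, rendered at 500-bp steps;
* allele-resolved count tables for a 2-genotype x 2-treatment x 2-clone
  design with planted escapees, silenced genes, miscalled-SNP artefacts,
  Class I labels and a reactivation effect under the combined perturbation.

Counts for the two alleles of a gene in a sample share a per-sample Gamma
factor, so each marginal is negative binomial with the requested dispersion
while the within-sample allelic ratio carries near-binomial noise — alleles
of one gene share most library and expression-level variation.

Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics_io import CoverageTrack, GenomeBinning
from .hic_balance import ContactMatrix

MM9_CHRX_LENGTH = 166_000_000
DEFAULT_MEGADOMAIN_BOUNDARY = 73_000_000

# (compartment_strength epsilon, megadomain_strength delta) per regime
REGIME_PRESETS = {
    "WT_Xi": (0.0, 0.0),        # compartment-less
    "SMCHD1_KO": (0.4, 0.4),    # S1/S2 checkerboard under megadomains
    "XIST_KO": (0.0, 0.4),      # megadomains only
    "Xa": (0.4, 0.0),           # A/B checkerboard, no megadomains
}


@dataclass
class ArchitectureTruth:
    """Planted chromosome architecture with per-bin ground-truth labels."""

    binning: GenomeBinning
    compartment_labels: np.ndarray       # +1 = S1/A, -1 = S2/B per bin
    regime: str = "SMCHD1_KO"
    megadomain_boundary_bp: int = DEFAULT_MEGADOMAIN_BOUNDARY
    decay_exponent: float = 1.0
    compartment_strength: float = 0.4    # epsilon
    megadomain_strength: float = 0.4     # delta
    unmappable_fraction: float = 0.14
    read_depth: int = 5_000_000
    seed: int = 0
    unmappable_bins: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.compartment_labels = np.asarray(self.compartment_labels, dtype=int)
        if len(self.compartment_labels) != self.binning.n_bins:
            raise ValueError("one compartment label per bin required")
        if self.unmappable_bins is None:
            self.unmappable_bins = _draw_unmappable(
                self.binning, self.unmappable_fraction,
                self.megadomain_boundary_bp, self.seed)
        self.unmappable_bins = np.asarray(self.unmappable_bins, dtype=bool)

    @property
    def boundary_bin(self) -> int:
        return self.megadomain_boundary_bp // self.binning.bin_size_bp


def _draw_unmappable(binning: GenomeBinning, fraction: float,
                     boundary_bp: int, seed: int) -> np.ndarray:
    """Random unmappable bins, never at the megadomain boundary bin."""
    rng = np.random.default_rng(seed)
    n = binning.n_bins
    boundary_bin = boundary_bp // binning.bin_size_bp
    candidates = np.setdiff1d(np.arange(n), [boundary_bin])
    k = int(round(fraction * n))
    chosen = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    return mask


def plant_compartment_labels(
    binning: GenomeBinning,
    n_compartments: int | None = 25,
    min_run_bins: int = 10,
    max_run_bins: int = 40,
    seed: int = 0,
) -> np.ndarray:
    """Alternating-sign compartment labels forming contiguous runs.

    With ``n_compartments`` given, exactly that many segments tile the
    chromosome (random cuts with a minimum run length); otherwise run
    lengths are drawn uniformly from [min_run_bins, max_run_bins].
    """
    rng = np.random.default_rng(seed)
    n = binning.n_bins
    if n_compartments is not None:
        if n_compartments * min_run_bins > n:
            raise ValueError("chromosome too short for requested compartments")
        extra = n - n_compartments * min_run_bins
        parts = rng.multinomial(extra, np.full(n_compartments, 1 / n_compartments))
        lengths = min_run_bins + parts
    else:
        lengths = []
        covered = 0
        while covered < n:
            l = int(rng.integers(min_run_bins, max_run_bins + 1))
            lengths.append(min(l, n - covered))
            covered += l
        lengths = np.array(lengths)
    labels = np.empty(n, dtype=int)
    sign = 1
    pos = 0
    for l in lengths:
        labels[pos : pos + l] = sign
        sign = -sign
        pos += l
    return labels


def make_architecture_truth(
    regime: str = "SMCHD1_KO",
    chrom_length_bp: int = MM9_CHRX_LENGTH,
    bin_size_bp: int = 200_000,
    n_compartments: int | None = 25,
    read_depth: int = 5_000_000,
    seed: int = 0,
    **overrides,
) -> ArchitectureTruth:
    """Study-condition presets for the four Xi/Xa regimes."""
    if regime not in REGIME_PRESETS:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIME_PRESETS)}")
    eps, delta = REGIME_PRESETS[regime]
    binning = GenomeBinning("chrX", chrom_length_bp, bin_size_bp)
    if n_compartments is not None:
        n_compartments = max(1, min(n_compartments, binning.n_bins // 10))
    labels = plant_compartment_labels(binning, n_compartments, seed=seed)
    kwargs = dict(
        regime=regime, compartment_strength=eps, megadomain_strength=delta,
        read_depth=read_depth, seed=seed,
    )
    kwargs.update(overrides)
    return ArchitectureTruth(binning, labels, **kwargs)


def expected_contact_means(truth: ArchitectureTruth) -> np.ndarray:
    """Unscaled expected contact matrix implied by the planted structure."""
    n = truth.binning.n_bins
    bs = truth.binning.bin_size_bp
    eps, delta = truth.compartment_strength, truth.megadomain_strength
    if eps < 0 or not 0 <= delta <= 1:
        raise ValueError("compartment strength must be >= 0 and megadomain strength in [0, 1]")
    idx = np.arange(n)
    # power-law decay over bin distance; +1 bin keeps the self-diagonal finite
    # (equivalent to ((|i-j|+1)*bin_size)^-alpha up to the depth scale factor)
    dist_bins = np.abs(idx[:, None] - idx[None, :])
    base = (dist_bins + 1.0) ** (-truth.decay_exponent)
    same = truth.compartment_labels[:, None] == truth.compartment_labels[None, :]
    base = base * np.where(same, 1.0 + eps, 1.0)
    starts = idx * bs
    crossing = (starts[:, None] < truth.megadomain_boundary_bp) & (
        starts[None, :] >= truth.megadomain_boundary_bp)
    crossing = crossing | crossing.T
    base = base * np.where(crossing, 1.0 - delta, 1.0)
    return base


def simulate_contact_matrix(truth: ArchitectureTruth) -> ContactMatrix:
    """Poisson contact matrix with the planted structure, scaled to read depth.

    Counts are drawn independently per upper-triangle pair from Poisson means
    proportional to ``(d+1)^-alpha * (1 + eps·same-compartment) *
    (1 - delta·boundary-crossing)``, scaled so the expected unmasked total is
    ``read_depth``; unmappable rows/columns are zeroed and masked.
    """
    rng = np.random.default_rng(truth.seed)
    means = expected_contact_means(truth)
    keep = ~truth.unmappable_bins
    n = truth.binning.n_bins
    iu, ju = np.triu_indices(n)
    pair_means = means[iu, ju]
    usable = keep[iu] & keep[ju]
    scale = truth.read_depth / pair_means[usable].sum()
    counts = rng.poisson(pair_means * usable * scale)
    mat = np.zeros((n, n))
    mat[iu, ju] = counts
    mat = mat + mat.T - np.diag(np.diag(mat))
    return ContactMatrix(
        truth.binning, mat, allele="mus", mask=truth.unmappable_bins.copy(),
        metadata={"regime": truth.regime, "seed": truth.seed,
                  "read_depth": truth.read_depth},
    )


def simulate_coverage(
    truth: ArchitectureTruth,
    enrichment_S1: float = 0.5,
    noise_sd: float = 0.2,
    base_level: float = 1.0,
    step_bp: int = 500,
    seed: int | None = None,
) -> CoverageTrack:
    """Coverage whose density follows the compartment labels plus noise.

    Per 500-bp step: ``base * (1 + enrichment_S1)`` inside S1 bins, ``base``
    elsewhere, plus Gaussian noise (values may go negative, as in
    input-subtracted signal).  Deterministic under seed.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    L = truth.binning.chrom_length_bp
    n_steps = -(-L // step_bp)
    starts = np.arange(n_steps, dtype=np.int64) * step_bp
    ends = np.minimum(starts + step_bp, L)
    bins = starts // truth.binning.bin_size_bp
    s1 = truth.compartment_labels[bins] > 0
    means = base_level * np.where(s1, 1.0 + enrichment_S1, 1.0)
    vals = means + rng.normal(0.0, noise_sd, n_steps) if noise_sd > 0 else means.astype(float)
    return CoverageTrack(truth.binning.chrom_name, starts, ends, vals)


# ---------------------------------------------------------------------------
# allelic expression
# ---------------------------------------------------------------------------

CONDITIONS = ("WT_DMSO", "WT_Aza", "KO_DMSO", "KO_Aza")


@dataclass
class ExpressionTruth:
    """Planted per-gene expression parameters and truth labels."""

    gene_ids: list[str]
    gene_length_bp: np.ndarray
    xa_mean: np.ndarray                   # expected cas (Xa) reads per sample
    silencing_ratio: np.ndarray           # Xi/Xa; escapee > 0.1, subject <= 0.1
    xci_status: np.ndarray                # 'escapee' | 'subject' | 'inactive' | 'low'
    class_label: np.ndarray               # 'I' | 'II' | 'III' | 'unclassified'
    is_reactivated: np.ndarray            # bool; effect applies in KO_Aza
    is_miscalled: np.ndarray              # bool; skew planted in pure-cas controls
    reactivation_multiplier: float = 5.0
    dispersion: float = 0.1
    n_clones: int = 2
    noiseless: bool = False
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_design(self) -> list[tuple[str, str, str]]:
        """(sample_id, condition, clone) for the full 4-condition design."""
        out = []
        for cond in CONDITIONS:
            for c in range(1, self.n_clones + 1):
                out.append((f"{cond}_c{c}", cond, f"c{c}"))
        return out


def make_expression_truth(
    n_genes: int = 200,
    escapee_fraction: float = 0.10,
    inactive_fraction: float = 0.05,
    low_count_fraction: float = 0.05,
    miscalled_fraction: float = 0.03,
    reactivated_fraction: float = 0.20,
    n_reactivated: int | None = None,
    reactivation_multiplier: float = 5.0,
    dispersion: float = 0.1,
    noiseless: bool = False,
    seed: int = 0,
) -> ExpressionTruth:
    """Plant a gene panel spanning every branch of the classification cascade.

    Fractions follow the study design they emulate: ~10% of assessable
    X-linked genes escape XCI, a small minority fail the activity or
    read-depth filters or carry miscalled SNPs, and reactivation under the
    combined perturbation hits a subset of the subject genes (planted among
    genes whose baseline Xi/Xa ratio is quantifiable, 0.02-0.06).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{k:04d}" for k in range(n_genes)]
    lengths = rng.integers(1_000, 50_000, n_genes)
    xa_mean = np.exp(rng.normal(np.log(500.0), 0.5, n_genes))

    status = np.full(n_genes, "subject", dtype=object)
    order = rng.permutation(n_genes)
    n_inact = int(round(inactive_fraction * n_genes))
    n_low = int(round(low_count_fraction * n_genes))
    n_esc = int(round(escapee_fraction * n_genes))
    n_mis = int(round(miscalled_fraction * n_genes))
    pos = 0
    inact = order[pos : pos + n_inact]; pos += n_inact
    low = order[pos : pos + n_low]; pos += n_low
    esc = order[pos : pos + n_esc]; pos += n_esc
    mis = order[pos : pos + n_mis]; pos += n_mis
    status[inact] = "inactive"
    status[low] = "low"
    status[esc] = "escapee"
    xa_mean[inact] = 0.0
    xa_mean[low] = 5.0

    ratio = rng.uniform(0.002, 0.06, n_genes)
    ratio[esc] = rng.uniform(0.15, 0.5, n_esc)
    ratio[inact] = 0.0

    is_miscalled = np.zeros(n_genes, dtype=bool)
    is_miscalled[mis] = True

    subject_idx = np.flatnonzero((status == "subject") & ~is_miscalled)
    n_react = (n_reactivated if n_reactivated is not None
               else int(round(reactivated_fraction * len(subject_idx))))
    if n_react > len(subject_idx):
        raise ValueError("more reactivated genes requested than subject genes")
    react_pool = rng.permutation(subject_idx)[:n_react]
    is_react = np.zeros(n_genes, dtype=bool)
    is_react[react_pool] = True
    ratio[react_pool] = rng.uniform(0.02, 0.06, n_react)

    classes = np.array(["unclassified"] * n_genes, dtype=object)
    # Class I = SMCHD1-dependent silencing, the reactivation-prone set
    classes[react_pool] = "I"
    others = np.setdiff1d(subject_idx, react_pool)
    rng.shuffle(others)
    third = len(others) // 3
    classes[others[:third]] = "II"
    classes[others[third : 2 * third]] = "III"
    return ExpressionTruth(
        gene_ids, lengths, xa_mean, ratio, status.astype(str), classes.astype(str),
        is_react, is_miscalled, reactivation_multiplier, dispersion,
        noiseless=noiseless, seed=seed,
    )


def _allele_counts(rng, xa_mean, ratio, dispersion, noiseless):
    """Shared-Gamma-factor counts: marginals NB(mean, dispersion)."""
    if noiseless:
        cas = np.rint(xa_mean).astype(np.int64)
        mus = np.rint(xa_mean * ratio).astype(np.int64)
        return mus, cas
    if dispersion > 0:
        g = rng.gamma(1.0 / dispersion, dispersion, len(xa_mean))
    else:
        g = np.ones(len(xa_mean))
    cas = rng.poisson(xa_mean * g)
    mus = rng.poisson(xa_mean * ratio * g)
    return mus, cas


def simulate_allelic_counts(truth: ExpressionTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allelic count tables for the 4-condition design plus pure-cas controls.

    Returns (table, control_table).  The reactivation multiplier applies to
    the Xi/Xa ratio in KO_Aza samples of reactivated genes only.  Control
    samples emulate pure-cas cells: near-zero mus reads except at planted
    miscalled-SNP genes, which show a spurious ~20% mus skew.
    """
    if np.any(truth.silencing_ratio < 0) or np.any(truth.xa_mean < 0):
        raise ValueError("negative expression parameters")
    rng = np.random.default_rng(truth.seed)
    lib_size_m = 30.0  # nominal library size (millions) for the FPKM scale
    rows = []
    for sample_id, cond, clone in truth.sample_design():
        ratio = truth.silencing_ratio.copy()
        if cond == "KO_Aza":
            ratio = np.where(truth.is_reactivated,
                             np.minimum(ratio * truth.reactivation_multiplier, 1.0),
                             ratio)
        mus, cas = _allele_counts(rng, truth.xa_mean, ratio,
                                  truth.dispersion, truth.noiseless)
        total = mus + cas
        fpkm = total / (truth.gene_length_bp / 1000.0) / lib_size_m
        rows.append(pd.DataFrame({
            "gene_id": truth.gene_ids, "gene_length_bp": truth.gene_length_bp,
            "sample_id": sample_id, "condition": cond, "clone": clone,
            "mus_reads": mus, "cas_reads": cas, "fpkm": fpkm,
        }))
    table = pd.concat(rows, ignore_index=True)

    ctrl_rows = []
    for k in range(1, 3):
        ctrl_ratio = np.where(truth.is_miscalled, 0.25, 0.001)
        ctrl_ratio = np.where(truth.xa_mean > 0, ctrl_ratio, 0.0)
        mus, cas = _allele_counts(rng, truth.xa_mean, ctrl_ratio,
                                  truth.dispersion, truth.noiseless)
        total = mus + cas
        fpkm = total / (truth.gene_length_bp / 1000.0) / lib_size_m
        ctrl_rows.append(pd.DataFrame({
            "gene_id": truth.gene_ids, "gene_length_bp": truth.gene_length_bp,
            "sample_id": f"pure_cas_{k}", "condition": "pure_cas", "clone": f"c{k}",
            "mus_reads": mus, "cas_reads": cas, "fpkm": fpkm,
        }))
    control = pd.concat(ctrl_rows, ignore_index=True)
    return table, control


def truth_to_segments(truth: ArchitectureTruth):
    """Ground-truth compartment labels as CompartmentSegments (for tests)."""
    from .compartments import CompartmentSegments

    labels = truth.compartment_labels
    segs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append((start, i, int(labels[start])))
            start = i
    return CompartmentSegments(truth.binning, segs)
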