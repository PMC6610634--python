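"""End-to-end orchestration: simulate -> balance -> compartments ->
insulation -> megadomains -> coverage deltas -> allelic classification.

A declarative YAML/dict config drives the whole chain and a single JSON
report collates every stage's summary statistics.  All randomness flows
from the config's seed, so re-running a config reproduces the report
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allelic_expression import call_reactivated, classify_genes
from .compartments import (call_segments, compute_compartments,
                           compute_compartments_blockwise,
                           correlate_with_feature, select_compartment_pc)
from .coverage_tracks import delta_track, s1s2_density_test, scale_to_reference
from .genomics_io import (BinnedSignal, GenomeBinning, Region, bin_track,
                          write_bed, write_bedgraph)
from .hic_balance import (ContactMatrix, ice_balance, mask_low_coverage,
                          observed_over_expected, pearson_map,
                          pearson_residuals)
from .insulation import call_boundaries, insulation_score
from .megadomains import compare_fractions, inter_megadomain_fraction
from .synthetic import (make_architecture_truth, make_expression_truth,
                        simulate_allelic_counts, simulate_contact_matrix,
                        simulate_coverage, truth_to_segments)

log = logging.getLogger("xi_origami")

DEFAULT_CONFIG = {
    "seed": 7,
    "chromosome": {"name": "chrX", "length_bp": 60_000_000},
    "resolutions": {"hic_bp": 100_000, "density_bp": 200_000},
    "hic": {
        "regimes": ["WT_Xi", "SMCHD1_KO", "XIST_KO"],
        "read_depth": 3_000_000,
        "n_compartments": 10,
        "boundary_bp": 27_000_000,
    },
    "thresholds": {
        "mask_quantile": 0.14,
        "min_run_bins": 3,
        "span_threshold_bp": 10_000_000,
        "insulation_square_bp": 500_000,
        "insulation_delta_bp": 400_000,
        "reactivation_fold": 3.0,
        "reactivation_p": 0.1,
    },
    "coverage": {"enrichment_S1": 0.5, "noise_sd": 0.2},
    "expression": {"n_genes": 150},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return merge_config(cfg)


def merge_config(cfg: dict) -> dict:
    """Overlay a user config on the defaults (one level of nesting)."""
    out = {}
    for key, default in DEFAULT_CONFIG.items():
        if isinstance(default, dict):
            out[key] = {**default, **cfg.get(key, {})}
        else:
            out[key] = cfg.get(key, default)
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return out


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum contacts into bins ``factor`` times wider (for coarse statistics)."""
    n = m.n_bins
    n2 = -(-n // factor)
    pad = n2 * factor - n
    vals = np.nan_to_num(m.values)
    if pad:
        vals = np.pad(vals, ((0, pad), (0, pad)))
    coarse = vals.reshape(n2, factor, n2, factor).sum(axis=(1, 3))
    mask = np.pad(m.mask, (0, pad), constant_values=True).reshape(n2, factor).all(axis=1)
    binning2 = GenomeBinning(m.binning.chrom_name, m.binning.chrom_length_bp,
                             m.binning.bin_size_bp * factor)
    return ContactMatrix(binning2, coarse, allele=m.allele, mask=mask,
                         metadata=dict(m.metadata))


def compartment_stage(balanced: ContactMatrix, reference, boundary_bin: int | None,
                      min_run_bins: int = 3):
    """Balanced counts -> residual map -> block-wise PCs -> sign-run segments.

    The megadomain boundary (when inside the chromosome) splits the
    eigendecomposition into per-megadomain blocks, the per-arm practice that
    keeps the large-scale split from mixing into the compartment eigenvector.
    Returns (profile, segments).
    """
    res = pearson_residuals(balanced)
    split = []
    if boundary_bin is not None and 0 < boundary_bin < balanced.n_bins:
        split = [boundary_bin]
    profile = compute_compartments_blockwise(res, reference, split)
    segments = call_segments(profile, min_run_bins=min_run_bins)
    return profile, segments


def _analyze_regime(truth, cfg, outdir: Path) -> dict:
    thr = cfg["thresholds"]
    raw = simulate_contact_matrix(truth)
    masked = mask_low_coverage(raw, thr["mask_quantile"])
    balanced = ice_balance(masked)

    reference = BinnedSignal(truth.binning,
                             (truth.compartment_labels > 0).astype(float))
    profile, segments = compartment_stage(balanced, reference, truth.boundary_bin,
                                          thr["min_run_bins"])

    # whole-chromosome PCs (megadomain-split detection, regime contrast)
    oe = observed_over_expected(balanced)
    whole_profile = compute_compartments(pearson_map(oe), reference)

    ins = insulation_score(balanced, thr["insulation_square_bp"],
                           thr["insulation_delta_bp"])
    boundaries = call_boundaries(ins)

    density_factor = cfg["resolutions"]["density_bp"] // cfg["resolutions"]["hic_bp"]
    coarse = coarsen(masked, density_factor) if density_factor > 1 else masked
    mega = inter_megadomain_fraction(coarse, truth.megadomain_boundary_bp,
                                     thr["span_threshold_bp"])

    regime = truth.regime
    pc1_track = pd.DataFrame({
        "chrom": truth.binning.chrom_name,
        "start": np.arange(truth.binning.n_bins) * truth.binning.bin_size_bp,
        "end": np.minimum((np.arange(truth.binning.n_bins) + 1) * truth.binning.bin_size_bp,
                          truth.binning.chrom_length_bp),
        "pc1": profile.pc1,
    })
    pc1_track.to_csv(outdir / f"{regime}.pc1.tsv", sep="\t", index=False,
                     float_format="%.6g")
    seg_regions = [Region(truth.binning.chrom_name,
                          s * truth.binning.bin_size_bp,
                          min(e * truth.binning.bin_size_bp, truth.binning.chrom_length_bp),
                          name="S1" if sign > 0 else "S2")
                   for s, e, sign in segments.segments]
    write_bed(seg_regions, outdir / f"{regime}.segments.bed")

    truth_labels = truth.compartment_labels
    called = segments.labels()
    ok = ~truth.unmappable_bins & (called != 0)
    agreement = float((called[ok] == truth_labels[ok]).mean()) if ok.any() else float("nan")
    # eigenvector sign is fixed by the reference, so direct label comparison applies
    return {
        "regime": regime,
        "n_compartments": segments.n_compartments,
        "mean_size_bp": segments.mean_size_bp,
        "explained_variance_pc1": profile.explained_variance_fraction[0],
        "reference_r_pc1": profile.reference_r[0],
        "whole_chrom_explained_variance_pc1": whole_profile.explained_variance_fraction[0],
        "whole_chrom_reference_r_pc1": whole_profile.reference_r[0],
        "truth_label_agreement": agreement,
        "n_boundaries": len(boundaries),
        "ice_iterations": balanced.metadata["ice_iterations"],
        "inter_megadomain_fraction": mega.fraction,
    }


def run_pipeline(cfg: dict, output_dir) -> dict:
    """Run the full synthetic analysis chain and write report + tables."""
    cfg = merge_config(cfg)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    chrom = cfg["chromosome"]
    report: dict = {
        "pipeline_version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "versions": _library_versions(),
        "regimes": [],
    }

    for k, regime in enumerate(cfg["hic"]["regimes"]):
        log.info("regime %s: simulate + balance + compartments", regime)
        truth = make_architecture_truth(
            regime,
            chrom_length_bp=chrom["length_bp"],
            bin_size_bp=cfg["resolutions"]["hic_bp"],
            n_compartments=cfg["hic"]["n_compartments"],
            read_depth=cfg["hic"]["read_depth"],
            seed=seed + k,
            megadomain_boundary_bp=cfg["hic"]["boundary_bp"],
        )
        report["regimes"].append(_analyze_regime(truth, cfg, outdir))

    # coverage chain on the compartmentalized regime
    log.info("coverage delta + S1/S2 enrichment")
    cov_truth = make_architecture_truth(
        "SMCHD1_KO", chrom_length_bp=chrom["length_bp"],
        bin_size_bp=cfg["resolutions"]["density_bp"],
        n_compartments=cfg["hic"]["n_compartments"],
        seed=seed, megadomain_boundary_bp=cfg["hic"]["boundary_bp"],
    )
    ko_track = simulate_coverage(cov_truth, cfg["coverage"]["enrichment_S1"],
                                 cfg["coverage"]["noise_sd"], seed=seed + 100)
    wt_track = simulate_coverage(cov_truth, 0.0, cfg["coverage"]["noise_sd"],
                                 seed=seed + 101)
    whole = Region(chrom["name"], 0, chrom["length_bp"])
    wt_scaled = scale_to_reference(wt_track, ko_track, whole)
    delta = delta_track(ko_track, wt_scaled)
    write_bedgraph(delta, outdir / "delta_coverage.bedgraph")
    binned = bin_track(delta, cov_truth.binning)
    s1s2 = s1s2_density_test(binned, truth_to_segments(cov_truth))
    report["coverage"] = {
        "s1s2_p_value": s1s2["p_value"],
        "n_s1_bins": s1s2["n_s1"],
        "n_s2_bins": s1s2["n_s2"],
        "median_delta_s1": s1s2.get("s1", {}).get("median"),
        "median_delta_s2": s1s2.get("s2", {}).get("median"),
    }

    # allelic classification cascade
    log.info("allelic classification + reactivation")
    etruth = make_expression_truth(cfg["expression"]["n_genes"], seed=seed + 200)
    table, control = simulate_allelic_counts(etruth)
    cls = classify_genes(table, control, ["WT_DMSO_c1", "WT_DMSO_c2"])
    react = call_reactivated(cls, fold=cfg["thresholds"]["reactivation_fold"],
                             p_threshold=cfg["thresholds"]["reactivation_p"])
    cls.genes.to_csv(outdir / "gene_classification.tsv", sep="\t")
    react.to_csv(outdir / "reactivation.tsv", sep="\t", float_format="%.6g")
    n_react = int(react["is_reactivated"].sum()) if len(react) else 0
    truth_react = {g for g, r in zip(etruth.gene_ids, etruth.is_reactivated) if r}
    called_react = set(react.index[react["is_reactivated"]]) if len(react) else set()
    report["expression"] = {
        **cls.summary(),
        "n_reactivated": n_react,
        "reactivation_sensitivity": (len(truth_react & called_react) / len(truth_react)
                                     if truth_react else float("nan")),
    }

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    log.info("report written to %s", report_path)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _library_versions() -> dict:
    import scipy
    return {"xi_origami": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
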