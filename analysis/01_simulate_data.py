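"""Generate the synthetic study datasets used by the downstream analyses.

Writes, for each Xi regime, an allele-tagged contact matrix (sparse TSV with
a truth sidecar), a compartment-following coverage track (bedGraph), and an
allelic count table (TSV) for the 2-genotype x 2-treatment x 2-clone design.
"""

import argparse
import json
from pathlib import Path

import xi_origami as xo
from xi_origami.genomics_io import write_bedgraph, write_sparse_matrix


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--length-bp", type=int, default=60_000_000)
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    for k, regime in enumerate(["WT_Xi", "SMCHD1_KO", "XIST_KO", "Xa"]):
        truth = xo.make_architecture_truth(
            regime, chrom_length_bp=args.length_bp, bin_size_bp=100_000,
            n_compartments=10, read_depth=3_000_000, seed=args.seed + k,
            megadomain_boundary_bp=args.length_bp * 27 // 60)
        mat = xo.simulate_contact_matrix(truth)
        write_sparse_matrix(mat.values, out / f"{regime}.matrix.tsv")
        sidecar = {
            "regime": regime,
            "compartment_labels": truth.compartment_labels.tolist(),
            "unmappable_bins": truth.unmappable_bins.nonzero()[0].tolist(),
            "megadomain_boundary_bp": truth.megadomain_boundary_bp,
            "seed": truth.seed,
        }
        (out / f"{regime}.truth.json").write_text(json.dumps(sidecar))
        track = xo.simulate_coverage(truth, enrichment_S1=0.5, noise_sd=0.2,
                                     seed=args.seed + 100 + k)
        write_bedgraph(track, out / f"{regime}.coverage.bedgraph")
        print(f"{regime}: {mat.n_bins} bins, "
              f"{int(mat.values.sum() / 2):,} contacts, "
              f"{truth.unmappable_bins.sum()} unmappable bins")

    etruth = xo.make_expression_truth(n_genes=200, seed=args.seed + 500)
    table, control = xo.simulate_allelic_counts(etruth)
    table.to_csv(out / "allelic_counts.tsv", sep="\t", index=False)
    control.to_csv(out / "allelic_counts.control.tsv", sep="\t", index=False)
    print(f"expression: {etruth.n_genes} genes x {table['sample_id'].nunique()} samples, "
          f"{etruth.is_reactivated.sum()} planted reactivated, "
          f"{(etruth.xci_status == 'escapee').sum()} escapees")


if __name__ == "__main__":
    main()
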