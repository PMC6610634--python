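import numpy as np
import pandas as pd
import pytest

from xi_origami import ContactMatrix, GenomeBinning


@pytest.fixture
def small_binning():
    return GenomeBinning("chrX", 2_000_000, 100_000)  # 20 bins


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_contact_matrix(n_bins=20, bin_size=100_000, seed=0, integer=False):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(1, 10, (n_bins, n_bins))
    vals = (vals + vals.T) / 2
    if integer:
        vals = np.round(vals * 10)
    binning = GenomeBinning("chrX", n_bins * bin_size, bin_size)
    return ContactMatrix(binning, vals)


def toy_allelic_tables():
    """Ten hand-built genes spanning every branch of the classification cascade.

    Expected outcomes (hand-applied cascade):
      g01 fails the activity filter (zero FPKM in one sample)
      g02 fails assessability (12 allele reads in one sample; threshold is 13)
      g03 exactly 13 reads everywhere -> assessable (inclusive), subject
      g04 miscalled SNP (10% mus in a pure-cas control, above 9.09)
      g05 control %mus 9.00, below the threshold -> subject
      g06 escapee (Xi/Xa = 11% in WT clone 1, above the strict 10%)
      g07 Xi/Xa exactly 10% -> NOT an escapee (strict >), subject
      g08 reactivated (KO_Aza mean 7% vs WT_DMSO mean 2%: 3.5-fold, p < 0.1)
      g09 fold 2.9 -> not reactivated
      g10 plain silenced subject gene
    """
    conditions = ["WT_DMSO", "WT_Aza", "KO_DMSO", "KO_Aza"]
    samples = [(f"{c}_c{k}", c, f"c{k}") for c in conditions for k in (1, 2)]
    # per-gene (mus, cas) defaults per sample; overrides below
    base = {g: (1, 99) for g in [f"g{k:02d}" for k in range(1, 11)]}
    rows = []
    for sid, cond, clone in samples:
        for gene, (mus, cas) in base.items():
            fpkm = 1.0
            if gene == "g01" and sid == "WT_Aza_c1":
                fpkm = 0.0
            if gene == "g02":
                mus, cas = (2, 10) if sid == "WT_Aza_c2" else (2, 20)  # 12 reads once
            if gene == "g03":
                mus, cas = 1, 12  # exactly 13 everywhere, ratio 0.083
            if gene == "g06":
                mus, cas = (11, 100) if sid == "WT_DMSO_c1" else (1, 99)
            if gene == "g07":
                mus, cas = 10, 100  # ratio exactly 0.10 in every WT clone
            if gene == "g08":
                mus, cas = {"WT_DMSO_c1": (2, 98), "WT_DMSO_c2": (2, 98),
                            "KO_Aza_c1": (8, 92), "KO_Aza_c2": (6, 94)}.get(sid, (2, 98))
            if gene == "g09":
                # baseline 5%, treated 14.5%: fold 2.9 misses the 3-fold bar
                mus, cas = {"WT_DMSO_c1": (5, 95), "WT_DMSO_c2": (5, 95),
                            "KO_Aza_c1": (29, 171), "KO_Aza_c2": (29, 171)}.get(sid, (5, 95))
            rows.append({"gene_id": gene, "gene_length_bp": 2000, "sample_id": sid,
                         "condition": cond, "clone": clone, "mus_reads": mus,
                         "cas_reads": cas, "fpkm": fpkm})
    table = pd.DataFrame(rows)

    ctrl_rows = []
    for k in (1, 2):
        for gene in base:
            mus, cas = 0, 100
            if gene == "g04":
                mus, cas = 10, 90   # 10.0% > 9.09 -> miscalled
            if gene == "g05":
                mus, cas = 9, 91    # 9.0% < 9.09 -> kept
            ctrl_rows.append({"gene_id": gene, "gene_length_bp": 2000,
                              "sample_id": f"pure_cas_{k}", "condition": "pure_cas",
                              "clone": f"c{k}", "mus_reads": mus, "cas_reads": cas,
                              "fpkm": 1.0})
    control = pd.DataFrame(ctrl_rows)
    return table, control
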