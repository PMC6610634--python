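"""Allele-resolved expression analysis of X-inactivation.

In the hybrid lines modelled here the inactive X (Xi) is of mus origin and
the active X (Xa) of cas origin, so the fraction of mus reads among
allele-assignable reads (%mus) is a per-gene proxy for residual or
reactivated Xi expression.  The module implements the classification
cascade applied to every X-linked gene:

  active (FPKM > 0 in all samples)
    -> allele-assessable (>= 13 allele-specific reads in all samples)
      -> miscalled-SNP filter (%mus > 9.09% in pure-cas control samples)
        -> escapee (Xi/Xa expression ratio > 10% in >= 1 WT clone)
        -> subject to XCI (the remainder)

plus the reactivation call (mean %mus under the test condition >= 3-fold
the baseline with one-sided Welch t p < 0.1), cumulative-distribution
comparisons, class-intersection tests and sample clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

TABLE_COLUMNS = [
    "gene_id", "gene_length_bp", "sample_id", "condition", "clone",
    "mus_reads", "cas_reads", "fpkm",
]

MISCALLED_PMUS_THRESHOLD = 9.09      # %mus above this in pure-cas controls
MIN_ALLELE_READS = 13                # inclusive, per sample
ESCAPEE_RATIO_THRESHOLD = 0.10       # strict >, Xi/Xa in >= 1 WT clone
REACTIVATION_FOLD = 3.0
REACTIVATION_P = 0.1


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema check: required columns, integral non-negative counts, and
    every gene present in every sample."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allelic table missing columns: {missing}")
    for col in ("mus_reads", "cas_reads"):
        vals = table[col].to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError(f"{col} must hold non-negative integers")
    counts = table.groupby("sample_id")["gene_id"].nunique()
    n_genes = table["gene_id"].nunique()
    bad = counts[counts != n_genes]
    if len(bad):
        raise ValueError(f"genes missing from samples: {list(bad.index)}")
    return table


def percent_mus(mus_reads, cas_reads):
    """%mus = 100 * mus / (mus + cas); NaN when no allele-specific reads."""
    mus = np.asarray(mus_reads, dtype=float)
    cas = np.asarray(cas_reads, dtype=float)
    tot = mus + cas
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, 100.0 * mus / tot, np.nan)
    return float(out) if out.ndim == 0 else out


def pmus_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample matrix of %mus."""
    t = table.copy()
    t["pmus"] = percent_mus(t["mus_reads"], t["cas_reads"])
    return t.pivot_table(index="gene_id", columns="sample_id", values="pmus",
                         aggfunc="first", dropna=False)


@dataclass
class GeneClassification:
    """Per-gene cascade outcome plus the %mus matrix it was computed from."""

    genes: pd.DataFrame          # index gene_id; bool flags + status + first_failed
    pmus: pd.DataFrame           # gene x sample %mus
    sample_conditions: pd.Series # sample_id -> condition

    @property
    def subject_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["status"] == "subject_to_XCI"])

    @property
    def escapees(self) -> list[str]:
        return list(self.genes.index[self.genes["status"] == "escapee"])

    def summary(self) -> dict:
        g = self.genes
        return {
            "n_genes": int(len(g)),
            "n_active": int(g["is_active"].sum()),
            "n_assessable": int(g["is_assessable"].sum()),
            "n_miscalled_snp": int(g["is_miscalled_snp"].sum()),
            "n_escapee": int((g["status"] == "escapee").sum()),
            "n_subject_to_XCI": int((g["status"] == "subject_to_XCI").sum()),
        }


def classify_genes(
    table: pd.DataFrame,
    control_table: pd.DataFrame | None,
    wt_reference_samples: Sequence[str],
) -> GeneClassification:
    """Apply the full cascade in its fixed order.

    ``control_table`` holds pure-cas background samples for the miscalled-SNP
    filter (skipped with a warning when absent); ``wt_reference_samples``
    names the WT clone samples used for the escapee Xi/Xa ratio.
    Each gene is annotated with the first filter it failed.
    """
    validate_table(table)
    genes = sorted(table["gene_id"].unique())
    idx = pd.Index(genes, name="gene_id")

    fpkm = table.pivot_table(index="gene_id", columns="sample_id", values="fpkm",
                             aggfunc="first").loc[idx]
    allele_reads = table.assign(ar=table["mus_reads"] + table["cas_reads"]).pivot_table(
        index="gene_id", columns="sample_id", values="ar", aggfunc="first").loc[idx]
    pmus = pmus_matrix(table).reindex(idx)

    is_active = (fpkm > 0).all(axis=1)
    is_assessable = is_active & (allele_reads >= MIN_ALLELE_READS).all(axis=1)

    is_miscalled = pd.Series(False, index=idx)
    if control_table is not None and len(control_table):
        ctrl_pmus = pmus_matrix(control_table)
        ctrl_pmus = ctrl_pmus.reindex(idx)
        is_miscalled = is_assessable & (ctrl_pmus > MISCALLED_PMUS_THRESHOLD).any(axis=1)
    else:
        warnings.warn("no pure-cas control samples; miscalled-SNP filter skipped")

    # Xi/Xa expression ratio from allelic counts within each WT clone
    mus = table.pivot_table(index="gene_id", columns="sample_id", values="mus_reads",
                            aggfunc="first").loc[idx]
    cas = table.pivot_table(index="gene_id", columns="sample_id", values="cas_reads",
                            aggfunc="first").loc[idx]
    missing_ref = [s for s in wt_reference_samples if s not in mus.columns]
    if missing_ref:
        raise ValueError(f"WT reference samples absent from table: {missing_ref}")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = mus[list(wt_reference_samples)] / cas[list(wt_reference_samples)]
    is_escapee = (
        is_assessable & ~is_miscalled & (ratio > ESCAPEE_RATIO_THRESHOLD).any(axis=1)
    )

    status = pd.Series("excluded", index=idx)
    status[is_escapee] = "escapee"
    status[is_assessable & ~is_miscalled & ~is_escapee] = "subject_to_XCI"

    first_failed = pd.Series("", index=idx)
    first_failed[~is_active] = "active"
    first_failed[is_active & ~is_assessable] = "assessable"
    first_failed[is_miscalled] = "miscalled_snp"

    out = pd.DataFrame({
        "is_active": is_active,
        "is_assessable": is_assessable,
        "is_miscalled_snp": is_miscalled,
        "status": status,
        "first_failed": first_failed,
    })
    conds = table.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    return GeneClassification(out, pmus, conds)


def _condition_samples(cls: GeneClassification, condition: str) -> list[str]:
    return list(cls.sample_conditions.index[cls.sample_conditions == condition])


def call_reactivated(
    cls: GeneClassification,
    baseline_condition: str = "WT_DMSO",
    test_condition: str = "KO_Aza",
    fold: float = REACTIVATION_FOLD,
    p_threshold: float = REACTIVATION_P,
) -> pd.DataFrame:
    """Reactivated = subject gene with mean %mus(test) >= fold x mean %mus(baseline)
    and one-sided Welch t p < ``p_threshold``.

    A baseline mean of exactly 0 satisfies the fold criterion whenever the
    test mean is positive.  Degenerate zero-variance groups fall back to a
    deterministic comparison of means (p = 0 or 1).
    """
    base_s = _condition_samples(cls, baseline_condition)
    test_s = _condition_samples(cls, test_condition)
    if len(base_s) < 2 or len(test_s) < 2:
        raise ValueError("need >= 2 clones per condition for the reactivation test")
    rows = []
    for gene in cls.subject_genes:
        b = cls.pmus.loc[gene, base_s].to_numpy(dtype=float)
        t = cls.pmus.loc[gene, test_s].to_numpy(dtype=float)
        b, t = b[np.isfinite(b)], t[np.isfinite(t)]
        if len(b) < 2 or len(t) < 2:
            continue
        mb, mt = b.mean(), t.mean()
        fold_ok = (mt >= fold * mb) if mb > 0 else (mt > 0)
        if b.std() == 0 and t.std() == 0:
            p = 0.0 if mt > mb else 1.0
        else:
            _, p = stats.ttest_ind(t, b, equal_var=False, alternative="greater")
        rows.append({
            "gene_id": gene, "mean_baseline": mb, "mean_test": mt,
            "fold_ok": bool(fold_ok), "p_value": float(p),
            "is_reactivated": bool(fold_ok and p < p_threshold),
        })
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["mean_baseline", "mean_test", "fold_ok", "p_value", "is_reactivated"])


def _group_mean_pmus(cls: GeneClassification, samples: Sequence[str],
                     genes: Sequence[str]) -> pd.Series:
    return cls.pmus.loc[list(genes), list(samples)].mean(axis=1)


def compare_cdp(
    cls: GeneClassification,
    group_a_samples: Sequence[str],
    group_b_samples: Sequence[str],
    paired: bool = True,
    alternative: str = "greater",
    genes: Sequence[str] | None = None,
) -> dict:
    """Cumulative-distribution comparison of per-gene mean %mus.

    %mus is averaged over each group's clones per gene (subject genes by
    default).  ``paired=True`` runs the Wilcoxon signed-rank test on
    per-gene differences (the paired analogue of the rank-sum test);
    ``alternative`` asks whether group_b exceeds group_a.  All-zero
    differences yield p = NaN by the zero-difference convention.
    Step-function (ECDF) coordinates for both groups are returned.
    """
    genes = list(genes) if genes is not None else cls.subject_genes
    a = _group_mean_pmus(cls, group_a_samples, genes)
    b = _group_mean_pmus(cls, group_b_samples, genes)
    ok = a.notna() & b.notna()
    a, b = a[ok].to_numpy(), b[ok].to_numpy()
    if paired:
        diff = b - a
        if np.all(diff == 0):
            stat, p = 0.0, float("nan")
        else:
            stat, p = stats.wilcoxon(b, a, alternative=alternative,
                                     zero_method="wilcox")
    else:
        stat, p = stats.mannwhitneyu(b, a, alternative=alternative)

    def ecdf(x):
        xs = np.sort(x)
        return xs, np.arange(1, len(xs) + 1) / len(xs)

    return {
        "statistic": float(stat), "p_value": float(p), "n_genes": int(len(a)),
        "cdp_a": ecdf(a), "cdp_b": ecdf(b),
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
    }


def class_enrichment(
    cls: GeneClassification,
    class_labels: Mapping[str, str],
    samples: Sequence[str],
    target_class: str = "I",
    alternative: str = "greater",
) -> dict:
    """Intersect an external gene-class annotation with the subject set and
    compare %mus of the target class against the rest (unpaired one-sided
    rank-sum).  Returns intersection counts alongside the test."""
    subject = cls.subject_genes
    in_class = [g for g in subject if class_labels.get(g) == target_class]
    out_class = [g for g in subject if class_labels.get(g) != target_class]
    result = {
        "n_subject": len(subject),
        "n_annotated": sum(1 for g in class_labels if class_labels[g] == target_class),
        "n_intersection": len(in_class),
        "n_other": len(out_class),
    }
    if not in_class or not out_class:
        warnings.warn("class intersection empty or degenerate; test skipped")
        result.update(statistic=float("nan"), p_value=float("nan"))
        return result
    x = _group_mean_pmus(cls, samples, in_class).dropna().to_numpy()
    y = _group_mean_pmus(cls, samples, out_class).dropna().to_numpy()
    stat, p = stats.mannwhitneyu(x, y, alternative=alternative)
    result.update(statistic=float(stat), p_value=float(p))
    return result


def cluster_samples(cls: GeneClassification, method: str = "average"):
    """Hierarchical clustering of samples on the subject-gene %mus matrix.

    Genes with any missing %mus are dropped listwise; returns the scipy
    linkage matrix and the (deterministic, sorted) sample order."""
    samples = sorted(cls.pmus.columns)
    if len(samples) < 4:
        raise ValueError("need >= 4 samples to cluster")
    mat = cls.pmus.loc[cls.subject_genes, samples].dropna(axis=0).to_numpy().T
    d = pdist(mat, metric="euclidean")
    return linkage(d, method=method), samples
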