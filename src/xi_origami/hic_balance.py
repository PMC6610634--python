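"""Contact-matrix preprocessing for allele-resolved Hi-C.

Covers the standard chain that precedes compartment analysis: mappability
masking of low-coverage bins, depth-matching by random down-sampling,
iterative correction (ICE), observed/expected normalization, and the
bin-by-bin Pearson correlation map whose leading eigenvector carries the
compartment signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome.

    ``mask[i] = True`` marks bin i unmappable: its row/column is excluded from
    every statistic.  ``allele`` distinguishes the mus (Xi), cas (Xa) and
    composite maps of a hybrid cell line.
    """

    binning: "GenomeBinning"
    values: np.ndarray
    allele: str = "comp"
    mask: np.ndarray | None = None
    balanced: bool = False
    signed: bool = False  # True for derived signal maps (residuals), not counts
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.binning.n_bins
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        with np.errstate(invalid="ignore"):
            if not self.signed and np.nanmin(self.values) < 0:
                raise ValueError("negative contact count")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("contact matrix must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins

    def total(self) -> float:
        """Total contacts: upper triangle incl. diagonal, unmasked pairs."""
        keep = ~self.mask
        sub = self.values[np.ix_(keep, keep)]
        return float(np.triu(np.nan_to_num(sub)).sum())

    def copy(self) -> "ContactMatrix":
        return replace(self, values=self.values.copy(), mask=self.mask.copy(),
                       metadata=dict(self.metadata))


@dataclass
class CorrelationMap:
    """Bin-by-bin Pearson correlation of O/E rows; NaN at masked bins."""

    binning: "GenomeBinning"
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


def mask_low_coverage(m: ContactMatrix, quantile: float = 0.14) -> ContactMatrix:
    """Mask the lowest-coverage bins (bottom ``quantile`` of marginals).

    Exactly ``ceil(quantile * n_bins)`` bins are masked, ties broken toward the
    lower bin index; all-zero bins are always masked.  Previously masked bins
    sort first, so re-masking an already-masked matrix is idempotent.
    """
    if not 0 <= quantile < 1:
        raise ValueError("quantile must lie in [0, 1)")
    out = m.copy()
    marg = np.nan_to_num(out.values).sum(axis=1)
    marg = marg.astype(float)
    marg[out.mask] = -np.inf  # keep prior masks at the bottom of the order
    # tolerance guards float artefacts (0.14 * 100 -> 14.000000000000002)
    k = int(np.ceil(quantile * out.n_bins - 1e-9))
    order = np.lexsort((np.arange(out.n_bins), marg))
    new_mask = out.mask.copy()
    new_mask[order[:k]] = True
    new_mask[marg == 0] = True
    out.mask = new_mask
    out.metadata["mask_quantile"] = quantile
    return out


def downsample(m: ContactMatrix, target_total: int, seed: int) -> ContactMatrix:
    """Down-sample contacts without replacement to an exact total.

    Individual contacts are drawn by a multivariate hypergeometric over the
    upper-triangle cells, so the expected per-cell count is proportional to
    the input and the post-total is exactly ``target_total``.
    """
    vals = np.nan_to_num(m.values)
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("downsampling requires integer counts")
    n = m.n_bins
    iu, ju = np.triu_indices(n)
    cell = np.round(vals[iu, ju]).astype(np.int64)
    total = int(cell.sum())
    if target_total > total:
        raise ValueError(f"target_total {target_total} exceeds matrix total {total}")
    rng = np.random.default_rng(seed)
    kept = rng.multivariate_hypergeometric(cell, target_total, method="marginals")
    out = m.copy()
    new = np.zeros_like(vals)
    new[iu, ju] = kept
    new = new + new.T - np.diag(np.diag(new))
    out.values = new
    out.metadata.update(downsample_seed=seed, downsample_target=target_total)
    return out


def match_depth(matrices: list[ContactMatrix], seed: int) -> list[ContactMatrix]:
    """Down-sample every matrix in a comparison to the minimum total."""
    target = int(min(mm.total() for mm in matrices))
    return [downsample(mm, target, seed + k) for k, mm in enumerate(matrices)]


def ice_balance(m: ContactMatrix, max_iter: int = 200, tol: float = 1e-6) -> ContactMatrix:
    """Iterative correction: equalize unmasked row sums (Imakaev-style).

    Iterates ``W <- W / (s_i s_j)`` with ``s`` the marginals scaled to unit
    mean, until the coefficient of variation of the unmasked marginals drops
    below ``tol``.  The result is rescaled so the mean of unmasked entries is
    preserved; the convergence iteration count lands in ``metadata``.
    """
    keep = ~m.mask
    if not keep.any():
        raise ValueError("fully masked matrix cannot be balanced")
    sub = np.nan_to_num(m.values[np.ix_(keep, keep)]).astype(float)
    mean_before = sub.mean()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        marg = sub.sum(axis=1)
        nz = marg > 0
        if not nz.any():
            break
        cv = marg[nz].std() / marg[nz].mean()
        if cv < tol:
            converged = True
            break
        s = np.ones_like(marg)
        s[nz] = marg[nz] / marg[nz].mean()
        sub /= np.outer(s, s)
    if not converged:
        marg = sub.sum(axis=1)
        nz = marg > 0
        cv = marg[nz].std() / marg[nz].mean() if nz.any() else np.nan
        if not (cv < tol):
            warnings.warn(f"ICE did not converge in {max_iter} iterations (CV={cv:.2e})")
    if sub.mean() > 0:
        sub *= mean_before / sub.mean()
    out = m.copy()
    out.values = np.full_like(m.values, np.nan)
    out.values[np.ix_(keep, keep)] = sub
    out.balanced = True
    out.metadata.update(ice_iterations=n_iter, ice_converged=converged)
    return out


def observed_over_expected(m: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean of its diagonal over unmasked pairs."""
    keep = ~m.mask
    n = m.n_bins
    vals = m.values.copy()
    oe = np.full_like(vals, np.nan)
    keep2 = np.outer(keep, keep)
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    valid = keep2 & np.isfinite(vals)
    # per-diagonal means over unmasked pairs
    expected = np.full(n, np.nan)
    flat_d = dist[valid]
    flat_v = vals[valid]
    sums = np.bincount(flat_d, weights=flat_v, minlength=n)
    counts = np.bincount(flat_d, minlength=n)
    nz = counts > 0
    expected[nz] = sums[nz] / counts[nz]
    exp_mat = expected[dist]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(valid & (exp_mat > 0), vals / exp_mat, np.nan)
    out = m.copy()
    out.values = oe
    out.metadata["normalization"] = "observed_over_expected"
    return out


def pearson_residuals(m: ContactMatrix) -> ContactMatrix:
    """Variance-stabilized residual map: (observed - expected) / sqrt(expected).

    ``expected`` is the per-diagonal mean over unmasked pairs of a balanced
    matrix.  Unlike the raw O/E ratio — whose sampling noise explodes at
    long range where expected counts fall below one — the Pearson residual
    has roughly unit variance at every distance, so the downstream
    correlation map weights each distance by its information content.
    """
    keep = ~m.mask
    n = m.n_bins
    vals = m.values
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    valid = np.outer(keep, keep) & np.isfinite(vals)
    sums = np.bincount(dist[valid], weights=vals[valid], minlength=n)
    counts = np.bincount(dist[valid], minlength=n)
    expected = np.full(n, np.nan)
    nz = counts > 0
    expected[nz] = sums[nz] / counts[nz]
    exp_mat = expected[dist]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = np.where(valid & (exp_mat > 0), (vals - exp_mat) / np.sqrt(exp_mat),
                       np.nan)
    out = m.copy()
    out.values = res
    out.signed = True
    out.metadata["normalization"] = "pearson_residual"
    return out


def _pearson_excluding_self(X: np.ndarray, min_pairs: int = 3) -> np.ndarray:
    """All-pairs Pearson of rows of X with pairwise NaN deletion, excluding
    columns i and j for pair (i, j).

    Built from matrix products of the value and finite-indicator matrices,
    with closed-form downdates for the two self-columns; O(m^2) memory and a
    handful of BLAS calls, no Python loops.
    """
    m = X.shape[0]
    F = np.isfinite(X)
    Xf = np.where(F, X, 0.0)
    Ff = F.astype(float)
    X2 = Xf * Xf

    n_ij = Ff @ Ff.T
    Sx = Xf @ Ff.T          # sum of x over columns finite in both rows
    Sy = Sx.T
    Sxx = X2 @ Ff.T
    Syy = Sxx.T
    Sxy = Xf @ Xf.T

    # downdate the k = i and k = j columns (when finite in both rows)
    d = np.diag(Xf)
    fd = np.diag(F)
    mask_i = (fd[:, None] & F.T).astype(float)   # column k = i present
    mask_j = (F & fd[None, :]).astype(float)     # column k = j present
    n_ij = n_ij - mask_i - mask_j
    Sx = Sx - d[:, None] * mask_i - Xf * mask_j
    Sy = Sy - Xf.T * mask_i - d[None, :] * mask_j
    Sxx = Sxx - (d ** 2)[:, None] * mask_i - X2 * mask_j
    Syy = Syy - (Xf.T ** 2) * mask_i - (d ** 2)[None, :] * mask_j
    Sxy = Sxy - d[:, None] * Xf.T * mask_i - Xf * d[None, :] * mask_j

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sy / n_ij
        var_i = Sxx - Sx ** 2 / n_ij
        var_j = Syy - Sy ** 2 / n_ij
        corr = cov / np.sqrt(var_i * var_j)
    # numeric floor: variances are sums of squares, tiny negatives are noise
    bad = (n_ij < min_pairs) | (var_i <= 1e-12 * np.maximum(Sxx, 1e-300)) | (
        var_j <= 1e-12 * np.maximum(Syy, 1e-300))
    corr[bad] = np.nan
    corr[~np.isfinite(corr)] = np.nan
    # diagonal: 1 where the row has any variance, NaN for constant rows
    row_n = Ff.sum(axis=1)
    row_mean = np.divide(Xf.sum(axis=1), row_n, out=np.zeros(m), where=row_n > 0)
    row_var = np.divide((X2).sum(axis=1), row_n, out=np.zeros(m),
                        where=row_n > 0) - row_mean ** 2
    const = row_var <= 1e-300
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    corr[np.diag_indices(m)] = np.where(const, np.nan, 1.0)
    return np.clip(corr, -1.0, 1.0)


def pearson_map(oe: ContactMatrix, min_pairs: int = 3) -> CorrelationMap:
    """Pearson correlation of O/E rows for every unmasked bin pair.

    The two self-columns (i and j) are excluded from each pairwise
    correlation; NaN entries in the O/E matrix are pairwise-deleted.
    Constant rows and pairs with fewer than ``min_pairs`` complete
    observations yield NaN.
    """
    keep = ~oe.mask
    sub = oe.values[np.ix_(keep, keep)]
    mm = sub.shape[0]
    if mm < min_pairs + 2:
        out_sub = np.full((mm, mm), np.nan)
    else:
        out_sub = _pearson_excluding_self(sub, min_pairs=min_pairs)
    n = oe.n_bins
    full = np.full((n, n), np.nan)
    full[np.ix_(keep, keep)] = out_sub
    return CorrelationMap(oe.binning, full, oe.mask.copy())
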