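"""Coverage-track arithmetic for CHART/ChIP-style signal comparison.

Implements the windowed smoothing, chromosome-sum-equalized scaling,
difference (delta) tracks, per-region and per-bin densities, the S1-vs-S2
enrichment test, and peak-summit-centered metaprofiles used to relate
Xist/H3K27me3/H2AK119ub coverage to compartment structure.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import stats

from .compartments import CompartmentSegments
from .genomics_io import BinnedSignal, CoverageTrack, GenomeBinning, Region


def fpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale so the total signal mass is 1e6 (fragments-per-million analogue)."""
    mass = float((track.values * (track.ends - track.starts)).sum())
    if mass <= 0:
        raise ValueError("cannot fpm-normalize a track with zero total signal")
    return CoverageTrack(track.chrom, track.starts.copy(), track.ends.copy(),
                         track.values * 1e6 / mass, normalization="fpm")


def smooth_windows(
    track: CoverageTrack,
    chrom_length_bp: int,
    window_bp: int = 1000,
    step_bp: int = 500,
) -> CoverageTrack:
    """Sliding-window mean recorded at fixed steps.

    Each output interval ``[k*step, (k+1)*step)`` carries the mean signal over
    the ``window_bp`` window centered on the interval midpoint, clipped at
    chromosome ends (the mean divides by the clipped width).
    """
    if window_bp < step_bp:
        raise ValueError("window must be >= step")
    n_steps = -(-chrom_length_bp // step_bp)
    anchors = np.arange(n_steps) * step_bp + step_bp / 2
    lo = np.clip(anchors - window_bp / 2, 0, chrom_length_bp)
    hi = np.clip(anchors + window_bp / 2, 0, chrom_length_bp)
    sums = track.integrals(lo, hi)
    vals = sums / np.maximum(hi - lo, 1e-12)
    starts = np.arange(n_steps, dtype=np.int64) * step_bp
    ends = np.minimum(starts + step_bp, chrom_length_bp)
    return CoverageTrack(track.chrom, starts, ends, vals, normalization=track.normalization)


def input_subtract(ip: CoverageTrack, inp: CoverageTrack, chrom_length_bp: int,
                   window_bp: int = 1000, step_bp: int = 500) -> CoverageTrack:
    """Windowed IP-minus-input at matched fpm normalization.

    A simple, documented windowed difference: both tracks are fpm-normalized,
    smoothed with the same window/step, then subtracted pointwise.
    """
    a = smooth_windows(fpm_normalize(ip), chrom_length_bp, window_bp, step_bp)
    b = smooth_windows(fpm_normalize(inp), chrom_length_bp, window_bp, step_bp)
    out = delta_track(a, b)
    return CoverageTrack(out.chrom, out.starts, out.ends, out.values,
                         normalization="input_subtracted")


def scale_to_reference(
    target: CoverageTrack, reference: CoverageTrack, region: Region
) -> CoverageTrack:
    """Multiply ``target`` so its integral over ``region`` matches the reference.

    The chromosome-sum-equalization step: two tracks representing the same
    underlying amount of signal (e.g. Xist coverage in two genotypes
    expressing Xist equally) are made quantitatively comparable.
    """
    t_sum = target.integral(region.start_bp, region.end_bp)
    r_sum = reference.integral(region.start_bp, region.end_bp)
    if t_sum == 0:
        raise ValueError("target track has zero signal over the scaling region")
    factor = r_sum / t_sum
    return CoverageTrack(target.chrom, target.starts.copy(), target.ends.copy(),
                         target.values * factor, normalization="scaled")


def delta_track(a: CoverageTrack, b: CoverageTrack) -> CoverageTrack:
    """Pointwise a - b over the union of both tracks' breakpoints."""
    if a.chrom != b.chrom:
        raise ValueError("delta requires tracks on the same chromosome")
    cuts = np.unique(np.concatenate([a.starts, a.ends, b.starts, b.ends]))
    if len(cuts) < 2:
        return CoverageTrack(a.chrom, np.array([], dtype=np.int64),
                             np.array([], dtype=np.int64), np.array([]))
    starts, ends = cuts[:-1], cuts[1:]
    vals = a.value_at(starts) - b.value_at(starts)
    keep = vals != 0.0
    # keep zero-valued segments too when they sit inside covered spans; simplest
    # faithful representation keeps every segment
    return CoverageTrack(a.chrom, starts, ends, vals)


def region_density(track: CoverageTrack, regions: list[Region]) -> np.ndarray:
    """Mean signal per bp over each region."""
    starts = np.array([r.start_bp for r in regions], dtype=float)
    ends = np.array([r.end_bp for r in regions], dtype=float)
    sums = track.integrals(starts, ends)
    return sums / (ends - starts)


def _boxplot_stats(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min() if len(x) else np.nan
    hi = x[x <= q3 + 1.5 * iqr].max() if len(x) else np.nan
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(lo), "whisker_high": float(hi), "n": int(len(x))}


def s1s2_density_test(
    delta: BinnedSignal,
    segments: CompartmentSegments,
    alternative: str = "greater",
) -> dict:
    """Rank-sum comparison of per-bin delta densities in S1 vs S2 compartments.

    Bins are partitioned by compartment sign (positive = S1 by the display
    convention); the unpaired one-sided Wilcoxon rank-sum asks whether S1
    bins carry higher delta signal.  Box-plot summaries (median, quartiles,
    1.5*IQR whiskers) are returned for both groups.
    """
    if delta.binning.n_bins != segments.binning.n_bins:
        raise ValueError("delta binning must match the segments' resolution")
    labels = segments.labels()
    vals = delta.values
    ok = np.isfinite(vals) & ~delta.mask & (labels != 0)
    s1 = vals[ok & (labels > 0)]
    s2 = vals[ok & (labels < 0)]
    if len(s1) == 0 or len(s2) == 0:
        warnings.warn("all bins in one compartment; S1/S2 test skipped")
        return {"statistic": float("nan"), "p_value": float("nan"),
                "n_s1": int(len(s1)), "n_s2": int(len(s2))}
    stat, p = stats.mannwhitneyu(s1, s2, alternative=alternative)
    return {
        "statistic": float(stat), "p_value": float(p),
        "n_s1": int(len(s1)), "n_s2": int(len(s2)),
        "s1": _boxplot_stats(s1), "s2": _boxplot_stats(s2),
        "s1_values": s1, "s2_values": s2,
    }


def summit_metaprofile(
    tracks: list[CoverageTrack],
    summits: list[Region],
    chrom_length_bp: int,
    flank_bp: int = 10_000,
    step_bp: int = 100,
) -> dict:
    """Signal around peak summits, averaged across summits.

    Each summit (a single-point region; its start is the summit position)
    contributes the mean signal in consecutive ``step_bp`` windows over
    ``[-flank, +flank)``.  Summits within ``flank_bp`` of a chromosome end
    are dropped (count reported).  Strand is ignored.
    """
    n_steps = 2 * flank_bp // step_bp
    offsets = -flank_bp + np.arange(n_steps) * step_bp
    kept, dropped = [], 0
    for s in summits:
        c = s.start_bp
        if c - flank_bp < 0 or c + flank_bp > chrom_length_bp:
            dropped += 1
        else:
            kept.append(c)
    per_track = {}
    for t_i, track in enumerate(tracks):
        mat = np.empty((len(kept), n_steps))
        for r, c in enumerate(kept):
            los = c + offsets
            mat[r] = track.integrals(los, los + step_bp) / step_bp
        per_track[t_i] = mat
    mean_curves = {k: (m.mean(axis=0) if len(m) else np.full(n_steps, np.nan))
                   for k, m in per_track.items()}
    return {
        "offsets_bp": offsets, "profiles": per_track, "mean_curves": mean_curves,
        "n_summits_used": len(kept), "n_summits_dropped": dropped,
    }
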