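"""Genomic binning, coordinate conventions, and text-format I/O.

All coordinates in this package are 0-based, half-open (BED convention).
Contact matrices travel as sparse upper-triangular TSV (``bin1  bin2  count``),
coverage as bedGraph, regions as BED3/BED6; every reader is gzip-transparent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width partition of one chromosome into bins.

    Bin ``i`` covers ``[i*bin_size_bp, min((i+1)*bin_size_bp, chrom_length_bp))``;
    the last bin may be short.
    """

    chrom_name: str
    chrom_length_bp: int
    bin_size_bp: int

    def __post_init__(self) -> None:
        if self.chrom_length_bp < 1:
            raise ValueError("chrom_length_bp must be >= 1")
        if self.bin_size_bp < 1:
            raise ValueError("bin_size_bp must be >= 1")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length_bp // self.bin_size_bp)

    def bin_of(self, bp: int | np.ndarray) -> int | np.ndarray:
        """Map base-pair position(s) to bin index; total and deterministic."""
        bp = np.asarray(bp)
        if np.any(bp < 0) or np.any(bp >= self.chrom_length_bp):
            raise ValueError("position outside chromosome")
        out = bp // self.bin_size_bp
        return int(out) if out.ndim == 0 else out.astype(np.int64)

    def bin_start(self, i: int | np.ndarray) -> int | np.ndarray:
        return np.asarray(i) * self.bin_size_bp if np.ndim(i) else i * self.bin_size_bp

    def bin_end(self, i: int) -> int:
        return min((i + 1) * self.bin_size_bp, self.chrom_length_bp)

    def bin_mid(self, i: int | np.ndarray):
        """Midpoint (bp) of bin i, used for distance computations."""
        return (np.asarray(i) * self.bin_size_bp * 2 + self.bin_size_bp) // 2


@dataclass
class Region:
    """A 0-based half-open genomic interval with optional annotation."""

    chrom: str
    start_bp: int
    end_bp: int
    name: str = "."
    strand: str = "."
    category: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp < 0:
            raise ValueError(f"negative start for region {self.name!r}")
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"region {self.name!r}: end ({self.end_bp}) must exceed start ({self.start_bp})"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class CoverageTrack:
    """Piecewise-constant signal over sorted, non-overlapping intervals.

    ``starts``/``ends``/``values`` are parallel arrays; bases not covered by
    any interval read as 0.  ``normalization`` is a provenance tag only.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts/ends/values length mismatch")
        if len(self.starts):
            if np.any(self.ends <= self.starts):
                raise ValueError("empty or inverted interval")
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise ValueError("overlapping or unsorted intervals")
            if not np.all(np.isfinite(self.values)):
                raise ValueError("non-finite coverage value")

    def __len__(self) -> int:
        return len(self.starts)

    def value_at(self, bp: np.ndarray) -> np.ndarray:
        """Signal value at each base position (vectorized; 0 where uncovered)."""
        bp = np.asarray(bp, dtype=np.int64)
        if len(self.starts) == 0:
            return np.zeros(len(bp), dtype=float)
        idx = np.searchsorted(self.starts, bp, side="right") - 1
        ok = (idx >= 0) & (bp < self.ends[np.clip(idx, 0, None)])
        out = np.zeros(len(bp), dtype=float)
        out[ok] = self.values[idx[ok]]
        return out

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints and the running integral of the signal at each breakpoint.

        Returns (pos, integ) with integ[k] = ∫ signal over [0, pos[k]).
        Suitable for O(log n) window sums via interpolation.
        """
        areas = self.values * (self.ends - self.starts)
        uniq = np.unique(np.concatenate([self.starts, self.ends]))
        end_idx = np.searchsorted(self.ends, uniq, side="right")
        full = np.concatenate([[0.0], np.cumsum(areas)])[end_idx]
        cover = np.searchsorted(self.starts, uniq, side="right") - 1
        partial = np.zeros(len(uniq))
        ok = (cover >= 0) & (cover >= end_idx)  # interval started but not ended
        partial[ok] = self.values[cover[ok]] * (uniq[ok] - self.starts[cover[ok]])
        return uniq, full + partial

    def integral(self, start_bp: float, end_bp: float) -> float:
        """∫ signal over [start_bp, end_bp)."""
        return float(self.integrals(np.array([start_bp]), np.array([end_bp]))[0])

    def integrals(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        pos, integ = self.cumulative()
        if len(pos) == 0:
            return np.zeros(len(starts))
        def interp(x):
            return np.interp(x, pos, integ, left=0.0, right=integ[-1])
        return interp(np.asarray(ends, float)) - interp(np.asarray(starts, float))


@dataclass
class BinnedSignal:
    """Per-bin summary (length-weighted mean) of a coverage track."""

    binning: GenomeBinning
    values: np.ndarray
    mask: np.ndarray | None = None  # True = excluded bin

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.binning.n_bins:
            raise ValueError("values length must equal n_bins")
        if self.mask is None:
            self.mask = np.zeros(self.binning.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def read_sparse_matrix(path, binning: GenomeBinning) -> np.ndarray:
    """Read (bin_i, bin_j, count) triples into a dense symmetric matrix.

    Upper-triangle or full input is accepted; the matrix is symmetrized on
    read so each off-diagonal triple contributes once to the total
    (``total = sum of input counts`` with the diagonal counted once).
    """
    n = binning.n_bins
    mat = np.zeros((n, n), dtype=float)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            fields = s.split()
            if fields[0] in ("bin1", "bin_i"):  # optional header
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            i, j = int(fields[0]), int(fields[1])
            c = float(fields[2])
            if i < 0 or j < 0 or i >= n or j >= n:
                raise ValueError(f"{path}:{lineno}: bin index out of range: {s!r}")
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count: {s!r}")
            if i == j:
                mat[i, i] += c
            else:
                mat[i, j] += c
                mat[j, i] += c
    return mat


def write_sparse_matrix(mat: np.ndarray, path) -> None:
    """Write the upper triangle (incl. diagonal) of a symmetric matrix as TSV."""
    iu, ju = np.nonzero(np.triu(mat))
    with _open_text(path, "wt") as fh:
        fh.write("bin1\tbin2\tcount\n")
        for i, j in zip(iu, ju):
            v = mat[i, j]
            fh.write(f"{i}\t{j}\t{v:.17g}\n")


def read_bedgraph(path, chrom: str | None = None) -> CoverageTrack:
    """Read a bedGraph file into a CoverageTrack (one chromosome)."""
    starts, ends, values = [], [], []
    seen_chrom = chrom
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line: {s!r}")
            c, a, b, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom is not None and c != chrom:
                continue
            if seen_chrom is None:
                seen_chrom = c
            elif c != seen_chrom:
                raise ValueError(
                    f"{path}:{lineno}: multiple chromosomes in track ({seen_chrom}, {c});"
                    " pass chrom= to select one"
                )
            starts.append(a)
            ends.append(b)
            values.append(v)
    if starts:
        order = np.argsort(starts, kind="stable")
        starts = np.asarray(starts)[order]
        ends = np.asarray(ends)[order]
        values = np.asarray(values)[order]
        if np.any(np.asarray(starts)[1:] < np.asarray(ends)[:-1]):
            raise ValueError(f"{path}: overlapping bedGraph intervals")
    return CoverageTrack(seen_chrom or "unknown", np.asarray(starts, dtype=np.int64),
                         np.asarray(ends, dtype=np.int64), np.asarray(values, dtype=float))


def write_bedgraph(track: CoverageTrack, path) -> None:
    with _open_text(path, "wt") as fh:
        for a, b, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.chrom}\t{a}\t{b}\t{v:.17g}\n")


def read_bed(path) -> list[Region]:
    """Read BED3/BED6 into Regions (coordinates preserved verbatim)."""
    out: list[Region] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, a, b = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(Region(chrom, a, b, name=name, strand=strand))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    return out


def write_bed(regions: Sequence[Region], path, scores: Sequence[float] | None = None) -> None:
    with _open_text(path, "wt") as fh:
        for k, r in enumerate(regions):
            score = 0.0 if scores is None else scores[k]
            fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.name}\t{score:g}\t{r.strand}\n")


def bin_track(track: CoverageTrack, binning: GenomeBinning) -> BinnedSignal:
    """Length-weighted mean of a coverage track per bin (resolution-independent)."""
    n = binning.n_bins
    edges = np.minimum(np.arange(n + 1) * binning.bin_size_bp, binning.chrom_length_bp)
    sums = track.integrals(edges[:-1], edges[1:])
    lengths = np.maximum(edges[1:] - edges[:-1], 1)
    return BinnedSignal(binning, sums / lengths)
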