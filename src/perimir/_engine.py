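"""Vectorized interval arithmetic on a linearized genome.

Chromosomes are concatenated onto one coordinate axis (each chromosome at a
fixed offset). Because no feature or domain may span a chromosome boundary,
overlap and membership queries reduce to searchsorted/interp operations on
two sorted arrays, which makes thousand-fold permutation loops cheap.

Internal module: the public interval API lives in :mod:`perimir.intervals`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .intervals import GenomeAssembly, GenomicInterval


class LinearGenome:
    """Mapping between (chrom, pos) coordinates and one linear axis."""

    def __init__(self, assembly: GenomeAssembly):
        self.assembly = assembly
        self.chroms = list(assembly.chrom_lengths)
        self.lengths = np.array([assembly.chrom_lengths[c] for c in self.chroms], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)[:-1]])
        self.size = int(self.lengths.sum())
        self._index = {c: i for i, c in enumerate(self.chroms)}

    def to_linear(
        self, intervals: Sequence[GenomicInterval]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Linear (start, end) arrays, in input order."""
        starts = np.empty(len(intervals), dtype=np.int64)
        ends = np.empty(len(intervals), dtype=np.int64)
        for i, iv in enumerate(intervals):
            off = self.offsets[self._index[iv.chrom]]
            starts[i] = off + iv.start
            ends[i] = off + iv.end
        return starts, ends

    def from_linear(self, starts: np.ndarray, ends: np.ndarray) -> list[GenomicInterval]:
        chrom_idx = np.searchsorted(self.offsets, starts, side="right") - 1
        out = []
        for s, e, ci in zip(starts, ends, chrom_idx):
            off = self.offsets[ci]
            out.append(GenomicInterval(self.chroms[ci], int(s - off), int(e - off)))
        return out


class CoverageIndex:
    """Sorted, merged linear intervals supporting vectorized queries."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        if starts.size and np.any(starts[1:] < ends[:-1]):
            raise ValueError("CoverageIndex requires merged (non-overlapping) intervals")
        self.starts = starts
        self.ends = ends
        # piecewise-linear cumulative coverage: covered bp strictly below x
        pts = np.empty(2 * starts.size, dtype=np.float64)
        pts[0::2], pts[1::2] = starts, ends
        cum = np.zeros_like(pts)
        lens = (ends - starts).astype(np.float64)
        csum = np.cumsum(lens)
        cum[1::2] = csum
        cum[2::2] = csum[:-1]
        self._pts, self._cum = pts, cum
        self.total_bp = int(csum[-1]) if starts.size else 0

    def cum_coverage(self, x: np.ndarray) -> np.ndarray:
        """Covered bp in [0, x)."""
        if self.starts.size == 0:
            return np.zeros_like(np.asarray(x, dtype=np.float64))
        return np.interp(x, self._pts, self._cum, left=0.0, right=float(self.total_bp))

    def overlap_with(self, qstarts: np.ndarray, qends: np.ndarray) -> np.ndarray:
        """Per-query covered bp; exact for non-overlapping queries."""
        return self.cum_coverage(qends) - self.cum_coverage(qstarts)

    def any_overlap(self, qstarts: np.ndarray, qends: np.ndarray) -> np.ndarray:
        """Boolean: does each query share >=1 bp with the covered set?"""
        if self.starts.size == 0:
            return np.zeros(np.shape(qstarts), dtype=bool)
        idx = np.searchsorted(self.starts, qends, side="left")
        hit = idx > 0
        prev_end = self.ends[np.maximum(idx - 1, 0)]
        return hit & (prev_end > qstarts)

    def midpoint_inside(self, qstarts: np.ndarray, qends: np.ndarray) -> np.ndarray:
        mids = (np.asarray(qstarts) + np.asarray(qends)) / 2
        if self.starts.size == 0:
            return np.zeros(mids.shape, dtype=bool)
        idx = np.searchsorted(self.starts, mids, side="right")
        inside = idx > 0
        prev_end = self.ends[np.maximum(idx - 1, 0)]
        return inside & (mids < prev_end)


def union_overlap_rows(
    starts: np.ndarray, lengths: np.ndarray, cov: CoverageIndex
) -> np.ndarray:
    """Overlap bp between the union of row intervals and a coverage index.

    ``starts`` has shape (n_rows, n_intervals); ``lengths`` broadcasts to it.
    Row intervals may overlap each other; each row is union-ed first so the
    result matches set intersection of merged interval files.
    """
    full_lengths = np.broadcast_to(np.asarray(lengths), starts.shape)
    order = np.argsort(starts, axis=1, kind="stable")
    s = np.take_along_axis(starts, order, axis=1)
    e = s + np.take_along_axis(full_lengths, order, axis=1)
    run_end = np.maximum.accumulate(e, axis=1)
    eff_start = s.copy()
    eff_start[:, 1:] = np.maximum(s[:, 1:], run_end[:, :-1])
    contrib = cov.cum_coverage(e) - cov.cum_coverage(np.minimum(eff_start, e))
    return np.maximum(contrib, 0.0).sum(axis=1)


def union_length_rows(starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Union bp of each row's intervals (rows of (start, start+length))."""
    full_lengths = np.broadcast_to(np.asarray(lengths), starts.shape)
    order = np.argsort(starts, axis=1, kind="stable")
    s = np.take_along_axis(starts, order, axis=1)
    e = s + np.take_along_axis(full_lengths, order, axis=1)
    run_end = np.maximum.accumulate(e, axis=1)
    eff_start = s.copy()
    eff_start[:, 1:] = np.maximum(s[:, 1:], run_end[:, :-1])
    return np.maximum(e - eff_start, 0).sum(axis=1)
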