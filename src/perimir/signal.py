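"""Expression evidence over gene loci: track aggregation and gene classes.

Mean aggregate scores of bedGraph-style signal tracks (e.g. GRO-seq
exported from bigWig) over locus coordinates, and the constitutive /
tissue-specific gene classification rules applied to RPKM-style
gene-by-tissue expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, normalize_chrom

__all__ = ["SignalTrack", "aggregate_score", "ExpressionMatrix", "classify_genes"]


class SignalTrack:
    """A bedGraph-semantics signal: per-chromosome (start, end, value) steps.

    Intervals within a chromosome must be non-overlapping; uncovered bases
    implicitly score 0.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(frame.columns):
            raise ValueError(f"track frame needs columns {sorted(required)}")
        if not np.isfinite(frame["value"]).all():
            raise ValueError("track values must be finite")
        frame = frame.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any(starts >= ends):
                raise ValueError(f"{chrom}: empty or inverted track interval")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping track intervals")
            self._per_chrom[str(chrom)] = (starts, ends, sub["value"].to_numpy(dtype=float))

    @classmethod
    def read_bedgraph(cls, path: str | Path) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"], dtype=str,
        )
        df = df[~df["chrom"].str.startswith(("track", "browser"))].copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        return cls(df)

    def chrom_arrays(self, chrom: str):
        return self._per_chrom.get(chrom)


def aggregate_score(track: SignalTrack, locus: GenomicInterval) -> float:
    """Length-weighted mean track value over the locus span.

    Uncovered bases contribute 0; a locus on a chromosome absent from the
    track scores 0.
    """
    if len(locus) == 0:
        raise ValueError("zero-length locus")
    arrays = track.chrom_arrays(locus.chrom)
    if arrays is None:
        return 0.0
    starts, ends, values = arrays
    lo = np.searchsorted(ends, locus.start, side="right")
    hi = np.searchsorted(starts, locus.end, side="left")
    if hi <= lo:
        return 0.0
    seg_start = np.maximum(starts[lo:hi], locus.start)
    seg_end = np.minimum(ends[lo:hi], locus.end)
    weights = np.maximum(seg_end - seg_start, 0)
    return float((weights * values[lo:hi]).sum() / len(locus))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x tissue normalized expression (RPKM semantics).

    ``high`` is an optional boolean gene x tissue indicator of
    "highly expressed" calls (e.g. imported from an expression atlas); when
    absent it can be derived from values by a per-tissue quantile cutoff.
    """

    values: pd.DataFrame
    high: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.high is not None and (
            not self.high.index.equals(self.values.index)
            or not self.high.columns.equals(self.values.columns)
        ):
            raise ValueError("high-indicator matrix must align with values")

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]


RULE_TISSUES = {"human32": 32, "mouse6": 6}


def classify_genes(
    matrix: ExpressionMatrix,
    species_rule: str,
    high_quantile: float = 0.5,
) -> pd.Series:
    """Label each gene constitutive / tissue_specific / neither.

    human32 (32 tissues): a gene highly expressed in >= 80% of tissues is
    constitutive; in < 10%, tissue_specific; otherwise neither. The
    high/low indicator is taken from ``matrix.high`` when given, else a
    gene is "high" in a tissue when its value reaches that tissue's
    ``high_quantile`` quantile (default: top half) — a configurable
    stand-in for external atlas calls.

    mouse6 (6 tissues): genes in the top decile of every tissue's
    expression ranking (ties at the cutoff included) are constitutive; no
    tissue-specific call is made.
    """
    if species_rule not in RULE_TISSUES:
        raise ValueError(f"unknown rule {species_rule!r}")
    expected = RULE_TISSUES[species_rule]
    if matrix.n_tissues != expected:
        raise ValueError(
            f"{species_rule} requires {expected} tissue columns, got {matrix.n_tissues}"
        )
    values = matrix.values
    if species_rule == "human32":
        if matrix.high is not None:
            high = matrix.high.astype(bool)
        else:
            cutoffs = values.quantile(high_quantile, axis=0)
            high = values.ge(cutoffs, axis=1)
        frac = high.sum(axis=1) / expected
        labels = pd.Series("neither", index=values.index, name="label")
        labels[frac >= 0.8] = "constitutive"
        labels[frac < 0.1] = "tissue_specific"
        return labels
    # mouse6: top decile per tissue, in all tissues
    cutoffs = values.quantile(0.9, axis=0)
    top = values.ge(cutoffs, axis=1)
    labels = pd.Series("neither", index=values.index, name="label")
    labels[top.all(axis=1)] = "constitutive"
    return labels
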