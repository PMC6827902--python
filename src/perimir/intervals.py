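"""Genomic interval data model and standard-format I/O.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
GFF3 input (1-based, closed) is converted at read time. Chromosome names
are normalized to the ``chr`` prefix so that DamID-derived BED files and
miRBase GFF3 annotations can be intersected directly. Strand is carried
but ignored by all overlap computations: lamina-associated domains (LADs)
are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyranges as pr

__all__ = [
    "GenomicInterval",
    "GenomeAssembly",
    "DomainSet",
    "read_bed",
    "read_chrom_sizes",
    "read_gff3_features",
    "write_bed",
    "merge_intervals",
    "overlap_bp",
    "union_bp",
    "features_overlapping",
    "complement",
]


class BedParseError(ValueError):
    """A malformed record in a BED/GFF/chrom.sizes file."""


def normalize_chrom(name: str) -> str:
    """Normalize chromosome dialects ('1' vs 'chr1') to the 'chr' prefix."""
    name = name.strip()
    if not name:
        raise BedParseError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open chromosomal span ``[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name ('chr' prefix).
    start, end : int
        0-based half-open coordinates; ``0 <= start < end``.
    name : str, optional
        Feature identifier (e.g. a miRBase pre-miRNA name).
    strand : str, optional
        One of ``+ - .``; ignored by overlap computations.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class GenomeAssembly:
    """A genome universe: chromosome name -> length in bp.

    Shuffles and coverage fractions are computed over this universe.
    """

    chrom_lengths: Mapping[str, int]
    build_label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("assembly has no chromosomes")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def validate(self, interval: GenomicInterval) -> None:
        length = self.chrom_lengths.get(interval.chrom)
        if length is None:
            raise ValueError(f"unknown chromosome {interval.chrom!r} in {self.build_label or 'assembly'}")
        if interval.end > length:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {length}"
            )


@dataclass(frozen=True)
class DomainSet:
    """A labeled collection of non-overlapping intervals on an assembly.

    Used for cLAD/ciLAD domain sets and nucleoporin peak sets. Intervals
    are merged (sorted, union of overlapping/adjacent spans) at
    construction, so the non-overlap invariant holds by construction.
    """

    label: str
    intervals: tuple[GenomicInterval, ...]
    assembly: GenomeAssembly

    @classmethod
    def from_intervals(
        cls, label: str, intervals: Iterable[GenomicInterval], assembly: GenomeAssembly
    ) -> "DomainSet":
        merged = merge_intervals(list(intervals))
        for iv in merged:
            assembly.validate(iv)
        return cls(label=label, intervals=tuple(merged), assembly=assembly)

    @property
    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    @property
    def coverage_fraction(self) -> float:
        return self.total_bp / self.assembly.genome_size

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path, build_label: str = "") -> GenomeAssembly:
    """Read a two-column TSV of chromosome name and length."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            chrom = normalize_chrom(fields[0])
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
            if chrom in lengths:
                raise BedParseError(f"{path}:{lineno}: duplicate chromosome {chrom}")
            lengths[chrom] = length
    label = build_label or Path(path).stem
    return GenomeAssembly(chrom_lengths=lengths, build_label=label)


def read_bed(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    one_based: bool = False,
) -> list[GenomicInterval]:
    """Read BED3/BED6 records, preserving file order.

    Parameters
    ----------
    assembly : optional
        When given, records on unknown chromosomes or exceeding chromosome
        bounds raise a validation error.
    one_based : bool
        Set for files using GFF-style 1-based closed coordinates (e.g.
        miRBase tables exported as BED-like text); converted to 0-based
        half-open on read.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid span [{fields[1]}, {fields[2]})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-", "."} else None
            iv = GenomicInterval(normalize_chrom(fields[0]), start, end, name, strand)
            if assembly is not None:
                assembly.validate(iv)
            intervals.append(iv)
    return intervals


def read_gff3_features(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    feature_types: set[str] | None = None,
) -> list[GenomicInterval]:
    """Read GFF3 records (miRBase genome annotation style).

    Only seqid/start/end/strand and the ``Name`` attribute are consumed;
    1-based closed coordinates become 0-based half-open.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise BedParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if feature_types is not None and fields[2] not in feature_types:
                continue
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"{path}:{lineno}: invalid span")
            name = None
            for attr in fields[8].split(";"):
                if attr.startswith("Name="):
                    name = attr[5:]
                    break
            strand = fields[6] if fields[6] in {"+", "-", "."} else None
            iv = GenomicInterval(normalize_chrom(fields[0]), start, end, name, strand)
            if assembly is not None:
                assembly.validate(iv)
            intervals.append(iv)
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand or '.'}\n")


# ---------------------------------------------------------------------------
# Interval algebra (pyranges-backed)
# ---------------------------------------------------------------------------

def _to_pyranges(intervals: Sequence[GenomicInterval]) -> pr.PyRanges:
    if not intervals:
        return pr.PyRanges(pd.DataFrame({"Chromosome": [], "Start": [], "End": []}))
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in intervals],
                "Start": [iv.start for iv in intervals],
                "End": [iv.end for iv in intervals],
            }
        )
    )


def _from_pyranges(granges: pr.PyRanges) -> list[GenomicInterval]:
    df = granges.df
    if df.empty:
        return []
    df = df.sort_values(["Chromosome", "Start"], kind="mergesort")
    return [
        GenomicInterval(str(row.Chromosome), int(row.Start), int(row.End))
        for row in df.itertuples()
    ]


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sorted union of the input spans; adjacent (end == start) spans merge."""
    if not intervals:
        return []
    # slack=0 in pyranges does not merge bookended intervals; slack applies
    # before overlap testing, so slack=1... safer to merge by sweep on the
    # pyranges-sorted frame to guarantee the adjacency rule.
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ordered[0].chrom, ordered[0].start, ordered[0].end
    for iv in ordered[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def union_bp(intervals: Sequence[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


def overlap_bp(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval] | DomainSet
) -> int:
    """Total base pairs in the intersection of the unions of ``a`` and ``b``.

    This is the bedtools-intersect quantity used for bp-mode overlap
    statistics; symmetric in its arguments.
    """
    if isinstance(b, DomainSet):
        b = b.intervals
    if not a or not b:
        return 0
    inter = _to_pyranges(merge_intervals(a)).intersect(_to_pyranges(merge_intervals(list(b))))
    df = inter.df
    if df.empty:
        return 0
    return int((df["End"] - df["Start"]).sum())


def features_overlapping(
    features: Sequence[GenomicInterval],
    domains: DomainSet,
    mode: str = "any",
) -> list[GenomicInterval]:
    """Features that belong to a domain set.

    mode='any': >=1 bp intersection with any domain interval (the default
    membership rule, matching interval-file intersection). mode='midpoint':
    the feature midpoint falls inside a domain.
    """
    if mode not in {"any", "midpoint"}:
        raise ValueError(f"unknown membership mode {mode!r}")
    per_chrom = domains.by_chrom()
    kept: list[GenomicInterval] = []
    for feat in features:
        doms = per_chrom.get(feat.chrom)
        if not doms:
            continue
        if mode == "any":
            hit = any(d.start < feat.end and d.end > feat.start for d in doms)
        else:
            mid = feat.midpoint
            hit = any(d.start <= mid < d.end for d in doms)
        if hit:
            kept.append(feat)
    return kept


def complement(domains: DomainSet, label: str | None = None) -> DomainSet:
    """The gaps of a domain set over its assembly (e.g. inter-LADs of LADs)."""
    per_chrom = domains.by_chrom()
    gaps: list[GenomicInterval] = []
    for chrom, length in domains.assembly.chrom_lengths.items():
        pos = 0
        for iv in per_chrom.get(chrom, []):
            if iv.start > pos:
                gaps.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < length:
            gaps.append(GenomicInterval(chrom, pos, length))
    return DomainSet.from_intervals(
        label or f"not_{domains.label}", gaps, domains.assembly
    )
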