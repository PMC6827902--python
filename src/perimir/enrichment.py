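"""Permutation-based overlap enrichment of feature sets against domain sets.

The observed overlap of a feature set (e.g. pre-miRNA loci) with a domain
set (cLADs, ciLADs, nucleoporin peaks) is compared to (a) an analytic
expectation under random placement and (b) an empirical null built by
shuffling the features genome-wide, keeping the multiset of feature lengths
and the feature count unchanged. One-sided empirical p-values count
permutations with overlap at least (enrichment tail) or at most (depletion
tail) as extreme as observed; ties count in both tails, which makes the
p-values conservative. When no permutation reaches the observed value the
p-value is reported as the bound "<1/N" (e.g. "<0.001" at N = 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._engine import CoverageIndex, LinearGenome, union_overlap_rows
from .intervals import DomainSet, GenomeAssembly, GenomicInterval, features_overlapping, overlap_bp

__all__ = ["ShuffleConfig", "EnrichmentResult", "expected_overlap", "shuffle_features", "permutation_test"]

MODES = ("bp", "feature_count")


@dataclass(frozen=True)
class ShuffleConfig:
    """Parameters of the size-preserving random shuffle.

    per_chromosome=False places each feature uniformly over every genomic
    position where it fits within a single chromosome (genome-wide
    universe); True restricts each feature to its own chromosome.
    allow_overlap_between_shuffled=True lets shuffled features overlap each
    other (rejection-free, so the size distribution is unbiased).
    """

    n_perm: int = 1000
    seed: int = 0
    per_chromosome: bool = False
    allow_overlap_between_shuffled: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected overlap with permutation p-values.

    enrichment = observed/expected; values > 1 indicate colocalization
    preference, < 1 avoidance. p_enriched / p_depleted are one-sided
    empirical tail fractions over n_perm shuffles; when the tail count is
    zero the stored p is the bound 1/n_perm and p_report renders "<1/N".
    """

    observed: float
    expected: float
    enrichment: float
    n_perm: int
    p_enriched: float
    p_depleted: float
    p_report: str
    mode: str
    n_features: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "observed": self.observed,
            "expected": self.expected,
            "enrichment": self.enrichment,
            "n_perm": self.n_perm,
            "p_enriched": self.p_enriched,
            "p_depleted": self.p_depleted,
            "p_report": self.p_report,
            "n_features": self.n_features,
            "seed": self.seed,
        }


def expected_overlap(
    features: Sequence[GenomicInterval], domains: DomainSet, mode: str = "feature_count"
) -> float:
    """Analytic expectation of the overlap statistic under random placement.

    bp mode: genome_size x coverage(features) x coverage(domains).
    feature_count mode: n_features x coverage(domains), treating features
    as points (the permutation null captures the finite-width correction).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    genome_size = domains.assembly.genome_size
    if genome_size <= 0:
        raise ValueError("zero genome size")
    cov_d = domains.coverage_fraction
    if mode == "feature_count":
        return len(features) * cov_d
    from .intervals import union_bp

    cov_f = union_bp(list(features)) / genome_size
    return genome_size * cov_f * cov_d


def observed_overlap(
    features: Sequence[GenomicInterval], domains: DomainSet, mode: str = "feature_count"
) -> float:
    if mode == "feature_count":
        return float(len(features_overlapping(features, domains, mode="any")))
    return float(overlap_bp(features, domains))


def _sample_linear_starts(
    rng: np.random.Generator,
    lengths: np.ndarray,
    linear: LinearGenome,
    n_perm: int,
) -> np.ndarray:
    """Uniform starts over all fitting positions, shape (n_perm, n_features).

    Placement universe: for a feature of length L, every (chrom, start)
    with start in [0, chrom_len - L]; chromosomes weighted by their number
    of valid starts.
    """
    n = lengths.size
    out = np.empty((n_perm, n), dtype=np.int64)
    clens = linear.lengths
    for length in np.unique(lengths):
        cols = np.flatnonzero(lengths == length)
        valid = np.maximum(clens - length + 1, 0)
        if valid.sum() == 0:
            raise ValueError(f"feature of length {length} fits on no chromosome")
        cum = np.cumsum(valid)
        u = rng.random((n_perm, cols.size)) * cum[-1]
        chrom_idx = np.searchsorted(cum, u, side="right")
        before = np.concatenate([[0], cum[:-1]])
        start_in_chrom = (u - before[chrom_idx]).astype(np.int64)
        out[:, cols] = linear.offsets[chrom_idx] + start_in_chrom
    return out


def _sample_per_chromosome_starts(
    rng: np.random.Generator,
    lengths: np.ndarray,
    chrom_idx: np.ndarray,
    linear: LinearGenome,
    n_perm: int,
) -> np.ndarray:
    valid = linear.lengths[chrom_idx] - lengths + 1
    if np.any(valid <= 0):
        raise ValueError("feature longer than its chromosome")
    u = rng.random((n_perm, lengths.size))
    starts = (u * valid).astype(np.int64)
    return linear.offsets[chrom_idx] + starts


def _reject_internal_overlaps(
    rng: np.random.Generator,
    starts: np.ndarray,
    lengths: np.ndarray,
    resample,
    max_rounds: int = 1000,
) -> np.ndarray:
    """Redraw whole permutation rows until no two features overlap."""
    from ._engine import union_length_rows

    total = int(lengths.sum())
    for _ in range(max_rounds):
        bad = union_length_rows(starts, lengths) < total
        if not bad.any():
            return starts
        starts[bad] = resample(int(bad.sum()))
    raise RuntimeError("could not place non-overlapping shuffled features")


def shuffle_features(
    features: Sequence[GenomicInterval],
    config: ShuffleConfig,
    assembly: GenomeAssembly,
) -> list[GenomicInterval]:
    """One random shuffle preserving the multiset of feature lengths."""
    linear = LinearGenome(assembly)
    lengths = np.array([len(f) for f in features], dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    if config.per_chromosome:
        chrom_idx = np.array([linear.chroms.index(f.chrom) for f in features])
        starts = _sample_per_chromosome_starts(rng, lengths, chrom_idx, linear, 1)
    else:
        starts = _sample_linear_starts(rng, lengths, linear, 1)
    if not config.allow_overlap_between_shuffled:
        if config.per_chromosome:
            resample = lambda k: _sample_per_chromosome_starts(rng, lengths, chrom_idx, linear, k)
        else:
            resample = lambda k: _sample_linear_starts(rng, lengths, linear, k)
        starts = _reject_internal_overlaps(rng, starts, lengths, resample)
    shuffled = linear.from_linear(starts[0], starts[0] + lengths)
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f.name, strand=f.strand)
        for iv, f in zip(shuffled, features)
    ]


def permutation_test(
    features: Sequence[GenomicInterval],
    domains: DomainSet,
    mode: str = "feature_count",
    config: ShuffleConfig = ShuffleConfig(),
) -> EnrichmentResult:
    """Size-preserving permutation test of feature/domain overlap.

    p_enriched = #{perm overlap >= observed}/n_perm and p_depleted the
    analogous <= fraction; deterministic for a given seed.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not features:
        raise ValueError("empty feature set")
    obs = observed_overlap(features, domains, mode)
    exp = expected_overlap(features, domains, mode)

    linear = LinearGenome(domains.assembly)
    dstarts, dends = linear.to_linear(domains.intervals)
    cov = CoverageIndex(dstarts, dends)
    lengths = np.array([len(f) for f in features], dtype=np.int64)
    rng = np.random.default_rng(config.seed)

    n_ge = n_le = 0
    chunk = max(1, min(config.n_perm, int(4e6 // max(1, len(features)))))
    done = 0
    chrom_idx = None
    if config.per_chromosome:
        chrom_idx = np.array([linear.chroms.index(f.chrom) for f in features])
    while done < config.n_perm:
        k = min(chunk, config.n_perm - done)
        if config.per_chromosome:
            starts = _sample_per_chromosome_starts(rng, lengths, chrom_idx, linear, k)
        else:
            starts = _sample_linear_starts(rng, lengths, linear, k)
        if not config.allow_overlap_between_shuffled:
            if config.per_chromosome:
                resample = lambda m: _sample_per_chromosome_starts(rng, lengths, chrom_idx, linear, m)
            else:
                resample = lambda m: _sample_linear_starts(rng, lengths, linear, m)
            starts = _reject_internal_overlaps(rng, starts, lengths, resample)
        if mode == "feature_count":
            stats = cov.any_overlap(starts, starts + lengths).sum(axis=1).astype(float)
        else:
            stats = union_overlap_rows(starts, lengths, cov)
        n_ge += int((stats >= obs - 1e-9).sum())
        n_le += int((stats <= obs + 1e-9).sum())
        done += k

    n_perm = config.n_perm
    # Empirical tail fraction; a zero count is reported as the bound <1/N.
    if n_ge == 0:
        p_enr, rep_enr = 1.0 / n_perm, f"<{1 / n_perm:g}"
    else:
        p_enr, rep_enr = n_ge / n_perm, f"{n_ge / n_perm:g}"
    if n_le == 0:
        p_dep, rep_dep = 1.0 / n_perm, f"<{1 / n_perm:g}"
    else:
        p_dep, rep_dep = n_le / n_perm, f"{n_le / n_perm:g}"
    # report the smaller (more interesting) tail, tagged by direction
    if p_enr <= p_dep:
        p_report = rep_enr
    else:
        p_report = rep_dep
    enr = obs / exp if exp > 0 else float("nan")
    return EnrichmentResult(
        observed=obs,
        expected=exp,
        enrichment=enr,
        n_perm=n_perm,
        p_enriched=p_enr,
        p_depleted=p_dep,
        p_report=p_report,
        mode=mode,
        n_features=len(features),
        seed=config.seed,
    )
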