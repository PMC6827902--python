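"""Shared fixtures and brute-force oracles.

The oracles here deliberately avoid the library's interval code paths:
interval algebra is checked against per-bp boolean masks on toy
chromosomes, rank-sum statistics against full enumeration, and empirical
distributions against closed forms.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from perimir.intervals import DomainSet, GenomeAssembly, GenomicInterval

TOY_CHROMS = {"chr1": 10_000, "chr2": 6_000}


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly(chrom_lengths=TOY_CHROMS, build_label="toy")


# ---------------------------------------------------------------------------
# per-bp mask oracles
# ---------------------------------------------------------------------------

def bp_mask(intervals, assembly: GenomeAssembly) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(l, dtype=bool) for c, l in assembly.chrom_lengths.items()}
    for iv in intervals:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks


def mask_union_bp(intervals, assembly) -> int:
    return int(sum(m.sum() for m in bp_mask(intervals, assembly).values()))


def mask_overlap_bp(a, b, assembly) -> int:
    ma, mb = bp_mask(a, assembly), bp_mask(b, assembly)
    return int(sum((ma[c] & mb[c]).sum() for c in ma))


def mask_membership(feature: GenomicInterval, domains, assembly) -> bool:
    m = bp_mask(domains, assembly)[feature.chrom]
    return bool(m[feature.start:feature.end].any())


def random_intervals(rng: np.random.Generator, n: int, assembly: GenomeAssembly,
                     max_len: int = 500) -> list[GenomicInterval]:
    out = []
    chroms = list(assembly.chrom_lengths)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        clen = assembly.chrom_lengths[chrom]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, clen - length + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


# ---------------------------------------------------------------------------
# enumeration oracles for the rank statistics
# ---------------------------------------------------------------------------

def brute_force_mannwhitney(a, b) -> tuple[float, float]:
    """U statistic by pair counting; two-sided p by enumerating all
    rank assignments (no ties assumed)."""
    a, b = list(a), list(b)
    u_obs = sum(1.0 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    pooled = sorted(a + b)
    n_a = len(a)
    mu = n_a * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        xa = [pooled[i] for i in combo]
        xb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1.0 for x in xa for y in xb if x > y)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


def brute_force_ks(a, b) -> float:
    """Two-sample KS D by sweeping empirical CDFs over all data points."""
    a, b = np.sort(a), np.sort(b)
    pts = np.concatenate([a, b])
    fa = np.searchsorted(a, pts, side="right") / a.size
    fb = np.searchsorted(b, pts, side="right") / b.size
    return float(np.abs(fa - fb).max())


def make_domainset(label: str, spans, assembly) -> DomainSet:
    return DomainSet.from_intervals(
        label, [GenomicInterval(c, s, e) for c, s, e in spans], assembly
    )
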