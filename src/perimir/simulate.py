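"""Seeded generators for every input the pipeline consumes.

These simulators emulate the study conditions with known ground truth:

* genomes tiled by alternating cLAD/ciLAD domains with log-normal sizes
  and a target cLAD genome coverage (default 0.40, the mouse regime in
  which LADs cover almost 40% of the genome);
* point-feature sets (pre-miRNA-sized loci) placed with a planted
  probability ``q`` of falling inside cLADs — ``q`` below the cLAD
  coverage emulates the observed avoidance of LADs (mouse: 14% of
  microRNA genes inside cLADs vs ~40% coverage);
* populations of spherical nuclei with two alleles per locus, radial
  positions drawn from density ∝ r²·exp(β·r/R) (β = 0: uniform in the
  sphere, analytically checkable; β large: peripheral concentration),
  independent Bernoulli expression, and lamina-contact ground truth from
  a peripheral shell fraction.

Every generator is a pure function of (spec, seed). Domain sizes are
rounded to even bp so that center-biased feature placement puts the
feature midpoint exactly on the domain midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fish import AlleleRecord, NucleusRecord
from .intervals import DomainSet, GenomeAssembly, GenomicInterval

__all__ = [
    "GenomeSpec",
    "FeaturePlacementSpec",
    "NucleusPopulationSpec",
    "generate_genome",
    "place_features",
    "place_features_uniform",
    "generate_nuclei",
    "write_chrom_sizes",
    "PRESETS",
]

_EVEN = 2


def _round_even(x: np.ndarray) -> np.ndarray:
    return np.maximum(_EVEN, (np.round(x / 2).astype(np.int64)) * 2)


@dataclass(frozen=True)
class GenomeSpec:
    """Scaled-down mouse-like genome: 4 x 50 Mb chromosomes by default,
    log-normal LAD sizes (median 500 kb), cLAD coverage target 0.40."""

    chromosome_lengths: tuple[int, ...] = (50_000_000,) * 4
    lad_median_bp: int = 500_000
    lad_sigma: float = 0.6  # log-normal shape of domain sizes
    lad_coverage_target: float = 0.40

    def __post_init__(self) -> None:
        if not 0 < self.lad_coverage_target < 1:
            raise ValueError("coverage target must be in (0, 1)")
        if self.lad_median_bp * 2 > min(self.chromosome_lengths):
            raise ValueError("chromosomes too short for the requested domain sizes")


@dataclass(frozen=True)
class FeaturePlacementSpec:
    """Planted placement of point features relative to the cLAD set."""

    n_features: int = 1000
    feature_length: int = 86  # pre-miRNA hairpin scale; even for center bias
    inside_probability: float = 0.14  # q: chance of placement inside cLADs
    position_bias: str = "uniform"  # uniform | center | boundary

    def __post_init__(self) -> None:
        if not 0 <= self.inside_probability <= 1:
            raise ValueError("inside_probability must be in [0, 1]")
        if self.position_bias not in {"uniform", "center", "boundary"}:
            raise ValueError(f"unknown position bias {self.position_bias!r}")


@dataclass(frozen=True)
class NucleusPopulationSpec:
    """A population of two-allele spherical nuclei.

    radial_bias is the β of the allele radial density ∝ r²·exp(β·r/R) on
    [0, R]: 0 gives uniform-in-sphere, large positive values concentrate
    alleles at the periphery. lamina_shell_fraction defines ground-truth
    lamina contact as surface distance <= fraction x radius.
    """

    n_nuclei: int = 120
    radius_mean: float = 3.5  # μm, T-lymphocyte scale
    radius_sd: float = 0.3
    radial_bias: float = 0.0
    expression_probability: float = 0.3
    lamina_shell_fraction: float = 0.05
    locus: str = "miR"
    cell_type: str = "sim"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("need at least one nucleus")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be > 0")


def generate_genome(
    spec: GenomeSpec, seed: int
) -> tuple[GenomeAssembly, DomainSet, DomainSet]:
    """Alternating cLAD/ciLAD tiling covering every bp exactly once.

    Realized cLAD coverage must land within 5% (absolute) of the target,
    else the spec is rejected as unachievable at this genome size.
    """
    rng = np.random.default_rng(seed)
    c = spec.lad_coverage_target
    mu_clad = np.log(spec.lad_median_bp)
    # inter-domain median chosen so expected coverage matches the target
    mu_cilad = np.log(spec.lad_median_bp * (1 - c) / c)

    lengths = {f"chr{i + 1}": int(l) for i, l in enumerate(spec.chromosome_lengths)}
    assembly = GenomeAssembly(chrom_lengths=lengths, build_label="sim1")
    clads: list[GenomicInterval] = []
    cilads: list[GenomicInterval] = []
    for chrom, clen in lengths.items():
        pos = 0
        is_clad = bool(rng.integers(2))
        while pos < clen:
            mu = mu_clad if is_clad else mu_cilad
            size = int(_round_even(np.exp(rng.normal(mu, spec.lad_sigma))))
            size = min(size, clen - pos)
            (clads if is_clad else cilads).append(GenomicInterval(chrom, pos, pos + size))
            pos += size
            is_clad = not is_clad
    clad_set = DomainSet.from_intervals("cLAD", clads, assembly)
    cilad_set = DomainSet.from_intervals("ciLAD", cilads, assembly)
    realized = clad_set.coverage_fraction
    if abs(realized - c) > 0.05:
        raise ValueError(
            f"realized cLAD coverage {realized:.3f} misses target {c:.2f} by >5%; "
            "use a larger genome or smaller domains"
        )
    return assembly, clad_set, cilad_set


def place_features(
    spec: FeaturePlacementSpec,
    clad: DomainSet,
    cilad: DomainSet,
    seed: int,
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Features planted inside cLADs with probability q, else inside ciLADs.

    Returns (features, ground-truth boolean array: True = inside cLAD).
    Within the chosen domain the position is uniform over fitting starts,
    at the exact domain center, or flush against the upstream boundary,
    per ``position_bias``.
    """
    rng = np.random.default_rng(seed)
    L = spec.feature_length
    in_clad = rng.random(spec.n_features) < spec.inside_probability

    def pick_and_place(domain_set: DomainSet, count: int) -> list[GenomicInterval]:
        doms = domain_set.intervals
        weights = np.array([max(0, len(d) - L + 1) for d in doms], dtype=float)
        if weights.sum() == 0:
            raise ValueError(f"no {domain_set.label} domain can hold a {L} bp feature")
        idx = rng.choice(len(doms), size=count, p=weights / weights.sum())
        out = []
        for i in idx:
            d = doms[i]
            if spec.position_bias == "uniform":
                start = d.start + int(rng.integers(0, len(d) - L + 1))
            elif spec.position_bias == "center":
                start = (d.start + d.end - L) // 2
            else:  # boundary: flush inside the upstream edge
                start = d.start
            out.append(GenomicInterval(d.chrom, start, start + L))
        return out

    placed_clad = pick_and_place(clad, int(in_clad.sum()))
    placed_cilad = pick_and_place(cilad, int((~in_clad).sum()))
    features: list[GenomicInterval | None] = [None] * spec.n_features
    it_c, it_i = iter(placed_clad), iter(placed_cilad)
    for j, flag in enumerate(in_clad):
        iv = next(it_c) if flag else next(it_i)
        features[j] = GenomicInterval(iv.chrom, iv.start, iv.end, name=f"feat_{j:05d}")
    return features, in_clad


def place_features_uniform(
    n_features: int,
    feature_length: int,
    assembly: GenomeAssembly,
    seed: int,
) -> list[GenomicInterval]:
    """Features placed uniformly over all fitting genomic positions.

    The exact null of the permutation shuffle (no planted preference);
    used for calibration runs.
    """
    from ._engine import LinearGenome
    from .enrichment import _sample_linear_starts

    linear = LinearGenome(assembly)
    lengths = np.full(n_features, feature_length, dtype=np.int64)
    rng = np.random.default_rng(seed)
    starts = _sample_linear_starts(rng, lengths, linear, 1)[0]
    placed = linear.from_linear(starts, starts + lengths)
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"feat_{j:05d}")
        for j, iv in enumerate(placed)
    ]


def _sample_radial(rng: np.random.Generator, beta: float, n: int) -> np.ndarray:
    """Draw r/R from density ∝ t²·exp(β·t) on [0, 1] by inverse-CDF lookup."""
    if beta == 0.0:
        return rng.random(n) ** (1.0 / 3.0)
    grid = np.linspace(0.0, 1.0, 4097)
    pdf = grid**2 * np.exp(np.clip(beta * grid, -700, 700))
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def generate_nuclei(
    spec: NucleusPopulationSpec, seed: int, emit_contact_flags: bool = True
) -> tuple[list[NucleusRecord], list[AlleleRecord], dict]:
    """Two alleles per nucleus with known radial law and expression.

    Returns (nuclei, alleles, ground_truth) where ground_truth carries the
    true nd, lamina-contact and expression arrays in allele order. With
    ``emit_contact_flags=False`` the allele records leave lamina_contact
    unset so the geometric contact call can be exercised.
    """
    rng = np.random.default_rng(seed)
    n_alleles = 2 * spec.n_nuclei
    radii = np.clip(
        rng.normal(spec.radius_mean, spec.radius_sd, spec.n_nuclei),
        0.2 * spec.radius_mean,
        None,
    )
    centers = rng.uniform(10.0, 50.0, size=(spec.n_nuclei, 3))
    t = _sample_radial(rng, spec.radial_bias, n_alleles)  # r/R
    direction = rng.normal(size=(n_alleles, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    expressed = rng.random(n_alleles) < spec.expression_probability

    nuclei: list[NucleusRecord] = []
    alleles: list[AlleleRecord] = []
    nd_true = 1.0 - t
    contact_true = nd_true <= spec.lamina_shell_fraction
    for i in range(spec.n_nuclei):
        nid = f"nuc_{i:05d}"
        nuclei.append(
            NucleusRecord(
                nucleus_id=nid,
                center=tuple(centers[i]),
                radius=float(radii[i]),
                cell_type=spec.cell_type,
                condition=spec.condition,
            )
        )
        for a in (2 * i, 2 * i + 1):
            pos = centers[i] + direction[a] * t[a] * radii[i]
            alleles.append(
                AlleleRecord(
                    nucleus_id=nid,
                    locus=spec.locus,
                    position=tuple(pos),
                    expressed=bool(expressed[a]),
                    lamina_contact=bool(contact_true[a]) if emit_contact_flags else None,
                )
            )
    ground_truth = {"nd": nd_true, "lamina_contact": contact_true, "expressed": expressed}
    return nuclei, alleles, ground_truth


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in assembly.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


#: named study regimes for the CLI: a null control, the mouse-like
#: avoidance regime (q = 0.14 vs 0.40 coverage; moderate peripheral bias),
#: and a strongly peripheral imaging regime.
PRESETS: dict[str, dict] = {
    "null": {
        "genome": GenomeSpec(),
        "features": FeaturePlacementSpec(inside_probability=0.40),
        "nuclei": NucleusPopulationSpec(radial_bias=0.0),
    },
    "mouse-like": {
        "genome": GenomeSpec(),
        "features": FeaturePlacementSpec(inside_probability=0.14),
        "nuclei": NucleusPopulationSpec(radial_bias=8.0),
    },
    "peripheral": {
        "genome": GenomeSpec(),
        "features": FeaturePlacementSpec(inside_probability=0.14),
        "nuclei": NucleusPopulationSpec(radial_bias=30.0),
    },
}
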