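"""Quantitative 3D-FISH analysis of allele positions in spherical nuclei.

Each scored nucleus is modeled as a sphere (center + radius, in μm) holding
two alleles of a locus. The allele-to-periphery distance is normalized by
the nuclear radius into ND in [0, 1] — ND = 0 is the nuclear periphery,
ND = 1 the center — and histogrammed into ten fixed concentric shells
([0,0.1), [0.1,0.2), ..., [0.9,1.0], last bin closed). Distributions of ND
values are compared with the two-sample Kolmogorov-Smirnov test; lamina
colocalization is taken from imaging-derived contact flags when present,
or from a peripheral shell-thickness criterion otherwise; per-cell counts
of expressed alleles summarize mono- vs biallelic expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NucleusRecord",
    "AlleleRecord",
    "NDRecord",
    "ShellHistogram",
    "AllelicSummary",
    "KSResult",
    "ColocalizationSummary",
    "normalized_distance",
    "normalized_distances",
    "shell_histogram",
    "ks_compare",
    "lamina_colocalization",
    "allelic_summary",
    "expressed_vs_silent_nd",
    "read_allele_table",
    "write_allele_table",
]

N_SHELLS = 10
SHELL_EDGES = np.linspace(0.0, 1.0, N_SHELLS + 1)
#: significance threshold used for allele-distribution comparisons
KS_ALPHA = 1e-4
#: alleles up to this fraction of the radius outside the sphere are clamped
#: to the surface (segmentation noise); farther out is an error
OUTSIDE_TOLERANCE = 0.02


@dataclass(frozen=True)
class NucleusRecord:
    nucleus_id: str
    center: tuple[float, float, float]
    radius: float
    cell_type: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"nucleus {self.nucleus_id}: radius must be > 0")


@dataclass(frozen=True)
class AlleleRecord:
    nucleus_id: str
    locus: str
    position: tuple[float, float, float]
    expressed: bool
    lamina_contact: bool | None = None


@dataclass(frozen=True)
class NDRecord:
    allele: AlleleRecord
    nd: float
    shell: int


@dataclass(frozen=True)
class ShellHistogram:
    counts: tuple[int, ...]
    fractions: tuple[float, ...]
    n: int


@dataclass(frozen=True)
class AllelicSummary:
    """Per-cell classification by number of expressed alleles."""

    n_cells: int
    n_mono: int
    n_bi: int
    n_silent: int

    @property
    def n_expressing(self) -> int:
        return self.n_mono + self.n_bi

    def fractions_of_all_cells(self) -> dict[str, float]:
        n = self.n_cells
        return {"mono": self.n_mono / n, "bi": self.n_bi / n, "silent": self.n_silent / n}

    def fractions_of_expressing_cells(self) -> dict[str, float]:
        n = self.n_expressing
        if n == 0:
            return {"mono": 0.0, "bi": 0.0}
        return {"mono": self.n_mono / n, "bi": self.n_bi / n}


@dataclass(frozen=True)
class KSResult:
    d: float
    pvalue: float
    significant: bool  # at the p < 1e-4 threshold
    method: str


@dataclass(frozen=True)
class ColocalizationSummary:
    frac_alleles: float  # fraction of all alleles in lamina contact
    frac_cells: float  # fraction of cells with >=1 contacting allele
    frac_expressed_alleles: float  # among expressed alleles only
    n_alleles: int
    n_cells: int
    n_expressed: int


def _shell_of(nd: float) -> int:
    return min(int(nd * N_SHELLS), N_SHELLS - 1)


def normalized_distance(allele: AlleleRecord, nucleus: NucleusRecord) -> NDRecord:
    """ND = (radius - |position - center|)/radius, clamped to [0, 1].

    Alleles up to OUTSIDE_TOLERANCE x radius outside the sphere are clamped
    to ND = 0; farther outside raises.
    """
    if allele.nucleus_id != nucleus.nucleus_id:
        raise ValueError("allele does not belong to this nucleus")
    r = float(np.linalg.norm(np.asarray(allele.position) - np.asarray(nucleus.center)))
    if r > nucleus.radius * (1.0 + OUTSIDE_TOLERANCE):
        raise ValueError(
            f"allele in nucleus {nucleus.nucleus_id} lies {r:.3f} μm from center, "
            f"beyond radius {nucleus.radius:.3f} μm plus tolerance"
        )
    nd = float(np.clip((nucleus.radius - r) / nucleus.radius, 0.0, 1.0))
    return NDRecord(allele=allele, nd=nd, shell=_shell_of(nd))


def normalized_distances(
    alleles: Iterable[AlleleRecord], nuclei: Mapping[str, NucleusRecord]
) -> list[NDRecord]:
    out = []
    for allele in alleles:
        nuc = nuclei.get(allele.nucleus_id)
        if nuc is None:
            raise KeyError(f"no nucleus record for {allele.nucleus_id!r}")
        out.append(normalized_distance(allele, nuc))
    return out


def shell_histogram(nds: Sequence[NDRecord | float]) -> ShellHistogram:
    """Counts per fixed decile shell; final bin [0.9, 1.0] closed."""
    if len(nds) == 0:
        raise ValueError("empty ND list")
    values = np.array([x.nd if isinstance(x, NDRecord) else float(x) for x in nds])
    counts, _ = np.histogram(values, bins=SHELL_EDGES)
    n = int(counts.sum())
    return ShellHistogram(
        counts=tuple(int(c) for c in counts),
        fractions=tuple(float(c) / n for c in counts),
        n=n,
    )


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> KSResult:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    Exact p-value when both samples have n <= 25, asymptotic otherwise;
    flags significance at the p < 1e-4 threshold used for allele
    distribution comparisons.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have size >= 2")
    method = "exact" if max(a.size, b.size) <= 25 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return KSResult(
        d=float(res.statistic),
        pvalue=float(res.pvalue),
        significant=bool(res.pvalue < KS_ALPHA),
        method=method,
    )


def lamina_colocalization(
    alleles: Sequence[AlleleRecord],
    nuclei: Mapping[str, NucleusRecord],
    shell_thickness: float = 0.1,
    fractional: bool = False,
) -> ColocalizationSummary:
    """Lamina-contact fractions per allele, per cell, and among expressed.

    Imaging-derived ``lamina_contact`` flags are used verbatim where
    present. Otherwise an allele is called in contact when its distance to
    the nuclear surface is <= shell_thickness (μm by default; a fraction of
    the radius when ``fractional``) — a geometric stand-in for the
    pixel-overlap colocalization criterion.
    """
    if not alleles:
        raise ValueError("empty allele list")
    contact_by_cell: dict[str, bool] = {}
    n_contact = n_expr = n_expr_contact = 0
    for allele in alleles:
        nuc = nuclei.get(allele.nucleus_id)
        if nuc is None:
            raise KeyError(f"no nucleus record for {allele.nucleus_id!r}")
        if allele.lamina_contact is not None:
            contact = allele.lamina_contact
        else:
            r = float(np.linalg.norm(np.asarray(allele.position) - np.asarray(nuc.center)))
            thickness = shell_thickness * nuc.radius if fractional else shell_thickness
            contact = (nuc.radius - r) <= thickness
        n_contact += contact
        if allele.expressed:
            n_expr += 1
            n_expr_contact += contact
        cell = allele.nucleus_id
        contact_by_cell[cell] = contact_by_cell.get(cell, False) or contact
    n_cells = len(contact_by_cell)
    return ColocalizationSummary(
        frac_alleles=n_contact / len(alleles),
        frac_cells=sum(contact_by_cell.values()) / n_cells,
        frac_expressed_alleles=(n_expr_contact / n_expr) if n_expr else float("nan"),
        n_alleles=len(alleles),
        n_cells=n_cells,
        n_expressed=n_expr,
    )


def allelic_summary(alleles: Sequence[AlleleRecord]) -> AllelicSummary:
    """Classify each nucleus as mono-, bi-allelic or silent for its locus."""
    expressed_count: dict[tuple[str, str], int] = {}
    seen: dict[tuple[str, str], int] = {}
    for allele in alleles:
        key = (allele.nucleus_id, allele.locus)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] > 2:
            raise ValueError(f">2 alleles for locus {allele.locus!r} in nucleus {allele.nucleus_id!r}")
        expressed_count[key] = expressed_count.get(key, 0) + int(allele.expressed)
    counts = list(expressed_count.values())
    return AllelicSummary(
        n_cells=len(counts),
        n_mono=sum(c == 1 for c in counts),
        n_bi=sum(c == 2 for c in counts),
        n_silent=sum(c == 0 for c in counts),
    )


def expressed_vs_silent_nd(nds: Sequence[NDRecord]) -> dict:
    """Compare ND distributions of expressed vs non-expressed alleles."""
    expressed = [r.nd for r in nds if r.allele.expressed]
    silent = [r.nd for r in nds if not r.allele.expressed]
    if not expressed or not silent:
        raise ValueError("need both expressed and silent alleles")
    return {
        "expressed_nd": expressed,
        "silent_nd": silent,
        "expressed_hist": shell_histogram(expressed),
        "silent_hist": shell_histogram(silent),
        "expressed_median": float(np.median(expressed)),
        "silent_median": float(np.median(silent)),
        "ks": ks_compare(expressed, silent),
    }


# ---------------------------------------------------------------------------
# Allele-table I/O (TSV exported from image analysis)
# ---------------------------------------------------------------------------

ALLELE_COLUMNS = [
    "nucleus_id", "cell_type", "condition", "center_x", "center_y", "center_z",
    "radius", "locus", "allele_x", "allele_y", "allele_z", "expressed",
    "lamina_contact",
]


def read_allele_table(path: str | Path) -> tuple[dict[str, NucleusRecord], list[AlleleRecord]]:
    """Read the per-allele TSV; returns (nuclei by id, alleles in file order)."""
    # read everything as strings so empty condition/contact cells survive
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ALLELE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"allele table missing columns: {sorted(missing)}")
    nuclei: dict[str, NucleusRecord] = {}
    alleles: list[AlleleRecord] = []
    for row in df.itertuples():
        nid = str(row.nucleus_id)
        if nid not in nuclei:
            nuclei[nid] = NucleusRecord(
                nucleus_id=nid,
                center=(float(row.center_x), float(row.center_y), float(row.center_z)),
                radius=float(row.radius),
                cell_type=str(row.cell_type),
                condition=str(row.condition),
            )
        raw_contact = str(getattr(row, "lamina_contact", "")).strip()
        contact = None if raw_contact == "" else bool(int(float(raw_contact)))
        alleles.append(
            AlleleRecord(
                nucleus_id=nid,
                locus=str(row.locus),
                position=(float(row.allele_x), float(row.allele_y), float(row.allele_z)),
                expressed=bool(int(float(row.expressed))),
                lamina_contact=contact,
            )
        )
    return nuclei, alleles


def write_allele_table(
    nuclei: Mapping[str, NucleusRecord], alleles: Sequence[AlleleRecord], path: str | Path
) -> None:
    rows = []
    for allele in alleles:
        nuc = nuclei[allele.nucleus_id]
        rows.append(
            {
                "nucleus_id": nuc.nucleus_id,
                "cell_type": nuc.cell_type,
                "condition": nuc.condition,
                "center_x": nuc.center[0],
                "center_y": nuc.center[1],
                "center_z": nuc.center[2],
                "radius": nuc.radius,
                "locus": allele.locus,
                "allele_x": allele.position[0],
                "allele_y": allele.position[1],
                "allele_z": allele.position[2],
                "expressed": int(allele.expressed),
                "lamina_contact": "" if allele.lamina_contact is None else int(allele.lamina_contact),
            }
        )
    pd.DataFrame(rows, columns=ALLELE_COLUMNS).to_csv(path, sep="\t", index=False)
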