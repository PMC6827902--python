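"""End-to-end orchestration of the comparative analyses from a config.

A run config names, per species, the feature BED (e.g. pre-miRNA loci),
the cLAD/ciLAD BEDs and a chrom.sizes table, plus enrichment and FISH
settings. ``run_all`` executes every stage, writing TSV/JSON results and a
manifest (seed, versions, input checksums) sufficient to re-execute the
run. Any stage failure aborts with a stage-tagged error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .boundary import compare_distance_distributions, scaled_distances
from .enrichment import ShuffleConfig, permutation_test
from .fish import (
    allelic_summary,
    ks_compare,
    lamina_colocalization,
    normalized_distances,
    read_allele_table,
    shell_histogram,
)
from .intervals import DomainSet, features_overlapping, read_bed, read_chrom_sizes

logger = logging.getLogger("perimir")

__all__ = ["RunConfig", "SpeciesConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    features: Path
    clad: Path
    cilad: Path
    chrom_sizes: Path
    build: str = ""
    features_one_based: bool = False


@dataclass(frozen=True)
class FishConfig:
    alleles: Path
    group_by: tuple[str, ...] = ("cell_type", "condition")
    lamina_thickness: float = 0.1
    fractional: bool = False


@dataclass(frozen=True)
class RunConfig:
    species: tuple[SpeciesConfig, ...]
    output_dir: Path
    seed: int = 0
    mode: str = "feature_count"
    n_perm: int = 1000
    fish: FishConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        species = tuple(
            SpeciesConfig(
                name=name,
                features=base / blk["features"],
                clad=base / blk["clad"],
                cilad=base / blk["cilad"],
                chrom_sizes=base / blk["chrom_sizes"],
                build=blk.get("build", ""),
                features_one_based=bool(blk.get("features_one_based", False)),
            )
            for name, blk in raw.get("species", {}).items()
        )
        fish = None
        if "fish" in raw:
            fb = raw["fish"]
            fish = FishConfig(
                alleles=base / fb["alleles"],
                group_by=tuple(fb.get("group_by", ["cell_type", "condition"])),
                lamina_thickness=float(fb.get("lamina_thickness", 0.1)),
                fractional=bool(fb.get("fractional", False)),
            )
        enr = raw.get("enrichment", {})
        cfg = cls(
            species=species,
            output_dir=base / raw["output_dir"],
            seed=int(raw.get("seed", 0)),
            mode=enr.get("mode", "feature_count"),
            n_perm=int(enr.get("n_perm", 1000)),
            fish=fish,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for sp in self.species:
            for p in (sp.features, sp.clad, sp.cilad, sp.chrom_sizes):
                if not Path(p).exists():
                    raise FileNotFoundError(f"species {sp.name}: missing input {p}")
        if self.fish is not None and not Path(self.fish.alleles).exists():
            raise FileNotFoundError(f"fish: missing allele table {self.fish.alleles}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return decorate


@_stage("enrichment")
def _run_enrichment(features, domain_sets, mode, n_perm, seed, outdir: Path) -> dict:
    if not features:
        raise ValueError("empty feature set")
    results = {}
    for i, domains in enumerate(domain_sets):
        res = permutation_test(
            features, domains, mode=mode,
            config=ShuffleConfig(n_perm=n_perm, seed=seed + i),
        )
        results[domains.label] = res.to_dict()
    with open(outdir / "enrichment.json", "w") as fh:
        json.dump(results, fh, indent=2)
    return results


@_stage("membership")
def _run_membership(features, clad: DomainSet, cilad: DomainSet, outdir: Path) -> dict:
    rows = []
    summary: dict[str, Any] = {}
    for mode in ("any", "midpoint"):
        in_clad = {id(f) for f in features_overlapping(features, clad, mode=mode)}
        per_chrom: dict[str, dict[str, int]] = {}
        for f in features:
            blk = per_chrom.setdefault(f.chrom, {"inside_clad": 0, "outside_clad": 0})
            blk["inside_clad" if id(f) in in_clad else "outside_clad"] += 1
        for chrom, blk in sorted(per_chrom.items()):
            rows.append({"mode": mode, "chrom": chrom, **blk})
        summary[mode] = {
            "n_features": len(features),
            "n_inside_clad": len(in_clad),
            "clad_fraction": len(in_clad) / len(features),
        }
    pd.DataFrame(rows).to_csv(outdir / "chromosome_counts.tsv", sep="\t", index=False)
    with open(outdir / "membership.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


@_stage("boundary")
def _run_boundary(features, clad: DomainSet, cilad: DomainSet, outdir: Path) -> dict:
    rows = []
    groups: dict[str, list[float]] = {}
    for domains in (clad, cilad):
        kept, dropped = scaled_distances(features, domains)
        groups[domains.label] = [r.scaled for r in kept]
        rows += [
            {
                "feature_id": r.feature_id,
                "domain_label": r.domain_label,
                "raw_distance": r.raw_distance,
                "scaled": r.scaled,
                "inside": int(r.inside),
                "retained": 1,
            }
            for r in kept
        ]
        rows += [
            {"feature_id": d.feature_id, "domain_label": domains.label,
             "raw_distance": "", "scaled": "", "inside": "", "retained": 0}
            for d in dropped
        ]
    pd.DataFrame(rows).to_csv(outdir / "scaled_distances.tsv", sep="\t", index=False)
    result: dict[str, Any] = {k: {"n": len(v)} for k, v in groups.items()}
    a, b = groups[clad.label], groups[cilad.label]
    if a and b:
        w = compare_distance_distributions(a, b)
        result["wilcoxon"] = {
            "statistic": w.statistic, "pvalue": w.pvalue, "method": w.method,
            "n_a": w.n_a, "n_b": w.n_b,
        }
    with open(outdir / "boundary_wilcoxon.json", "w") as fh:
        json.dump(result, fh, indent=2)
    return result


@_stage("fish")
def _run_fish(cfg: FishConfig, outdir: Path) -> dict:
    nuclei, alleles = read_allele_table(cfg.alleles)
    nds = normalized_distances(alleles, nuclei)
    key_of = {
        "cell_type": lambda r: nuclei[r.allele.nucleus_id].cell_type,
        "condition": lambda r: nuclei[r.allele.nucleus_id].condition,
        "locus": lambda r: r.allele.locus,
    }
    getters = [key_of[k] for k in cfg.group_by]
    grouped: dict[str, list] = {}
    for rec in nds:
        key = "/".join(str(g(rec)) for g in getters) or "all"
        grouped.setdefault(key, []).append(rec)

    hist_rows, report = [], {}
    for key, recs in sorted(grouped.items()):
        hist = shell_histogram(recs)
        for shell, (cnt, frac) in enumerate(zip(hist.counts, hist.fractions)):
            hist_rows.append({"group": key, "shell": shell, "count": cnt, "fraction": frac})
        summ = allelic_summary([r.allele for r in recs])
        coloc = lamina_colocalization(
            [r.allele for r in recs], nuclei,
            shell_thickness=cfg.lamina_thickness, fractional=cfg.fractional,
        )
        report[key] = {
            "n_alleles": hist.n,
            "shell_fractions": list(hist.fractions),
            "allelic": {
                "n_cells": summ.n_cells, "n_mono": summ.n_mono,
                "n_bi": summ.n_bi, "n_silent": summ.n_silent,
                "fractions_all_cells": summ.fractions_of_all_cells(),
                "fractions_expressing_cells": summ.fractions_of_expressing_cells(),
            },
            "colocalization": {
                "frac_alleles": coloc.frac_alleles,
                "frac_cells": coloc.frac_cells,
                "frac_expressed_alleles": coloc.frac_expressed_alleles,
            },
        }
    pd.DataFrame(hist_rows).to_csv(outdir / "shell_histograms.tsv", sep="\t", index=False)

    ks_matrix = {}
    keys = sorted(grouped)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            res = ks_compare([r.nd for r in grouped[ka]], [r.nd for r in grouped[kb]])
            ks_matrix[f"{ka} vs {kb}"] = {
                "D": res.d, "pvalue": res.pvalue, "significant": res.significant,
            }
    with open(outdir / "fish_report.json", "w") as fh:
        json.dump({"groups": report, "ks_matrix": ks_matrix}, fh, indent=2)
    return report


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage; returns the report bundle."""
    config.validate()
    outroot = Path(config.output_dir)
    outroot.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "n_perm": config.n_perm,
        "inputs": {},
    }
    bundle: dict[str, Any] = {}
    for sp in config.species:
        outdir = outroot / sp.name
        outdir.mkdir(parents=True, exist_ok=True)
        for tag, path in (("features", sp.features), ("clad", sp.clad),
                          ("cilad", sp.cilad), ("chrom_sizes", sp.chrom_sizes)):
            manifest["inputs"][f"{sp.name}/{tag}"] = {
                "path": str(path), "sha256": _sha256(Path(path)),
            }
        assembly = read_chrom_sizes(sp.chrom_sizes, build_label=sp.build)
        features = read_bed(sp.features, assembly, one_based=sp.features_one_based)
        clad = DomainSet.from_intervals("cLAD", read_bed(sp.clad, assembly), assembly)
        cilad = DomainSet.from_intervals("ciLAD", read_bed(sp.cilad, assembly), assembly)
        logger.info(
            "species=%s n_features=%d clad_cov=%.3f cilad_cov=%.3f seed=%d",
            sp.name, len(features), clad.coverage_fraction,
            cilad.coverage_fraction, config.seed,
        )
        bundle[sp.name] = {
            "enrichment": _run_enrichment(
                features, [clad, cilad], config.mode, config.n_perm, config.seed, outdir
            ),
            "membership": _run_membership(features, clad, cilad, outdir),
            "boundary": _run_boundary(features, clad, cilad, outdir),
        }
    if config.fish is not None:
        fishdir = outroot / "fish"
        fishdir.mkdir(parents=True, exist_ok=True)
        manifest["inputs"]["fish/alleles"] = {
            "path": str(config.fish.alleles), "sha256": _sha256(Path(config.fish.alleles)),
        }
        bundle["fish"] = _run_fish(config.fish, fishdir)
    with open(outroot / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return bundle
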