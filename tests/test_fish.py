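"""3D-FISH statistics: ND normalization, shells, KS, colocalization."""

import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_ks
from perimir.fish import (
    AlleleRecord,
    NucleusRecord,
    allelic_summary,
    expressed_vs_silent_nd,
    ks_compare,
    lamina_colocalization,
    normalized_distance,
    normalized_distances,
    read_allele_table,
    shell_histogram,
    write_allele_table,
)
from perimir.simulate import NucleusPopulationSpec, generate_nuclei


def make_nucleus(radius=5.0, center=(10.0, 10.0, 10.0), nid="n1"):
    return NucleusRecord(nucleus_id=nid, center=center, radius=radius)


def allele_at(pos, nid="n1", expressed=False, contact=None):
    return AlleleRecord(nucleus_id=nid, locus="miR", position=pos,
                        expressed=expressed, lamina_contact=contact)


class TestNormalizedDistance:
    def test_center_surface_and_half_radius(self):
        nuc = make_nucleus()
        assert normalized_distance(allele_at((10, 10, 10)), nuc).nd == 1.0
        assert normalized_distance(allele_at((10, 10, 10)), nuc).shell == 9
        surf = normalized_distance(allele_at((15, 10, 10)), nuc)
        assert surf.nd == 0.0 and surf.shell == 0
        half = normalized_distance(allele_at((12.5, 10, 10)), nuc)
        assert half.nd == 0.5 and half.shell == 5

    def test_slightly_outside_clamped_farther_rejected(self):
        nuc = make_nucleus(radius=5.0)
        near = normalized_distance(allele_at((15.05, 10, 10)), nuc)  # 1% out
        assert near.nd == 0.0
        with pytest.raises(ValueError):
            normalized_distance(allele_at((15.5, 10, 10)), nuc)  # 10% out

    def test_wrong_nucleus_rejected(self):
        with pytest.raises(ValueError):
            normalized_distance(allele_at((0, 0, 0), nid="other"), make_nucleus())

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        # random rotation matrix via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(size=3) * 10
        center = np.array([20.0, 20.0, 20.0])
        pos = center + rng.normal(size=3)
        nuc = make_nucleus(radius=6.0, center=tuple(center))
        nd0 = normalized_distance(allele_at(tuple(pos)), nuc).nd
        center2 = q @ center + shift
        pos2 = q @ pos + shift
        nuc2 = make_nucleus(radius=6.0, center=tuple(center2))
        nd1 = normalized_distance(allele_at(tuple(pos2)), nuc2).nd
        assert nd1 == pytest.approx(nd0, abs=1e-12)


class TestShellHistogram:
    def test_one_allele_per_bin_midpoint(self):
        nds = np.arange(10) / 10 + 0.05
        hist = shell_histogram(list(nds))
        assert hist.counts == (1,) * 10
        assert sum(hist.fractions) == pytest.approx(1.0)

    def test_upper_bin_closed_at_one(self):
        hist = shell_histogram([1.0] * 7)
        assert hist.counts[9] == 7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            shell_histogram([])

    def test_uniform_sphere_shell0_closed_form(self):
        # P(nd <= x) = 1 - (1 - x)^3 for uniform placement in the sphere
        nuclei, alleles, _ = generate_nuclei(
            NucleusPopulationSpec(n_nuclei=20_000, radial_bias=0.0), seed=5
        )
        nds = normalized_distances(alleles, {n.nucleus_id: n for n in nuclei})
        hist = shell_histogram(nds)
        assert hist.fractions[0] == pytest.approx(1 - 0.9**3, abs=0.01)

    def test_peripheral_bias_monotone_shells(self):
        nuclei, alleles, _ = generate_nuclei(
            NucleusPopulationSpec(n_nuclei=5_000, radial_bias=30.0), seed=6
        )
        nds = normalized_distances(alleles, {n.nucleus_id: n for n in nuclei})
        hist = shell_histogram(nds)
        fr = np.array(hist.fractions)
        assert fr[0] > 0.5
        assert (np.diff(fr) <= 0).all()


class TestKSCompare:
    def test_identical_samples_d_zero(self):
        s = [0.1, 0.4, 0.7]
        assert ks_compare(s, s).d == 0.0

    def test_disjoint_samples_d_one(self):
        res = ks_compare([0.1, 0.2, 0.3], [0.5, 0.6, 0.7])
        assert res.d == 1.0

    def test_frozen_small_sample_value(self):
        res = ks_compare([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        assert res.d == pytest.approx(1 / 3)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_ecdf_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(int(rng.integers(2, 20)))
        b = rng.random(int(rng.integers(2, 20)))
        assert ks_compare(a, b).d == pytest.approx(brute_force_ks(a, b))

    def test_undersized_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([0.1], [0.2, 0.3])


class TestColocalization:
    def test_all_on_surface_every_cell_contacts(self):
        nuclei = {f"n{i}": make_nucleus(nid=f"n{i}") for i in range(4)}
        alleles = [allele_at((15, 10, 10), nid=f"n{i}") for i in range(4)]
        res = lamina_colocalization(alleles, nuclei, shell_thickness=0.2)
        assert res.frac_cells == 1.0 and res.frac_alleles == 1.0

    def test_all_at_center_no_contact(self):
        nuclei = {"n1": make_nucleus()}
        alleles = [allele_at((10, 10, 10)), allele_at((10, 10, 10))]
        res = lamina_colocalization(alleles, nuclei, shell_thickness=1.0)
        assert res.frac_cells == 0.0

    def test_imaging_flags_take_precedence(self):
        nuclei = {"n1": make_nucleus()}
        # allele at center, but imaging called it lamina-associated
        alleles = [allele_at((10, 10, 10), contact=True)]
        res = lamina_colocalization(alleles, nuclei, shell_thickness=0.1)
        assert res.frac_alleles == 1.0

    def test_expressed_allele_fraction_separately_reported(self):
        nuclei = {"n1": make_nucleus()}
        alleles = [
            allele_at((15, 10, 10), expressed=True),  # surface, expressed
            allele_at((10, 10, 10), expressed=False),  # center, silent
        ]
        res = lamina_colocalization(alleles, nuclei, shell_thickness=0.2)
        assert res.frac_expressed_alleles == 1.0
        assert res.frac_alleles == 0.5

    def test_planted_contact_rate_recovered(self):
        spec = NucleusPopulationSpec(
            n_nuclei=3_000, radial_bias=10.0, lamina_shell_fraction=0.05
        )
        nuclei, alleles, truth = generate_nuclei(spec, seed=8, emit_contact_flags=False)
        res = lamina_colocalization(
            alleles, {n.nucleus_id: n for n in nuclei},
            shell_thickness=0.05, fractional=True,
        )
        assert res.frac_alleles == pytest.approx(truth["lamina_contact"].mean(), abs=1e-9)

    def test_missing_nucleus_is_error(self):
        with pytest.raises(KeyError):
            lamina_colocalization([allele_at((0, 0, 0), nid="ghost")], {})


class TestAllelicSummary:
    def test_mixed_population_fractions(self):
        alleles = []
        for i in range(10):
            n_expr = 1 if i < 6 else (2 if i < 8 else 0)
            for a in range(2):
                alleles.append(
                    AlleleRecord(f"n{i}", "miR", (0, 0, 0), expressed=a < n_expr)
                )
        s = allelic_summary(alleles)
        assert (s.n_mono, s.n_bi, s.n_silent) == (6, 2, 2)
        assert s.fractions_of_expressing_cells()["mono"] == pytest.approx(0.75)
        assert s.fractions_of_all_cells()["silent"] == pytest.approx(0.2)

    def test_all_silent(self):
        alleles = [AlleleRecord(f"n{i}", "miR", (0, 0, 0), False) for i in range(5)]
        s = allelic_summary(alleles)
        assert s.n_mono == s.n_bi == 0 and s.n_silent == 5
        assert s.fractions_of_expressing_cells() == {"mono": 0.0, "bi": 0.0}

    def test_more_than_two_alleles_rejected(self):
        alleles = [AlleleRecord("n1", "miR", (0, 0, 0), False)] * 3
        with pytest.raises(ValueError):
            allelic_summary(alleles)

    def test_independent_expression_binomial_ratio(self):
        # per-allele Bernoulli(p): E[bi/(mono+bi)] = p / (2 - p)
        p = 0.2
        nuclei, alleles, _ = generate_nuclei(
            NucleusPopulationSpec(n_nuclei=5_000, expression_probability=p), seed=9
        )
        s = allelic_summary(alleles)
        ratio = s.n_bi / (s.n_mono + s.n_bi)
        expected = p / (2 - p)
        se = np.sqrt(expected * (1 - expected) / (s.n_mono + s.n_bi))
        assert abs(ratio - expected) < 4 * se


class TestExpressedVsSilent:
    def test_positionally_restricted_expression_detected(self):
        rng = np.random.default_rng(3)
        nuclei, alleles, truth = generate_nuclei(
            NucleusPopulationSpec(n_nuclei=500), seed=10
        )
        nuc_map = {n.nucleus_id: n for n in nuclei}
        nds = normalized_distances(alleles, nuc_map)
        # re-flag expression as interior-only (nd > 0.5)
        forced = [
            type(r)(allele=AlleleRecord(
                r.allele.nucleus_id, r.allele.locus, r.allele.position,
                expressed=r.nd > 0.5), nd=r.nd, shell=r.shell)
            for r in nds
        ]
        out = expressed_vs_silent_nd(forced)
        assert out["ks"].d >= 0.5

    def test_null_expression_rarely_significant(self):
        # expression independent of position: alpha=0.05 rejections <= 6% of
        # 100 replicates
        n_sig = 0
        for rep in range(100):
            nuclei, alleles, _ = generate_nuclei(
                NucleusPopulationSpec(n_nuclei=150), seed=200 + rep
            )
            nds = normalized_distances(alleles, {n.nucleus_id: n for n in nuclei})
            out = expressed_vs_silent_nd(nds)
            n_sig += out["ks"].pvalue < 0.05
        assert n_sig <= 6


class TestAlleleTableIO:
    def test_roundtrip_bit_identical(self, tmp_path):
        nuclei, alleles, _ = generate_nuclei(NucleusPopulationSpec(n_nuclei=20), seed=1)
        nuc_map = {n.nucleus_id: n for n in nuclei}
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_allele_table(nuc_map, alleles, p1)
        nuclei2, alleles2 = read_allele_table(p1)
        write_allele_table(nuclei2, alleles2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("nucleus_id\tradius\nn1\t5.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_allele_table(p)
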