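"""Genotype containers, file round trips, codings, LD and top-list pruning."""

import numpy as np
import pytest

from episcape import (FormatError, MarkerLookupError, MarkerInfo, Phenotype,
                      SimConfig, code_exposure, ld_r2, prune_top_list,
                      read_genotypes, simulate, write_genotypes)
from episcape.datamodel import MISSING

from conftest import make_genotypes


class TestTsvReader:
    def test_small_tsv_with_na(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "sample_id\tstatus\trs1\trs2\n"
            "s1\tcase\t0\t1\n"
            "s2\tcase\t1\t2\n"
            "s3\tcontrol\t2\t0\n"
            "s4\tcontrol\tNA\t1\n"
        )
        g, ph = read_genotypes(p)
        assert g.marker_ids == ["rs1", "rs2"]
        assert (g.dosage("rs2") == [1, 2, 0, 1]).all()
        assert (g.dosages == MISSING).sum() == 1
        assert g.dosage("rs1")[3] == MISSING
        assert ph.n_cases == 2 and ph.n_controls == 2

    def test_header_dialect_enforced(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\tpheno\trs1\ns1\tcase\t0\n")
        with pytest.raises(FormatError):
            read_genotypes(p)

    def test_round_trip_exact(self, tmp_path):
        res = simulate(SimConfig(n_cases=50, n_controls=50, n_markers=50,
                                 missing_rate=0.05, seed=11))
        path = tmp_path / "sim.tsv"
        write_genotypes(res.genotypes, res.phenotype, path)
        g2, p2 = read_genotypes(path)
        assert (g2.dosages == res.genotypes.dosages).all()
        assert (p2.status == res.phenotype.status).all()
        assert g2.marker_ids == res.genotypes.marker_ids


class TestPedReader:
    def _write(self, tmp_path, ped_lines, map_lines):
        (tmp_path / "d.ped").write_text("\n".join(ped_lines) + "\n")
        (tmp_path / "d.map").write_text("\n".join(map_lines) + "\n")
        return tmp_path / "d.ped"

    def test_minor_allele_dosage(self, tmp_path):
        # G appears 3 times, A 5 times -> G minor; dosages count G
        ped = [
            "f1 s1 0 0 1 2 A A",
            "f1 s2 0 0 1 2 A G",
            "f1 s3 0 0 1 1 G G",
            "f1 s4 0 0 1 1 A A",
        ]
        path = self._write(tmp_path, ped, ["1 rs1 0 100"])
        g, ph = read_genotypes(path)
        assert list(g.dosage("rs1")) == [0, 1, 2, 0]
        assert list(ph.status) == [1, 1, 0, 0]

    def test_missing_allele_token(self, tmp_path):
        ped = ["f1 s1 0 0 1 2 0 0", "f1 s2 0 0 1 1 A G"]
        path = self._write(tmp_path, ped, ["1 rs1 0 100"])
        g, _ = read_genotypes(path)
        assert g.dosage("rs1")[0] == MISSING

    def test_monomorphic_marker_dosage_zero(self, tmp_path):
        ped = ["f1 s1 0 0 1 2 A A", "f1 s2 0 0 1 1 A A"]
        path = self._write(tmp_path, ped, ["1 rs1 0 100"])
        g, _ = read_genotypes(path)
        assert list(g.dosage("rs1")) == [0, 0]
        assert g.monomorphic()[0]

    def test_dimension_mismatch(self, tmp_path):
        ped = ["f1 s1 0 0 1 2 A A G G"]
        path = self._write(tmp_path, ped, ["1 rs1 0 100"])  # 1 marker, 2 given
        with pytest.raises(FormatError):
            read_genotypes(path)


class TestCoding:
    @pytest.mark.parametrize(
        "coding,expected",
        [("dominant", [0, 1, 1, MISSING]), ("recessive", [0, 0, 1, MISSING])],
    )
    def test_coding_definitions(self, coding, expected):
        g = make_genotypes(np.array([[0], [1], [2], [MISSING]]))
        assert list(code_exposure(g, "m0", coding)) == expected

    def test_all_heterozygote_recessive_is_zero(self):
        g = make_genotypes(np.ones((6, 1)))
        assert not code_exposure(g, "m0", "recessive").any()

    def test_unknown_marker(self):
        g = make_genotypes(np.zeros((2, 1)))
        with pytest.raises(MarkerLookupError):
            code_exposure(g, "nope", "dominant")

    def test_dominant_dominates_recessive(self, rng):
        d = rng.integers(0, 3, size=(200, 1))
        g = make_genotypes(d)
        dom = code_exposure(g, "m0", "dominant")
        rec = code_exposure(g, "m0", "recessive")
        assert (dom >= rec).all()


class TestLd:
    def test_identical_markers(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0]])
        g = make_genotypes(d)
        assert ld_r2(g, "m0", "m1") == pytest.approx(1.0)

    def test_independent_markers_near_zero(self, rng):
        d = rng.integers(0, 3, size=(5000, 2))
        g = make_genotypes(d)
        assert ld_r2(g, "m0", "m1") < 0.01

    def test_brute_force_six_samples(self):
        a = np.array([0, 1, 2, 2, 1, 0])
        b = np.array([0, 0, 2, 1, 1, 1])
        g = make_genotypes(np.column_stack([a, b]))
        # exhaustive-summation Pearson correlation
        n = 6
        sxy = (a * b).sum() - a.sum() * b.sum() / n
        sxx = (a * a).sum() - a.sum() ** 2 / n
        syy = (b * b).sum() - b.sum() ** 2 / n
        expected = sxy**2 / (sxx * syy)
        assert ld_r2(g, "m0", "m1") == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_allele_flip_invariance(self, rng):
        d = rng.integers(0, 3, size=(50, 2))
        g = make_genotypes(d)
        r_ab = ld_r2(g, "m0", "m1")
        assert ld_r2(g, "m1", "m0") == pytest.approx(r_ab)
        flipped = d.copy()
        flipped[:, 0] = 2 - flipped[:, 0]  # relabel which allele is minor
        g2 = make_genotypes(flipped)
        assert ld_r2(g2, "m0", "m1") == pytest.approx(r_ab, rel=1e-12)

    def test_constant_marker_undefined(self):
        d = np.column_stack([np.ones(5), np.arange(5) % 3])
        g = make_genotypes(d)
        assert np.isnan(ld_r2(g, "m0", "m1"))

    def test_missing_excluded_pairwise(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [MISSING, 0], [0, MISSING]])
        g = make_genotypes(d)
        assert ld_r2(g, "m0", "m1") == pytest.approx(1.0)


class TestPrune:
    def test_redundant_pair_dropped(self, rng):
        # m1dup duplicates m1: pair2 tags pair1 in both slots -> dropped
        base = rng.integers(0, 3, size=(100, 5))
        base[:, 1] = base[:, 0]  # m1 duplicated as m1dup
        g = make_genotypes(base, ["m1", "m1dup", "m2", "c", "d"])
        ranked = [("m1", "m2"), ("m1dup", "m2"), ("c", "d")]
        kept = prune_top_list(ranked, g, r2_max=0.2, k=10)
        assert kept == [("m1", "m2"), ("c", "d")]

    def test_shared_marker_with_new_partner_kept(self, rng):
        d = rng.integers(0, 3, size=(200, 3))
        g = make_genotypes(d, ["a", "b", "c"])
        ranked = [("a", "b"), ("a", "c")]
        # partner markers b and c are independent: second pair survives
        assert prune_top_list(ranked, g, r2_max=0.2, k=10) == ranked

    def test_r2max_one_is_noop(self, rng):
        d = rng.integers(0, 3, size=(50, 4))
        g = make_genotypes(d, ["a", "b", "c", "d"])
        ranked = [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")]
        assert prune_top_list(ranked, g, r2_max=1.0, k=3) == ranked[:3]

    def test_kept_list_has_no_redundant_pairs(self, rng):
        # LD block: markers 0-4 identical, 5-9 identical, 10-14 independent
        n = 300
        block1 = rng.integers(0, 3, size=(n, 1)).repeat(5, axis=1)
        block2 = rng.integers(0, 3, size=(n, 1)).repeat(5, axis=1)
        free = rng.integers(0, 3, size=(n, 5))
        g = make_genotypes(np.hstack([block1, block2, free]))
        ids = g.marker_ids
        ranked = [(ids[i], ids[j]) for i in range(15) for j in range(i + 1, 15)]
        kept = prune_top_list(ranked, g, r2_max=0.2, k=8)
        for i, (a, b) in enumerate(kept):
            for c, d in kept[i + 1:]:
                both_direct = (a == c or ld_r2(g, a, c) > 0.2) and \
                              (b == d or ld_r2(g, b, d) > 0.2)
                both_cross = (a == d or ld_r2(g, a, d) > 0.2) and \
                             (b == c or ld_r2(g, b, c) > 0.2)
                assert not (both_direct or both_cross)


def test_monomorphic_flagged():
    d = np.column_stack([np.zeros(5), np.arange(5) % 3])
    g = make_genotypes(d)
    assert list(g.monomorphic()) == [True, False]


def test_chromosome_x_rejected():
    with pytest.raises(ValueError):
        MarkerInfo("rsX", chromosome=23)


def test_phenotype_needs_both_groups():
    with pytest.raises(ValueError):
        Phenotype(np.ones(4))
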