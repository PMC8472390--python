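import numpy as np
import pytest

from runscan.genotype import MISSING
from runscan.islands import Island
from runscan.ld import (
    LDParams,
    LDRecord,
    composite_r2,
    em_r2,
    genotype_counts,
    ld_island_overlap,
    pairwise_ld,
)

from _oracles import grid_ml_r2, haplotype_count_r2
from conftest import make_gm


class TestEmR2:
    def test_perfect_coupling_r2_one(self):
        # 50 individuals all AB/AB or ab/ab: counts on the diagonal corners
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 30
        counts[2, 2] = 20
        assert em_r2(counts) == pytest.approx(1.0)

    def test_independence_r2_zero(self):
        # genotype counts exactly matching independent loci at p = q = 0.5
        # haplotype freqs multiply: n * P(g1) * P(g2) with P = (1/4, 1/2, 1/4)
        base = np.outer([1, 2, 1], [1, 2, 1])  # x 16 individuals / 16
        counts = base * 16
        assert em_r2(counts) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_locus_undefined(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 10
        counts[0, 2] = 10
        assert em_r2(counts) is None

    def test_against_grid_search_oracle_worked_example(self):
        counts = np.array([[20, 5, 1], [6, 10, 4], [2, 5, 18]])
        assert em_r2(counts) == pytest.approx(grid_ml_r2(counts), abs=1e-6)

    def test_against_grid_search_oracle_random_tables(self, rng):
        for _ in range(60):
            counts = rng.integers(0, 12, size=(3, 3))
            got = em_r2(counts)
            expected = grid_ml_r2(counts)
            if got is None or expected is None:
                assert got is None and expected is None
                continue
            assert got == pytest.approx(expected, abs=1e-6)

    def test_exact_when_no_double_heterozygotes(self, rng):
        for _ in range(40):
            counts = rng.integers(0, 15, size=(3, 3))
            counts[1, 1] = 0
            got = em_r2(counts)
            # direct haplotype counting: every genotype resolves unambiguously
            hap = np.zeros((2, 2))
            for g1 in range(3):
                for g2 in range(3):
                    c = counts[g1, g2]
                    if g1 != 1 and g2 != 1:
                        hap[g1 // 2, g2 // 2] += 2 * c
                    elif g1 == 1:
                        hap[0, g2 // 2] += c
                        hap[1, g2 // 2] += c
                    else:
                        hap[g1 // 2, 0] += c
                        hap[g1 // 2, 1] += c
            expected = haplotype_count_r2(hap)
            if got is None or expected is None:
                continue
            assert got == pytest.approx(expected, abs=1e-12)

    def test_allele_swap_invariance(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 10, size=(3, 3))
            a = em_r2(counts)
            b = em_r2(counts[::-1, :])  # swap allele labels at locus 1
            c = em_r2(counts[:, ::-1])  # swap at locus 2
            if a is None:
                assert b is None and c is None
                continue
            assert a == pytest.approx(b, abs=1e-9)
            assert a == pytest.approx(c, abs=1e-9)


class TestCompositeR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 0, 2], dtype=np.int8)
        assert composite_r2(v, v) == pytest.approx(1.0)

    def test_orthogonal_contrast_zero(self):
        a = np.array([0, 0, 2, 2], dtype=np.int8)
        b = np.array([0, 2, 0, 2], dtype=np.int8)
        assert composite_r2(a, b) == pytest.approx(0.0, abs=1e-15)

    def test_constant_vector_undefined(self):
        assert composite_r2(np.zeros(5, np.int8), np.array([0, 1, 2, 1, 0], np.int8)) is None

    def test_matches_direct_formula(self, rng):
        a = rng.integers(0, 3, 200).astype(np.int8)
        b = rng.integers(0, 3, 200).astype(np.int8)
        x, y = a.astype(float), b.astype(float)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        expected = cov**2 / (x.var() * y.var())
        assert composite_r2(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_missing_handling(self):
        a = np.array([0, 1, 2, MISSING, 2], dtype=np.int8)
        b = np.array([0, 1, 2, 2, MISSING], dtype=np.int8)
        assert composite_r2(a, b) == pytest.approx(1.0)


class TestPairwiseLd:
    def test_duplicated_snp_r2_one(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 1], dtype=np.int8)
        gm = make_gm(np.column_stack([col, col]), positions=[100_000, 200_000])
        records = pairwise_ld(gm, LDParams())
        assert len(records) == 1
        assert records[0].r2 == pytest.approx(1.0)
        assert records[0].distance_bp == 100_000

    def test_distance_cap_excludes_far_pairs(self):
        col = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        gm = make_gm(np.column_stack([col, col]), positions=[100_000, 1_300_000])
        assert pairwise_ld(gm, LDParams(max_pair_distance_bp=1_000_000)) == []

    def test_matches_bruteforce_all_pairs(self, rng):
        dosage = rng.integers(0, 3, size=(40, 12)).astype(np.int8)
        gm = make_gm(dosage, spacing_bp=100_000)
        params = LDParams(r2_report_min=0.0, max_pair_distance_bp=10_000_000)
        records = pairwise_ld(gm, params)
        got = {(r.pos_a_bp, r.pos_b_bp): r.r2 for r in records}
        pos = gm.positions
        for j in range(12):
            for k in range(j + 1, 12):
                r2 = em_r2(genotype_counts(dosage[:, j], dosage[:, k]))
                key = (int(pos[j]), int(pos[k]))
                if r2 is None or r2 <= 0.0:
                    assert key not in got
                else:
                    assert got[key] == pytest.approx(r2)


class TestLdIslandOverlap:
    def rec(self, a, b, r2, pop="POP", chrom="1"):
        return LDRecord(pop, chrom, a, b, r2)

    def isl(self, s, e, pop="POP", chrom="1"):
        return Island(pop, chrom, s, e, 10, "ROH", 0.5)

    def test_qualifying_overlap_reported(self):
        out = ld_island_overlap(
            [self.rec(1_000_000, 1_600_000, 0.95)],
            [self.isl(1_200_000, 1_400_000)],
            min_pair_distance_bp=500_000,
            r2_min=0.9,
        )
        assert len(out) == 1

    def test_distance_filter_excludes(self):
        out = ld_island_overlap(
            [self.rec(1_000_000, 1_600_000, 0.95)],
            [self.isl(1_200_000, 1_400_000)],
            min_pair_distance_bp=700_000,
            r2_min=0.9,
        )
        assert len(out) == 0

    def test_matches_exhaustive_double_loop(self, rng):
        records = [
            self.rec(int(a), int(a + d), float(r))
            for a, d, r in zip(
                rng.integers(0, 5_000_000, 50),
                rng.integers(1, 2_000_000, 50),
                rng.random(50),
            )
        ]
        islands = [
            self.isl(int(s), int(s + w))
            for s, w in zip(rng.integers(0, 6_000_000, 5), rng.integers(0, 800_000, 5))
        ]
        out = ld_island_overlap(records, islands, 250_000, 0.3)
        expected = 0
        for r in records:
            for i in islands:
                if (
                    r.distance_bp >= 250_000
                    and r.r2 > 0.3
                    and r.pos_a_bp <= i.end_bp
                    and i.start_bp <= r.pos_b_bp
                ):
                    expected += 1
        assert len(out) == expected

    def test_filter_monotonicity(self, rng):
        records = [
            self.rec(int(a), int(a + d), float(r))
            for a, d, r in zip(
                rng.integers(0, 5_000_000, 80),
                rng.integers(1, 2_000_000, 80),
                rng.random(80),
            )
        ]
        islands = [self.isl(1_000_000, 3_000_000)]
        sizes = [
            len(ld_island_overlap(records, islands, d, r))
            for d, r in [(0, 0.2), (250_000, 0.2), (250_000, 0.5), (500_000, 0.9)]
        ]
        assert sizes == sorted(sizes, reverse=True)
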