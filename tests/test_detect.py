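import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from runscan.detect import (
    HRR,
    ROH,
    RunParams,
    assemble_runs,
    detect_runs,
    hrr_scenario_params,
    roh_default_params,
    scenario_sweep,
    snp_membership,
    swap_mode_dosage,
    window_scan,
)
from runscan.genotype import MISSING, SnpRecord

from _oracles import brute_detect_vector, brute_window_scan
from conftest import make_gm


def snps_at(positions, chrom="1"):
    return [SnpRecord(chrom, f"s{k}", int(p)) for k, p in enumerate(positions)]


ROH_P = roh_default_params()


class TestWindowScan:
    def test_all_homozygous_proportion_one(self):
        props = window_scan(np.zeros(30, dtype=np.int8), ROH_P)
        assert np.allclose(props, 1.0)

    def test_all_heterozygous_proportion_zero(self):
        props = window_scan(np.ones(30, dtype=np.int8), ROH_P)
        assert np.allclose(props, 0.0)

    def test_matches_bruteforce_on_het_spiked_vector(self):
        vec = np.zeros(50, dtype=np.int8)
        vec[10] = 1
        vec[14] = 1
        assert np.allclose(window_scan(vec, ROH_P), brute_window_scan(vec, ROH_P))

    def test_short_chromosome_single_truncated_window(self):
        vec = np.zeros(5, dtype=np.int8)
        props = window_scan(vec, ROH_P)  # n < window: one truncated window
        assert np.allclose(props, 1.0)
        vec[2] = 1
        vec[3] = 1
        assert np.allclose(window_scan(vec, ROH_P), 0.0)

    def test_empty_vector(self):
        assert window_scan(np.zeros(0, dtype=np.int8), ROH_P).size == 0


class TestMembership:
    @pytest.mark.parametrize(
        "prop,expected", [(1.0, True), (0.0, False), (0.05, False), (0.051, True)]
    )
    def test_strict_threshold(self, prop, expected):
        assert snp_membership(np.array([prop]), ROH_P)[0] == expected


class TestAssembleRuns:
    def test_clean_run_kept_with_exact_coordinates(self):
        pos = [50_000 * (k + 1) for k in range(100)]
        vec = np.zeros(100, dtype=np.int8)
        runs = assemble_runs(np.ones(100, bool), vec, snps_at(pos), ROH_P, "i", "p")
        assert len(runs) == 1
        r = runs[0]
        assert (r.start_bp, r.end_bp, r.n_snps) == (50_000, 5_000_000, 100)
        assert r.length_bp == 4_950_000

    def test_min_length_rejection(self):
        pos = [20_000 * (k + 1) for k in range(30)]  # span 580 kb < 1 Mb
        runs = assemble_runs(np.ones(30, bool), np.zeros(30, np.int8), snps_at(pos), ROH_P)
        assert runs == []

    def test_density_rejection(self):
        pos = [100_000 * (k + 1) for k in range(20)]  # 1.9 Mb / 20 SNPs = 95 kb/SNP
        runs = assemble_runs(np.ones(20, bool), np.zeros(20, np.int8), snps_at(pos), ROH_P)
        assert runs == []

    def test_gap_splits_candidates_evaluated_separately(self):
        # 60 SNPs at 50 kb with a single 300 kb internal gap after SNP 29
        pos = [50_000 * (k + 1) for k in range(30)]
        pos += [pos[-1] + 300_000 + 50_000 * k for k in range(30)]
        runs = assemble_runs(np.ones(60, bool), np.zeros(60, np.int8), snps_at(pos), ROH_P)
        assert len(runs) == 2
        assert runs[0].n_snps == 30 and runs[1].n_snps == 30
        assert runs[0].end_bp == pos[29] and runs[1].start_bp == pos[30]

    def test_run_level_opposite_limit(self):
        pos = [50_000 * (k + 1) for k in range(40)]
        vec = np.zeros(40, dtype=np.int8)
        vec[10] = 1
        vec[20] = 1  # 2 hets > max 1 in run
        runs = assemble_runs(np.ones(40, bool), vec, snps_at(pos), ROH_P)
        assert runs == []


class TestDetectRuns:
    def test_all_heterozygous_panel_no_roh(self):
        gm = make_gm(np.ones((3, 60), dtype=np.int8))
        assert detect_runs(gm, ROH_P) == []

    def test_all_heterozygous_panel_full_hrr(self):
        gm = make_gm(np.ones((2, 60), dtype=np.int8))  # 60 SNPs x 50 kb
        runs = detect_runs(gm, hrr_scenario_params()["2"])
        assert len(runs) == 2
        for r in runs:
            assert (r.start_bp, r.end_bp) == (50_000, 3_000_000)

    def test_mode_symmetry(self, rng):
        dosage = rng.integers(-1, 3, size=(10, 120)).astype(np.int8)
        gm = make_gm(dosage, spacing_bp=30_000)
        params_roh = RunParams(
            mode=ROH,
            window_snps=10,
            min_snps_in_run=10,
            min_length_bp=250_000,
            max_gap_bp=1_000_000,
            max_opposite_in_window=3,
            max_missing_in_window=2,
            max_opposite_in_run=3,
            max_missing_in_run=2,
        )
        params_hrr = RunParams(**{**params_roh.__dict__, "mode": HRR})
        swapped = make_gm(swap_mode_dosage(dosage), spacing_bp=30_000)
        runs_a = detect_runs(gm, params_roh)
        runs_b = detect_runs(swapped, params_hrr)
        coords_a = [(r.individual_id, r.chromosome, r.start_bp, r.end_bp) for r in runs_a]
        coords_b = [(r.individual_id, r.chromosome, r.start_bp, r.end_bp) for r in runs_b]
        assert coords_a == coords_b

    def test_runs_sorted_and_nonoverlapping(self, rng):
        dosage = rng.integers(0, 3, size=(20, 300)).astype(np.int8)
        gm = make_gm(dosage, spacing_bp=20_000)
        params = hrr_scenario_params()["3"]
        runs = detect_runs(gm, params)
        per_key = {}
        for r in runs:
            per_key.setdefault((r.individual_id, r.chromosome), []).append(r)
        for rs in per_key.values():
            for a, b in zip(rs, rs[1:]):
                assert a.end_bp < b.start_bp  # sorted and disjoint


@st.composite
def vector_and_params(draw):
    n = draw(st.integers(min_value=1, max_value=120))
    vec = draw(
        st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=n, max_size=n)
    )
    gaps = draw(
        st.lists(st.integers(min_value=1, max_value=400_000), min_size=n, max_size=n)
    )
    positions = np.cumsum(gaps)
    mode = draw(st.sampled_from([ROH, HRR]))
    params = RunParams(
        mode=mode,
        window_snps=draw(st.integers(2, 25)),
        min_snps_in_run=draw(st.integers(1, 25)),
        min_length_bp=draw(st.sampled_from([0, 10_000, 250_000, 1_000_000])),
        min_density_kb_per_snp=draw(st.sampled_from([30.0, 70.0, 500.0])),
        max_gap_bp=draw(st.sampled_from([100_000, 250_000, 1_000_000])),
        max_opposite_in_window=draw(st.integers(0, 3)),
        max_missing_in_window=draw(st.integers(0, 2)),
        max_opposite_in_run=draw(st.integers(0, 3)),
        max_missing_in_run=draw(st.integers(0, 2)),
        window_threshold=draw(st.sampled_from([0.0, 0.05, 0.5])),
    )
    return np.array(vec, dtype=np.int8), positions, params


@given(vector_and_params())
@settings(max_examples=150, deadline=None, derandomize=True)
def test_detector_equals_bruteforce_oracle(case):
    """The vectorized detector reproduces a naive re-enumeration exactly."""
    vec, positions, params = case
    snps = snps_at(positions)
    props = window_scan(vec, params)
    member = snp_membership(props, params)
    got = [
        (r.start_bp, r.end_bp, r.n_snps, r.n_opposite, r.n_missing)
        for r in assemble_runs(member, vec, snps, params)
    ]
    assert got == brute_detect_vector(list(vec), list(positions), params)
    assert np.allclose(props, brute_window_scan(list(vec), params))


@given(vector_and_params())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_no_run_violates_its_constraints(case):
    vec, positions, params = case
    snps = snps_at(positions)
    member = snp_membership(window_scan(vec, params), params)
    for r in assemble_runs(member, vec, snps, params):
        assert r.n_snps >= params.min_snps_in_run
        assert r.length_bp >= params.min_length_bp
        assert r.length_bp / r.n_snps <= params.min_density_kb_per_snp * 1000
        assert r.n_opposite <= params.max_opposite_in_run
        assert r.n_missing <= params.max_missing_in_run


class TestScenarios:
    def test_standard_scenario_parameters(self):
        s = hrr_scenario_params()
        assert len(s) == 9
        one, five, nine = s["1"], s["5"], s["9"]
        assert (one.window_snps, one.min_snps_in_run) == (10, 10)
        assert one.min_length_bp == 400_000
        assert one.max_gap_bp == 1_000_000
        assert (one.max_opposite_in_run, one.max_missing_in_run) == (3, 2)
        assert five.min_length_bp == 250_000
        assert (five.max_opposite_in_run, five.max_opposite_in_window) == (1, 1)
        assert five.max_missing_in_run == 2
        assert (nine.window_snps, nine.min_length_bp) == (5, 10_000)
        assert all(p.min_density_kb_per_snp == 70.0 for p in s.values())
        assert all(p.mode == HRR for p in s.values())

    def test_min_length_relaxation_monotone(self, rng):
        dosage = rng.integers(0, 3, size=(15, 400)).astype(np.int8)
        gm = make_gm(dosage, spacing_bp=30_000)
        s = hrr_scenario_params()
        sweep = {
            x.scenario_id: x.n_runs_total
            for x in scenario_sweep(gm, [(k, s[k]) for k in ("1", "2", "3")])
        }
        assert sweep["3"] >= sweep["2"] >= sweep["1"]

    def test_duplicate_ids_rejected(self, rng):
        gm = make_gm(np.zeros((1, 30), dtype=np.int8))
        p = hrr_scenario_params()["2"]
        with pytest.raises(ValueError, match="duplicate"):
            scenario_sweep(gm, [("a", p), ("a", p)])
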