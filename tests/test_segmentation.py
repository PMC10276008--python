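"""Segment grids, call/event classification, per-patient bin states."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cnbuffer import (
    GenomeBuild,
    build_grid,
    classify_call,
    classify_event,
    patient_bin_states,
    states_matrix,
)
from conftest import brute_force_states, random_toy_cohort

MB = 1_000_000


@pytest.fixture
def build():
    return GenomeBuild({"chr1": 100 * MB, "chr2": 80 * MB},
                       {"chr1": 60 * MB, "chr2": 40 * MB})


class TestBuildGrid:
    def test_fixed_tiling_with_short_last_bin(self, build):
        grid = build_grid(build, "fixed", bin_size=36 * MB)
        chr1 = grid.bins[grid.bins["chrom"] == "chr1"]
        assert (chr1["end"] - chr1["start"]).tolist() == [36 * MB, 36 * MB, 28 * MB]

    def test_chromosome_scale_one_bin_per_autosome(self, build):
        grid = build_grid(build, "chromosome")
        assert grid.bins["bin_id"].tolist() == ["chr1", "chr2"]
        assert grid.bins["end"].tolist() == [100 * MB, 80 * MB]

    def test_arm_scale_splits_at_boundary(self, build):
        grid = build_grid(build, "arm")
        chr1 = grid.bins[grid.bins["chrom"] == "chr1"]
        assert chr1[["start", "end"]].to_numpy().tolist() == [
            [0, 60 * MB], [60 * MB, 100 * MB]]

    def test_sex_chromosomes_excluded(self):
        b = GenomeBuild({"chr1": 10 * MB, "chrX": 10 * MB},
                        {"chr1": 5 * MB, "chrX": 5 * MB})
        grid = build_grid(b, "chromosome")
        assert grid.bins["chrom"].tolist() == ["chr1"]

    def test_invalid_bin_size(self, build):
        with pytest.raises(ValueError):
            build_grid(build, "fixed", bin_size=0)

    def test_deterministic(self, build):
        g1 = build_grid(build, "fixed", bin_size=7 * MB)
        g2 = build_grid(build, "fixed", bin_size=7 * MB)
        pd.testing.assert_frame_equal(g1.bins, g2.bins)


class TestClassifyCall:
    @pytest.mark.parametrize("mean,expected", [
        (0.30, "amplified"),
        (-0.25, "deleted"),
        (0.20, "neutral"),   # boundary values are interior, not events
        (-0.20, "neutral"),
        (0.0, "neutral"),
    ])
    def test_cutoff_semantics(self, mean, expected):
        assert classify_call(mean) == expected

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_call(0.5, amp_cut=0.0)


class TestClassifyEvent:
    def test_whole_chromosome(self, build):
        assert classify_event("chr1", 0, 95 * MB, build) == "chromosomal"

    def test_majority_of_arm(self, build):
        # 55% of the 60 Mbp p arm
        assert classify_event("chr1", 0, 33 * MB, build) == "arm"

    def test_small_event_is_focal(self, build):
        assert classify_event("chr1", 62 * MB, 66 * MB, build) == "focal"

    def test_centromere_spanning_uses_larger_overlap_arm(self, build):
        # 25 Mbp on p (60 Mbp arm) + 4 on q: tested on p, 29/60 < 50% -> focal
        assert classify_event("chr1", 35 * MB, 64 * MB, build) == "focal"
        # 10 on p + 21 on q: tested on q (larger overlap), 31/40 >= 50% -> arm
        assert classify_event("chr1", 50 * MB, 81 * MB, build) == "arm"

    def test_invariant_to_chromosome_naming(self):
        b1 = GenomeBuild({"a": 100, "b": 100}, {"a": 50, "b": 50})
        b2 = GenomeBuild({"b": 100, "a": 100}, {"b": 50, "a": 50})
        assert classify_event("a", 0, 95, b1) == classify_event("a", 0, 95, b2)


def _call(patient, chrom, start, end, mean):
    return dict(patient=patient, chrom=chrom, start=start, end=end,
                segment_mean=mean)


class TestPatientBinStates:
    def test_full_overlap_is_amplified(self, build):
        grid = build_grid(build, "fixed", bin_size=50 * MB)
        calls = pd.DataFrame([_call("p1", "chr1", 0, 50 * MB, 0.5)])
        states = patient_bin_states(calls, grid, ["p1"])
        assert states.set_index("bin_id").loc["chr1:0", "state"] == "A"

    def test_no_calls_means_all_neutral(self, build):
        grid = build_grid(build, "fixed", bin_size=50 * MB)
        states = patient_bin_states(pd.DataFrame(
            columns=["patient", "chrom", "start", "end", "segment_mean"]),
            grid, ["p1", "p2"])
        assert (states["state"] == "N").all()

    def test_minor_overlap_stays_neutral(self, build):
        grid = build_grid(build, "fixed", bin_size=50 * MB)
        calls = pd.DataFrame([_call("p1", "chr1", 0, 5 * MB, 0.5)])  # 10% of bin
        states = patient_bin_states(calls, grid, ["p1"], overlap_frac=0.5)
        assert states.set_index("bin_id").loc["chr1:0", "state"] == "N"

    def test_union_of_same_state_calls_counts_once(self, build):
        grid = build_grid(build, "fixed", bin_size=50 * MB)
        # two overlapping amplified calls jointly cover 30 of 50 Mbp
        calls = pd.DataFrame([
            _call("p1", "chr1", 0, 20 * MB, 0.5),
            _call("p1", "chr1", 10 * MB, 30 * MB, 0.6),
        ])
        states = patient_bin_states(calls, grid, ["p1"], overlap_frac=0.5)
        assert states.set_index("bin_id").loc["chr1:0", "state"] == "A"
        states = patient_bin_states(calls, grid, ["p1"], overlap_frac=0.7)
        assert states.set_index("bin_id").loc["chr1:0", "state"] == "N"

    def test_larger_coverage_wins_between_states(self, build):
        grid = build_grid(build, "fixed", bin_size=50 * MB)
        calls = pd.DataFrame([
            _call("p1", "chr1", 0, 30 * MB, 0.5),
            _call("p1", "chr1", 30 * MB, 50 * MB + 25 * MB, -0.5),
        ])
        states = patient_bin_states(calls, grid, ["p1"], overlap_frac=0.3)
        assert states.set_index("bin_id").loc["chr1:0", "state"] == "A"

    def test_event_filter_restricts_call_classes(self, build):
        grid = build_grid(build, "fixed", bin_size=50 * MB)
        calls = pd.DataFrame([_call("p1", "chr1", 0, 95 * MB, 0.5)])
        states = patient_bin_states(calls, grid, ["p1"], build=build,
                                    event_filter=["focal"])
        assert (states["state"] == "N").all()
        states = patient_bin_states(calls, grid, ["p1"], build=build,
                                    event_filter=["chromosomal"])
        assert (states.set_index("bin_id").loc["chr1:0", "state"]) == "A"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_per_base_oracle(self, seed):
        build, grid, patients, cna, muts, cb = random_toy_cohort(seed)
        states = patient_bin_states(cna, grid, patients)
        expected = brute_force_states(cna, patients, grid.bins)
        got = {(r.patient, r.bin_id): r.state for r in states.itertuples()}
        assert got == expected

    @given(st.integers(0, 10_000))
    def test_partition_invariant(self, seed):
        build, grid, patients, cna, muts, cb = random_toy_cohort(seed)
        states = patient_bin_states(cna, grid, patients)
        counts = states.groupby("bin_id")["state"].count()
        assert (counts == len(patients)).all()

    def test_states_matrix_shape(self, build):
        grid = build_grid(build, "fixed", bin_size=50 * MB)
        states = patient_bin_states(pd.DataFrame(
            columns=["patient", "chrom", "start", "end", "segment_mean"]),
            grid, ["p1", "p2"])
        mat = states_matrix(states)
        assert mat.shape == (len(grid.bins), 2)
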