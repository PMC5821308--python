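"""Origin calling: smoothing, peak detection, efficiency, merging, matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriscope import (
    OriginCall,
    OriginSet,
    TruthOriginMap,
    assign_efficiency,
    augment_origin_list,
    call_origins,
    detect_candidate_peaks,
    efficiencies_at_fixed_list,
    iterative_smooth,
    make_genome,
    match_origins,
    merge_close_origins,
    normalize_condition,
    probe_ratio,
    simulate_hu_pair,
    window_geomean,
)
from oriscope.calling import Candidate


def brute_force_peaks(values, threshold):
    """Oracle: strict local maxima (plateaus -> central probe, left of center
    for even widths) above the threshold, scanning every probe."""
    peaks = []
    n = len(values)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if j < n - 1 and values[i] > values[i - 1] and values[i] > values[j + 1]:
            apex = (i + j) // 2
            if values[apex] > threshold:
                peaks.append(apex)
        i = j + 1
    return peaks


class TestIterativeSmooth:
    def test_constant_track_is_fixed_point(self, make_track):
        t = make_track([1.2] * 30)
        assert np.allclose(iterative_smooth(t, 10).values["chr1"], 1.2)

    def test_spike_apex_erodes_under_repeated_smoothing(self, make_track):
        # direct repeated application: the spike spreads into a plateau whose
        # apex never rises and is strictly lower after several rounds
        vals = np.ones(41)
        vals[20] = 2.0
        t = make_track(vals)
        heights = []
        for r in range(6):
            t = iterative_smooth(t, 1)
            heights.append(t.values["chr1"].max())
        assert all(a >= b for a, b in zip(heights, heights[1:]))
        assert heights[-1] < heights[0] < 2.0

    def test_zero_rounds_returns_input(self, make_track):
        t = make_track([1.0, 1.5, 1.1])
        out = iterative_smooth(t, 0)
        assert np.array_equal(out.values["chr1"], t.values["chr1"])

    def test_ten_rounds_equals_composition(self, make_track):
        rng = np.random.default_rng(3)
        t = make_track(rng.lognormal(0, 0.1, 60))
        direct = iterative_smooth(t, 10)
        composed = t
        for _ in range(10):
            composed = window_geomean(composed)
        assert np.allclose(direct.values["chr1"], composed.values["chr1"])


class TestDetectCandidatePeaks:
    def test_flat_track_has_no_candidates(self, make_track):
        assert detect_candidate_peaks(make_track([1.0] * 50)) == []

    def test_single_bump_yields_one_candidate_at_apex(self, make_track):
        vals = np.ones(60)
        vals[25:30] = [1.1, 1.25, 1.3, 1.25, 1.1]
        t = make_track(vals)
        cands = detect_candidate_peaks(t)
        oracle = brute_force_peaks(vals, 1.05)
        assert [c.index for c in cands] == oracle == [27]

    def test_bump_below_threshold_ignored(self, make_track):
        vals = np.ones(30)
        vals[14:17] = [1.02, 1.04, 1.02]
        assert detect_candidate_peaks(make_track(vals)) == []

    def test_plateau_resolved_to_central_probe(self, make_track):
        vals = np.ones(30)
        vals[10:14] = 1.3  # even plateau of 4 probes -> left-of-center
        cands = detect_candidate_peaks(make_track(vals))
        assert [c.index for c in cands] == [11]

    def test_secondary_maximum_below_prominence_filtered(self, make_track):
        # a noise-split peak top: the secondary maximum rises only 0.004 over
        # the valley separating it from the main apex, so it is not a
        # separate candidate
        vals = np.ones(40)
        vals[14:23] = [1.1, 1.2, 1.3, 1.295, 1.299, 1.295, 1.2, 1.1, 1.05]
        cands = detect_candidate_peaks(make_track(vals), prominence=0.01)
        assert [c.index for c in cands] == [16]


class TestAssignEfficiency:
    def test_conversion_and_cutoff(self, make_track):
        vals = np.ones(30)
        vals[15] = 1.45
        t = make_track(vals)
        cand = [Candidate("chr1", 15, int(t.grid.positions["chr1"][15]), 1.2)]
        oset = assign_efficiency(cand, t)
        assert len(oset) == 1
        assert oset[0].efficiency == pytest.approx(45.0)

    def test_below_cutoff_discarded(self, make_track):
        vals = np.ones(30)
        vals[15] = 1.08
        t = make_track(vals)
        cand = [Candidate("chr1", 15, int(t.grid.positions["chr1"][15]), 1.06)]
        assert len(assign_efficiency(cand, t)) == 0

    def test_maximum_taken_within_two_probes(self, make_track):
        vals = np.ones(30)
        vals[13] = 1.5  # two probes left of the apex candidate
        vals[15] = 1.2
        t = make_track(vals)
        cand = [Candidate("chr1", 15, int(t.grid.positions["chr1"][15]), 1.18)]
        oset = assign_efficiency(cand, t)
        assert oset[0].efficiency == pytest.approx(50.0)


def _oset(positions, copy_numbers, chrom="chr1"):
    return OriginSet(
        [
            OriginCall(chrom, p, cn, (cn - 1) * 100)
            for p, cn in zip(positions, copy_numbers)
        ]
    )


class TestMergeCloseOrigins:
    def test_close_pair_keeps_higher_copy_number(self):
        merged = merge_close_origins(_oset([100_000, 103_000], [1.3, 1.2]))
        assert len(merged) == 1
        assert merged[0].position == 100_000

    def test_distant_pair_kept(self):
        merged = merge_close_origins(_oset([100_000, 106_000], [1.3, 1.2]))
        assert len(merged) == 2

    def test_chain_collapses_to_strongest(self):
        merged = merge_close_origins(_oset([1000, 5000, 9000], [1.2, 1.5, 1.2]))
        assert len(merged) == 1
        assert merged[0].position == 5000

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1000, 500_000, 250), 40, replace=False))
        oset = _oset(pos, rng.uniform(1.1, 1.6, 40))
        once = merge_close_origins(oset)
        twice = merge_close_origins(once)
        assert [c.position for c in once] == [c.position for c in twice]
        d = np.diff([c.position for c in once])
        assert np.all(d >= 5000)


class TestMatchOrigins:
    def test_identical_sets_fully_matched_at_zero(self):
        a = _oset([10_000, 50_000, 90_000], [1.2, 1.3, 1.4])
        res = match_origins(a, a)
        assert res.n_matched == 3
        assert all(d == 0 for _, _, d in res.pairs)
        assert not res.a_only and not res.b_only

    @pytest.mark.parametrize("offset,matched", [(4900, 1), (5100, 0)])
    def test_five_kb_boundary(self, offset, matched):
        a = _oset([100_000], [1.3])
        b = _oset([100_000 + offset], [1.3])
        assert match_origins(a, b).n_matched == matched

    def test_interleaved_matches_exhaustive_minimal_assignment(self):
        a = _oset([100_000, 200_000, 300_000], [1.2, 1.3, 1.4])
        b = _oset([102_000, 304_000], [1.2, 1.3])
        res = match_origins(a, b)
        # oracle: enumerate all one-to-one assignments, keep max cardinality
        # with minimal total distance among pairs within tolerance
        best = None
        for perm in itertools.permutations(range(3), 2):
            pairs = [
                (i, j, abs(a[i].position - b[j].position))
                for j, i in enumerate(perm)
                if abs(a[i].position - b[j].position) < 5000
            ]
            key = (-len(pairs), sum(d for *_, d in pairs))
            if best is None or key < best[0]:
                best = (key, pairs)
        got = sorted((a.calls.index(pa), b.calls.index(pb), d) for pa, pb, d in res.pairs)
        assert got == sorted(best[1])

    def test_greedy_equals_bruteforce_rederivation_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            na, nb = rng.integers(1, 6, 2)
            a = _oset(np.sort(rng.choice(np.arange(1, 60) * 1000, na, replace=False)), [1.2] * na)
            b = _oset(np.sort(rng.choice(np.arange(1, 60) * 1000, nb, replace=False)), [1.2] * nb)
            res = match_origins(a, b, tol=5000)
            # literal greedy re-derivation with an O(n^3) loop
            cand = sorted(
                (abs(x.position - y.position), i, j)
                for i, x in enumerate(a)
                for j, y in enumerate(b)
                if abs(x.position - y.position) < 5000
            )
            ua, ub, oracle = set(), set(), []
            for d, i, j in cand:
                if i not in ua and j not in ub:
                    ua.add(i)
                    ub.add(j)
                    oracle.append((i, j, d))
            got = [(a.calls.index(pa), b.calls.index(pb), d) for pa, pb, d in res.pairs]
            assert sorted(got) == sorted(oracle)


class TestFixedListEfficiencies:
    def test_spike_at_origin_probe(self, make_track):
        vals = np.ones(30)
        vals[15] = 1.5
        t = make_track(vals)
        origins = _oset([int(t.grid.positions["chr1"][15])], [1.5])
        assert efficiencies_at_fixed_list(origins, t)[0] == pytest.approx(50.0)

    def test_spike_two_probes_away_captured(self, make_track):
        vals = np.ones(30)
        vals[13] = 1.5
        vals[15] = 1.2
        t = make_track(vals)
        origins = _oset([int(t.grid.positions["chr1"][15])], [1.2])
        assert efficiencies_at_fixed_list(origins, t)[0] == pytest.approx(50.0)

    def test_spike_three_probes_away_excluded(self, make_track):
        vals = np.ones(30)
        vals[12] = 1.5
        vals[15] = 1.2
        t = make_track(vals)
        origins = _oset([int(t.grid.positions["chr1"][15])], [1.2])
        # oracle: window membership is probes 13..17, which excludes probe 12
        assert efficiencies_at_fixed_list(origins, t)[0] == pytest.approx(20.0)


def _truth(grid, positions, efficiencies):
    name = grid.chrom_names[0]
    return TruthOriginMap(
        pd.DataFrame(
            {"chrom": name, "position": positions, "efficiency": efficiencies, "domain": ""}
        )
    )


class TestAugmentOriginList:
    def test_no_new_peaks_leaves_base_unchanged(self, make_track):
        base = _oset([100_000], [1.4])
        flat = make_track(np.ones(800))
        out = augment_origin_list(base, flat)
        assert [c.position for c in out] == [100_000]

    def test_isolated_new_peak_appended_with_provenance(self):
        grid = make_genome([500_000], 250, names=["chr1"])
        truth = _truth(grid, [250_000], [20.0])
        pair = simulate_hu_pair(truth, grid, noise_cv=0, baseline_offset=0, seed=0)
        track, _ = normalize_condition([pair])
        base = _oset([50_000], [1.4])
        out = augment_origin_list(base, track)
        assert len(out) == 2
        added = [c for c in out if c.provenance == "supplemental-list"]
        assert len(added) == 1
        assert abs(added[0].position - 250_000) < 500

    def test_union_recovers_all_origins_when_some_are_silent(self):
        grid = make_genome([1_500_000], 250, names=["chr1"])
        positions = list(range(100_000, 1_100_000, 100_000))  # 10 origins
        eff_a = [30, 30, 5, 30, 5, 30, 30, 5, 30, 30]  # 3 silent in condition A
        eff_b = [30.0] * 10
        pair_a = simulate_hu_pair(_truth(grid, positions, eff_a), grid, 0, seed=0, baseline_offset=0)
        pair_b = simulate_hu_pair(_truth(grid, positions, eff_b), grid, 0, seed=0, baseline_offset=0)
        track_a, _ = normalize_condition([pair_a])
        track_b, _ = normalize_condition([pair_b])
        base = call_origins(track_a)
        assert len(base) == 7
        union = augment_origin_list(base, track_b)
        assert len(union) == 10
        for want, got in zip(positions, union):
            assert abs(got.position - want) <= 250


class TestPipelineRecovery:
    def test_noiseless_roundtrip_recovers_positions_and_efficiencies(self):
        from oriscope import place_origins

        grid = make_genome([2_000_000], 250, names=["chr1"])
        truth = place_origins(grid, 25, "uniform", min_spacing=20_000, seed=8)
        pair = simulate_hu_pair(truth, grid, noise_cv=0, baseline_offset=0.12, seed=0)
        track, report = normalize_condition([pair])
        assert report.factor == pytest.approx(0.12, abs=1e-9)
        called = call_origins(track)
        strong = truth.origins[truth.origins.efficiency >= 10.0]
        assert len(called) == len(strong)
        for want, got in zip(strong.itertuples(), called):
            assert abs(got.position - want.position) <= 125  # half probe spacing
            assert got.efficiency == pytest.approx(want.efficiency, abs=1.0)

    def test_recovered_efficiencies_scale_with_truth(self):
        from oriscope import place_origins

        grid = make_genome([1_000_000], 250, names=["chr1"])
        truth = place_origins(grid, 12, "uniform", min_spacing=30_000, seed=5)
        means = []
        for f in (1.0, 0.8):
            pair = simulate_hu_pair(truth.scaled(f), grid, noise_cv=0, baseline_offset=0, seed=0)
            track, _ = normalize_condition([pair])
            eff = efficiencies_at_fixed_list(
                _oset(truth.origins.position.astype(int).tolist(), [1.2] * len(truth)), track
            )
            means.append(np.nanmean(eff))
        assert means[1] == pytest.approx(0.8 * means[0], rel=1e-6)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 1000))
    def test_merge_output_satisfies_spacing_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        pos = np.sort(rng.choice(np.arange(1, 400) * 500, n, replace=False))
        merged = merge_close_origins(_oset(pos.tolist(), rng.uniform(1.1, 1.8, n).tolist()))
        d = np.diff([c.position for c in merged])
        assert np.all(d >= 5000)
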