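import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breakscape as bs
from breakscape.simulate import expected_log2


class TestProbeGrid:
    def test_count_matches_spacing(self):
        g = bs.GenomeModel({"chr1": 1_000_000}, "one")
        grid = bs.make_probe_grid(g, 10_000, seed=1)
        start, end = grid["chr1"]
        assert abs(len(start) - 100) <= 5
        assert np.all(np.diff(start) > 0)
        assert np.all(end > start)
        assert start.min() >= 0 and end.max() <= 1_000_000

    def test_same_seed_same_grid(self, toy_genome):
        a = bs.make_probe_grid(toy_genome, 20_000, seed=9)
        b = bs.make_probe_grid(toy_genome, 20_000, seed=9)
        for chrom in toy_genome.chromosomes:
            np.testing.assert_array_equal(a[chrom][0], b[chrom][0])

    def test_hg19_at_244k_density(self):
        g = bs.hg19(include_y=True)
        grid = bs.make_probe_grid(g, 12_700, seed=0)
        total = sum(len(s) for s, _ in grid.values())
        assert abs(total - 244_000) / 244_000 < 0.02

    def test_tiny_chromosome_floors_at_two_probes(self):
        g = bs.GenomeModel({"chrS": 5_000}, "tiny")
        grid = bs.make_probe_grid(g, 100_000, seed=0)
        assert len(grid["chrS"][0]) == 2


class TestStepwiseCna:
    def test_no_events_no_breakpoints(self, toy_genome):
        truth = bs.plant_stepwise_cna(toy_genome, 0, seed=1)
        assert truth.bpi(0.0) == 0 and truth.events == {}

    def test_single_gain_two_breakpoints(self, toy_genome):
        truth = bs.GroundTruth(toy_genome)
        truth.add_event("chrA", 1_000_000, 2_000_000, 4)
        bps = truth.true_breakpoints("chrA")
        assert len(bps) == 2
        assert [pos for pos, _ in bps] == [1_000_000, 2_000_000]
        assert [round(d, 3) for _, d in bps] == [1.0, -1.0]

    def test_nested_amplicon_four_breakpoints(self, toy_genome):
        truth = bs.GroundTruth(toy_genome)
        truth.add_event("chrA", 1_000_000, 2_000_000, 3)
        truth.add_event("chrA", 2_000_000, 3_000_000, 5)
        truth.add_event("chrA", 3_000_000, 4_000_000, 3)
        assert len(truth.true_breakpoints("chrA")) == 4

    def test_breakpoint_count_equals_state_changes(self, toy_genome):
        truth = bs.plant_stepwise_cna(toy_genome, 5, seed=3, gap_bp=100_000, nested_prob=0.5)
        for chrom in toy_genome.chromosomes:
            tiles = truth.state_tiling(chrom)
            changes = sum(
                1 for (_, _, c1), (_, _, c2) in zip(tiles[:-1], tiles[1:]) if c1 != c2
            )
            assert len(truth.true_breakpoints(chrom)) == changes

    def test_overfull_genome_raises(self):
        g = bs.GenomeModel({"chrS": 600_000}, "small")
        with pytest.raises(ValueError, match="could not place"):
            bs.plant_stepwise_cna(g, 10, seed=1)

    def test_overlap_rejected(self, toy_genome):
        truth = bs.GroundTruth(toy_genome)
        truth.add_event("chrA", 1_000_000, 2_000_000, 3)
        with pytest.raises(ValueError, match="overlap"):
            truth.add_event("chrA", 1_500_000, 2_500_000, 4)


class TestChromothripsisPlanting:
    def test_ten_breaks_gives_eleven_segments(self, toy_genome):
        truth = bs.plant_chromothripsis(toy_genome, "chrA", 10, 2, seed=1, states=(1, 3))
        # 11 oscillating segments, all aberrant for a non-neutral state pair
        assert len(truth.events["chrA"]) == 11
        states = [c for _, _, c in truth.events["chrA"]]
        assert all(a != b for a, b in zip(states[:-1], states[1:]))
        assert set(states) == {1, 3}
        assert truth.chromothripsis == {"chrA"}

    def test_neutral_state_set_interleaves_gaps(self, toy_genome):
        truth = bs.plant_chromothripsis(toy_genome, "chrA", 10, 2, seed=2, states=(2, 4))
        # neutral members are rendered as gaps: only the gains are planted,
        # and the realized state changes equal the requested break count
        assert len(truth.true_breakpoints("chrA")) == 10
        assert {c for _, _, c in truth.events["chrA"]} == {4}

    def test_degenerate_inputs_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="n_states"):
            bs.plant_chromothripsis(toy_genome, "chrA", 10, 1, seed=1)
        with pytest.raises(ValueError, match="n_breaks"):
            bs.plant_chromothripsis(toy_genome, "chrA", 5, 2, seed=1)
        with pytest.raises(ValueError, match="below the minimum"):
            bs.plant_chromothripsis(
                toy_genome, "chrA", 10, 2, seed=1, seg_len_range=(50_000, 80_000)
            )
        with pytest.raises(ValueError, match="exceeding"):
            bs.plant_chromothripsis(
                toy_genome, "chrB", 20, 2, seed=1, seg_len_range=(400_000, 500_000)
            )

    def test_flag_only_on_target_chromosome(self, toy_genome):
        truth = bs.plant_chromothripsis(toy_genome, "chrA", 8, 2, seed=4)
        assert "chrB" not in truth.chromothripsis


class TestRenderProfile:
    def test_neutral_renders_zero(self, toy_genome):
        truth = bs.GroundTruth(toy_genome, sigma_probe=0.0)
        grid = bs.make_probe_grid(toy_genome, 100_000, seed=1)
        track = bs.render_profile(grid, truth)
        assert np.allclose(track.all_log2(), 0.0)

    def test_closed_form_log2(self, toy_genome):
        # c=4 pure tumor -> log2 = 1; c=4 at 50% admixture -> log2(3/2)
        assert expected_log2(4, 0.0) == pytest.approx(1.0)
        assert expected_log2(4, 0.5) == pytest.approx(math.log2(1.5))
        assert expected_log2(2, 0.73) == pytest.approx(0.0)
        assert expected_log2(0, 0.0) == -4.0  # clamped floor

    def test_rendered_probes_match_expected_state(self, toy_genome):
        truth = bs.GroundTruth(toy_genome, sigma_probe=0.0, contamination=0.25)
        truth.add_event("chrA", 2_000_000, 4_000_000, 4)
        grid = bs.make_probe_grid(toy_genome, 50_000, seed=2)
        track = bs.render_profile(grid, truth)
        start, end, log2 = track.chromosome("chrA")
        mid = (start + end) // 2
        inside = (mid >= 2_000_000) & (mid < 4_000_000)
        want = expected_log2(4, 0.25)
        assert np.allclose(log2[inside], want)
        assert np.allclose(log2[~inside], 0.0)

    @given(
        c=st.sampled_from([1, 3, 4, 5]),
        p=st.floats(0.0, 0.95),
        dp=st.floats(0.01, 0.05),
    )
    @settings(max_examples=50, deadline=None)
    def test_contamination_shrinks_signal_monotonically(self, c, p, dp):
        # strict for states off the clamp floor (c=0 saturates at the floor)
        if p + dp >= 1.0:
            return
        assert abs(expected_log2(c, p + dp)) < abs(expected_log2(c, p))

    def test_noise_free_rendering_is_invertible(self, toy_genome):
        truth = bs.plant_stepwise_cna(
            toy_genome, 4, seed=8, gap_bp=200_000, sigma_probe=0.0
        )
        grid = bs.make_probe_grid(toy_genome, 20_000, seed=9)
        track = bs.render_profile(grid, truth)
        for chrom in toy_genome.chromosomes:
            start, end, log2 = track.chromosome(chrom)
            mid = (start + end) // 2
            aberrant = np.zeros(len(mid), dtype=bool)
            for s, e, _ in truth.events.get(chrom, []):
                aberrant |= (mid >= s) & (mid < e)
            np.testing.assert_array_equal(np.abs(log2) > 0.3, aberrant)


class TestCohortSimulation:
    def test_empty_cohort(self):
        assert bs.simulate_cohort(0, seed=1, genome=bs.hg19().scaled(0.02)) == []

    def test_fixed_seed_reproducible(self, scaled_hg19):
        g = scaled_hg19
        a = bs.simulate_cohort({"ER+": 1}, seed=5, genome=g, mean_spacing_bp=50_000)
        b = bs.simulate_cohort({"ER+": 1}, seed=5, genome=g, mean_spacing_bp=50_000)
        (ta, ma, ga), (tb, mb, gb) = a[0], b[0]
        assert ma == mb and ga.events == gb.events
        np.testing.assert_array_equal(ta.all_log2(), tb.all_log2())

    def test_chromothripsis_fraction_within_binomial_bounds(self, scaled_hg19):
        spec = {"TNBC": bs.SubtypeSpec(events_range=(2, 5), chromothripsis_prob=0.5)}
        cohort = bs.simulate_cohort(
            {"TNBC": 12}, specs=spec, seed=11, genome=scaled_hg19, mean_spacing_bp=100_000
        )
        flagged = sum(bool(truth.chromothripsis) for _, _, truth in cohort)
        # binomial 95% bounds for n=12, p=0.5
        assert 2 <= flagged <= 10

    def test_ground_truth_bpi_counts_filterable_breaks(self, toy_genome):
        truth = bs.GroundTruth(toy_genome)
        truth.add_event("chrA", 1_000_000, 2_000_000, 4)   # edges |d|=1
        truth.add_event("chrA", 2_000_000, 3_000_000, 5)   # internal step 0.32
        assert truth.bpi(0.0) == 3
        assert truth.bpi(0.5) == 2
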