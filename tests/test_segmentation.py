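import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breakscape as bs
from breakscape.segmentation import (
    SIGMA_FLOOR,
    SegmentationParams,
    call_aberrations,
    estimate_noise_sd,
    interval_score,
    max_score_interval,
    segment_chromosome,
)

from conftest import make_track


def brute_force_max_interval(x, sigma):
    """Exhaustive search with the same tie rule (longer, then leftmost)."""
    best_key, best = None, None
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n + 1):
            s = np.mean(x[i:j]) * np.sqrt(j - i) / sigma
            key = (abs(s), j - i, -i)
            if best_key is None or key > best_key:
                best_key, best = key, (i, j, s)
    return best


class TestNoiseEstimate:
    def test_recovers_known_sigma(self):
        rng = np.random.default_rng(1)
        track = make_track("chrA", rng.normal(0, 0.2, 10_000))
        assert 0.18 <= estimate_noise_sd(track) <= 0.22

    def test_constant_track_hits_floor(self):
        track = make_track("chrA", np.zeros(100))
        assert estimate_noise_sd(track) == SIGMA_FLOOR

    def test_robust_to_short_spike(self):
        rng = np.random.default_rng(2)
        clean = rng.normal(0, 0.2, 1000)
        spiked = clean.copy()
        spiked[500:503] += 2.0
        s0 = estimate_noise_sd(make_track("chrA", clean))
        s1 = estimate_noise_sd(make_track("chrA", spiked))
        assert abs(s1 - s0) / s0 < 0.05

    def test_too_few_probes(self):
        with pytest.raises(ValueError, match="10 probes"):
            estimate_noise_sd(make_track("chrA", np.zeros(5)))


class TestIntervalScore:
    def test_zero_ratios_zero_score(self):
        assert interval_score(np.zeros(10), 0.2) == 0.0

    def test_matches_threshold_closed_form(self):
        # 25 probes at +0.5 with sigma 0.25: 0.5 * 5 / 0.25 = 10
        assert interval_score(np.full(25, 0.5), 0.25) == pytest.approx(10.0)

    def test_signed(self):
        assert interval_score(np.full(4, -0.5), 0.2) == pytest.approx(-5.0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            interval_score(np.ones(5), 0.0)

    def test_default_threshold_is_conservative_ten(self):
        assert SegmentationParams().score_threshold == 10.0


class TestMaxScoreInterval:
    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(1, 13))
        x = rng.normal(0, 1, n) * float(rng.choice([0.2, 1.0]))
        sigma = float(rng.uniform(0.1, 0.5))
        i, j, s = max_score_interval(x, sigma)
        bi, bj, bscore = brute_force_max_interval(x, sigma)
        assert (i, j) == (bi, bj)
        assert s == pytest.approx(bscore)

    def test_tie_prefers_longer_interval(self):
        # all-equal values: every interval has score mean*sqrt(n)/sigma,
        # maximized by the full interval
        i, j, _ = max_score_interval(np.full(6, 0.4), 0.2)
        assert (i, j) == (0, 6)


class TestSegmentChromosome:
    def test_noise_free_nested_amplicon(self, toy_genome):
        truth = bs.GroundTruth(toy_genome, sigma_probe=0.0)
        truth.add_event("chrA", 2_000_000, 3_000_000, 3)
        truth.add_event("chrA", 3_000_000, 4_000_000, 5)
        truth.add_event("chrA", 4_000_000, 5_000_000, 3)
        grid = bs.make_probe_grid(toy_genome, 10_000, seed=1)
        track = bs.render_profile(grid, truth, seed=2)
        tiles = bs.segment_track(track)["chrA"]
        aberrant = [s for s in tiles if s.is_aberrant]
        assert [round(s.mean_log2, 3) for s in aberrant] == [0.585, 1.322, 0.585]

    def test_pure_noise_rarely_calls_anything(self):
        false_calls = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            track = make_track("chrA", rng.normal(0, 0.2, 2000))
            tiles = bs.segment_track(track, sigma=0.2)["chrA"]
            false_calls += any(s.is_aberrant for s in tiles)
        assert false_calls <= 1

    def test_planted_100kb_gain_recovered_within_two_spacings(self):
        g = bs.GenomeModel({"chrA": 30_000_000}, "one")
        truth = bs.GroundTruth(g, sigma_probe=0.2)
        truth.add_event("chrA", 10_000_000, 10_100_000, 4)  # ~ +1.0, 8 probes
        grid = bs.make_probe_grid(g, 12_000, seed=3)
        track = bs.render_profile(grid, truth, seed=4)
        tiles = bs.segment_track(track)["chrA"]
        aberrant = [s for s in tiles if s.is_aberrant]
        assert len(aberrant) == 1
        seg = aberrant[0]
        assert abs(seg.start - 10_000_000) <= 24_000
        assert abs(seg.end - 10_100_000) <= 24_000

    def test_empty_chromosome(self):
        assert segment_chromosome("chrA", np.empty(0), np.empty(0), np.empty(0), 0.2) == []

    def test_tiling_covers_every_probe(self, toy_genome):
        truth = bs.plant_stepwise_cna(toy_genome, 4, seed=5, gap_bp=200_000)
        grid = bs.make_probe_grid(toy_genome, 20_000, seed=6)
        track = bs.render_profile(grid, truth, seed=7)
        for chrom, tiles in bs.segment_track(track).items():
            n_probes = len(track.chromosome(chrom)[0])
            assert sum(s.n_probes for s in tiles) == n_probes
            for a, b in zip(tiles[:-1], tiles[1:]):
                assert a.end <= b.start

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.2, 300)
        x[100:150] += 0.9
        start = np.arange(300, dtype=np.int64) * 10_000
        end = start + 60
        up = segment_chromosome("chrA", start, end, x, 0.2)
        down = segment_chromosome("chrA", start, end, -x, 0.2)
        assert [s.n_probes for s in up] == [s.n_probes for s in down]
        for a, b in zip(up, down):
            assert a.mean_log2 == pytest.approx(-b.mean_log2)
            assert abs(a.score) == pytest.approx(abs(b.score))


class TestCallAberrations:
    def _tiles(self, specs, sigma=0.2):
        """Build a tiling from (n_probes, mean) pairs on a 10kb grid."""
        x = np.concatenate([np.full(n, m) for n, m in specs])
        start = np.arange(len(x), dtype=np.int64) * 10_000
        end = start + 60
        return segment_chromosome("chrA", start, end, x, sigma), x

    def test_four_probe_segment_rejected(self):
        tiles, x = self._tiles([(50, 0.0), (4, 1.0), (50, 0.0)])
        called = call_aberrations(tiles, probe_log2=x)
        assert not any(s.is_aberrant for s in called)
        assert len(called) == 1  # merged back into one neutral run

    def test_low_amplitude_segment_rejected(self):
        tiles, x = self._tiles([(50, 0.0), (50, 0.25), (50, 0.0)])
        called = call_aberrations(tiles, probe_log2=x)
        assert not any(s.is_aberrant for s in called)

    def test_score_threshold_boundary(self):
        # 6 probes at +0.8, sigma 0.2: score 9.8 -> rejected;
        # at +0.9: score 11.0 -> kept
        tiles, x = self._tiles([(50, 0.0), (6, 0.8), (50, 0.0)])
        assert not any(s.is_aberrant for s in call_aberrations(tiles, probe_log2=x))
        tiles, x = self._tiles([(50, 0.0), (6, 0.9), (50, 0.0)])
        kept = [s for s in call_aberrations(tiles, probe_log2=x) if s.is_aberrant]
        assert len(kept) == 1 and kept[0].n_probes == 6
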