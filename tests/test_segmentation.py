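import numpy as np
import pytest
from scipy.stats import rankdata

from paircn.core import GenomeGrid, RatioProfile
from paircn.segmentation import SegmentationParams, best_rank_split, segment


def profile_on_line(y, sample_id="s"):
    g = GenomeGrid.uniform({"1": len(y) * 17_000}, 17_000)
    return RatioProfile(sample_id, "primary", "none", g, np.asarray(y, float))


def brute_force_best_arc(values, min_probes):
    """Independent exhaustive scan: standardized rank-sum of every arc."""
    ranks = rankdata(values)
    n = len(ranks)
    rbar = ranks.mean()
    var_r = np.mean((ranks - rbar) ** 2)
    best, best_z = None, 0.0
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if (i, j) == (0, n) or k < min_probes or n - k < min_probes:
                continue
            if i > 0 and j == n:
                continue  # complement of [0, i): same split
            if 0 < i and j < n and (i < min_probes or n - j < min_probes):
                continue
            z = abs(ranks[i:j].sum() - k * rbar) / np.sqrt(k * (n - k) / (n - 1) * var_r)
            if z > best_z + 1e-12:
                best, best_z = (i, j), z
    return best, best_z


class TestBestSplit:
    def test_matches_brute_force_on_small_vectors(self):
        rng = np.random.default_rng(3)
        for trial in range(30):
            n = int(rng.integers(8, 31))
            y = rng.normal(0, 1, n)
            if trial % 2:  # half the trials carry a real changepoint
                a, b = sorted(rng.choice(np.arange(1, n), 2, replace=False))
                y[a:b] += 2.0
            arc, z = best_rank_split(y, min_probes=2)
            arc_bf, z_bf = brute_force_best_arc(y, 2)
            assert z == pytest.approx(z_bf, rel=1e-12)
            assert arc == arc_bf

    def test_constant_segment_has_no_split(self):
        assert best_rank_split(np.ones(20), 3) == (None, 0.0)


class TestSegment:
    def test_constant_profile_single_segment_per_chromosome(self):
        g = GenomeGrid.uniform({"1": 500_000, "2": 500_000}, 17_000)
        prof = RatioProfile("s", "primary", "none", g, np.full(g.n_probes, 0.3))
        sp = segment(prof, SegmentationParams(n_permutations=200))
        assert len(sp.segments) == 2

    def test_step_breakpoint_recovered_within_2_probes(self):
        rng = np.random.default_rng(7)
        y = np.concatenate([np.zeros(100), np.ones(100)]) + rng.normal(0, 0.05, 200)
        sp = segment(profile_on_line(y), SegmentationParams(seed=7))
        assert len(sp.segments) == 2
        bkpt = sp.segments[0].last_probe + 1
        assert abs(bkpt - 100) <= 2

    def test_two_chromosome_levels_split_at_boundary_only(self):
        g = GenomeGrid.uniform({"1": 340_000, "2": 340_000}, 17_000)
        y = np.concatenate([np.zeros(20), np.ones(20)])
        sp = segment(RatioProfile("s", "primary", "none", g, y),
                     SegmentationParams(n_permutations=200))
        assert len(sp.segments) == 2
        assert {s.chromosome for s in sp.segments} == {"1", "2"}

    def test_noiseless_multilevel_recovered_exactly(self):
        """Noiseless steps of >= 0.5 between runs of >= 20 probes are exact."""
        y = np.concatenate([np.zeros(25), np.full(30, 0.6), np.zeros(20),
                            np.full(22, -0.8)])
        sp = segment(profile_on_line(y), SegmentationParams(n_permutations=500))
        bkpts = [s.first_probe for s in sp.segments]
        assert bkpts == [0, 25, 55, 75]
        for s in sp.segments:
            assert min(abs(s.mean_log2 - v) for v in (0.0, 0.6, -0.8)) < 1e-12

    def test_segment_means_equal_member_averages(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 0.3, 120)
        y[40:80] += 1.0
        prof = profile_on_line(y)
        sp = segment(prof, SegmentationParams(n_permutations=300))
        for s in sp.segments:
            members = y[s.first_probe : s.last_probe + 1]
            assert s.mean_log2 == pytest.approx(members.mean(), abs=1e-12)
        assert np.isfinite(sp.per_probe_mean).all()

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 0.4, 150)
        y[30:60] += 0.5
        y[100:120] -= 0.5
        prof = profile_on_line(y)
        counts = [
            len(segment(prof, SegmentationParams(alpha=a, n_permutations=400, seed=1)).segments)
            for a in (0.2, 0.05, 0.01, 0.001)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_missing_probes_inherit_segment_mean(self):
        y = np.concatenate([np.zeros(30), np.ones(30)])
        y[10] = np.nan
        y[29] = np.nan  # adjacent to the breakpoint
        prof = profile_on_line(y)
        sp = segment(prof, SegmentationParams(n_permutations=300))
        assert len(sp.segments) == 2
        assert np.isfinite(sp.per_probe_mean).all()
        assert sp.per_probe_mean[10] == sp.segments[0].mean_log2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 0.3, 100)
        y[50:] += 0.8
        prof = profile_on_line(y)
        a = segment(prof, SegmentationParams(seed=9, n_permutations=300))
        b = segment(prof, SegmentationParams(seed=9, n_permutations=300))
        assert [(s.first_probe, s.last_probe) for s in a.segments] == [
            (s.first_probe, s.last_probe) for s in b.segments
        ]

    def test_tiny_chromosome_yields_single_segment(self):
        g = GenomeGrid.uniform({"1": 68_000}, 17_000)  # 4 probes < 2*min_probes
        prof = RatioProfile("s", "primary", "none", g, np.array([0, 0, 1.0, 1.0]))
        sp = segment(prof, SegmentationParams(min_probes_per_segment=3))
        assert len(sp.segments) == 1

    def test_focal_event_in_interior_is_isolated(self):
        rng = np.random.default_rng(13)
        y = rng.normal(0, 0.1, 118)
        y[71:79] += 2.3
        sp = segment(profile_on_line(y), SegmentationParams(n_permutations=300))
        focal = [s for s in sp.segments if s.mean_log2 > 1.5]
        assert len(focal) == 1
        assert focal[0].first_probe >= 69 and focal[0].last_probe <= 80
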