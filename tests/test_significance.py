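import numpy as np
import pytest
from scipy.stats import hypergeom

from paircn.core import GenomeGrid, PairedCase, RatioProfile
from paircn.calling import call_segments
from paircn.significance import (
    DifferenceProfile,
    difference_profiles,
    group_frequency_comparison,
    gscore,
)
from paircn.segmentation import SegmentationParams, segment
from helpers import make_segmented


def line_grid(m, spacing=17_000):
    return GenomeGrid.uniform({"1": m * spacing}, spacing)


def diffs_from(matrix, patient_prefix="pt"):
    return [
        DifferenceProfile(f"{patient_prefix}{i}", f"m{i}", np.asarray(row, float))
        for i, row in enumerate(matrix)
    ]


class TestDifferenceProfiles:
    def _case(self, grid, y_p, y_m):
        p = RatioProfile("p0", "primary", "none", grid, y_p)
        m = RatioProfile("m0", "metastasis", "liver", grid, y_m)
        return PairedCase("pt0", p, [m])

    def test_identical_pair_gives_zero_difference(self):
        g = line_grid(60)
        y = np.zeros(60)
        y[10:30] = 1.0
        case = self._case(g, y, y.copy())
        segd = {
            s.sample_id: segment(s, SegmentationParams(n_permutations=200))
            for s in case.samples
        }
        (d,) = difference_profiles([case], segd)
        assert np.allclose(d.d, 0.0, atol=1e-12)

    def test_metastasis_private_segment_appears_in_difference(self):
        g = line_grid(60)
        y_p = np.zeros(60)
        y_m = np.zeros(60)
        y_m[20:40] = 1.0
        case = self._case(g, y_p, y_m)
        segd = {
            s.sample_id: segment(s, SegmentationParams(n_permutations=200))
            for s in case.samples
        }
        (d,) = difference_profiles([case], segd)
        assert np.allclose(d.d[20:40], 1.0, atol=1e-12)
        assert np.allclose(np.delete(d.d, slice(20, 40)), 0.0, atol=1e-12)

    def test_one_vector_per_metastasis_and_missing_mate_error(self):
        g = line_grid(10)
        p = RatioProfile("p0", "primary", "none", g, np.zeros(10))
        m1 = RatioProfile("m0a", "metastasis", "liver", g, np.zeros(10))
        m2 = RatioProfile("m0b", "metastasis", "lung", g, np.zeros(10))
        case = PairedCase("pt0", p, [m1, m2])
        segd = {
            s.sample_id: segment(s, SegmentationParams(n_permutations=100))
            for s in case.samples
        }
        assert len(difference_profiles([case], segd)) == 2
        del segd["m0b"]
        with pytest.raises(KeyError, match="m0b"):
            difference_profiles([case], segd)


class TestGScore:
    def test_all_zero_differences_no_signal(self):
        g = line_grid(50)
        track, peaks = gscore(diffs_from(np.zeros((3, 50))), g, n_permutations=100)
        assert np.all(track["G"] == 0)
        assert peaks == []

    def test_single_exceedance_sums_correctly(self):
        g = line_grid(50)
        D = np.zeros((2, 50))
        D[0, 7] = 1.2
        track, _ = gscore(diffs_from(D), g, theta=0.2, n_permutations=100)
        assert track["G"][7] == pytest.approx(1.0)
        assert track["G"].drop(7).eq(0).all()

    def test_additive_over_samples_and_zero_without_exceedance(self):
        g = line_grid(40)
        D = np.zeros((3, 40))
        D[0, 5] = 0.7
        D[1, 5] = 0.5
        D[2, 20] = 0.15  # below theta
        track, _ = gscore(diffs_from(D), g, theta=0.2, n_permutations=100)
        assert track["G"][5] == pytest.approx(0.5 + 0.3)
        assert track["G"][20] == 0.0
        assert (track["G"] >= 0).all()

    def test_lower_direction_mirrors_higher(self):
        g = line_grid(30)
        D = np.zeros((2, 30))
        D[0, 4] = -1.2
        hi, _ = gscore(diffs_from(D), g, "higher", n_permutations=100)
        lo, _ = gscore(diffs_from(D), g, "lower", n_permutations=100)
        assert hi["G"].sum() == 0.0
        assert lo["G"][4] == pytest.approx(1.0)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(0)
        g = line_grid(80)
        D = rng.normal(0, 0.3, (4, 80))
        t1, _ = gscore(diffs_from(D), g, n_permutations=200, seed=5)
        t2, _ = gscore(diffs_from(D), g, n_permutations=200, seed=5)
        assert np.array_equal(t1["p"], t2["p"])
        t3, _ = gscore(diffs_from(D), g, n_permutations=200, seed=6)
        assert not np.array_equal(t1["p"], t3["p"])

    def test_planted_recurrent_region_recovered(self):
        """30% of pairs share a +1.0 region; it is the only q<0.05 peak."""
        rng = np.random.default_rng(11)
        n_pairs, m = 20, 400
        D = rng.normal(0, 0.1, (n_pairs, m))
        D[:6, 150:170] += 1.0
        g = line_grid(m)
        track, peaks = gscore(diffs_from(D), g, "higher", n_permutations=300, seed=11)
        assert len(peaks) == 1
        sig = np.nonzero((track["q"] < 0.05).to_numpy())[0]
        assert sig.min() >= 148 and sig.max() <= 171

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            gscore(diffs_from(np.zeros((2, 10))), line_grid(10), "sideways")

    def test_bh_qvalues_match_reference_step_up(self):
        rng = np.random.default_rng(3)
        g = line_grid(60)
        D = rng.normal(0, 0.4, (4, 60))
        track, _ = gscore(diffs_from(D), g, n_permutations=200, seed=1)
        p = track["p"].to_numpy()
        # independent BH step-up: q_(i) = min_{j>=i} p_(j) * m / j
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        q_ref = np.empty(m)
        q_ref[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(track["q"], q_ref, atol=1e-12)


class TestGroupFrequency:
    def test_identical_groups_p_one(self, toy_grid):
        called = [
            call_segments(make_segmented(toy_grid, [("1", 10, 0.5), ("2", 10, 0.0)]))
            for _ in range(4)
        ]
        out = group_frequency_comparison(called, called)
        assert (out["gain_p"] == 1.0).all()
        assert (out["loss_p"] == 1.0).all()

    def test_extreme_table_matches_hypergeometric_enumeration(self, toy_grid):
        gain = call_segments(make_segmented(toy_grid, [("1", 10, 0.5), ("2", 10, 0.0)]))
        neut = call_segments(make_segmented(toy_grid, [("1", 10, 0.0), ("2", 10, 0.0)]))
        out = group_frequency_comparison([gain] * 10, [neut] * 10)
        # Fisher p for 10/10 vs 0/10 by direct hypergeometric enumeration:
        # tables at least as extreme are exactly {10 gains all in group 1}
        # and {10 gains all in group 2}
        p_expected = 2 * hypergeom.pmf(10, 20, 10, 10)
        assert out["gain_p"][0] == pytest.approx(p_expected, rel=1e-9)
        assert out["gain_significant"][0]

    def test_single_probe_fdr_equals_raw_p(self):
        g = GenomeGrid.uniform({"1": 10_000}, 10_000)
        gain = call_segments(make_segmented(g, [("1", 1, 0.5)]))
        neut = call_segments(make_segmented(g, [("1", 1, 0.0)]))
        out = group_frequency_comparison([gain] * 5, [neut] * 5)
        assert out["gain_q"][0] == pytest.approx(out["gain_p"][0])

    def test_empty_group_rejected(self, toy_grid):
        called = call_segments(make_segmented(toy_grid, [("1", 10, 0.0), ("2", 10, 0.0)]))
        with pytest.raises(ValueError, match="non-empty"):
            group_frequency_comparison([], [called])
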