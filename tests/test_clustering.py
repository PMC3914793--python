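import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from paircn.clustering import (
    hierarchical_cluster,
    pair_adjacency,
    spearman_distance_matrix,
)
from paircn.core import GenomeGrid
from helpers import make_segmented


def seg_profiles(toy_grid, vectors):
    """Per-probe-mean profiles straight from vectors (one segment per probe)."""
    out = []
    for sid, v in vectors.items():
        runs = []
        i = 0
        for chrom in toy_grid.chromosome_list:
            sl = toy_grid.chrom_slice(chrom)
            for _ in range(sl.stop - sl.start):
                runs.append((chrom, 1, float(v[i])))
                i += 1
        out.append(make_segmented(toy_grid, runs, sample_id=sid))
    return out


class TestSpearmanDistance:
    def test_identical_profiles_distance_zero(self, toy_grid):
        v = np.linspace(-1, 1, toy_grid.n_probes)
        d = spearman_distance_matrix(seg_profiles(toy_grid, {"a": v, "b": v.copy()}))
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diag(d) == 0)

    def test_monotone_decreasing_transform_distance_two(self, toy_grid):
        v = np.linspace(-1, 1, toy_grid.n_probes)
        d = spearman_distance_matrix(seg_profiles(toy_grid, {"a": v, "b": -(v**3) - v}))
        assert d.loc["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_matches_hand_computed_rank_correlation(self):
        g = GenomeGrid.uniform({"1": 50_000}, 10_000)
        x = np.array([0.1, 0.4, -0.2, 0.9, 0.0])
        y = np.array([0.2, 0.1, -0.5, 0.8, 0.3])
        d = spearman_distance_matrix(seg_profiles(g, {"x": x, "y": y}))
        rx, ry = rankdata(x), rankdata(y)
        rho = np.corrcoef(rx, ry)[0, 1]
        assert d.loc["x", "y"] == pytest.approx(1 - rho, abs=1e-12)

    def test_invariant_under_monotone_transform(self, toy_grid):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, toy_grid.n_probes)
        w = rng.normal(0, 1, toy_grid.n_probes)
        d1 = spearman_distance_matrix(seg_profiles(toy_grid, {"a": v, "b": w}))
        d2 = spearman_distance_matrix(seg_profiles(toy_grid, {"a": np.exp(v), "b": w}))
        assert d1.loc["a", "b"] == pytest.approx(d2.loc["a", "b"], abs=1e-12)

    def test_flat_profile_rejected_by_name(self, toy_grid):
        v = np.linspace(-1, 1, toy_grid.n_probes)
        flat = np.zeros(toy_grid.n_probes)
        with pytest.raises(ValueError, match="flatty"):
            spearman_distance_matrix(
                seg_profiles(toy_grid, {"a": v, "flatty": flat})
            )


def dist_df(labels, d):
    return pd.DataFrame(np.asarray(d, float), index=labels, columns=labels)


class TestHierarchicalCluster:
    def test_two_samples_single_merge(self):
        dend = hierarchical_cluster(dist_df(["a", "b"], [[0, 0.4], [0.4, 0]]))
        assert dend.linkage_matrix.shape == (1, 4)
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.4)

    def test_closest_pair_merges_first(self):
        d = [[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]]
        dend = hierarchical_cluster(dist_df(["s1", "s2", "s3"], d))
        assert set(dend.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_average_linkage_merge_heights_hand_computed(self):
        # d(a,b)=.2 merge first; then c joins (a,b) at mean(.5,.6)=.55;
        # then d joins at mean(.9,1.0,.3)=.7333
        d = np.array(
            [
                [0.0, 0.2, 0.5, 0.9],
                [0.2, 0.0, 0.6, 1.0],
                [0.5, 0.6, 0.0, 0.3],
                [0.9, 1.0, 0.3, 0.0],
            ]
        )
        dend = hierarchical_cluster(dist_df(list("abcd"), d), "average")
        heights = dend.linkage_matrix[:, 2]
        assert heights[0] == pytest.approx(0.2)
        assert heights[1] == pytest.approx(0.3)
        assert heights[2] == pytest.approx(np.mean([0.5, 0.6, 0.9, 1.0]))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(dist_df(["a", "b"], [[0, 0.1], [0.2, 0]]))
        with pytest.raises(ValueError, match="non-negative"):
            hierarchical_cluster(dist_df(["a", "b"], [[0, -0.1], [-0.1, 0]]))
        with pytest.raises(ValueError, match="linkage"):
            hierarchical_cluster(dist_df(["a", "b"], [[0, 0.1], [0.1, 0]]), "ward")

    def test_newick_export_contains_all_leaves(self):
        d = [[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]]
        nwk = hierarchical_cluster(dist_df(["s1", "s2", "s3"], d)).to_newick()
        assert nwk.endswith(";")
        for lab in ("s1", "s2", "s3"):
            assert lab in nwk


class TestPairAdjacency:
    def _block_matrix(self, pairs, eps=0.05, far=1.0):
        """Distance matrix where matched samples sit at eps, others at >= far."""
        labels = [s for p, (pr, ms) in pairs.items() for s in [pr, *ms]]
        rng = np.random.default_rng(1)
        n = len(labels)
        d = far + rng.uniform(0, 0.2, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        df = dist_df(labels, d)
        for p, (pr, ms) in pairs.items():
            for m in ms:
                df.loc[pr, m] = df.loc[m, pr] = eps
        return df

    def test_tight_pairs_all_joined(self):
        pairs = {f"pt{i}": (f"p{i}", [f"m{i}"]) for i in range(4)}
        dend = hierarchical_cluster(self._block_matrix(pairs))
        rep = pair_adjacency(dend, pairs)
        assert rep.fraction_joined == 1.0
        assert (rep.table["leaves_between"] == 0).all()

    def test_two_metastases_joining_first_still_counts(self):
        pairs = {"pt0": ("p0", ["m0a", "m0b"]), "pt1": ("p1", ["m1"])}
        labels = ["p0", "m0a", "m0b", "p1", "m1"]
        d = np.full((5, 5), 1.0)
        np.fill_diagonal(d, 0)
        df = dist_df(labels, d)
        df.loc["m0a", "m0b"] = df.loc["m0b", "m0a"] = 0.02  # mets merge first
        df.loc["p0", "m0a"] = df.loc["m0a", "p0"] = 0.1
        df.loc["p0", "m0b"] = df.loc["m0b", "p0"] = 0.1
        df.loc["p1", "m1"] = df.loc["m1", "p1"] = 0.05
        rep = pair_adjacency(hierarchical_cluster(df), pairs)
        assert rep.table["joined_pairwise"].all()

    def test_planted_confusable_pair_not_joined(self):
        """A metastasis closest to another patient's primary breaks its pair."""
        pairs = {"pt0": ("p0", ["m0"]), "pt1": ("p1", ["m1"]), "pt2": ("p2", ["m2"])}
        df = self._block_matrix(pairs)
        # m0 now resembles p1 more than its own primary
        df.loc["p0", "m0"] = df.loc["m0", "p0"] = 0.9
        df.loc["p1", "m0"] = df.loc["m0", "p1"] = 0.01
        rep = pair_adjacency(hierarchical_cluster(df), pairs)
        t = rep.table.set_index("patient_id")
        assert not t.loc["pt0", "joined_pairwise"]
        assert t.loc["pt2", "joined_pairwise"]

    def test_leaves_between_counts_foreign_samples(self):
        """Primaries merge with each other, mets likewise: each pair ends up
        with exactly one foreign sample between its leaves."""
        pairs = {"pt0": ("p0", ["m0"]), "pt1": ("p1", ["m1"])}
        labels = ["p0", "m0", "p1", "m1"]
        d = np.array(
            [
                [0.0, 0.90, 0.05, 0.92],
                [0.90, 0.0, 0.94, 0.06],
                [0.05, 0.94, 0.0, 0.96],
                [0.92, 0.06, 0.96, 0.0],
            ]
        )
        dend = hierarchical_cluster(dist_df(labels, d))
        assert dend.leaf_order == ["p0", "p1", "m0", "m1"]
        rep = pair_adjacency(dend, pairs)
        t = rep.table.set_index("patient_id")
        assert not t["joined_pairwise"].any()
        assert (t["leaves_between"] == 1).all()

    def test_missing_sample_rejected(self):
        pairs = {"pt0": ("p0", ["ghost"])}
        dend = hierarchical_cluster(dist_df(["p0", "x"], [[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValueError, match="ghost"):
            pair_adjacency(dend, pairs)
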