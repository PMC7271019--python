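import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcbp import validity as val
from rcbp.clustering import Labeling
from rcbp.types import MaskVolume
from conftest import as_matrix


def mklab(labels, k):
    return Labeling(labels=np.asarray(labels), k=k)


# -- independent brute-force oracles ----------------------------------------

def silhouette_oracle(X, labels):
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            scores[i] = 0.0
            continue
        a = d[i, own & (np.arange(n) != i)].mean()
        b = min(d[i, labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        scores[i] = (b - a) / max(a, b)
    return scores.mean()


def ch_oracle(X, labels):
    n, k = len(X), len(np.unique(labels))
    grand = X.mean(axis=0)
    between = within = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        c = members.mean(axis=0)
        between += len(members) * ((c - grand) ** 2).sum()
        within += ((members - c) ** 2).sum()
    return (between / (k - 1)) / (within / (n - k))


def db_oracle(X, labels):
    uniq = np.unique(labels)
    cents = np.stack([X[labels == lab].mean(axis=0) for lab in uniq])
    s = np.array([np.linalg.norm(X[labels == lab] - cents[i], axis=1).mean()
                  for i, lab in enumerate(uniq)])
    total = 0.0
    for i in range(len(uniq)):
        total += max((s[i] + s[j]) / np.linalg.norm(cents[i] - cents[j])
                     for j in range(len(uniq)) if j != i)
    return total / len(uniq)


def random_instance(rng, max_n=200):
    n = int(rng.integers(10, max_n + 1))
    k = int(rng.integers(2, 6))
    X = rng.standard_normal((n, 3))
    labels = rng.integers(1, k + 1, size=n)
    labels[:k] = np.arange(1, k + 1)
    return X, labels, k


class TestInternalIndices:
    def test_1d_hand_example(self):
        m = as_matrix(np.array([[0.0], [1.0], [10.0], [11.0]]))
        lab = mklab([1, 1, 2, 2], 2)
        assert val.silhouette(m, lab) == pytest.approx(0.89975, abs=5e-6)
        assert val.calinski_harabasz(m, lab) == pytest.approx(200.0)
        assert val.davies_bouldin(m, lab) == pytest.approx(0.1)

    def test_far_separated_tight_clusters_approach_limits(self, rng):
        X = np.vstack([rng.standard_normal((10, 2)) * 1e-3,
                       rng.standard_normal((10, 2)) * 1e-3 + 1e4])
        lab = mklab(np.r_[np.ones(10, int), np.full(10, 2)], 2)
        assert val.silhouette(as_matrix(X), lab) > 0.999
        assert val.davies_bouldin(as_matrix(X), lab) < 1e-3

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        X, labels, k = random_instance(rng, max_n=60)
        m, lab = as_matrix(X), mklab(labels, k)
        assert val.silhouette(m, lab) == pytest.approx(
            silhouette_oracle(X, labels), abs=1e-10)
        assert val.calinski_harabasz(m, lab) == pytest.approx(
            ch_oracle(X, labels), rel=1e-9)
        assert val.davies_bouldin(m, lab) == pytest.approx(
            db_oracle(X, labels), rel=1e-9)

    def test_zero_within_scatter_gives_sentinel(self):
        X = np.repeat([[0.0, 0.0], [5.0, 5.0]], 3, axis=0)
        lab = mklab([1] * 3 + [2] * 3, 2)
        assert val.calinski_harabasz(as_matrix(X), lab) == val.DEGENERATE_SENTINEL
        assert val.davies_bouldin(as_matrix(X), lab) == 0.0

    def test_coincident_centroids_give_sentinel(self):
        X = np.array([[0.0], [2.0], [0.0], [2.0]])
        lab = mklab([1, 1, 2, 2], 2)
        assert val.davies_bouldin(as_matrix(X), lab) == val.DEGENERATE_SENTINEL

    def test_degenerate_k_rejected(self, rng):
        m = as_matrix(rng.standard_normal((4, 2)))
        with pytest.raises(ValueError):
            val.silhouette(m, mklab([1, 2, 3, 4], 4))  # k == n


class TestAgreementMetrics:
    def test_identical_labelings_score_one(self, rng):
        a = rng.integers(1, 4, size=50)
        a[:3] = [1, 2, 3]
        assert val.ari(a, a) == 1.0
        assert val.v_measure(a, a) == 1.0
        assert val.ami(a, a) == 1.0

    def test_ari_crossed_pairs_hand_value(self):
        assert val.ari([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_v_measure_degenerate_constant_labeling(self):
        assert val.v_measure([1, 1, 1, 1], [1, 1, 2, 2]) == 0.0

    def test_ami_near_zero_for_independent_labelings(self):
        rng = np.random.default_rng(99)
        vals = [val.ami(rng.integers(1, 4, 1000), rng.integers(1, 4, 1000))
                for _ in range(100)]
        assert abs(np.mean(vals)) < 0.02

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(1, 5, size=60)
        b = rng.integers(1, 5, size=60)
        perm = rng.permutation(4) + 1
        a_perm = perm[a - 1]
        for f in (val.ari, val.v_measure, val.ami):
            assert f(a, b) == pytest.approx(f(b, a), abs=1e-12)
            assert f(a, b) == pytest.approx(f(a_perm, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            val.ari([1, 2], [1, 2, 3])


class TestModelSelection:
    def test_all_indices_rank_planted_k_best(self):
        from rcbp.clustering import ClusterParams, cluster_subject
        from rcbp.synthetic import PlantedDesign, make_connectivity_cohort
        design = PlantedDesign(roi_shape=(6, 5, 4), k_true=3, n_subjects=1,
                               n_targets=40, seed=5)
        cohort, _, _ = make_connectivity_cohort(design)
        m = cohort[0]
        scores = {}
        for k in (2, 3, 4, 5):
            lab = cluster_subject(m, ClusterParams(k=k, n_init=16, seed=0))
            scores[k] = (val.silhouette(m, lab), val.calinski_harabasz(m, lab),
                         val.davies_bouldin(m, lab))
        assert max(scores, key=lambda k: scores[k][0]) == 3
        assert max(scores, key=lambda k: scores[k][1]) == 3
        assert min(scores, key=lambda k: scores[k][2]) == 3


class TestSimilarityReport:
    def labs(self, rows, k):
        return [Labeling(labels=np.asarray(r), k=k, subject_id=f"s{i}")
                for i, r in enumerate(rows)]

    def test_identical_subjects_all_ones(self):
        labs = self.labs([[1, 1, 2, 2]] * 3, 2)
        table = val.similarity_report(labs, np.array([1, 1, 2, 2]))
        assert np.allclose(table.pairwise, 1.0)
        assert np.allclose(table.to_group, 1.0)

    def test_two_blocks_split_at_top_of_dendrogram(self):
        from scipy.cluster import hierarchy
        block_a = [[1, 1, 1, 2, 2, 2]] * 3
        block_b = [[1, 2, 1, 2, 1, 2]] * 3
        labs = self.labs(block_a + block_b, 2)
        table = val.similarity_report(labs, np.asarray(block_a[0]))
        top = hierarchy.fcluster(table.linkage, 2, criterion="maxclust")
        assert len(set(top[:3])) == 1 and len(set(top[3:])) == 1
        assert top[0] != top[3]

    def test_metric_selection_switches_outputs(self, rng):
        labs = self.labs([random_labels(rng) for _ in range(3)], 3)
        group = random_labels(rng)
        t_ari = val.similarity_report(labs, group, metric="ari")
        t_ami = val.similarity_report(labs, group, metric="ami")
        assert not np.allclose(t_ari.pairwise, t_ami.pairwise)

    def test_figure_file_written(self, tmp_path, rng):
        labs = self.labs([random_labels(rng) for _ in range(3)], 3)
        fig = tmp_path / "dendro.png"
        val.similarity_report(labs, random_labels(rng), figure_path=str(fig))
        assert fig.exists() and fig.stat().st_size > 0


def random_labels(rng, n=30, k=3):
    labels = rng.integers(1, k + 1, size=n)
    labels[:k] = np.arange(1, k + 1)
    return labels


class TestCompareReference:
    def roi(self, n=20):
        data = np.zeros((n, 1, 1), dtype=np.uint8)
        data[:, 0, 0] = 1
        return MaskVolume(data=data, affine=np.eye(4))

    def test_reference_equal_to_group_is_perfect(self, rng):
        group = random_labels(rng, n=20)
        roi = self.roi(20)
        ref_img = np.zeros(roi.shape)
        ref_img[:, 0, 0] = group
        comp = val.compare_reference(group, roi, ref_img)
        assert comp.score == 1.0 and comp.n_mismatched == 0

    def test_mismatch_percentage_arithmetic(self):
        n, mism = 972, 76
        group = np.r_[np.ones(n // 2, int), np.full(n - n // 2, 2)]
        ref = group.copy()
        ref[:mism] = 3 - ref[:mism]
        comp = val.compare_labels(group, ref)
        assert comp.n_mismatched == 76
        assert comp.percent_mismatched == pytest.approx(7.8189, abs=5e-3)

    def test_permuted_reference_ids_same_score(self, rng):
        group = random_labels(rng, n=40)
        ref = group.copy()
        ref[:5] = (ref[:5] % 3) + 1
        comp1 = val.compare_labels(group, ref)
        perm = np.array([2, 3, 1])
        comp2 = val.compare_labels(group, perm[ref - 1])
        assert comp1.score == pytest.approx(comp2.score, abs=1e-12)
        assert comp1.n_mismatched == comp2.n_mismatched

    def test_reference_missing_roi_voxels_rejected(self, rng):
        roi = self.roi(10)
        ref_img = np.zeros(roi.shape)  # all zero: every ROI voxel missing
        with pytest.raises(ValueError, match="missing"):
            val.compare_reference(random_labels(rng, n=10, k=2), roi, ref_img)
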