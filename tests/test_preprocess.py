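import itertools

import numpy as np
import pandas as pd
import pytest

from tgamir.io import SchemaError
from tgamir.preprocess import (
    detection_filter,
    hierarchical_cluster,
    log2_transform,
    quantile_normalize,
)

from conftest import make_matrix


def meta_for(samples, groups):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "overt_hf": False,
            "death": False,
            "ntprobnp": np.nan,
            "hstnt": np.nan,
            "egfr": np.nan,
        }
    )


class TestDetectionFilter:
    @pytest.fixture
    def two_groups(self):
        samples = [f"s{i}" for i in range(8)]
        groups = ["TGA_RV"] * 4 + ["control"] * 4
        return samples, meta_for(samples, groups)

    def test_fully_detected_kept_both_modes(self, two_groups):
        samples, meta = two_groups
        m = make_matrix(np.ones((1, 8)), sample_ids=samples)
        for mode in ("any_group", "all_groups"):
            kept, report = detection_filter(m, meta, mode=mode)
            assert report.kept_features == ["f0"]

    def test_never_detected_dropped_both_modes(self, two_groups):
        samples, meta = two_groups
        m = make_matrix(np.ones((1, 8)), sample_ids=samples, detected=np.zeros((1, 8)))
        for mode in ("any_group", "all_groups"):
            kept, report = detection_filter(m, meta, mode=mode)
            assert report.dropped_features == ["f0"]

    def test_asymmetric_detection_mode_dependent(self, two_groups):
        # detected 3/4 in one group, 1/4 in the other: the 50% rule keeps it
        # only under the at-least-one-group reading
        samples, meta = two_groups
        det = [[True, True, True, False, True, False, False, False]]
        m = make_matrix(np.ones((1, 8)), sample_ids=samples, detected=det)
        _, any_report = detection_filter(m, meta, mode="any_group")
        assert any_report.kept_features == ["f0"]
        _, all_report = detection_filter(m, meta, mode="all_groups")
        assert all_report.dropped_features == ["f0"]

    def test_partition_and_fractions(self, two_groups):
        samples, meta = two_groups
        rng = np.random.default_rng(0)
        det = rng.random((30, 8)) < 0.5
        m = make_matrix(np.ones((30, 8)), sample_ids=samples, detected=det)
        kept, report = detection_filter(m, meta)
        assert sorted(report.kept_features + report.dropped_features) == sorted(m.feature_ids)
        assert not set(report.kept_features) & set(report.dropped_features)
        expected_rv = det[:, :4].mean(axis=1)
        assert np.allclose(report.detection_fractions["TGA_RV"].to_numpy(), expected_rv)

    def test_idempotent(self, two_groups):
        samples, meta = two_groups
        rng = np.random.default_rng(1)
        det = rng.random((30, 8)) < 0.6
        m = make_matrix(np.ones((30, 8)), sample_ids=samples, detected=det)
        once, _ = detection_filter(m, meta)
        twice, report = detection_filter(once, meta)
        assert once.feature_ids == twice.feature_ids
        assert not report.dropped_features

    def test_unannotated_sample_rejected(self, two_groups):
        samples, meta = two_groups
        m = make_matrix(np.ones((1, 9)), sample_ids=samples + ["extra"])
        with pytest.raises(SchemaError, match="extra"):
            detection_filter(m, meta)


class TestQuantileNormalize:
    def test_hand_example(self):
        # columns [1,3] and [2,6]: sorted-row means are (1.5, 4.5)
        m = make_matrix([[1.0, 2.0], [3.0, 6.0]])
        out = quantile_normalize(m)
        assert np.array_equal(out.values.to_numpy(), [[1.5, 1.5], [4.5, 4.5]])

    def test_identical_columns_fixed_point(self):
        col = np.array([4.0, 1.0, 9.0, 2.0])
        m = make_matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_single_feature_unchanged_with_warning(self):
        m = make_matrix([[5.0, 7.0]])
        with pytest.warns(UserWarning, match="single-feature"):
            out = quantile_normalize(m)
        assert np.array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_columns_share_sorted_vector(self, default_bundle):
        out = quantile_normalize(default_bundle.mirna)
        arr = np.sort(out.values.to_numpy(), axis=0)
        for j in range(1, arr.shape[1]):
            assert np.allclose(arr[:, 0], arr[:, j], atol=1e-12, rtol=0)

    def test_preserves_within_column_rank_order_with_ties(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 6, size=(40, 5)).astype(float)  # many ties
        m = make_matrix(values)
        out = quantile_normalize(m).values.to_numpy()
        for j in range(5):
            order_in = np.argsort(values[:, j], kind="mergesort")
            assert np.all(np.diff(out[order_in, j]) >= -1e-12)
            # tied inputs stay tied
            for v in np.unique(values[:, j]):
                tied = out[values[:, j] == v, j]
                assert np.allclose(tied, tied[0])


class TestLog2Transform:
    @pytest.mark.parametrize("value,offset,expected", [(0.0, 1.0, 0.0), (3.0, 1.0, 2.0), (1023.0, 1.0, 10.0)])
    def test_pointwise(self, value, offset, expected):
        out = log2_transform(make_matrix([[value]]), offset=offset)
        assert out.values.iloc[0, 0] == pytest.approx(expected)
        assert out.scale == "log2"

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(make_matrix([[1.0]]), offset=-1.0)


def brute_force_upgma(points):
    """O(n^3) average-linkage agglomeration from the raw point-pair distances."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or avg < best[0] - 1e-12:
                best = (avg, a, b)
        avg, a, b = best
        heights.append(avg)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_zero(self):
        m = make_matrix(np.ones((3, 2)), scale="log2")
        dend = hierarchical_cluster(m, axis="samples")
        assert dend.heights[0] == 0.0

    def test_hand_example_one_dimensional(self):
        # points {0, 1, 10}: merge (0,1) at 1; then at (10 + 9)/2 = 9.5
        m = make_matrix(np.array([[0.0, 1.0, 10.0]]), sample_ids=["a", "b", "c"], scale="log2")
        dend = hierarchical_cluster(m, axis="samples")
        assert dend.heights == pytest.approx([1.0, 9.5])

    def test_heights_match_brute_force(self):
        rng = np.random.default_rng(3)
        for n in range(2, 9):
            points = rng.normal(size=(n, 4))
            labels = [f"s{i}" for i in range(n)]
            m = make_matrix(points.T, sample_ids=labels, scale="log2")
            dend = hierarchical_cluster(m, axis="samples")
            assert dend.heights == pytest.approx(brute_force_upgma(points), abs=1e-9)

    def test_permutation_invariant_heights(self):
        rng = np.random.default_rng(4)
        points = rng.normal(size=(6, 3))
        labels = [f"s{i}" for i in range(6)]
        m1 = make_matrix(points.T, sample_ids=labels, scale="log2")
        perm = rng.permutation(6)
        m2 = make_matrix(points[perm].T, sample_ids=[labels[i] for i in perm], scale="log2")
        d1 = hierarchical_cluster(m1, axis="samples")
        d2 = hierarchical_cluster(m2, axis="samples")
        assert d1.heights == pytest.approx(d2.heights)
        assert d1.labels == d2.labels  # lexicographic leaf order

    def test_heights_non_decreasing(self, default_bundle):
        from tgamir.preprocess import log2_transform, quantile_normalize

        logm = log2_transform(quantile_normalize(default_bundle.mirna))
        dend = hierarchical_cluster(logm, axis="samples")
        assert np.all(np.diff(dend.heights) >= -1e-9)

    def test_single_item_trivial_tree(self):
        m = make_matrix([[1.0], [2.0]], sample_ids=["only"], scale="log2")
        with pytest.warns(UserWarning, match="single item"):
            dend = hierarchical_cluster(m, axis="samples")
        assert dend.merges == [] and dend.labels == ["only"]
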