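"""Splits, interval subsampling, SMOTE geometry, class weights, assembly."""

import numpy as np
import pytest

from hotspot1d.assembly import (
    IntervalSamplerSpec,
    SmoteSpec,
    SplitSpec,
    assemble_training_set,
    compute_class_weights,
    interval_subsample,
    smote_generate,
    split_dataset,
)
from hotspot1d.synthetic import FeatureCloudSpec, generate_feature_cloud
from hotspot1d.windowing import WindowDataset


def make_windows(n_pos, n_neg, width=3, dim=2, tag="w", seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    return WindowDataset(
        X=rng.normal(size=(n, width, dim)).astype(np.float32),
        y=np.array([1] * n_pos + [0] * n_neg, dtype=np.int8),
        meta=[(tag, i + 1) for i in range(n)],
    )


class TestSplitDataset:
    def test_benchmark_partition_sizes(self):
        """A 698-example corpus split in fifths gives 140 test / 112 validation."""
        wd = make_windows(349, 349)
        train, val, test = split_dataset(wd, SplitSpec(seed=3))
        assert len(test) == 140
        assert len(val) == 112
        assert len(train) == 446

    def test_tiny_split(self):
        wd = make_windows(2, 3)
        train, val, test = split_dataset(wd, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (3, 1, 1)

    def test_partitions_disjoint_and_exhaustive(self):
        wd = make_windows(50, 150)
        parts = split_dataset(wd, SplitSpec(seed=9))
        keys = [m for p in parts for m in p.meta]
        assert len(keys) == len(set(keys)) == len(wd)
        assert set(keys) == set(wd.meta)

    def test_seed_determinism_and_variation(self):
        wd = make_windows(30, 70)
        a = split_dataset(wd, SplitSpec(seed=5))
        b = split_dataset(wd, SplitSpec(seed=5))
        c = split_dataset(wd, SplitSpec(seed=6))
        assert [p.meta for p in a] == [p.meta for p in b]
        assert [p.meta for p in a] != [p.meta for p in c]

    def test_stratified_preserves_class_fractions(self):
        wd = make_windows(100, 100)
        _, val, test = split_dataset(wd, SplitSpec(seed=2), stratify=True)
        assert test.class_counts() == (20, 20)
        assert val.class_counts() == (16, 16)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=1.5)

    def test_too_few_examples(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_dataset(make_windows(1, 1), SplitSpec())


class TestIntervalSubsample:
    def test_stride_definition(self):
        assert interval_subsample(list(range(10)), 3, 0) == [0, 3, 6, 9]

    def test_truncation(self):
        assert interval_subsample(list(range(10)), 3, 0, subset_size=3) == [0, 3, 6]

    def test_benchmark_negative_total(self):
        """Stride 63 at offsets 0..4 with subsets of 349 collects 1745 items."""
        items = list(range(22244))
        subsets = [interval_subsample(items, 63, off, 349) for off in range(5)]
        assert all(len(s) == 349 for s in subsets)
        union = set().union(*subsets)
        assert len(union) == 1745

    def test_distinct_offsets_disjoint(self):
        items = list(range(1000))
        subsets = [set(interval_subsample(items, 7, off)) for off in range(7)]
        for i in range(7):
            for j in range(i + 1, 7):
                assert not subsets[i] & subsets[j]

    def test_oversized_request_reports_yield(self):
        with pytest.raises(ValueError, match="only 4"):
            interval_subsample(list(range(10)), 3, 0, subset_size=5)

    def test_offset_bounds(self):
        with pytest.raises(ValueError):
            interval_subsample(list(range(10)), 3, 3)


class TestSmote:
    @pytest.fixture
    def minority(self, rng):
        return rng.normal(size=(40, 6))

    def test_r_zero_reproduces_source_points(self, minority):
        out = smote_generate(minority, SmoteSpec(k=5, n_new=20, seed=1), r_override=0.0)
        for row in out:
            assert np.isclose(row, minority, atol=1e-12).all(axis=1).any()

    def test_r_one_reproduces_neighbors(self, minority):
        out = smote_generate(minority, SmoteSpec(k=5, n_new=20, seed=1), r_override=1.0)
        for row in out:
            assert np.isclose(row, minority, atol=1e-12).all(axis=1).any()

    def test_every_point_on_a_neighbor_segment(self):
        """Triangle equality over all (source, k-NN) pairs, exhaustively."""
        minority, _ = generate_feature_cloud(FeatureCloudSpec(n_minority=60, seed=4))
        k = 5
        out = smote_generate(minority, SmoteSpec(k=k, n_new=120, seed=7))
        d2 = np.linalg.norm(minority[:, None] - minority[None, :], axis=2)
        neighbor_idx = np.argsort(d2, axis=1)[:, 1 : k + 1]
        for new in out:
            found = False
            for i, x_old in enumerate(minority):
                for j in neighbor_idx[i]:
                    x_n = minority[j]
                    lhs = np.linalg.norm(new - x_old) + np.linalg.norm(x_n - new)
                    if abs(lhs - np.linalg.norm(x_n - x_old)) < 1e-8:
                        found = True
                        break
                if found:
                    break
            assert found, "synthetic point off every minority->neighbor segment"

    def test_convex_hull_bounding_box(self, minority):
        out = smote_generate(minority, SmoteSpec(k=5, n_new=50, seed=2))
        assert (out >= minority.min(axis=0) - 1e-12).all()
        assert (out <= minority.max(axis=0) + 1e-12).all()

    def test_deterministic_under_seed(self, minority):
        a = smote_generate(minority, SmoteSpec(k=3, n_new=10, seed=5))
        b = smote_generate(minority, SmoteSpec(k=3, n_new=10, seed=5))
        np.testing.assert_array_equal(a, b)

    def test_too_few_minority_samples(self, rng):
        with pytest.raises(ValueError, match="more than k"):
            smote_generate(rng.normal(size=(5, 3)), SmoteSpec(k=5, n_new=1))

    def test_zero_requested(self, minority):
        assert smote_generate(minority, SmoteSpec(k=5, n_new=0)).shape == (0, 6)


class TestClassWeights:
    def test_balanced_gives_unit_weights(self):
        w = compute_class_weights(np.array([0, 1] * 25))
        assert w == {0: 1.0, 1: 1.0}

    def test_formula_oracle(self):
        w = compute_class_weights(np.array([0] * 100 + [1] * 25))
        assert w[0] == pytest.approx(0.625)
        assert w[1] == pytest.approx(2.5)

    def test_weighted_totals_equal(self, rng):
        y = (rng.random(200) < 0.3).astype(int)
        w = compute_class_weights(y)
        assert (y == 1).sum() * w[1] == pytest.approx((y == 0).sum() * w[0])
        assert w[0] <= 1.0 <= w[1] or w[1] <= 1.0 <= w[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(np.ones(10))


class TestAssembleTrainingSet:
    def test_benchmark_composition(self):
        """232 positives + 214 negatives + 4 stride subsets of 349 ->
        1378 SMOTE positives and 3220 examples, exactly balanced."""
        train_pos = make_windows(232, 0, tag="pos")
        train_neg = make_windows(0, 214, tag="neg")
        pool = make_windows(0, 22244, tag="pool")
        sampler = IntervalSamplerSpec(interval=63, n_subsets=4, subset_size=349, first_offset=1)
        out = assemble_training_set(train_pos, train_neg, pool, sampler, SmoteSpec(k=5, seed=0))
        n_pos, n_neg = out.class_counts()
        assert n_pos == n_neg == 1610
        assert len(out) == 3220
        n_synth = sum(1 for pid, _ in out.meta if pid == "synthetic:smote")
        assert n_synth == 1378

    def test_already_balanced_passthrough(self):
        train_pos = make_windows(20, 0, tag="pos")
        train_neg = make_windows(0, 20, tag="neg")
        pool = make_windows(0, 0, tag="pool")
        sampler = IntervalSamplerSpec(interval=1, n_subsets=1, subset_size=0)
        out = assemble_training_set(train_pos, train_neg, pool, sampler, SmoteSpec(k=5))
        assert len(out) == 40
        assert set(out.meta) == set(train_pos.meta) | set(train_neg.meta)

    @pytest.mark.parametrize("n_pos, n_neg, n_sub", [(10, 40, 2), (7, 30, 1)])
    def test_output_balanced_for_random_compositions(self, n_pos, n_neg, n_sub):
        train_pos = make_windows(n_pos, 0, tag="pos")
        train_neg = make_windows(0, 5, tag="neg")
        pool = make_windows(0, n_neg, tag="pool")
        sampler = IntervalSamplerSpec(interval=4, n_subsets=n_sub, subset_size=None, first_offset=1)
        out = assemble_training_set(train_pos, train_neg, pool, sampler, SmoteSpec(k=3))
        a, b = out.class_counts()
        assert a == b

    def test_positive_surplus_rejected(self):
        train_pos = make_windows(50, 0, tag="pos")
        train_neg = make_windows(0, 10, tag="neg")
        pool = make_windows(0, 8, tag="pool")
        sampler = IntervalSamplerSpec(interval=2, n_subsets=1, first_offset=1)
        with pytest.raises(ValueError, match="cannot remove"):
            assemble_training_set(train_pos, train_neg, pool, sampler, SmoteSpec(k=5))

    def test_leakage_detected(self):
        train_pos = make_windows(8, 0, tag="pos")
        train_neg = make_windows(0, 8, tag="neg")
        pool = make_windows(0, 40, tag="pool")
        sampler = IntervalSamplerSpec(interval=4, n_subsets=2, first_offset=1)
        held_out = {("pool", 2)}  # offset 1, stride 4 selects index 1 -> key ("pool", 2)
        with pytest.raises(ValueError, match="leakage"):
            assemble_training_set(
                train_pos, train_neg, pool, sampler, SmoteSpec(k=3), forbid_meta=held_out
            )

    def test_shuffle_deterministic(self):
        train_pos = make_windows(10, 0, tag="pos")
        train_neg = make_windows(0, 12, tag="neg")
        pool = make_windows(0, 0, tag="pool")
        sampler = IntervalSamplerSpec(interval=1, n_subsets=1, subset_size=0)
        a = assemble_training_set(train_pos, train_neg, pool, sampler, SmoteSpec(k=3, seed=2), seed=4)
        b = assemble_training_set(train_pos, train_neg, pool, sampler, SmoteSpec(k=3, seed=2), seed=4)
        assert a.meta == b.meta
        np.testing.assert_array_equal(a.X, b.X)
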