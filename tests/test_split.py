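import numpy as np
import pytest

from colowt.core import PhaseLabel
from colowt.split import (
    FEATURE_LABELS,
    BalancedSample,
    ProcedureFeatures,
    _largest_remainder,
    cluster_procedures,
    features_from_timeline,
    stratified_split,
    subsample_training,
)
from colowt.synthetic import generate_timeline

from conftest import fast_config  # noqa: F401


def features(pid, counts, patient=None):
    return ProcedureFeatures(pid, np.asarray(counts), patient or f"pat-{pid}")


def random_features(n, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    return [
        features(f"p{i}", rng.poisson(50, size=len(FEATURE_LABELS)) + shift)
        for i in range(n)
    ]


class TestClusterProcedures:
    def test_single_cluster(self):
        labels = cluster_procedures(random_features(8), k=1)
        assert set(labels) == {0}

    def test_recovers_well_separated_groups(self):
        rng = np.random.default_rng(1)
        a = [
            features(f"a{i}", rng.poisson(20, len(FEATURE_LABELS)))
            for i in range(10)
        ]
        b = [
            features(f"b{i}", rng.poisson(20, len(FEATURE_LABELS)) + 100000)
            for i in range(10)
        ]
        labels = cluster_procedures(a + b, k=2, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_deterministic(self):
        feats = random_features(20)
        l1 = cluster_procedures(feats, k=3, seed=5)
        l2 = cluster_procedures(feats, k=3, seed=5)
        assert (l1 == l2).all()

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_procedures(random_features(3), k=4)


class TestLargestRemainder:
    @pytest.mark.parametrize(
        "m,expected",
        [
            (10, [7, 2, 1]),
            (20, [14, 4, 2]),
            (1, [1, 0, 0]),  # single procedure lands in train
            (96, [67, 19, 10]),
        ],
    )
    def test_allocations(self, m, expected):
        assert _largest_remainder(m, (0.7, 0.2, 0.1)) == expected

    def test_allocation_sums_to_m(self):
        for m in range(1, 60):
            assert sum(_largest_remainder(m, (0.7, 0.2, 0.1))) == m


class TestStratifiedSplit:
    def test_single_cluster_of_ten(self):
        feats = random_features(10)
        split = stratified_split(feats, [0] * 10, seed=1)
        sizes = {s: len(split.members(s)) for s in ("train", "test", "val")}
        assert sizes == {"train": 7, "test": 2, "val": 1}

    def test_per_cluster_proportions(self):
        feats = random_features(30)
        labels = [0] * 10 + [1] * 20
        split = stratified_split(feats, labels, seed=2)
        for cluster, ids in ((0, feats[:10]), (1, feats[10:])):
            counts = {"train": 0, "test": 0, "val": 0}
            for f in ids:
                counts[split.assignment[f.procedure_id]] += 1
            expected = _largest_remainder(len(ids), (0.7, 0.2, 0.1))
            assert [counts["train"], counts["test"], counts["val"]] == expected

    def test_partition_is_total_and_disjoint(self):
        feats = random_features(25)
        split = stratified_split(feats, [i % 3 for i in range(25)], seed=3)
        assert set(split.assignment) == {f.procedure_id for f in feats}

    def test_patient_overlap_rejected(self):
        # five procedures of one patient in one cluster must split 4/1/0,
        # so some pair of them always straddles two sets
        feats = [features(f"p{i}", [1] * 11, patient="shared") for i in range(5)]
        with pytest.raises(ValueError, match="patient"):
            stratified_split(feats, [0] * 5, seed=0)

    def test_deterministic(self):
        feats = random_features(16)
        labels = [i % 2 for i in range(16)]
        s1 = stratified_split(feats, labels, seed=7)
        s2 = stratified_split(feats, labels, seed=7)
        assert s1.assignment == s2.assignment


class TestSubsampleTraining:
    def pool(self, washing=500, suction=300, negatives=5000):
        frames = []
        for i in range(washing):
            frames.append((f"w{i}", frozenset({PhaseLabel.WASHING})))
        for i in range(suction):
            frames.append((f"s{i}", frozenset({PhaseLabel.SUCTION})))
        for i in range(negatives):
            frames.append((f"n{i}", frozenset()))
        return frames

    def test_equalises_subclasses_and_adds_negatives(self):
        sample = subsample_training(self.pool(), "cleaning", seed=0)
        assert len(sample.positives[PhaseLabel.WASHING]) == 300
        assert len(sample.positives[PhaseLabel.SUCTION]) == 300
        assert len(sample.negatives) == 1200  # 2/3 negative, 1/3 positive
        assert sample.warnings == []

    def test_detection_ratio_variant(self):
        sample = subsample_training(
            self.pool(), "cleaning", seed=0, negative_ratio=0.5
        )
        assert len(sample.negatives) == 300  # 1/3 negative, 2/3 positive

    def test_already_balanced_pool_unchanged_in_count(self):
        sample = subsample_training(
            self.pool(washing=400, suction=400), "cleaning", seed=1
        )
        assert sample.n_positive == 800

    def test_insufficient_negatives_takes_all_with_warning(self):
        with pytest.warns(UserWarning, match="only 100 available"):
            sample = subsample_training(
                self.pool(negatives=100), "cleaning", seed=2
            )
        assert len(sample.negatives) == 100
        assert sample.warnings

    def test_sampling_without_replacement(self):
        sample = subsample_training(self.pool(), "cleaning", seed=3)
        for refs in sample.positives.values():
            assert len(set(refs)) == len(refs)
        assert len(set(sample.negatives)) == len(sample.negatives)

    def test_deterministic(self):
        a = subsample_training(self.pool(), "cleaning", seed=4)
        b = subsample_training(self.pool(), "cleaning", seed=4)
        assert a.positives == b.positives and a.negatives == b.negatives

    def test_empty_subclass_rejected(self):
        frames = [("w0", frozenset({PhaseLabel.WASHING}))]
        with pytest.raises(ValueError, match="no frames"):
            subsample_training(frames, "cleaning")


def test_features_from_timeline_counts_every_label(fast_config):
    t = generate_timeline(fast_config)
    feats = features_from_timeline(t)
    index = {lab: i for i, lab in enumerate(FEATURE_LABELS)}
    manual = np.zeros(len(FEATURE_LABELS), dtype=int)
    for ann in t.annotations:
        for lab in ann.labels:
            manual[index[lab]] += 1
    assert (feats.counts == manual).all()
    assert feats.procedure_id == t.procedure_id
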