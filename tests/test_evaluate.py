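import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netgenes.evaluate import (
    auroc,
    compare_label_versions,
    load_reference_scores,
    loso,
)
from netgenes.io import LabelSet
from netgenes.model import ModelConfig
from netgenes.refex import base_features
from netgenes.synthetic import SyntheticCohortConfig, generate_interactome, plant_labels


def pair_counting_auroc(scores, labels):
    """Exhaustive positive-negative pair enumeration (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.1], [1, 0]) == 1.0

    def test_total_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 0, 0, 0, 0]) == 0.5

    def test_three_of_four_pairs(self):
        assert auroc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            auroc([0.1, 0.2], [1, 1])

    @settings(derandomize=True, max_examples=150)
    @given(st.data())
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(2, 12))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < len(l)
            )
        )
        scores = data.draw(
            st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n)
        )
        assert auroc(scores, labels) == pytest.approx(
            pair_counting_auroc(scores, labels)
        )

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_complement_identity(self, data):
        n = data.draw(st.integers(2, 10))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < len(l)
            )
        )
        scores = data.draw(st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n))
        flipped = [1 - l for l in labels]
        assert auroc(scores, labels) + auroc(scores, flipped) == pytest.approx(1.0)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.RandomState(3)
        scores = rng.normal(size=40)
        labels = rng.randint(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        assert auroc(np.exp(scores), labels) == pytest.approx(auroc(scores, labels))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.RandomState(11)
        scores = rng.choice([0.1, 0.4, 0.4, 0.9], size=60)
        labels = rng.randint(0, 2, size=60)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


def tiny_cohort(betas=(3.0, 0.0), n_organisms=3, n_nodes=150, seed=5):
    """Small cohort using only the six base features (research-scale schema)."""
    cfg = SyntheticCohortConfig(
        n_organisms=n_organisms, n_nodes=n_nodes, m=2,
        beta_deg=betas[0], beta_btw=betas[1], seed=seed,
    )
    cohort = []
    for i in range(n_organisms):
        net = generate_interactome(cfg, i)
        cohort.append((net, base_features(net), plant_labels(net, cfg, i)))
    return cohort


class TestLoso:
    def test_strong_signal_recovered_across_species(self):
        cohort = tiny_cohort()
        res = loso(cohort, ModelConfig(n_trees=30, n_folds=3, seed=0),
                   allow_nonstandard_schema=True)
        assert len(res.per_organism) == 3
        assert res.mean_auroc > 0.7

    def test_never_trains_on_held_out_organism(self):
        cohort = tiny_cohort()
        res = loso(cohort, ModelConfig(n_trees=5, n_folds=2, seed=0),
                   allow_nonstandard_schema=True)
        for held_out, trained in res.trained_on.items():
            assert held_out not in trained
            assert len(trained) == len(cohort) - 1

    def test_single_class_organism_skipped_with_warning(self, caplog):
        cohort = tiny_cohort()
        net, fm, lbl = cohort[0]
        degenerate = LabelSet(
            organism=lbl.organism, essential=set(), universe=lbl.universe,
            version_tag=lbl.version_tag,
        )
        cohort[0] = (net, fm, degenerate)
        with caplog.at_level(logging.WARNING, logger="netgenes"):
            res = loso(cohort, ModelConfig(n_trees=5, n_folds=2, seed=0),
                       allow_nonstandard_schema=True)
        assert res.n_skipped == 1
        assert lbl.organism not in res.per_organism

    def test_mean_is_arithmetic_mean_of_per_organism(self):
        cohort = tiny_cohort()
        res = loso(cohort, ModelConfig(n_trees=5, n_folds=2, seed=0),
                   allow_nonstandard_schema=True)
        assert res.mean_auroc == pytest.approx(
            np.mean(list(res.per_organism.values()))
        )

    def test_cohort_of_one_rejected(self):
        cohort = tiny_cohort()[:1]
        with pytest.raises(ValueError, match="two organisms"):
            loso(cohort, ModelConfig(n_folds=2), allow_nonstandard_schema=True)

    def test_records_csv_round_trip(self, tmp_path):
        cohort = tiny_cohort()
        res = loso(cohort, ModelConfig(n_trees=5, n_folds=2, seed=0),
                   allow_nonstandard_schema=True)
        out = tmp_path / "loso.csv"
        res.to_csv(out)
        back = pd.read_csv(out)
        assert list(back.columns) == ["organism", "auroc", "n_pos", "n_neg", "version_tag"]
        assert len(back) == 3


def fake_result(values):
    from netgenes.evaluate import LosoResult

    return LosoResult(
        per_organism=dict(values),
        records=pd.DataFrame(
            [{"organism": o, "auroc": v, "n_pos": 1, "n_neg": 1, "version_tag": "x"}
             for o, v in values.items()]
        ),
        version_tag="x",
        config=ModelConfig(),
        trained_on={},
    )


class TestCompareLabelVersions:
    def test_identical_results_are_degenerate_with_zero_difference(self):
        res = fake_result({"a": 0.7, "b": 0.8})
        rep = compare_label_versions(res, res)
        assert rep.mean_diff == 0.0 and rep.degenerate
        assert "degenerate" in rep.summary()

    def test_constant_shift_flagged_degenerate(self):
        res_a = fake_result({"a": 0.6, "b": 0.7})
        res_b = fake_result({"a": 0.7, "b": 0.8})
        rep = compare_label_versions(res_a, res_b)
        assert rep.mean_diff == pytest.approx(0.1)
        assert rep.degenerate and np.isnan(rep.paired_p)

    def test_organism_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            compare_label_versions(fake_result({"a": 0.5}), fake_result({"b": 0.5}))

    def test_both_tests_reported_on_generic_data(self):
        rng = np.random.RandomState(0)
        orgs = [f"o{i}" for i in range(10)]
        res_a = fake_result({o: v for o, v in zip(orgs, rng.uniform(0.5, 0.9, 10))})
        res_b = fake_result({o: v for o, v in zip(orgs, rng.uniform(0.5, 0.9, 10))})
        rep = compare_label_versions(res_a, res_b)
        assert 0 <= rep.paired_p <= 1 and 0 <= rep.welch_p <= 1


class TestReferenceScores:
    def test_reference_table_shape(self):
        ref = load_reference_scores()
        assert len(ref) == 34
        assert ref["training_cohort"].sum() == 27
        assert set(["auroc_deg10", "auroc_deg15"]) <= set(ref.columns)

    def test_label_version_gain_from_published_scores(self):
        ref = load_reference_scores()
        res10 = fake_result(dict(zip(ref["organism"], ref["auroc_deg10"])))
        res15 = fake_result(dict(zip(ref["organism"], ref["auroc_deg15"])))
        rep = compare_label_versions(res10, res15)
        assert rep.mean_diff_percent == 4
        assert not rep.degenerate
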