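"""Metric formulas against brute-force enumeration, AUC properties, the
cross-validation protocol, rank-level accuracy, random baselines."""

import itertools
import math

import numpy as np
import pytest

from viralmil.bags import Instance, VirusBag
from viralmil.datasets import TaxonomyRecord
from viralmil.evaluation import (
    auc_score,
    confusion,
    cross_validate,
    metrics,
    random_baseline,
    rank_accuracy,
)
from viralmil.mil_core import MILConfig


class TestConfusion:
    def test_hand_enumeration(self):
        c = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_all_correct_positives(self):
        c = confusion([1, 1], [1, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 0)

    def test_empty(self):
        c = confusion([], [])
        assert c.total == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1], [1, 0])


def brute_metrics(pred, lab):
    """Formula restatement by direct counting, used as the oracle."""
    tp = sum(p == 1 and l == 1 for p, l in zip(pred, lab))
    tn = sum(p == 0 and l == 0 for p, l in zip(pred, lab))
    fp = sum(p == 1 and l == 0 for p, l in zip(pred, lab))
    fn = sum(p == 0 and l == 1 for p, l in zip(pred, lab))
    div = lambda a, b: a / b if b else math.nan
    return {
        "accuracy": div(tp + tn, tp + tn + fp + fn),
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "precision": div(tp, tp + fp),
    }


class TestMetricFormulas:
    def test_balanced_confusion_case(self):
        r = metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], [1, 0, 1, 0])
        assert r.accuracy == 0.5
        assert r.sensitivity == 0.5
        assert r.specificity == 0.5
        assert r.precision == 0.5

    def test_all_four_sample_configurations_match_oracle(self):
        """Exhaustive check over every prediction/label assignment on 4 samples."""
        for lab in itertools.product([0, 1], repeat=4):
            if len(set(lab)) < 2:
                continue  # AUC undefined
            for pred in itertools.product([0, 1], repeat=4):
                scores = [p + 0.5 * l * 1e-9 for p, l in zip(pred, lab)]
                r = metrics(scores, list(pred), list(lab))
                o = brute_metrics(pred, lab)
                for key, expected in o.items():
                    got = getattr(r, key)
                    if math.isnan(expected):
                        assert math.isnan(got), (pred, lab, key)
                    else:
                        assert got == pytest.approx(expected), (pred, lab, key)

    def test_undefined_ratio_is_nan_not_zero(self):
        r = metrics([0.2, 0.1], [0, 0], [0, 1])  # no predicted positives
        assert math.isnan(r.precision)

    def test_macro_f1_averages_both_classes(self):
        # pred == labels: both per-class F1s are 1
        r = metrics([0.9, 0.1], [1, 0], [1, 0])
        assert r.f1_macro == 1.0


class TestAuc:
    def test_perfectly_separated(self):
        assert auc_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_monotone_transform_invariant(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        a1 = auc_score(scores, labels)
        a2 = auc_score(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2)

    def test_random_scores_near_half(self, rng):
        labels = np.tile([0, 1], 2000)
        scores = rng.uniform(size=4000)
        assert auc_score(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.5, 0.4], [1, 1])

    def test_matches_rank_statistic_oracle(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        from scipy.stats import rankdata
        r = rankdata(scores)
        pos = labels == 1
        n1, n0 = pos.sum(), (~pos).sum()
        oracle = (r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc_score(scores, labels) == pytest.approx(oracle)


def _labelled_bags(rng, n=100, dim=5, shift=6.0):
    bags = []
    for i in range(n):
        label = i % 2
        m = int(rng.integers(2, 5))
        X = rng.normal(size=(m, dim))
        if label:
            X[0, 0] += shift
        bags.append(VirusBag(f"b{i}", [Instance(f"p{j}") for j in range(m)], X, label))
    return bags


@pytest.fixture(scope="module")
def cv_result():
    rng = np.random.default_rng(0)
    bags = _labelled_bags(rng)
    config = MILConfig(input_dim=5, hidden_dim=16, attention_dim=4,
                       epochs=60, seed=0)
    return bags, cross_validate(bags, config, seed=0, n_folds=5)


class TestCrossValidate:
    def test_five_reports_and_best_fold(self, cv_result):
        _, res = cv_result
        assert len(res.fold_reports) == 5
        assert res.best_fold == int(np.argmax(res.fold_val_auc))

    def test_test_split_fraction(self, cv_result):
        bags, res = cv_result
        assert len(res.test_ids) == 20  # 20% of 100

    def test_separable_folds_learn(self, cv_result):
        _, res = cv_result
        assert all(r.auc >= 0.95 for r in res.fold_reports)

    def test_deterministic(self, cv_result):
        bags, res = cv_result
        config = MILConfig(input_dim=5, hidden_dim=16, attention_dim=4,
                           epochs=60, seed=0)
        res2 = cross_validate(bags, config, seed=0, n_folds=5)
        assert res2.test_ids == res.test_ids
        assert res2.fold_val_auc == res.fold_val_auc

    def test_too_few_bags_rejected(self, rng):
        bags = _labelled_bags(rng, n=9)
        with pytest.raises(ValueError):
            cross_validate(bags, MILConfig(input_dim=5), seed=0)

    def test_fold_partition(self, rng):
        # every 80%-bag appears in exactly one validation fold
        from sklearn.model_selection import StratifiedKFold, train_test_split
        labels = np.array([b.label for b in _labelled_bags(rng)])
        idx = np.arange(100)
        tr, te = train_test_split(idx, test_size=0.2, random_state=0, stratify=labels)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for _, va in skf.split(tr, labels[tr]):
            seen.extend(tr[i] for i in va)
        assert sorted(seen) == sorted(tr)


class TestRankAccuracy:
    taxonomy = {
        "hostA": TaxonomyRecord("hostA", dict(genus="g1", family="f1", order="o1",
                                              **{"class": "c1"}, phylum="p1", kingdom="k1")),
        "hostB": TaxonomyRecord("hostB", dict(genus="g2", family="f2", order="o2",
                                              **{"class": "c2"}, phylum="p1", kingdom="k1")),
        "hostC": TaxonomyRecord("hostC", dict(genus="g9", family="f9", order="o9",
                                              **{"class": "c9"}, phylum="p9", kingdom="k9")),
    }

    def test_exact_match_everywhere(self):
        out = rank_accuracy(["hostA"] * 3, ["hostA"] * 3, self.taxonomy)
        assert all(v["accuracy"] == 1.0 for v in out.values())

    def test_shared_phylum_only(self):
        out = rank_accuracy(["hostB"], ["hostA"], self.taxonomy)
        assert out["genus"]["accuracy"] == 0.0
        assert out["class"]["accuracy"] == 0.0
        assert out["phylum"]["accuracy"] == 1.0
        assert out["kingdom"]["accuracy"] == 1.0

    def test_disjoint_lineages(self):
        out = rank_accuracy(["hostC"], ["hostA"], self.taxonomy)
        assert all(v["accuracy"] == 0.0 for v in out.values())

    def test_missing_rank_excluded_with_count(self):
        taxo = dict(self.taxonomy)
        taxo["hostX"] = TaxonomyRecord("hostX", {"phylum": "p1"})
        out = rank_accuracy(["hostX", "hostA"], ["hostA", "hostA"], taxo)
        assert out["genus"]["excluded"] == 1
        assert out["genus"]["n"] == 1
        assert out["phylum"]["excluded"] == 0


class TestRandomBaseline:
    @pytest.mark.parametrize("k,expected", [(22, 0.045), (36, 0.028), (1, 1.0), (2, 0.5)])
    def test_values(self, k, expected):
        assert random_baseline(k) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            random_baseline(0)
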