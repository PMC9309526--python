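"""Compound preprocessing, binarization, diversity split, and metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qualnet.mleval import (
    EXCLUDED,
    binarize,
    diverse_split,
    evaluate,
    preprocess_compounds,
    score_classifier,
)
from qualnet.synthetic import synthetic_compound_table


class TestBinarize:
    @pytest.mark.parametrize(
        "ic50, expected",
        [
            (10.0, 1),      # at the active threshold
            (0.01, 1),
            (15.0, EXCLUDED),  # inside the (10, 18] window
            (18.0, EXCLUDED),
            (18.01, 0),
            (1600.0, 0),    # range endpoint
        ],
    )
    def test_dual_cutoff_labels(self, ic50, expected):
        assert binarize(ic50) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            binarize(0.0)
        with pytest.raises(ValueError):
            binarize(-1.0)

    @given(st.floats(min_value=0.01, max_value=1600.0),
           st.floats(min_value=0.01, max_value=1600.0))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_lower_ic50_never_less_active(self, a, b):
        lo, hi = min(a, b), max(a, b)
        rank = {1: 2, EXCLUDED: 1, 0: 0}
        assert rank[binarize(lo)] >= rank[binarize(hi)]

    def test_custom_cutoffs(self):
        assert binarize(12.0, active_max=15.0, least_active_min=15.0) == 1
        assert binarize(16.0, active_max=15.0, least_active_min=15.0) == 0


def _records(rows):
    return pd.DataFrame(rows, columns=["id", "mw", "ic50_um"])


class TestPreprocess:
    def test_small_fragment_removed_and_logged(self):
        df = _records([("a", 150.0, 1.0), ("b", 300.0, 1.0)])
        clean, log = preprocess_compounds(df)
        assert list(clean["id"]) == ["b"]
        assert "fragment" in log.iloc[0]["reason"]

    def test_empty_input_gives_empty_output_and_log(self):
        clean, log = preprocess_compounds(_records([]))
        assert clean.empty and log.empty

    def test_inconsistent_duplicates_both_removed(self):
        df = _records([("a", 300.0, 0.1), ("a", 300.0, 10.0), ("b", 300.0, 1.0)])
        clean, log = preprocess_compounds(df, consistency_ratio=10.0)
        assert list(clean["id"]) == ["b"]
        assert "inconsistent" in log.iloc[0]["reason"]

    def test_consistent_duplicates_collapse_to_geometric_mean(self):
        df = _records([("a", 300.0, 1.0), ("a", 300.0, 4.0)])
        clean, log = preprocess_compounds(df, consistency_ratio=10.0)
        assert len(clean) == 1
        assert clean.iloc[0]["ic50_um"] == pytest.approx(2.0)  # sqrt(1*4)
        assert "collapsed" in log.iloc[0]["reason"]

    def test_missing_required_columns_rejected(self):
        with pytest.raises(ValueError, match="required"):
            preprocess_compounds(pd.DataFrame({"id": ["a"]}))

    def test_rows_with_missing_fields_dropped_and_logged(self):
        df = _records([("a", np.nan, 1.0), ("b", 300.0, 1.0)])
        clean, log = preprocess_compounds(df)
        assert list(clean["id"]) == ["b"]
        assert "missing" in log.iloc[0]["reason"]


class TestDiverseSplit:
    def test_line_of_points_puts_both_ends_in_test(self):
        df = pd.DataFrame(
            {"id": [str(i) for i in range(10)], "d01": list(range(10))}
        )
        res = diverse_split(df, test_fraction=0.2, seed=0)
        assert set(res.test_ids) == {"0", "9"}

    def test_partition_property(self):
        df = synthetic_compound_table(seed=5, n=60)
        res = diverse_split(df, test_fraction=0.2, seed=1)
        assert set(res.train_ids) | set(res.test_ids) == set(df["id"])
        assert not set(res.train_ids) & set(res.test_ids)
        assert len(res.test_ids) == 12

    def test_seed_determinism(self):
        df = synthetic_compound_table(seed=6, n=40)
        a = diverse_split(df, seed=3)
        b = diverse_split(df, seed=3)
        assert a == b

    def test_maximin_beats_median_random_split_spread(self):
        # the minimum pairwise test-set distance under the diverse split
        # must exceed the median of the same statistic over random splits
        rng = np.random.default_rng(0)
        df = synthetic_compound_table(seed=7, n=40)
        cols = [c for c in df.columns if c.startswith("d")]
        x = df[cols].to_numpy()
        z = (x - x.mean(0)) / x.std(0)

        def min_pairwise(idx):
            pts = z[idx]
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            return d[np.triu_indices(len(idx), k=1)].min()

        res = diverse_split(df, test_fraction=0.2, seed=0)
        pos = {cid: i for i, cid in enumerate(df["id"])}
        ours = min_pairwise([pos[c] for c in res.test_ids])
        n_test = len(res.test_ids)
        randoms = [
            min_pairwise(rng.choice(len(df), size=n_test, replace=False))
            for _ in range(1000)
        ]
        assert ours >= np.median(randoms)

    def test_missing_descriptors_rejected(self):
        df = pd.DataFrame({"id": ["a", "b"], "d01": [1.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            diverse_split(df)


class TestEvaluate:
    def test_perfect_prediction(self):
        cm, m = evaluate([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 0, 2, 0)
        assert m.accuracy == 1.0 and m.mcc == 1.0 and m.f_measure == 1.0

    def test_hand_worked_confusion_matrix(self):
        # TP=5 FP=1 TN=3 FN=1: accuracy 0.8, MCC 14/24, F 5/6
        pred = [1] * 5 + [1] + [0] * 3 + [0]
        true = [1] * 5 + [0] + [0] * 3 + [1]
        cm, m = evaluate(pred, true)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (5, 1, 3, 1)
        assert m.accuracy == pytest.approx(0.8)
        assert m.mcc == pytest.approx(14 / 24)
        assert m.f_measure == pytest.approx(5 / 6)
        assert m.precision == pytest.approx(5 / 6)
        assert m.sensitivity == m.recall == pytest.approx(5 / 6)
        assert m.specificity == pytest.approx(3 / 4)

    def test_mcc_undefined_when_a_marginal_vanishes(self):
        _, m = evaluate([1, 1], [1, 1])  # no negatives at all
        assert m.mcc is None

    def test_length_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([1], [1, 0])
        with pytest.raises(ValueError, match="binary"):
            evaluate([2], [1])

    def test_agrees_with_sklearn_on_random_labelings(self):
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            true = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            if len(set(true)) < 2 or len(set(pred)) < 2:
                continue  # degenerate marginals handled separately
            _, m = evaluate(list(pred), list(true))
            assert m.accuracy == pytest.approx(accuracy_score(true, pred))
            assert m.recall == pytest.approx(recall_score(true, pred))
            assert m.precision == pytest.approx(precision_score(true, pred))
            assert m.f_measure == pytest.approx(f1_score(true, pred))
            assert m.mcc == pytest.approx(matthews_corrcoef(true, pred))

    def test_class_swap_exchanges_sensitivity_and_specificity(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            true = list(rng.integers(0, 2, n))
            pred = list(rng.integers(0, 2, n))
            _, m = evaluate(pred, true)
            _, swapped = evaluate([1 - p for p in pred], [1 - t for t in true])
            assert swapped.accuracy == pytest.approx(m.accuracy)
            assert swapped.sensitivity == pytest.approx(m.specificity)
            assert swapped.specificity == pytest.approx(m.sensitivity)
            if m.mcc is not None and swapped.mcc is not None:
                assert abs(swapped.mcc) == pytest.approx(abs(m.mcc))


class TestScoreClassifier:
    def test_decision_tree_separates_well_separated_classes(self):
        from sklearn.tree import DecisionTreeClassifier

        df = synthetic_compound_table(seed=8, n=300, class_separation=4.0)
        df["label"] = df["ic50_um"].map(binarize)
        df = df[df["label"].notna()].copy()
        res = diverse_split(df, test_fraction=0.2, seed=0)
        train = df[df["id"].isin(res.train_ids)]
        test = df[df["id"].isin(res.test_ids)]
        _, metrics = score_classifier(
            DecisionTreeClassifier(random_state=0, min_samples_leaf=1), train, test
        )
        assert metrics.accuracy > 0.75
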