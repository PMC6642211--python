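"""LFQ quantifiability, differential testing, classification, tiers, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from structbind import condensate as cond
from structbind.errors import DegenerateInputError
from structbind.synthetic import LfqParams, generate_lfq_experiment


def matrix_from_rows(rows):
    cols = [f"{c}_{r}" for c in cond.CONDITIONS for r in range(1, 5)]
    return pd.DataFrame(
        {c: [row.get(c, np.nan) for row in rows.values()] for c in cols},
        index=pd.Index(rows.keys(), name="protein_id"),
    )


class TestQuantifiableFilter:
    def test_three_valid_in_one_condition_retained(self):
        rows = {"p1": {f"background_{i}": 10.0 for i in range(1, 4)}}
        kept = cond.quantifiable_filter(matrix_from_rows(rows))
        assert list(kept.index) == ["p1"]

    def test_two_valid_everywhere_dropped(self):
        rows = {"p1": {f"{c}_{i}": 10.0
                       for c in cond.CONDITIONS for i in (1, 2)}}
        kept = cond.quantifiable_filter(matrix_from_rows(rows))
        assert len(kept) == 0

    def test_fully_observed_retained(self):
        rows = {"p1": {f"{c}_{i}": 10.0
                       for c in cond.CONDITIONS for i in range(1, 5)}}
        assert len(cond.quantifiable_filter(matrix_from_rows(rows))) == 1


class TestDifferential:
    def test_identical_values_flagged_null(self):
        rows = {"p1": {f"{c}_{i}": 100.0
                       for c in cond.CONDITIONS for i in range(1, 5)}}
        diff = cond.differential(matrix_from_rows(rows), "hs_rna")
        assert diff.loc["p1", "log_ratio"] == 0.0
        assert diff.loc["p1", "neglog_p"] == 0.0  # p = 1
        assert diff.loc["p1", "zero_variance"]

    def test_planted_twofold_decrease_detected(self):
        rng = np.random.default_rng(1)
        rows = {}
        for i in range(20):
            base = 2 ** rng.normal(25, 0.05, 4)
            hs = 2 ** (np.log2(2 ** rng.normal(25, 0.05, 4)) - 1.0)
            rows[f"p{i}"] = {
                **{f"background_{r}": base[r - 1] for r in range(1, 5)},
                **{f"hs_rna_{r}": hs[r - 1] for r in range(1, 5)},
                **{f"ls_rna_{r}": base[r - 1] for r in range(1, 5)},
            }
        diff = cond.differential(matrix_from_rows(rows), "hs_rna")
        assert (diff["neglog_p"] > -np.log10(0.05)).all()
        assert (diff["log_ratio"] < 0).all()
        assert diff["log_ratio"].mean() == pytest.approx(-1.0, abs=0.1)

    def test_untestable_with_single_value(self):
        rows = {"p1": {"background_1": 10.0,
                       **{f"hs_rna_{i}": 9.0 for i in range(1, 5)}}}
        diff = cond.differential(matrix_from_rows(rows), "hs_rna")
        assert diff.loc["p1", "untestable"]

    def test_null_type_one_error_near_alpha(self):
        params = LfqParams(n_proteins=1000, effect_size=0.0, missing_rate=0.0)
        matrix, _, _ = generate_lfq_experiment(params, seed=21)
        diff = cond.differential(cond.quantifiable_filter(matrix), "hs_rna")
        fp_rate = (diff["neglog_p"] > -np.log10(0.05)).mean()
        assert fp_rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 1000))


class TestClassify:
    @pytest.mark.parametrize(
        "neglog_p, log_ratio, expected",
        [
            (2.0, -0.4, "released"),
            (2.0, 0.4, "kept"),
            (0.5, -3.0, "static"),
            (1.3, -0.4, "static"),  # threshold itself is not significant
        ],
    )
    def test_rule_application(self, neglog_p, log_ratio, expected):
        diff = pd.DataFrame(
            {"log_ratio": [log_ratio], "neglog_p": [neglog_p],
             "untestable": [False], "zero_variance": [False]},
            index=pd.Index(["p1"], name="protein_id"),
        )
        assert cond.classify(diff)["p1"] == expected

    def test_untestable_is_unquantified(self):
        diff = pd.DataFrame(
            {"log_ratio": [np.nan], "neglog_p": [np.nan],
             "untestable": [True], "zero_variance": [False]},
            index=pd.Index(["p1"], name="protein_id"),
        )
        assert cond.classify(diff)["p1"] == "unquantified"

    def test_partition_on_synthetic_experiment(self, lfq_experiment):
        matrix, _, truth = lfq_experiment
        quant = cond.quantifiable_filter(matrix)
        labels = cond.classify(cond.differential(quant, "hs_rna"))
        assert set(labels.unique()) <= {"released", "kept", "static",
                                        "unquantified"}
        recovered = (labels == truth[quant.index]).mean()
        assert recovered > 0.9


class TestStringencyTiers:
    def make_diff(self, entries):
        return pd.DataFrame(
            {
                "log_ratio": [e[0] for e in entries.values()],
                "neglog_p": [e[1] for e in entries.values()],
                "untestable": False,
                "zero_variance": False,
            },
            index=pd.Index(entries.keys(), name="protein_id"),
        )

    def test_examples(self):
        entries = {
            "tight": (0.1, 1.0),    # all tiers
            "sig": (0.1, 2.0),      # significant: no tier
            "loose": (0.5, 1.0),    # low tier only
        }
        diff = self.make_diff(entries)
        tiers = cond.stringency_tiers(diff, diff)
        assert "tight" in tiers["high"] and "tight" in tiers["low"]
        assert all("sig" not in t for t in tiers.values())
        assert "loose" in tiers["low"] and "loose" not in tiers["medium"]

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_nesting_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        entries_hs = {f"p{i}": (rng.normal(0, 0.5), rng.uniform(0, 3))
                      for i in range(n)}
        entries_ls = {f"p{i}": (rng.normal(0, 0.5), rng.uniform(0, 3))
                      for i in range(n)}
        tiers = cond.stringency_tiers(self.make_diff(entries_hs),
                                      self.make_diff(entries_ls))
        assert tiers["high"] <= tiers["medium"] <= tiers["low"]


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"a": 3.0, "b": 2.5, "c": 1.0, "d": 0.5}
        assert cond.roc_auc(scores, ["a", "b"], ["c", "d"]) == 1.0

    def test_hand_pair_enumeration(self):
        scores = {"p1": 3, "p2": 1, "n1": 2, "n2": 0}
        assert cond.roc_auc(scores, ["p1", "p2"], ["n1", "n2"]) == 0.75

    def test_ties_credited_half(self):
        scores = {"p": 1.0, "n": 1.0}
        assert cond.roc_auc(scores, ["p"], ["n"]) == 0.5

    def test_random_labels_near_half(self, rng):
        scores = {f"p{i}": float(v) for i, v in
                  enumerate(rng.normal(size=1000))}
        ids = list(scores)
        assert cond.roc_auc(scores, ids[:500], ids[500:]) == pytest.approx(
            0.5, abs=0.05
        )

    def test_monotone_transform_invariance(self, rng):
        scores = {f"p{i}": float(v) for i, v in
                  enumerate(rng.normal(size=60))}
        ids = list(scores)
        pos, neg = ids[:20], ids[20:]
        base = cond.roc_auc(scores, pos, neg)
        warped = {k: np.exp(3 * v) for k, v in scores.items()}
        assert cond.roc_auc(warped, pos, neg) == pytest.approx(base)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = np.round(rng.normal(size=200), 1)  # rounded to force ties
        scores = {f"p{i}": float(v) for i, v in enumerate(values)}
        ids = list(scores)
        pos, neg = ids[:80], ids[80:]
        y_true = [1] * len(pos) + [0] * len(neg)
        y_score = [scores[p] for p in pos + neg]
        assert cond.roc_auc(scores, pos, neg) == pytest.approx(
            roc_auc_score(y_true, y_score)
        )

    def test_overlap_and_empty_rejected(self):
        scores = {"a": 1.0, "b": 2.0}
        with pytest.raises(ValueError):
            cond.roc_auc(scores, ["a"], ["a", "b"])
        with pytest.raises(DegenerateInputError):
            cond.roc_auc(scores, [], ["a"])


class TestStringencyRoc:
    def test_auc_improves_as_negatives_tighten(self):
        params = LfqParams(n_proteins=1500, planted_auc=0.75,
                           static_drift_sd=0.25, score_drift_coupling=1.5,
                           missing_rate=0.0)
        matrix, scores, truth = generate_lfq_experiment(params, seed=13)
        quant = cond.quantifiable_filter(matrix)
        diff_hs = cond.differential(quant, "hs_rna")
        diff_ls = cond.differential(quant, "ls_rna")
        labels_hs = cond.classify(diff_hs)
        labels_ls = cond.classify(diff_ls)
        positives = [p for p in quant.index
                     if labels_hs[p] == "released" and labels_ls[p] != "released"]
        tiers = cond.stringency_tiers(diff_hs, diff_ls)
        score_map = scores.to_dict()
        aucs = {}
        for name in ("low", "medium", "high"):
            negatives = [p for p in tiers[name] if p not in positives]
            aucs[name] = cond.roc_auc(score_map, positives, negatives)
        assert aucs["low"] <= aucs["medium"] <= aucs["high"]
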