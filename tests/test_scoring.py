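import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from npcpgx.scoring import (
    label_by_ic50,
    random_signature_null,
    roc_auc,
    score_genesets,
    score_response_correlation,
    ssgsea_score,
)


def _toy_matrix():
    # 5 genes x 2 samples; set genes occupy the top ranks of s1 only
    return pd.DataFrame(
        {
            "s_top": [50.0, 40.0, 3.0, 2.0, 1.0],
            "s_bottom": [1.0, 2.0, 30.0, 40.0, 50.0],
        },
        index=["gA", "gB", "gC", "gD", "gE"],
    )


def _brute_force_ssgsea(values, in_set, alpha):
    """Independent running-sum evaluation for one sample (plain loops)."""
    order = np.argsort(-np.asarray(values), kind="stable")
    ranks = {
        g: r for r, g in enumerate(sorted(range(len(values)),
                                          key=lambda i: values[i]), start=1)
    }
    w_total = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = sum(1 for i in order if not in_set[i])
    score, p_in, p_out = 0.0, 0.0, 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** alpha / w_total
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


class TestSSGSEA:
    def test_extremal_orderings(self):
        scores = ssgsea_score(_toy_matrix(), ["gA", "gB"])
        assert scores["s_top"] > scores["s_bottom"]

    def test_monotone_transform_invariance(self):
        x = _toy_matrix()
        a = ssgsea_score(x, ["gA", "gB"])
        b = ssgsea_score(np.exp(x / 10.0), ["gA", "gB"])
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_matches_brute_force_running_sum(self):
        x = _toy_matrix()
        alpha = 0.25
        scores = ssgsea_score(x, ["gA", "gB"], alpha=alpha)
        in_set = [g in ("gA", "gB") for g in x.index]
        for col in x.columns:
            expected = _brute_force_ssgsea(x[col].tolist(), in_set, alpha)
            assert scores[col] == pytest.approx(expected, abs=1e-9)

    def test_too_small_set_rejected(self):
        with pytest.raises(ValueError, match=">= 2 genes"):
            ssgsea_score(_toy_matrix(), ["gA"])
        with pytest.raises(ValueError, match=">= 2 genes"):
            ssgsea_score(_toy_matrix(), ["gA", "gB", "gC", "gD"])

    def test_rescaled_variant_in_unit_interval(self):
        s = ssgsea_score(_toy_matrix(), ["gA", "gB"], rescale=True)
        assert s.min() == 0.0 and s.max() == 1.0

    def test_score_genesets_matches_single_calls(self, rng):
        x = pd.DataFrame(
            rng.normal(size=(30, 6)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(6)],
        )
        sets = {"a": [f"g{i}" for i in range(5)],
                "b": [f"g{i}" for i in range(10, 18)]}
        multi = score_genesets(x, sets)
        for name, members in sets.items():
            np.testing.assert_allclose(
                multi[name].values, ssgsea_score(x, members).values, atol=1e-12
            )


class TestLabelByIC50:
    def test_floor_arithmetic_n20(self):
        ic50 = pd.Series(np.arange(20, dtype=float) + 1)
        labels = label_by_ic50(ic50, q=0.10)
        assert (labels == "sensitive").sum() == 2
        assert (labels == "resistant").sum() == 2
        assert (labels == "unlabeled").sum() == 16

    def test_cell_line_panel_scale(self):
        rng = np.random.default_rng(1)
        ic50 = pd.Series(rng.lognormal(0, 1, size=880))
        labels = label_by_ic50(ic50, q=0.10)
        assert (labels == "sensitive").sum() == 88
        assert (labels == "resistant").sum() == 88

    def test_sensitive_ic50s_below_resistant(self):
        rng = np.random.default_rng(2)
        ic50 = pd.Series(rng.permutation(np.linspace(0.1, 20, 50)))
        labels = label_by_ic50(ic50, q=0.10)
        assert ic50[labels == "sensitive"].max() < ic50[labels == "resistant"].min()

    def test_identical_ic50s_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            label_by_ic50(pd.Series([1.0] * 20))

    def test_tiny_cohort_warns(self):
        with pytest.warns(UserWarning, match="tiny"):
            label_by_ic50(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]), q=0.2)

    def test_bad_quantile_rejected(self):
        with pytest.raises(ValueError, match="q must be"):
            label_by_ic50(pd.Series([1.0, 2.0]), q=0.6)


def _labels(seq):
    return pd.Series(
        ["sensitive" if v else "resistant" for v in seq],
        index=[f"s{i}" for i in range(len(seq))],
    )


def _scores(vals):
    return pd.Series(vals, index=[f"s{i}" for i in range(len(vals))])


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc(_scores([0.9, 0.8, 0.2, 0.1]), _labels([1, 1, 0, 0]))
        assert res.auc == 1.0

    def test_all_ties_half(self):
        res = roc_auc(_scores([0.5] * 6), _labels([1, 1, 1, 0, 0, 0]))
        assert res.auc == 0.5

    def test_four_pair_enumeration(self):
        res = roc_auc(_scores([0.9, 0.7, 0.6, 0.2]), _labels([1, 0, 1, 0]))
        assert res.auc == pytest.approx(0.75)

    def test_curve_endpoints(self):
        res = roc_auc(_scores([0.9, 0.7, 0.6, 0.2]), _labels([1, 0, 1, 0]))
        np.testing.assert_allclose(res.points[0], [0.0, 0.0])
        np.testing.assert_allclose(res.points[-1], [1.0, 1.0])

    def test_label_complementarity(self, rng):
        s = _scores(rng.normal(size=12))
        y = _labels(rng.integers(0, 2, 12).tolist())
        if y.nunique() < 2:
            y.iloc[0] = "sensitive" if (y == "resistant").all() else "resistant"
        auc = roc_auc(s, y).auc
        flipped = y.map({"sensitive": "resistant", "resistant": "sensitive"})
        assert roc_auc(s, flipped).auc == pytest.approx(1.0 - auc)

    def test_unlabeled_excluded(self):
        labels = _labels([1, 1, 0, 0])
        labels["s4"] = "unlabeled"
        res = roc_auc(_scores([0.9, 0.8, 0.2, 0.1, 100.0]), labels)
        assert res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            roc_auc(_scores([0.1, 0.2]), _labels([1, 1]))

    def test_matches_sklearn_on_random_data(self, rng):
        for _ in range(20):
            s = rng.choice([0.0, 0.5, 1.0, 2.0], size=15)
            y = rng.integers(0, 2, 15)
            if y.min() == y.max():
                continue
            ours = roc_auc(_scores(s), _labels(y.tolist())).auc
            assert ours == pytest.approx(roc_auc_score(y, s))

    def test_midrank_equals_brute_force_exhaustive(self):
        """Tie-corrected midrank AUC == pairwise concordance, all n<=8 labelings."""
        score_grid = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        for n in range(2, 9):
            s = score_grid[:n]
            for labels in itertools.product([0, 1], repeat=n):
                y = np.array(labels)
                if y.min() == y.max():
                    continue
                ours = roc_auc(_scores(s), _labels(y.tolist())).auc
                pos, neg = s[y == 1], s[y == 0]
                conc = sum(
                    1.0 if p > q else 0.5 if p == q else 0.0
                    for p in pos for q in neg
                )
                assert ours == pytest.approx(conc / (len(pos) * len(neg)))


class TestCorrelationAndNull:
    def test_perfect_class_separation_gives_unit_correlation(self):
        # within-class-constant scores: point-biserial reaches exactly +1
        scores = pd.DataFrame({"set1": [3.0, 3.0, 0.5, 0.5]},
                              index=[f"s{i}" for i in range(4)])
        out = score_response_correlation(scores, _labels([1, 1, 0, 0]))
        assert out["correlation"].iloc[0] == pytest.approx(1.0)

    def test_ordered_scores_strongly_positive(self):
        scores = pd.DataFrame({"set1": [3.0, 2.5, 1.0, 0.5]},
                              index=[f"s{i}" for i in range(4)])
        out = score_response_correlation(scores, _labels([1, 1, 0, 0]))
        assert out["correlation"].iloc[0] > 0.9

    def test_constant_scores_missing_not_zero(self):
        scores = pd.DataFrame({"set1": [1.0] * 4},
                              index=[f"s{i}" for i in range(4)])
        out = score_response_correlation(scores, _labels([1, 1, 0, 0]))
        assert np.isnan(out["correlation"].iloc[0])
        assert out["note"].iloc[0] == "zero variance"

    def test_null_determinism(self, small_expression):
        norm, meta, _ = small_expression
        labels = label_by_ic50(meta["ic50_uM"], q=0.2)
        a = random_signature_null(norm, labels, n_genes=20, n_iter=5, seed=3)
        b = random_signature_null(norm, labels, n_genes=20, n_iter=5, seed=3)
        np.testing.assert_array_equal(a["aucs"], b["aucs"])

    def test_true_signature_beats_random_null(self, small_expression):
        norm, meta, truth = small_expression
        labels = label_by_ic50(meta["ic50_uM"], q=0.2)
        sig = truth.log2fc[truth.log2fc != 0].index
        sig_auc = roc_auc(ssgsea_score(norm, sig), labels).auc
        null = random_signature_null(norm, labels, n_genes=len(sig),
                                     n_iter=30, seed=0)
        assert sig_auc > null["mean_auc"]

    def test_oversized_geneset_rejected(self, small_expression):
        norm, meta, _ = small_expression
        labels = label_by_ic50(meta["ic50_uM"], q=0.2)
        with pytest.raises(ValueError, match="universe"):
            random_signature_null(norm, labels, n_genes=10**6, n_iter=1)
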