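"""Splitting, AUC, DeLong machinery, Clopper-Pearson, ensembling, reports."""

from itertools import combinations

import numpy as np
import pytest

from xmodal.errors import ConfigError, ContractError, DataError
from xmodal.evaluation import (auc, clopper_pearson, delong_test, ensemble_predict,
                               evaluate, reports_to_frame, round_half_up,
                               stratified_split)
from xmodal.synthetic import CohortSpec, generate_cohort


def brute_force_auc(scores, labels):
    """Pair-counting oracle: wins + half-ties over all pos/neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_default_cohort_test_counts(self, default_cohort):
        plan = stratified_split(default_cohort, strat_var="diagnosis_label", seed=0)
        test_strata = [plan.strat_of[i] for i in plan.test_ids]
        assert test_strata.count("tumor") == 16
        assert test_strata.count("mimic") == 21
        assert len(plan.fold_of) == 188 - 37

    def test_fold_val_fraction_is_16_percent(self, default_cohort):
        plan = stratified_split(default_cohort, strat_var="diagnosis_label", seed=0)
        for fold in range(1, 6):
            n_val = len(plan.val_ids(fold))
            assert abs(n_val - 0.16 * 188) <= 2.0
            assert len(plan.train_ids(fold)) + n_val + len(plan.test_ids) == 188

    def test_per_class_proportions_within_one(self, default_cohort):
        plan = stratified_split(default_cohort, strat_var="class_name", seed=3)
        totals = {}
        for r in default_cohort:
            totals[r.class_name] = totals.get(r.class_name, 0) + 1
        for part_ids, frac in ((plan.test_ids, 0.2), (plan.val_ids(2), 0.16)):
            for cls, total in totals.items():
                got = sum(plan.strat_of[i] == cls for i in part_ids)
                assert abs(got - frac * total) <= 1.0 + 1e-9

    def test_all_train_fractions(self, default_cohort):
        plan = stratified_split(default_cohort, fractions=(1.0, 0.0, 0.0))
        assert plan.test_ids == []
        assert len(plan.fold_of) == 188

    def test_two_seeds_differ_but_counts_match(self, default_cohort):
        p1 = stratified_split(default_cohort, strat_var="class_name", seed=1)
        p2 = stratified_split(default_cohort, strat_var="class_name", seed=2)
        assert p1.test_ids != p2.test_ids
        c1 = sorted(p1.strat_of[i] for i in p1.test_ids)
        c2 = sorted(p2.strat_of[i] for i in p2.test_ids)
        assert c1 == c2

    def test_no_patient_crosses_parts(self, default_cohort):
        plan = stratified_split(default_cohort, strat_var="class_name", seed=5)
        plan.audit()
        for fold in range(1, 6):
            assert not set(plan.train_ids(fold)) & set(plan.val_ids(fold))
            assert not set(plan.test_ids) & set(plan.fold_of)

    def test_tiny_stratum_warns(self):
        strat = {f"p{i}": ("rare" if i < 3 else "common") for i in range(40)}
        with pytest.warns(UserWarning, match="rare"):
            stratified_split(strat, seed=0)

    def test_bad_fractions_rejected(self, default_cohort):
        with pytest.raises(ConfigError):
            stratified_split(default_cohort, fractions=(0.5, 0.2, 0.2))


class TestAuc:
    def test_examples(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.4, 0.4, 0.4, 0.4], [1, 0, 1, 0]) == 0.5
        assert auc([0.7, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_one_class_rejected(self):
        with pytest.raises(DataError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            scores = rng.random(40)
            labels = (rng.random(40) > 0.6).astype(int)
            if labels.sum() in (0, 40):
                continue
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)


class TestDelong:
    SCORES = np.array([0.15, 0.3, 0.45, 0.6, 0.75, 0.9])
    LABELS = np.array([1, 0, 0, 0, 1, 1])  # AUC 6/9

    def test_variance_matches_value_frozen_from_pROC(self):
        """Independent oracle: pROC's delong variance for the 8/9-AUC
        arrangement of these six scores is 0.02469136."""
        res = delong_test([0.2, 0.3, 0.4, 0.6, 0.7, 0.9], [0, 0, 1, 0, 1, 1])
        assert res.auc_a == pytest.approx(8 / 9, abs=1e-12)
        assert res.var_a == pytest.approx(0.02469136, abs=1e-7)

    def test_p_close_to_exhaustive_permutation_oracle(self):
        """All C(6,3)=20 label placements enumerate the exact permutation
        null; the asymptotic p agrees within the discreteness gap."""
        res = delong_test(self.SCORES, self.LABELS)
        obs = abs(res.auc_a - 0.5)
        hits = 0
        for pos in combinations(range(6), 3):
            lab = np.zeros(6, int)
            lab[list(pos)] = 1
            if abs(auc(self.SCORES, lab) - 0.5) >= obs - 1e-12:
                hits += 1
        p_exact = hits / 20
        assert abs(res.p_value - p_exact) < 0.1

    def test_variance_vs_jackknife_structural_factor(self):
        """At 3 positives vs 3 negatives the delete-one jackknife exceeds
        the structural-components estimate by exactly 5/4; asserting the
        constant validates both computations."""
        res = delong_test(self.SCORES, self.LABELS)
        jk = []
        for i in range(6):
            keep = [j for j in range(6) if j != i]
            jk.append(auc(self.SCORES[keep], self.LABELS[keep]))
        jk = np.array(jk)
        var_jack = (len(jk) - 1) / len(jk) * np.sum((jk - jk.mean()) ** 2)
        assert res.var_a / var_jack == pytest.approx(0.8, abs=1e-9)

    def test_identical_paired_scores_give_p_one(self, rng):
        s = rng.random(20)
        y = (rng.random(20) > 0.5).astype(int)
        y[:2] = [0, 1]
        res = delong_test(s, y, scores_b=s.copy())
        assert res.p_value == 1.0
        assert res.auc_a == res.auc_b

    def test_perfect_separation_flags_degenerate(self):
        res = delong_test([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.degenerate
        assert res.ci_a is None
        assert res.p_value == 0.0
        assert np.isfinite(res.p_value)

    def test_ci_brackets_auc_and_truncates(self, rng):
        s = rng.random(30)
        y = (s + 0.3 * rng.standard_normal(30) > 0.5).astype(int)
        if len(set(y)) < 2:
            y[:2] = [0, 1]
        res = delong_test(s, y)
        lo, hi = res.ci_a
        assert 0.0 <= lo <= res.auc_a <= hi <= 1.0

    def test_type_one_error_under_null(self, rng):
        """Rejection rate at alpha=0.05 for label-permuted scores (n=40)
        stays within [0.03, 0.07] over 2000 replicates."""
        n, rejections, reps = 40, 0, 2000
        y = np.array([1] * 20 + [0] * 20)
        for _ in range(reps):
            scores = rng.random(n)
            lab = rng.permutation(y)
            if delong_test(scores, lab).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_unpaired_mode_not_supported(self, rng):
        with pytest.raises(ConfigError):
            delong_test([0.1, 0.9], [0, 1], scores_b=[0.2, 0.8], paired=False)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (3, 3, 0.29, 1.00),
        (2, 3, 0.09, 0.99),
        (1, 3, 0.01, 0.91),
        (11, 11, 0.72, 1.00),
        (8, 8, 0.63, 1.00),
        (7, 10, 0.35, 0.93),
    ])
    def test_printed_interval_values(self, k, n, lo, hi):
        got_lo, got_hi = clopper_pearson(k, n)
        assert round_half_up(got_lo) == lo
        assert round_half_up(got_hi) == hi

    def test_boundaries_exact(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_invalid_arguments(self):
        for k, n in ((-1, 5), (6, 5), (0, 0)):
            with pytest.raises(ConfigError):
                clopper_pearson(k, n)

    def test_conservative_coverage(self, rng):
        """Empirical coverage >= nominal 95% across p and n grids."""
        for p in (0.1, 0.5, 0.9):
            for n in (3, 10, 30):
                intervals = [clopper_pearson(k, n) for k in range(n + 1)]
                ks = rng.binomial(n, p, size=10_000)
                cover = np.mean([(intervals[k][0] - 1e-12 <= p <= intervals[k][1] + 1e-12)
                                 for k in ks])
                assert cover >= 0.95


class _ConstantHead:
    def __init__(self, probs):
        self.probs = probs

    def predict_proba(self, embeddings):
        return dict(self.probs)


class TestEnsemble:
    def test_identical_folds_equal_single(self):
        probs = {"a": 0.3, "b": 0.9}
        out = ensemble_predict([_ConstantHead(probs)] * 5, None)
        assert out == probs

    def test_mean_of_two(self):
        out = ensemble_predict([_ConstantHead({"a": 0.2}), _ConstantHead({"a": 0.8})], None)
        assert out["a"] == pytest.approx(0.5)

    def test_inconsistent_coverage_rejected(self):
        with pytest.raises(ContractError):
            ensemble_predict([_ConstantHead({"a": 0.2}), _ConstantHead({"b": 0.8})], None)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            ensemble_predict([], None)

    def test_ensemble_auc_at_least_worst_fold(self, rng):
        """On a synthetic test set, the averaged ensemble is no worse than
        the weakest individual fold model."""
        ids = [f"p{i}" for i in range(60)]
        y = {p: i % 2 for i, p in enumerate(ids)}
        heads = []
        for k in range(5):
            noise = rng.normal(scale=0.5, size=60)
            heads.append(_ConstantHead({p: float(np.clip(y[p] + noise[i], 0, 1))
                                        for i, p in enumerate(ids)}))
        fold_aucs = [auc([h.predict_proba(None)[p] for p in ids], [y[p] for p in ids])
                     for h in heads]
        ens = ensemble_predict(heads, None)
        ens_auc = auc([ens[p] for p in ids], [y[p] for p in ids])
        assert ens_auc >= min(fold_aucs)


class TestEvaluate:
    def test_perfect_three_pos_eight_neg_matches_printed_cis(self):
        """Perfect separation of 3 positives vs 8 negatives: sensitivity
        1.00 (CI low 0.29), specificity 1.00 (CI low 0.63)."""
        preds = {f"p{i}": (0.9 if i < 3 else 0.1) for i in range(11)}
        labels = {f"p{i}": (1 if i < 3 else 0) for i in range(11)}
        reps = evaluate(preds, labels)
        sens, spec = reps["sensitivity"], reps["specificity"]
        assert sens.point == 1.0 and round_half_up(sens.ci_low) == 0.29
        assert spec.point == 1.0 and round_half_up(spec.ci_low) == 0.63
        assert reps["auc"].degenerate and reps["auc"].ci_low is None

    def test_threshold_extremes(self, rng):
        preds = {f"p{i}": rng.uniform(0.1, 0.9) for i in range(20)}
        labels = {p: int(i < 10) for i, p in enumerate(preds)}
        lo = evaluate(preds, labels, threshold=0.0)
        assert lo["sensitivity"].point == 1.0 and lo["specificity"].point == 0.0
        hi = evaluate(preds, labels, threshold=1.0)
        assert hi["sensitivity"].point == 0.0

    def test_counts_consistent_with_points(self, rng):
        preds = {f"p{i}": rng.random() for i in range(40)}
        labels = {p: int(rng.random() > 0.5) for p in preds}
        if len(set(labels.values())) < 2:
            labels["p0"], labels["p1"] = 0, 1
        reps = evaluate(preds, labels)
        for name in ("accuracy", "sensitivity", "specificity"):
            r = reps[name]
            assert r.point == pytest.approx(r.numerator / r.denominator)
            assert r.ci_low <= r.point <= r.ci_high

    def test_report_frame_layout(self):
        preds = {f"p{i}": (0.8 if i < 5 else 0.3) for i in range(12)}
        labels = {f"p{i}": int(i < 5) for i in range(12)}
        labels["p11"] = 1  # imperfect separation for a finite CI
        df = reports_to_frame({"model_a": evaluate(preds, labels)})
        assert set(df.columns) >= {"model", "auc", "auc_ci", "accuracy",
                                   "sensitivity", "specificity", "p_vs_chance"}
        assert df.loc[0, "model"] == "model_a"
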