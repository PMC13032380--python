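"""Evaluation layer: stratified splitting with 5-fold CV, AUC with DeLong
variance and tests, exact Clopper–Pearson intervals, fold ensembling, and
report assembly.

AUC uses the Mann–Whitney formulation (ties count 1/2), equal to the
probability that a random positive outscores a random negative. DeLong's
structural-components estimator supplies the AUC variance/covariance for
the vs-chance z-test, the paired model comparison, and 95% CIs. Proportion
metrics (accuracy, sensitivity, specificity) carry exact Clopper–Pearson
intervals from beta quantiles, with the integer numerator/denominator
exposed for auditability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ContractError, DataError
from .synthetic import largest_remainder

DEFAULT_FRACTIONS = (0.64, 0.16, 0.20)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Patient assignment to a held-out test set and 5 cross-validation folds.

    Non-test patients carry a fold index 1..n_folds; for fold k, that
    fold's patients are the validation set and the remaining non-test
    patients train. With 5 folds and a 20% test set this realizes the
    64:16:20 train:val:test split for every fold.
    """

    n_folds: int
    test_ids: list
    fold_of: dict  # patient_id -> 1..n_folds (non-test only)
    strat_of: dict = field(default_factory=dict)

    @property
    def all_ids(self) -> list:
        return sorted(list(self.fold_of) + list(self.test_ids))

    def train_ids(self, fold: int) -> list:
        return sorted(i for i, f in self.fold_of.items() if f != fold)

    def val_ids(self, fold: int) -> list:
        return sorted(i for i, f in self.fold_of.items() if f == fold)

    def part_of(self, patient_id: str, fold: int) -> str:
        if patient_id in set(self.test_ids):
            return "test"
        return "val" if self.fold_of[patient_id] == fold else "train"

    def audit(self) -> None:
        """Raise if any patient appears in more than one part."""
        test = set(self.test_ids)
        cv = set(self.fold_of)
        if test & cv:
            raise ContractError(f"patients in both test and CV pools: {sorted(test & cv)[:3]}")
        if len(self.test_ids) != len(test):
            raise ContractError("duplicate ids in test set")

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, "test", 0, self.strat_of.get(i, "")) for i in sorted(self.test_ids)]
        rows += [(i, "cv", f, self.strat_of.get(i, "")) for i, f in sorted(self.fold_of.items())]
        return pd.DataFrame(rows, columns=["patient_id", "pool", "fold", "stratum"])


def stratified_split(cohort, fractions: tuple = DEFAULT_FRACTIONS,
                     strat_var: str = "diagnosis_label", seed: int = 0,
                     n_folds: int = 5) -> FoldPlan:
    """Diagnosis-stratified split into a test set and round-robin CV folds.

    ``cohort`` is a list of records with a ``patient_id`` and the
    stratification attribute, or a mapping patient_id -> stratum. The test
    count per stratum comes from a deterministic largest-remainder
    apportionment at the test fraction; remaining patients are dealt to
    folds round-robin in seeded shuffled order, keeping per-class
    proportions within one patient of the global proportions in every part.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {fractions}")
    if isinstance(cohort, dict):
        strat = dict(cohort)
    else:
        strat = {r.patient_id: getattr(r, strat_var) for r in cohort}
    if not strat:
        raise DataError("empty cohort")
    strata = sorted({str(v) for v in strat.values()})
    rng = np.random.default_rng(seed)
    test_frac = fractions[2]
    test_ids: list = []
    fold_of: dict = {}
    for s in strata:
        ids = sorted(i for i, v in strat.items() if str(v) == s)
        if len(ids) < n_folds:
            warnings.warn(f"stratum {s!r} has {len(ids)} patients, fewer than "
                          f"{n_folds} folds; fold balance is degenerate for it")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n_test = int(largest_remainder(np.array([1 - test_frac, test_frac]), len(ids))[1])
        test_ids += ids[:n_test]
        for k, pid in enumerate(ids[n_test:]):
            fold_of[pid] = (k % n_folds) + 1
    plan = FoldPlan(n_folds=n_folds, test_ids=sorted(test_ids), fold_of=fold_of,
                    strat_of={i: str(v) for i, v in strat.items()})
    plan.audit()
    return plan


# ---------------------------------------------------------------------------
# AUC and DeLong
# ---------------------------------------------------------------------------

def _check_two_class(labels: np.ndarray) -> tuple:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise DataError("AUC requires both classes present (labels in {0, 1})")
    return labels == 1, labels == 0


def auc(scores, labels) -> float:
    """Mann–Whitney AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(labels)
    ranks = stats.rankdata(scores)
    m, n = pos.sum(), neg.sum()
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def _structural_components(score_matrix: np.ndarray, labels) -> tuple:
    """Per-classifier AUCs and the DeLong covariance matrix.

    ``score_matrix`` is (n_classifiers, n_subjects). Returns (aucs, S)
    where S[i, j] estimates Cov(auc_i, auc_j).
    """
    pos, neg = _check_two_class(labels)
    x = score_matrix[:, pos]  # (k, m)
    y = score_matrix[:, neg]  # (k, n)
    m, n = x.shape[1], y.shape[1]
    # psi(x_i, y_j): 1 / 0.5 / 0 comparison kernel
    psi = (x[:, :, None] > y[:, None, :]).astype(float)
    psi += 0.5 * (x[:, :, None] == y[:, None, :])
    v10 = psi.mean(axis=2)  # (k, m) structural components of positives
    v01 = psi.mean(axis=1)  # (k, n)
    aucs = v10.mean(axis=1)
    s10 = np.atleast_2d(np.cov(v10, ddof=1)) if m > 1 else np.zeros((len(aucs),) * 2)
    s01 = np.atleast_2d(np.cov(v01, ddof=1)) if n > 1 else np.zeros((len(aucs),) * 2)
    return aucs, s10 / m + s01 / n


@dataclass
class DelongResult:
    """Outcome of a DeLong z-test (vs chance or paired comparison)."""

    auc_a: float
    auc_b: float | None
    var_a: float
    var_b: float | None
    cov_ab: float | None
    z: float | None
    p_value: float
    ci_a: tuple | None
    ci_b: tuple | None
    mode: str  # "vs_chance" | "paired"
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("auc_a", "auc_b", "var_a", "var_b",
                                           "cov_ab", "z", "p_value", "mode", "degenerate")}
        d["ci_a"] = list(self.ci_a) if self.ci_a else None
        d["ci_b"] = list(self.ci_b) if self.ci_b else None
        return d


def _auc_ci(a: float, var: float, level: float = 0.95) -> tuple | None:
    if var <= 0:
        return None
    half = stats.norm.ppf(0.5 + level / 2) * np.sqrt(var)
    return (max(0.0, a - half), min(1.0, a + half))


def delong_test(scores_a, labels, scores_b=None, paired: bool = True,
                null_auc: float = 0.5) -> DelongResult:
    """DeLong z-test of one AUC against chance or of two paired AUCs.

    In vs-chance mode (``scores_b`` is None) the z statistic is
    (AUC - null_auc) / SE with the structural-components SE. In paired
    mode both score vectors must be for the same subjects/labels; the
    difference variance uses the estimated covariance. Perfect separation
    gives zero variance: the CI is reported as None ("not calculable") and
    the p-value takes its documented limit (0 unless the tested difference
    is exactly zero, then 1), with ``degenerate=True``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    if scores_b is None:
        aucs, s = _structural_components(scores_a[None, :], labels)
        a, var = float(aucs[0]), float(s[0, 0])
        if var <= 1e-16:
            return DelongResult(a, None, var, None, None, None,
                                1.0 if a == null_auc else 0.0,
                                None, None, "vs_chance", degenerate=True)
        z = (a - null_auc) / np.sqrt(var)
        return DelongResult(a, None, var, None, None, float(z),
                            float(2 * stats.norm.sf(abs(z))),
                            _auc_ci(a, var), None, "vs_chance")
    scores_b = np.asarray(scores_b, dtype=float)
    if not paired:
        raise ConfigError("two-sample unpaired DeLong is not provided; use paired mode")
    if scores_b.shape != scores_a.shape:
        raise DataError("paired DeLong requires score vectors over the same subjects")
    aucs, s = _structural_components(np.vstack([scores_a, scores_b]), labels)
    a, b = float(aucs[0]), float(aucs[1])
    var_a, var_b, cov = float(s[0, 0]), float(s[1, 1]), float(s[0, 1])
    var_diff = var_a + var_b - 2 * cov
    if var_diff <= 1e-16:
        return DelongResult(a, b, var_a, var_b, cov, None,
                            1.0 if a == b else 0.0,
                            _auc_ci(a, var_a), _auc_ci(b, var_b),
                            "paired", degenerate=True)
    z = (a - b) / np.sqrt(var_diff)
    return DelongResult(a, b, var_a, var_b, cov, float(z),
                        float(2 * stats.norm.sf(abs(z))),
                        _auc_ci(a, var_a), _auc_ci(b, var_b), "paired")


# ---------------------------------------------------------------------------
# Clopper–Pearson
# ---------------------------------------------------------------------------

def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple:
    """Exact binomial CI from beta quantiles; (0, ·) at k=0 and (·, 1) at k=n."""
    k, n = int(successes), int(trials)
    if n < 1 or not (0 <= k <= n):
        raise ConfigError(f"invalid Clopper-Pearson arguments k={successes}, n={trials}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def round_half_up(x: float, places: int = 2) -> float:
    """Display rounding matching printed tables (half away from zero)."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Ensembling and report assembly
# ---------------------------------------------------------------------------

def ensemble_predict(fold_heads: list, embeddings) -> dict:
    """Unweighted mean of per-fold predicted probabilities per patient."""
    if not fold_heads:
        raise DataError("ensemble needs at least one fold model")
    per_fold = [h.predict_proba(embeddings) for h in fold_heads]
    ids = set(per_fold[0])
    for d in per_fold[1:]:
        if set(d) != ids:
            raise ContractError("fold models cover different patients")
    return {i: float(np.mean([d[i] for d in per_fold])) for i in sorted(ids)}


@dataclass
class EvalReport:
    """One metric with its CI, counts, and test provenance."""

    metric: str
    point: float
    ci_low: float | None
    ci_high: float | None
    ci_method: str                  # "delong" | "clopper_pearson" | "none"
    p_value: float | None = None
    test_tag: str | None = None
    numerator: int | None = None
    denominator: int | None = None
    counts: dict | None = None      # tp/fp/tn/fn
    threshold: float | None = None
    degenerate: bool = False

    def __post_init__(self):
        if self.ci_low is not None and not (self.ci_low - 1e-12 <= self.point
                                            <= self.ci_high + 1e-12):
            raise ContractError(f"{self.metric}: point {self.point} outside CI "
                                f"({self.ci_low}, {self.ci_high})")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def evaluate(predictions, labels, threshold: float = 0.5) -> dict:
    """Full metric panel for one model on one set of subjects.

    ``predictions`` maps patient_id -> probability (or is an array aligned
    with ``labels``). Emits AUC with DeLong CI and vs-chance p, plus
    accuracy / sensitivity / specificity with exact Clopper–Pearson CIs
    and their integer k/n. Returns {metric_name: EvalReport}.
    """
    if isinstance(predictions, dict):
        ids = sorted(predictions)
        scores = np.array([predictions[i] for i in ids], dtype=float)
        y = np.array([labels[i] for i in ids], dtype=int)
    else:
        scores = np.asarray(predictions, dtype=float)
        y = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise DataError("no predictions to evaluate")
    res = delong_test(scores, y)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    counts = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
    out = {"auc": EvalReport("auc", res.auc_a,
                             res.ci_a[0] if res.ci_a else None,
                             res.ci_a[1] if res.ci_a else None,
                             "delong" if res.ci_a else "none",
                             p_value=res.p_value, test_tag="delong_vs_chance",
                             counts=counts, degenerate=res.degenerate)}
    for name, k, n in (("accuracy", tp + tn, len(y)),
                       ("sensitivity", tp, tp + fn),
                       ("specificity", tn, tn + fp)):
        lo, hi = clopper_pearson(k, n)
        out[name] = EvalReport(name, k / n, lo, hi, "clopper_pearson",
                               numerator=k, denominator=n, counts=counts,
                               threshold=threshold)
    return out


def reports_to_frame(named_reports: dict) -> pd.DataFrame:
    """Flatten {model_name: {metric: EvalReport}} to a table mirroring the
    printed performance-table layout (point estimates with 2-decimal CIs)."""
    rows = []
    for model, reps in named_reports.items():
        row = {"model": model}
        for metric in ("auc", "accuracy", "sensitivity", "specificity"):
            r = reps.get(metric)
            if r is None:
                continue
            row[metric] = round_half_up(r.point)
            if r.ci_low is not None:
                row[f"{metric}_ci"] = (f"({round_half_up(r.ci_low):.2f}, "
                                       f"{round_half_up(r.ci_high):.2f})")
            else:
                row[f"{metric}_ci"] = "(NA)"
        if reps.get("auc") is not None:
            row["p_vs_chance"] = reps["auc"].p_value
        rows.append(row)
    return pd.DataFrame(rows)
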