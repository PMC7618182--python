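"""TRTR / TSRTR evaluation harness over patient-grouped folds.

TRTR (train on real, test on real) is evaluated both with the original
class imbalance and after balancing by subsampling; TSRTR (train on
synthetic *and* real, test on real) trains on the policy-augmented
balanced training split.  All schemes are evaluated on the same untouched
real test fold, with folds grouped by patient, on a fixed zoo of 10
classifiers.  The headline quantity is the percent change

    %dM = (X_TSRTR - X_TRTR) / X_TRTR * 100

of a metric (default macro one-vs-rest AUROC) relative to the balanced
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .augment import AugmentationPolicy, apply_policy
from .data import FrameSet, log_power_spectrum, patient_folds, subsample_balance

__all__ = [
    "classifier_zoo",
    "run_harness",
    "percent_change",
    "factor_tests",
    "HarnessResult",
]


def classifier_zoo(seed: int = 0) -> list[tuple[str, object]]:
    """The 10-model classifier zoo with pinned hyperparameters.

    Order is stable; every model exposes fit / predict_proba.
    """
    return [
        ("naive_bayes", GaussianNB()),
        ("lda", LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")),
        ("qda", QuadraticDiscriminantAnalysis(solver="eigen", shrinkage=0.1, reg_param=0.1)),
        ("knn", KNeighborsClassifier(n_neighbors=5)),
        ("logistic_regression", LogisticRegression(max_iter=1000, random_state=seed)),
        ("svm", SVC(probability=True, random_state=seed)),
        ("decision_tree", DecisionTreeClassifier(random_state=seed)),
        ("random_forest", RandomForestClassifier(n_estimators=100, random_state=seed)),
        ("adaboost", AdaBoostClassifier(n_estimators=50, random_state=seed)),
        ("mlp", MLPClassifier(hidden_layer_sizes=(50,), max_iter=300, random_state=seed)),
    ]


def percent_change(x_tsrtr: float, x_trtr: float) -> float:
    """Percent change of a metric relative to a positive baseline."""
    x_trtr = np.asarray(x_trtr, dtype=float)
    if np.any(x_trtr <= 0):
        raise ValueError("baseline metric must be positive")
    return (np.asarray(x_tsrtr, dtype=float) - x_trtr) / x_trtr * 100.0


def _macro_auroc(clf, X_test: np.ndarray, y_test: np.ndarray) -> float:
    proba = clf.predict_proba(X_test)
    classes = np.asarray(clf.classes_)
    if classes.size == 2:
        return float(roc_auc_score(y_test, proba[:, 1]))
    return float(
        roc_auc_score(y_test, proba, multi_class="ovr", average="macro", labels=classes)
    )


@dataclass
class HarnessResult:
    """Tidy table of per-(method, policy, classifier, fold, scheme) metrics."""

    df: pd.DataFrame
    metric: str = "auroc"
    baseline_scheme: str = "TRTR_balanced"

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def model_means(self, scheme: str, method: str = "-", policy_id: str = "-") -> pd.Series:
        """Metric per classifier, averaged over folds, for one scheme."""
        sel = self.df[
            (self.df.scheme == scheme)
            & (self.df.method == method)
            & (self.df.policy == policy_id)
        ]
        return sel.groupby("classifier")["value"].mean()

    def percent_change_table(self, baseline: str | None = None) -> pd.DataFrame:
        """%d metric per (method, policy, classifier), fold-averaged.

        Requires matching baseline rows for every fold; the per-classifier
        metric is averaged over folds in both schemes before the ratio.
        """
        baseline = baseline or self.baseline_scheme
        base = self.model_means(baseline)
        rows = []
        tsrtr = self.df[self.df.scheme == "TSRTR"]
        for (method, policy_id), grp in tsrtr.groupby(["method", "policy"]):
            means = grp.groupby("classifier")["value"].mean()
            meta = grp.iloc[0]
            for clf_name, val in means.items():
                rows.append(
                    {
                        "method": method,
                        "policy": policy_id,
                        "target_class": meta["target_class"],
                        "degree": meta["degree"],
                        "ratio": meta["ratio"],
                        "classifier": clf_name,
                        "pct_change": percent_change(val, base[clf_name]),
                    }
                )
        return pd.DataFrame(rows)

    def best_percent_change(self, method: str, baseline: str | None = None) -> dict:
        """Two aggregations of the best %d metric for one method.

        ``max_then_mean``: per classifier take the best policy, then average
        over classifiers.  ``mean_then_max``: average over classifiers per
        policy, then take the best policy.
        """
        table = self.percent_change_table(baseline)
        table = table[table.method == method]
        if table.empty:
            raise ValueError(f"no TSRTR rows for method {method!r}")
        per_clf_best = table.groupby("classifier")["pct_change"].max()
        per_policy_mean = table.groupby("policy")["pct_change"].mean()
        return {
            "max_then_mean": float(per_clf_best.mean()),
            "mean_then_max": float(per_policy_mean.max()),
        }


def run_harness(
    frames: FrameSet,
    augmenters: dict[str, object],
    policies: list[AugmentationPolicy],
    feature_fn=log_power_spectrum,
    metric: str = "auroc",
    patients_per_class: int = 1,
    seed: int = 0,
    classifiers: list[tuple[str, object]] | None = None,
) -> HarnessResult:
    """Run TRTR and TSRTR over patient-grouped folds and the classifier zoo.

    ``augmenters`` maps a method name to an object with ``sample(n, cls,
    rng)`` or to a callable ``train_frames -> augmenter`` (for baselines
    that must see only the fold's training data).  Synthetic data is only
    ever added to training splits; every test fold is untouched real data.
    """
    if metric != "auroc":
        raise ValueError("only the macro one-vs-rest AUROC metric is implemented")
    classifiers = classifiers if classifiers is not None else classifier_zoo(seed)
    folds = patient_folds(frames, patients_per_class, seed=seed)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def evaluate(train_fr: FrameSet, test_feats, y_test, meta: dict) -> bool:
        if not np.array_equal(np.unique(train_fr.labels), frames.classes):
            warnings.warn(
                f"fold {meta['fold']} scheme {meta['scheme']}: training split "
                "is missing a class; skipped",
                stacklevel=2,
            )
            return False
        feats = feature_fn(train_fr)
        for clf_name, clf in classifiers:
            model = clone(clf)
            model.fit(feats.features, feats.labels)
            value = _macro_auroc(model, test_feats, y_test)
            rows.append({**meta, "classifier": clf_name, "value": value})
        return True

    for fold_i, (train_idx, test_idx) in enumerate(folds):
        train_fr = frames.subset(train_idx)
        test_fr = frames.subset(test_idx)
        test_feats = feature_fn(test_fr)
        base_meta = {
            "fold": fold_i,
            "method": "-",
            "policy": "-",
            "target_class": np.nan,
            "degree": np.nan,
            "ratio": np.nan,
        }
        balanced = subsample_balance(train_fr, seed=seed + fold_i)
        evaluate(train_fr, test_feats.features, test_feats.labels,
                 {**base_meta, "scheme": "TRTR_imbalanced"})
        evaluate(balanced, test_feats.features, test_feats.labels,
                 {**base_meta, "scheme": "TRTR_balanced"})
        for method, augmenter in augmenters.items():
            aug = augmenter(balanced) if callable(augmenter) else augmenter
            for policy in policies:
                augmented = apply_policy(
                    balanced, aug, policy, np.random.default_rng(rng.integers(2**31))
                )
                meta = {
                    "fold": fold_i,
                    "method": method,
                    "policy": policy.id,
                    "target_class": policy.target_class,
                    "degree": policy.imbalance_degree,
                    "ratio": policy.synth_ratio,
                    "scheme": "TSRTR",
                }
                evaluate(augmented, test_feats.features, test_feats.labels, meta)

    return HarnessResult(pd.DataFrame(rows), metric=metric)


def factor_tests(
    data: pd.DataFrame, factor: str, value_col: str = "pct_change"
) -> pd.DataFrame:
    """Hypothesis tests of a factor's effect on an outcome column.

    Two-level factors get a t-test plus a Wilcoxon rank-sum test;
    multi-level factors get one-way ANOVA plus Kruskal-Wallis.  A Shapiro
    normality p-value is reported per level alongside.
    """
    groups = {lvl: grp[value_col].to_numpy() for lvl, grp in data.groupby(factor)}
    levels = list(groups)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("every factor level needs at least 2 observations")
    samples = [groups[lvl] for lvl in levels]
    rows = []
    if len(levels) == 2:
        t_stat, t_p = stats.ttest_ind(*samples)
        w_stat, w_p = stats.ranksums(*samples)
        rows.append({"test": "t-test", "statistic": t_stat, "p_value": t_p})
        rows.append({"test": "wilcoxon_rank_sum", "statistic": w_stat, "p_value": w_p})
    else:
        f_stat, f_p = stats.f_oneway(*samples)
        k_stat, k_p = stats.kruskal(*samples)
        rows.append({"test": "anova", "statistic": f_stat, "p_value": f_p})
        rows.append({"test": "kruskal_wallis", "statistic": k_stat, "p_value": k_p})
    for lvl, vals in groups.items():
        if vals.size >= 3 and np.ptp(vals) > 0:
            s_stat, s_p = stats.shapiro(vals)
        else:
            s_stat, s_p = np.nan, np.nan
        rows.append(
            {
                "test": f"shapiro[{factor}={lvl}]",
                "statistic": s_stat,
                "p_value": s_p,
                "mean": vals.mean(),
                "n": vals.size,
            }
        )
    return pd.DataFrame(rows)
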