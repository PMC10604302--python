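"""Classifier fitting, the repeated (multiple) holdout, and its aggregates.

Five classifiers are evaluated with fixed configurations: Gaussian
naive Bayes, random forest (500 trees), logistic regression (logit
link, 0.5 probability threshold), AdaBoost (10 rounds), and a
polynomial-kernel SVM with cost 100.  The multiple holdout repeats a
stratified train/test split (default 70/30) J times (default 100); each
iteration yields a confusion matrix, and the aggregates are

    mean accuracy, SD of accuracy with the (J-1) denominator,
    ASe  = mean of TP / (TP + FN)   (average sensitivity),
    ASp  = mean of TN / (TN + FP)   (average specificity),
    ATPP = mean of TP / (TP + FP)   (average positive predictive value),

all as percentages.  An iteration whose denominator is zero contributes
a missing value to that average (never a silent zero); the number of
such iterations is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .datasets import Cohort
from .feature_selection import composite, scenario_features

logger = logging.getLogger(__name__)

CLASSIFIERS = ("nb", "rf", "lr", "adaboost", "svm")


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix cells, class-0 row (tn, fp) / class-1 row (fn, tp)."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def accuracy(self) -> float:
        """Percent correctly classified."""
        return 100.0 * (self.tn + self.tp) / self.total

    def _rate(self, num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def tpp(self) -> float:
        """Positive predictive value; NaN when nothing was predicted positive."""
        return self._rate(self.tp, self.tp + self.fp)


@dataclass
class HoldoutResult:
    """Aggregated multiple-holdout outcome plus per-iteration counts."""

    per_iteration: list[ConfusionCounts]
    mu_accuracy: float
    sigma_accuracy: float
    ase: float
    asp: float
    atpp: float
    undefined: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def holdout_split(
    df: pd.DataFrame, train_fraction: float = 0.7, seed: int | None = None,
    y_col: str = "Y",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One stratified train/test split, deterministic given ``seed``.

    Class proportions are preserved within rounding on both sides.
    A single-class table raises ``ValueError``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = df[y_col]
    if y.nunique() < 2:
        raise ValueError("both classes must be present to split")
    splitter = StratifiedShuffleSplit(
        n_splits=1, train_size=train_fraction, random_state=seed
    )
    train_idx, test_idx = next(splitter.split(np.zeros(len(df)), y))
    return df.iloc[train_idx], df.iloc[test_idx]


def build_classifier(name: str, seed: int | None = None):
    """Instantiate one of the five fixed-configuration classifiers."""
    name = name.lower()
    if name == "nb":
        return GaussianNB()
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if name == "lr":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(n_estimators=10, random_state=seed)
    if name == "svm":
        # polynomial kernel, cost 100, no internal feature scaling
        return SVC(kernel="poly", C=100, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def fit_predict(
    classifier_name: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: list[str],
    seed: int | None = None,
    y_col: str = "Y",
) -> np.ndarray:
    """Fit on complete-case training rows; binary predictions for test.

    All classifiers use list-wise deletion of rows with a missing
    feature or label; test rows with missing features are predicted
    from their observed columns after median imputation from training
    (so every test row gets a prediction).
    """
    if not features:
        raise ValueError("empty feature set; model unfittable")
    cc = train.dropna(subset=list(features) + [y_col])
    if cc.empty or cc[y_col].nunique() < 2:
        raise ValueError("training data degenerate after complete-case filtering")
    X = cc[features].to_numpy(dtype=float)
    y = cc[y_col].to_numpy(dtype=float).astype(int)
    clf = build_classifier(classifier_name, seed)
    clf.fit(X, y)
    Xt = test[features].to_numpy(dtype=float)
    if np.isnan(Xt).any():
        med = np.nanmedian(X, axis=0)
        idx = np.where(np.isnan(Xt))
        Xt[idx] = np.take(med, idx[1])
    if classifier_name.lower() == "lr":
        prob = clf.predict_proba(Xt)[:, 1]
        return (prob > 0.5).astype(int)
    return clf.predict(Xt).astype(int)


def confusion(predicted, truth) -> ConfusionCounts:
    """Confusion counts from equal-length binary vectors."""
    pred = np.asarray(predicted).astype(int)
    obs = np.asarray(truth).astype(int)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    return ConfusionCounts(
        tn=int(np.sum((obs == 0) & (pred == 0))),
        fp=int(np.sum((obs == 0) & (pred == 1))),
        fn=int(np.sum((obs == 1) & (pred == 0))),
        tp=int(np.sum((obs == 1) & (pred == 1))),
    )


def _nanmean(values: list[float]) -> tuple[float, int]:
    arr = np.asarray(values, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    if n_missing == arr.size:
        return float("nan"), n_missing
    return float(np.nanmean(arr)), n_missing


def aggregate(results: list[ConfusionCounts], config: dict | None = None) -> HoldoutResult:
    """Aggregate per-iteration confusion counts into holdout statistics.

    SD uses the (J-1) denominator; with a single iteration it is NaN
    (undefined, never 0).  Iterations with an undefined rate are
    averaged over and counted in ``undefined``.
    """
    if not results:
        raise ValueError("no iterations to aggregate")
    acc = np.array([c.accuracy for c in results])
    ase, n_se = _nanmean([c.sensitivity for c in results])
    asp, n_sp = _nanmean([c.specificity for c in results])
    atpp, n_pp = _nanmean([c.tpp for c in results])
    undefined = {"sensitivity": n_se, "specificity": n_sp, "tpp": n_pp}
    if any(undefined.values()):
        logger.info("iterations with undefined rates: %s", undefined)
    sigma = float(np.std(acc, ddof=1)) if acc.size > 1 else float("nan")
    return HoldoutResult(
        per_iteration=list(results),
        mu_accuracy=float(acc.mean()),
        sigma_accuracy=sigma,
        ase=ase,
        asp=asp,
        atpp=atpp,
        undefined=undefined,
        config=dict(config or {}),
    )


def run_holdout(
    df: pd.DataFrame,
    features: list[str],
    classifier: str,
    iterations: int = 100,
    train_fraction: float = 0.7,
    seed: int | None = None,
    config: dict | None = None,
) -> HoldoutResult:
    """Multiple holdout of one classifier over a fixed feature set."""
    ss = np.random.SeedSequence(seed)
    iter_seeds = [int(s) % (2**31) for s in ss.generate_state(iterations)]
    counts = []
    for j, sj in enumerate(iter_seeds):
        train, test = holdout_split(df, train_fraction, sj)
        pred = fit_predict(classifier, train, test, features, seed=sj)
        counts.append(confusion(pred, test["Y"].to_numpy()))
    cfg = dict(config or {})
    cfg.update(
        classifier=classifier, features=list(features), iterations=iterations,
        train_fraction=train_fraction, seed=seed,
    )
    return aggregate(counts, cfg)


def run_experiment(
    cohort: Cohort,
    scenario: int,
    criterion: str,
    classifier: str,
    iterations: int = 100,
    train_fraction: float = 0.7,
    seed: int | None = None,
    nested: bool = False,
) -> HoldoutResult:
    """Feature selection + multiple holdout, with full provenance.

    Selection runs once on the full cohort (the fixed-variable-list
    presentation); ``nested=True`` instead re-selects inside every
    holdout iteration for leakage-sensitivity analysis.
    """
    df = cohort.data
    base_cfg = {
        "scenario": scenario, "criterion": criterion, "nested": nested,
        "provenance": cohort.provenance,
    }
    if not nested:
        sel = composite(criterion, df, cohort.y, scenario_features(scenario, cohort))
        if not sel.kept:
            raise ValueError(f"criterion {criterion!r} kept no features")
        base_cfg["selected"] = list(sel.kept)
        return run_holdout(
            df, sel.kept, classifier, iterations, train_fraction, seed, base_cfg
        )
    candidates = scenario_features(scenario, cohort)
    ss = np.random.SeedSequence(seed)
    iter_seeds = [int(s) % (2**31) for s in ss.generate_state(iterations)]
    counts = []
    for sj in iter_seeds:
        train, test = holdout_split(df, train_fraction, sj)
        sel = composite(criterion, train, train["Y"], candidates)
        feats = sel.kept or candidates
        pred = fit_predict(classifier, train, test, feats, seed=sj)
        counts.append(confusion(pred, test["Y"].to_numpy()))
    base_cfg.update(classifier=classifier, iterations=iterations,
                    train_fraction=train_fraction, seed=seed)
    return aggregate(counts, base_cfg)
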