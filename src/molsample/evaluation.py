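"""Random-Forest evaluation harness: stratified CV and external validation.

Metric notes
------------
Sensitivity is the true positive rate tp/(tp+fn) and specificity the true
negative rate tn/(tn+fp); the F-measure is the harmonic mean of precision
and recall.  Ratios with a zero denominator are reported as 0.0 and
flagged, so aggregate tables never silently drop folds.  ROC-AUC is the
Mann-Whitney rank statistic with ties contributing 1/2.

By default a sampler runs inside the cross-validation loop, on the
training part of each fold only — resampling before splitting leaks
duplicated/synthetic minority rows into held-out folds and inflates
scores.  That leaky variant remains available behind ``leaky=True`` for
reproduction studies and logs a prominent warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from molsample._seeds import derive_seed
from molsample.fingerprints_io import FingerprintDataset
from molsample.samplers import apply_sampler

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f_measure", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard 2x2 counts with 1 = positive/active."""
    yt = np.asarray(y_true).ravel()
    yp = np.asarray(y_pred).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics_from_confusion(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity and F-measure from counts.

    Returns a dict with the four rates plus ``flags``: the names of any
    rates whose denominator was zero (reported as 0.0).
    """
    if c.total == 0:
        raise ValueError("empty confusion: no evaluated samples")
    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    accuracy = (c.tp + c.tn) / c.total
    if precision + sensitivity == 0:
        if "f_measure" not in flags:
            flags.append("f_measure")
        f_measure = 0.0
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f_measure": f_measure,
        "flags": flags,
    }


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic."""
    yt = np.asarray(y_true).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if yt.shape != s.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {s.shape}")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes in y_true")
    ranks = rankdata(s)  # average ranks: ties contribute 1/2
    rank_sum = float(ranks[yt == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


def train_rf(
    dataset: FingerprintDataset, n_trees: int = 1000, seed: int = 0
) -> RandomForestClassifier:
    """Fit a seeded Random Forest; scores are tree-vote fractions."""
    dataset.require_both_classes()
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2**32), n_jobs=1
    )
    clf.fit(dataset.X, dataset.y)
    return clf


def predict_scores(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """P(class = 1) for each row of ``X``."""
    proba = clf.predict_proba(X)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos_col]


def _evaluate_block(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict:
    y_pred = (scores >= threshold).astype(np.int64)
    c = confusion(y_true, y_pred)
    metrics = metrics_from_confusion(c)
    flags = metrics.pop("flags")
    if np.sum(y_true == 1) == 0 or np.sum(y_true == 0) == 0:
        metrics["auc"] = 0.0
        flags.append("auc")
    else:
        metrics["auc"] = roc_auc(y_true, scores)
    metrics["flags"] = flags
    metrics["confusion"] = {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
    return metrics


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------


@dataclass
class ConditionReport:
    """Per-fold and aggregate metrics for one sampling condition."""

    condition: str
    sampler_params: dict
    seed: int
    n_folds: int
    n_trees: int
    leaky: bool
    folds: list[dict]            # one metric dict per fold
    mean: dict                   # metric -> mean across folds
    std: dict                    # metric -> std (ddof=0) across folds
    external: dict | None = None # metric dict + misclassified ids

    def gap(self) -> float:
        return abs(self.mean["sensitivity"] - self.mean["specificity"])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvaluationReport:
    """Consolidated report over several sampling conditions."""

    conditions: list[ConditionReport]
    seed: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "notes": self.notes,
            "conditions": [c.to_dict() for c in self.conditions],
            "gap": {c.condition: c.gap() for c in self.conditions},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "EvaluationReport":
        conditions = [
            ConditionReport(
                condition=c["condition"],
                sampler_params=c["sampler_params"],
                seed=c["seed"],
                n_folds=c["n_folds"],
                n_trees=c["n_trees"],
                leaky=c["leaky"],
                folds=c["folds"],
                mean=c["mean"],
                std=c["std"],
                external=c.get("external"),
            )
            for c in data["conditions"]
        ]
        return cls(conditions=conditions, seed=data["seed"], notes=list(data.get("notes", [])))

    @classmethod
    def load(cls, path: str | Path) -> "EvaluationReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _aggregate(folds: list[dict]) -> tuple[dict, dict]:
    mean = {m: float(np.mean([f[m] for f in folds])) for m in METRIC_NAMES}
    std = {m: float(np.std([f[m] for f in folds])) for m in METRIC_NAMES}
    return mean, std


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def make_folds(
    dataset: FingerprintDataset, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified folds as (train_indices, test_indices) pairs."""
    counts = dataset.class_counts()
    if n_folds > min(counts.values()):
        raise ValueError(
            f"n_folds={n_folds} exceeds the minority class size {min(counts.values())}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    return [(tr.copy(), te.copy()) for tr, te in skf.split(dataset.X, dataset.y)]


def cross_validate(
    dataset: FingerprintDataset,
    sampler_name: str = "none",
    sampler_params: dict | None = None,
    n_folds: int = 10,
    n_trees: int = 1000,
    seed: int = 0,
    leaky: bool = False,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ConditionReport:
    """Stratified k-fold CV with the sampler applied to training folds only.

    Pass precomputed ``folds`` to share one split across conditions.
    With ``leaky=True`` the whole dataset is resampled before splitting
    (leaks synthetic/duplicated rows into held-out folds; avoid except
    for reproduction studies).
    """
    sampler_params = dict(sampler_params or {})
    dataset.require_both_classes()

    if leaky:
        logger.warning(
            "LEAKY evaluation: resampling before the CV split leaks resampled "
            "minority rows into held-out folds and inflates scores"
        )
        result = apply_sampler(
            sampler_name, dataset, seed=derive_seed(seed, "leaky-sampler"), **sampler_params
        )
        work = result.dataset
        if folds is None:
            folds = make_folds(work, n_folds, derive_seed(seed, "folds"))
    else:
        work = dataset
        if folds is None:
            folds = make_folds(work, n_folds, derive_seed(seed, "folds"))

    fold_metrics: list[dict] = []
    for i, (train_idx, test_idx) in enumerate(folds):
        train = work.subset(train_idx)
        test = work.subset(test_idx)
        if leaky:
            resampled = train
        else:
            resampled = apply_sampler(
                sampler_name, train, seed=derive_seed(seed, f"sampler-fold{i}"), **sampler_params
            ).dataset
        clf = train_rf(resampled, n_trees=n_trees, seed=derive_seed(seed, f"rf-fold{i}"))
        scores = predict_scores(clf, test.X)
        fold_metrics.append(_evaluate_block(test.y, scores))
    mean, std = _aggregate(fold_metrics)
    return ConditionReport(
        condition=sampler_name,
        sampler_params=sampler_params,
        seed=int(seed),
        n_folds=len(folds),
        n_trees=n_trees,
        leaky=leaky,
        folds=fold_metrics,
        mean=mean,
        std=std,
    )


def external_validate(
    train: FingerprintDataset,
    test: FingerprintDataset,
    sampler_name: str = "none",
    sampler_params: dict | None = None,
    n_trees: int = 1000,
    seed: int = 0,
) -> dict:
    """Resample the training set only, fit, and score the untouched test set.

    Returns the metric block plus per-compound misclassification lists
    (``false_negatives`` / ``false_positives`` ids).
    """
    sampler_params = dict(sampler_params or {})
    if train.bit_count != test.bit_count:
        raise ValueError(
            f"train/test bit widths differ: {train.bit_count} vs {test.bit_count}"
        )
    resampled = apply_sampler(
        sampler_name, train, seed=derive_seed(seed, "external-sampler"), **sampler_params
    ).dataset
    clf = train_rf(resampled, n_trees=n_trees, seed=derive_seed(seed, "external-rf"))
    scores = predict_scores(clf, test.X)
    block = _evaluate_block(test.y, scores)
    y_pred = (scores >= 0.5).astype(np.int64)
    block["false_negatives"] = [
        test.ids[i] for i in np.flatnonzero((test.y == 1) & (y_pred == 0))
    ]
    block["false_positives"] = [
        test.ids[i] for i in np.flatnonzero((test.y == 0) & (y_pred == 1))
    ]
    return block


def run_comparison(
    train: FingerprintDataset,
    test: FingerprintDataset | None = None,
    conditions: list[tuple[str, dict]] | list[str] | None = None,
    n_folds: int = 10,
    n_trees: int = 1000,
    seed: int = 0,
    leaky: bool = False,
) -> EvaluationReport:
    """Run CV (and external validation when ``test`` is given) for every
    condition, sharing one stratified fold split across conditions."""
    if conditions is None:
        conditions = ["none"]
    normalized: list[tuple[str, dict]] = [
        (c, {}) if isinstance(c, str) else (c[0], dict(c[1])) for c in conditions
    ]
    shared_folds = None if leaky else make_folds(train, n_folds, derive_seed(seed, "folds"))
    reports: list[ConditionReport] = []
    for name, params in normalized:
        rep = cross_validate(
            train,
            sampler_name=name,
            sampler_params=params,
            n_folds=n_folds,
            n_trees=n_trees,
            seed=seed,
            leaky=leaky,
            folds=shared_folds,
        )
        if test is not None:
            rep.external = external_validate(
                train, test, sampler_name=name, sampler_params=params,
                n_trees=n_trees, seed=seed,
            )
        reports.append(rep)
    notes = [
        "sensitivity = tp/(tp+fn) (true positive rate); "
        "specificity = tn/(tn+fp); zero-denominator rates reported as 0.0 and flagged",
    ]
    if leaky:
        notes.append("LEAKY mode: resampling happened before the CV split")
    return EvaluationReport(conditions=reports, seed=int(seed), notes=notes)


def plot_comparison(report: EvaluationReport, path: str | Path) -> None:
    """Grouped bar chart of mean CV metrics per condition (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [c.condition for c in report.conditions]
    x = np.arange(len(names))
    width = 0.16
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(names)), 4))
    for i, metric in enumerate(METRIC_NAMES):
        vals = [c.mean[metric] for c in report.conditions]
        errs = [c.std[metric] for c in report.conditions]
        ax.bar(x + (i - 2) * width, vals, width, yerr=errs, label=metric, capsize=2)
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    ax.set_ylabel("mean over folds")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
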