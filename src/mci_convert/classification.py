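"""RBF-SVM transfer classification: train on NC vs AD, test on MCI.

The classifier is fitted on the extreme groups (cognitively normal
controls vs Alzheimer's patients) with (C, gamma) chosen by stratified
cross-validated AUC over a coarse power-of-four grid, then applied to
the intermediate MCI subjects. The continuous SVM output f(x) -- the
signed, scaled distance from the separating hyperplane -- is the
subject's predictive value. The stored sign convention places the
AD-like side at negative values, so a subject is predicted to convert
(MCIc) exactly when f(x) < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocessing import ScalingParams, apply_minmax, fit_minmax, scale_with_bounds

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "SvmConfig",
    "TrainedClassifier",
    "PredictionRecord",
    "MetricsReport",
    "train_svm",
    "predict_decision_values",
    "predict_cohort",
    "evaluate",
    "rank_auc",
    "records_to_frame",
    "frame_to_records",
]

# Standard coarse RBF grid: C in 2^-5..2^15, gamma in 2^-15..2^3, steps of 4x.
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 2))


@dataclass
class SvmConfig:
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(v <= 0 for v in list(self.c_grid) + list(self.gamma_grid)):
            raise ValueError("C and gamma candidates must be > 0")


@dataclass
class TrainedClassifier:
    """Fitted SVM with its scaling, feature subset and sign convention.

    ``sign`` multiplies the raw libsvm decision function so that the
    AD-labelled side of the hyperplane is negative.
    """

    svc: SVC
    scaling: ScalingParams
    feature_names: tuple
    C: float
    gamma: float
    sign: int
    cv_auc: float
    ad_label: str = "AD"

    def decision_values(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.feature_names if n not in X.columns]
            if missing:
                raise KeyError(f"test data lacks model features: {missing}")
            X = X.loc[:, list(self.feature_names)]
        scaled = apply_minmax(self.scaling, X)
        arr = scaled.to_numpy() if isinstance(scaled, pd.DataFrame) else scaled
        return self.sign * self.svc.decision_function(arr)


@dataclass(frozen=True)
class PredictionRecord:
    """One test subject's continuous predictive value and labels."""

    subject_id: str
    decision_value: float
    predicted_label: str  # "MCIc" iff decision_value < 0, else "MCInc"
    true_label: str
    conversion_month: int | None = None


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and summary metrics with MCIc as positive class."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float  # percent
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def train_svm(X, y, config: SvmConfig | None = None, *, ad_label: str = "AD") -> TrainedClassifier:
    """Grid-search (C, gamma) by cross-validated AUC, refit on all data.

    ``X`` is the NC-and-AD feature matrix (DataFrame), ``y`` the group
    labels. Scaling to [0, 1] is learned inside each CV fold for the
    search and on the full training set for the final refit. Ties in the
    grid keep the first (smallest C, then gamma) candidate.
    """
    config = config or SvmConfig()
    config.validate()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if ad_label not in classes:
        raise ValueError(f"label {ad_label!r} absent from training labels")
    arr = X.to_numpy(dtype=float)
    y01 = (y == ad_label).astype(np.int64)  # 1 = AD

    from sklearn.metrics import roc_auc_score

    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    splits = list(cv.split(arr, y01))
    candidates = []  # (auc, acc, C, gamma)
    for C in config.c_grid:
        for gamma in config.gamma_grid:
            aucs, accs = [], []
            for tr, va in splits:
                mins, maxs = arr[tr].min(axis=0), arr[tr].max(axis=0)
                svc = SVC(C=C, kernel="rbf", gamma=gamma)
                svc.fit(scale_with_bounds(arr[tr], mins, maxs), y01[tr])
                scores = svc.decision_function(scale_with_bounds(arr[va], mins, maxs))
                aucs.append(0.5 if np.ptp(scores) == 0 else roc_auc_score(y01[va], scores))
                accs.append(float(np.mean((scores > 0) == (y01[va] == 1))))
            candidates.append((float(np.mean(aucs)), float(np.mean(accs)), C, gamma))
    # primary: CV AUC; ties (common on separable training data) broken by CV
    # accuracy so a well-placed zero threshold wins over models whose
    # decision values merely rank correctly; remaining ties -- often a large
    # plateau of perfect candidates -- resolved toward the candidate closest
    # to the plateau's log-space centroid, i.e. the interior of the optimal
    # region, which is robust to one-step hyperparameter perturbations.
    top = max(c[:2] for c in candidates)
    tied = [c for c in candidates if c[:2] == top]
    log_pts = np.log2([[c[2], c[3]] for c in tied])
    centroid = log_pts.mean(axis=0)
    cv_auc, _, C, gamma = tied[int(np.argmin(((log_pts - centroid) ** 2).sum(axis=1)))]
    scaling = fit_minmax(X)
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(apply_minmax(scaling, X).to_numpy(), y01)
    # enforce the sign convention: AD side negative
    train_dec = svc.decision_function(apply_minmax(scaling, X).to_numpy())
    sign = -1 if train_dec[y01 == 1].mean() > 0 else 1
    return TrainedClassifier(
        svc, scaling, tuple(X.columns), float(C), float(gamma), sign, cv_auc, ad_label
    )


def predict_decision_values(
    model: TrainedClassifier,
    X,
    subject_ids=None,
    true_labels=None,
    conversion_months=None,
) -> list:
    """Predictive values and threshold-at-zero labels for test subjects."""
    values = model.decision_values(X)
    n = len(values)
    ids = list(subject_ids) if subject_ids is not None else [f"T{i:04d}" for i in range(n)]
    labels = list(true_labels) if true_labels is not None else [""] * n
    months = list(conversion_months) if conversion_months is not None else [None] * n
    records = []
    for i in range(n):
        m = months[i]
        m = None if (m is None or (isinstance(m, float) and np.isnan(m)) or m is pd.NA) else int(m)
        records.append(
            PredictionRecord(
                subject_id=str(ids[i]),
                decision_value=float(values[i]),
                predicted_label="MCIc" if values[i] < 0 else "MCInc",
                true_label=str(labels[i]),
                conversion_month=m,
            )
        )
    return records


def predict_cohort(model: TrainedClassifier, cohort, groups=("MCInc", "MCIc")) -> list:
    """Convenience wrapper: predict the MCI subjects of a cohort."""
    sub = cohort.subset(groups)
    return predict_decision_values(
        model,
        sub.data.loc[:, list(model.feature_names)],
        subject_ids=sub.data["subject_id"],
        true_labels=sub.data["group"],
        conversion_months=sub.data["conversion_month"].tolist(),
    )


def rank_auc(scores, positive_mask) -> float:
    """Mann-Whitney (rank-based) AUC with half credit for ties.

    Probability that a random positive scores higher than a random
    negative under ``scores``.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(positive_mask, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one subject of each class")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(records, positive_label: str = "MCIc", negative_label: str = "MCInc") -> MetricsReport:
    """Confusion counts, accuracy/sensitivity/specificity (%) and AUC.

    MCIc is the positive class; AUC is computed on the negated decision
    values so that more negative (more AD-like) means more MCIc-like.
    """
    records = list(records)
    true = np.asarray([r.true_label for r in records])
    pred = np.asarray([r.predicted_label for r in records])
    dv = np.asarray([r.decision_value for r in records], dtype=float)
    pos = true == positive_label
    neg = true == negative_label
    if not pos.any() or not neg.any():
        raise ValueError("need at least one record of each true class")
    if not (pos | neg).all():
        bad = sorted(set(true) - {positive_label, negative_label})
        raise ValueError(f"unexpected true labels {bad}")
    tp = int(np.sum(pos & (pred == positive_label)))
    fn = int(np.sum(pos & (pred != positive_label)))
    tn = int(np.sum(neg & (pred == negative_label)))
    fp = int(np.sum(neg & (pred != negative_label)))
    total = tp + fn + tn + fp
    return MetricsReport(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        accuracy=100.0 * (tp + tn) / total,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        auc=rank_auc(-dv, pos),
    )


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "decision_value": [r.decision_value for r in records],
            "predicted_label": [r.predicted_label for r in records],
            "true_label": [r.true_label for r in records],
            "conversion_month": pd.array(
                [r.conversion_month if r.conversion_month is not None else pd.NA for r in records],
                dtype="Int64",
            ),
        }
    )


def frame_to_records(df: pd.DataFrame) -> list:
    records = []
    for row in df.itertuples(index=False):
        m = row.conversion_month
        records.append(
            PredictionRecord(
                subject_id=str(row.subject_id),
                decision_value=float(row.decision_value),
                predicted_label=str(row.predicted_label),
                true_label=str(row.true_label),
                conversion_month=None if pd.isna(m) else int(m),
            )
        )
    return records
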