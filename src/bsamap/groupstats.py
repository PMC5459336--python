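"""Group comparison, regression associations, and LOOCV SVM classification.

A cohort is a pandas DataFrame with columns ``subject_id``, ``group``
(control / patient) and one numeric column per feature (ROI activity means,
ROI SUVR, volume fractions, the neuronal-component count k, covariates such
as MMSE and CSF biomarkers).

Group differences use an omnibus one-way ANOVA over the stacked
(subject x feature) observations followed by per-feature Welch t-tests with
Bonferroni adjustment (factor = number of features). Classification is a
linear SVM evaluated by leave-one-out cross-validation with per-fold
standardization (training-fold statistics only, so no test leakage);
sensitivity/specificity get Wilson 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError
from .pet import PearsonResult

__all__ = [
    "ClassificationReport",
    "make_cohort",
    "group_compare",
    "roi_association",
    "loocv_linear_svm",
]

GROUPS = ("control", "patient")


def make_cohort(records: list[dict]) -> pd.DataFrame:
    """Build a cohort table from per-subject dicts; validates the schema."""
    df = pd.DataFrame.from_records(records)
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise DataError(f"cohort table needs a '{col}' column")
    unknown = set(df["group"]) - set(GROUPS)
    if unknown:
        raise DataError(f"unknown group labels {sorted(unknown)}; expected {GROUPS}")
    return df


def _split(df: pd.DataFrame, feature: str) -> tuple[np.ndarray, np.ndarray]:
    if feature not in df.columns:
        raise DataError(f"missing feature column '{feature}'")
    vals = df[feature].to_numpy(float)
    if np.isnan(vals).any():
        raise DataError(f"missing values in feature '{feature}'")
    g = df["group"].to_numpy()
    return vals[g == "control"], vals[g == "patient"]


def group_compare(df: pd.DataFrame, feature_names: list[str]) -> tuple[float, pd.DataFrame]:
    """Omnibus ANOVA plus per-feature Welch t-tests with Bonferroni adjustment.

    Returns ``(omnibus_p, table)`` where the table has one row per feature with
    group means/SEM, the Welch statistic, raw p and the Bonferroni-adjusted p
    (raw p times the number of features, capped at 1).
    """
    df = validate_cohort(df)
    if not feature_names:
        raise DataError("no features requested")
    counts = df["group"].value_counts()
    if any(counts.get(g, 0) < 2 for g in GROUPS):
        raise DataError("need >= 2 subjects per group")
    stacked_c, stacked_p = [], []
    rows = []
    m = len(feature_names)
    for feat in feature_names:
        c, p = _split(df, feat)
        stacked_c.append(c)
        stacked_p.append(p)
        if np.std(np.concatenate([c, p])) == 0.0:
            raise DataError(f"feature '{feat}' is constant in both groups")
        t, p_raw = stats.ttest_ind(c, p, equal_var=False)
        t, p_raw = float(t), float(p_raw)
        if np.isnan(t):  # zero variance in both groups with equal means
            t, p_raw = 0.0, 1.0
        rows.append(
            {
                "feature": feat,
                "mean_control": float(c.mean()),
                "sem_control": float(stats.sem(c)),
                "mean_patient": float(p.mean()),
                "sem_patient": float(stats.sem(p)),
                "t_welch": t,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * m),
            }
        )
    omnibus = stats.f_oneway(np.concatenate(stacked_c), np.concatenate(stacked_p))
    return float(omnibus.pvalue), pd.DataFrame(rows)


def roi_association(df: pd.DataFrame, x_name: str, y_name: str,
                    n_tests: int = 1) -> PearsonResult:
    """Pearson/linear-regression association between two subject features.

    ``n_tests`` is the number of associations examined in the same analysis;
    the returned ``p_adjusted`` is the Bonferroni-scaled p, capped at 1.
    """
    df = validate_cohort(df)
    for name in (x_name, y_name):
        if name not in df.columns:
            raise DataError(f"missing feature column '{name}'")
    sub = df[[x_name, y_name]].dropna()
    if len(sub) < 3:
        raise DataError("need >= 3 subjects with both features")
    x = sub[x_name].to_numpy(float)
    y = sub[y_name].to_numpy(float)
    if x.std() == 0.0 or y.std() == 0.0:
        raise DataError("constant feature; association undefined")
    res = stats.linregress(x, y)
    return PearsonResult(
        r=float(res.rvalue), n=len(sub), slope=float(res.slope),
        intercept=float(res.intercept), p=float(res.pvalue),
        p_adjusted=min(1.0, float(res.pvalue) * n_tests),
    )


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]
    predictions: pd.DataFrame  # subject_id, group, predicted, correct

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ci_sensitivity": list(self.ci_sensitivity),
            "ci_specificity": list(self.ci_specificity),
        }


def loocv_linear_svm(df: pd.DataFrame, feature_names: list[str],
                     C: float = 1.0) -> ClassificationReport:
    """Leave-one-out linear-SVM classification; patient is the positive class.

    Each fold standardizes features with the training fold's statistics, fits
    a linear SVM (regularization C), and predicts the held-out subject.
    Sensitivity = patient recall, specificity = control recall; both carry
    Wilson 95% intervals.
    """
    df = validate_cohort(df).reset_index(drop=True)
    counts = df["group"].value_counts()
    if any(counts.get(g, 0) < 2 for g in GROUPS):
        raise DataError("need >= 2 subjects per group for LOOCV")
    X = df[list(feature_names)].to_numpy(float)
    if np.isnan(X).any():
        raise DataError("missing feature values")
    y = (df["group"] == "patient").to_numpy(int)
    n = len(df)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise DataError(
                f"training fold for subject {df['subject_id'][i]} has a single class"
            )
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="linear", C=C).fit(scaler.transform(X[train]), y_tr)
        preds[i] = int(clf.predict(scaler.transform(X[i:i + 1]))[0])
    correct = preds == y
    pos, neg = y == 1, y == 0
    tp, tn = int(correct[pos].sum()), int(correct[neg].sum())
    sens = tp / pos.sum()
    spec = tn / neg.sum()
    ci_sens = proportion_confint(tp, int(pos.sum()), alpha=0.05, method="wilson")
    ci_spec = proportion_confint(tn, int(neg.sum()), alpha=0.05, method="wilson")
    table = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "group": df["group"],
            "predicted": np.where(preds == 1, "patient", "control"),
            "correct": correct,
        }
    )
    return ClassificationReport(
        accuracy=float(correct.mean()),
        sensitivity=float(sens),
        specificity=float(spec),
        ci_sensitivity=(float(ci_sens[0]), float(ci_sens[1])),
        ci_specificity=(float(ci_spec[0]), float(ci_spec[1])),
        predictions=table,
    )
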