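"""End-to-end cohort pipeline.

Glue that runs the full analysis on a (synthetic or real) cohort: extract
the nonlinear feature vector for every subject-night, assemble the cohort
feature table, predict AHI with the screening equation, and evaluate
screening and severity classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, extract_features
from .models import (
    PUBLISHED_AHI_MODEL,
    GainRatioTreeClassifier,
    classify_severity,
    cpap_group_from_ahi,
    evaluate_cv,
)
from .stats import pearson_r, roc_auc, sens_spec
from .synthetic import CohortSubject, generate_cohort

__all__ = [
    "extract_cohort_features",
    "run_cohort_pipeline",
    "cohort_summary",
]


def extract_cohort_features(subjects: list[CohortSubject], **extract_kwargs) -> pd.DataFrame:
    """Feature table with one row per subject (conventional column names),
    plus identifiers and ground-truth indices."""
    rows = []
    for s in subjects:
        if s.recording is None:
            raise ValueError(f"subject {s.id} has no recording")
        fv = extract_features(
            s.recording,
            demographics={"age": s.age, "sex": s.sex, "bmi": s.bmi, "epworth": s.epworth},
            **extract_kwargs,
        )
        row = {"id": s.id, **fv.to_dict(), "AHI": s.ahi_true, "AI": s.ai, "HI": s.hi}
        rows.append(row)
    return pd.DataFrame(rows)


def predict_table_ahi(table: pd.DataFrame, model=PUBLISHED_AHI_MODEL) -> np.ndarray:
    """Apply the screening equation row-wise to a cohort feature table.

    Accepts either the table-style column spellings (``mmDFAt2``) or the
    predictor names themselves (``mmDFA_t2``).
    """

    def col(*names):
        for name in names:
            if name in table.columns:
                return table[name].to_numpy(dtype=float)
        raise KeyError(f"table is missing predictor column {names[0]!r}")

    values = {
        "BMI": col("BMI"),
        "T90": col("T90"),
        "dDFA_f2": col("dDFA_f2"),
        "dLLE": col("dLLE"),
        "mmDFA_t2": col("mmDFAt2", "mmDFA_t2"),
    }
    out = np.full(len(table), model.intercept, dtype=float)
    for name, coef in model.coefficients.items():
        out += coef * values[name]
    return out


def run_cohort_pipeline(
    n_subjects: int = 40,
    seed: int = 0,
    *,
    duration: float = 6 * 3600.0,
    cutoff: float = 8.0,
    cv_folds: int = 10,
    subjects: list[CohortSubject] | None = None,
) -> dict:
    """Simulate (or accept) a cohort, extract features, and evaluate.

    Returns a dict with the feature ``table`` and evaluation numbers:
    predicted-vs-true AHI correlation, sensitivity/specificity of the
    screening equation at ``cutoff``, ROC AUC for OSA detection, and
    stratified-CV metrics of the severity decision tree.
    """
    if subjects is None:
        subjects = generate_cohort(n_subjects, seed=seed, duration=duration)
    table = extract_cohort_features(subjects)
    pred = predict_table_ahi(table)
    true = table["AHI"].to_numpy()

    r, p = pearson_r(pred, true)
    sens, spec = sens_spec(pred, true, cutoff=cutoff)
    auc = roc_auc(pred, (true >= 5.0).astype(int))

    cpap_labels = np.array([cpap_group_from_ahi(a) for a in true])
    feature_cols = [c for c in FEATURE_COLUMNS if c not in ("SEX",)]
    X = table[feature_cols].copy()
    cv = None
    if len(np.unique(cpap_labels)) == 2:
        cv = evaluate_cv(X, cpap_labels, GainRatioTreeClassifier(), k=cv_folds, seed=seed)

    return {
        "subjects": subjects,
        "table": table,
        "pred_ahi": pred,
        "pearson_r": r,
        "pearson_p": p,
        "sensitivity": sens,
        "specificity": spec,
        "auc": auc,
        "severity": [classify_severity(a) for a in true],
        "cv": cv,
    }


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean/SD descriptive statistics of the numeric columns of a
    cohort table (the standard descriptive-table layout)."""
    num = table.select_dtypes(include=[np.number])
    return pd.DataFrame(
        {
            "Minimum": num.min(),
            "Maximum": num.max(),
            "Mean": num.mean(),
            "Standard Deviation": num.std(ddof=1),
        }
    )
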