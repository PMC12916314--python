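"""Normative residualization: leakage-safe removal of linear age/sex effects.

Age and sex regressors are estimated per feature by ordinary least squares on
the *healthy training* subjects only, then the fitted linear trend is
subtracted from every subject (patients and controls, training and test
alike).  Fitting on healthy subjects keeps diagnosis effects out of the
regressors; fitting on training folds only keeps test data out of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splitting import FoldPlan


@dataclass
class ResidualModel:
    """Per-feature linear model y = intercept + age_coef*(age - age_center) + sex_coef*sex."""

    intercept: np.ndarray
    age_coef: np.ndarray
    sex_coef: np.ndarray
    age_center: float
    n_hc_used: int
    train_fold_ids: tuple[int, ...]
    rows_used: np.ndarray          # integer row indices into the fitting cohort

    @property
    def n_features(self) -> int:
        return self.intercept.shape[0]

    def save(self, path) -> None:
        """Persist to HDF5 (coefficient arrays + JSON metadata attribute)."""
        import json

        import h5py

        with h5py.File(path, "w") as f:
            for name in ("intercept", "age_coef", "sex_coef", "rows_used"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["meta"] = json.dumps({
                "age_center": self.age_center,
                "n_hc_used": self.n_hc_used,
                "train_fold_ids": list(self.train_fold_ids),
            })

    @classmethod
    def load(cls, path) -> "ResidualModel":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            return cls(
                intercept=f["intercept"][()], age_coef=f["age_coef"][()],
                sex_coef=f["sex_coef"][()], rows_used=f["rows_used"][()],
                age_center=meta["age_center"], n_hc_used=meta["n_hc_used"],
                train_fold_ids=tuple(meta["train_fold_ids"]),
            )


def fit_normative(
    features: np.ndarray,
    cohort: pd.DataFrame,
    train_fold_ids,
    plan: FoldPlan,
) -> ResidualModel:
    """OLS of each feature on [1, age - mean(age_HC), sex] over HC training rows.

    Degenerate designs fall back gracefully: a single-sex HC set fixes the sex
    coefficient at 0, an age-constant HC set fixes the age coefficient at 0
    (each with a warning).
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] != len(cohort):
        raise ValueError("features must be (n_subjects, n_features) aligned with cohort")
    train_fold_ids = tuple(int(f) for f in train_fold_ids)
    folds = plan.fold_of(cohort["subject_id"])
    in_train = np.isin(folds, train_fold_ids)
    is_hc = cohort["dx"].to_numpy().astype(int) == 0
    rows = np.flatnonzero(in_train & is_hc)
    if len(rows) == 0:
        raise ValueError("no healthy subjects in the training folds")
    if len(rows) < 3:
        raise ValueError(f"need >= 3 healthy training subjects, found {len(rows)}")

    age = cohort["age"].to_numpy()[rows]
    sex = cohort["sex"].to_numpy().astype(np.float64)[rows]
    age_center = float(age.mean())
    age_c = age - age_center

    use_age = age_c.std() > 1e-12
    use_sex = len(np.unique(sex)) > 1
    if not use_age:
        warnings.warn("HC training ages are constant; age coefficient set to 0",
                      RuntimeWarning, stacklevel=2)
    if not use_sex:
        warnings.warn("HC training set has a single sex; sex coefficient set to 0",
                      RuntimeWarning, stacklevel=2)

    cols = [np.ones(len(rows))]
    if use_age:
        cols.append(age_c)
    if use_sex:
        cols.append(sex)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, features[rows], rcond=None)

    p = features.shape[1]
    intercept = coef[0]
    age_coef = np.zeros(p)
    sex_coef = np.zeros(p)
    j = 1
    if use_age:
        age_coef = coef[j]
        j += 1
    if use_sex:
        sex_coef = coef[j]
    return ResidualModel(
        intercept=intercept, age_coef=age_coef, sex_coef=sex_coef,
        age_center=age_center, n_hc_used=len(rows),
        train_fold_ids=train_fold_ids, rows_used=rows,
    )


def apply_residualization(
    model: ResidualModel, features: np.ndarray, cohort: pd.DataFrame
) -> np.ndarray:
    """Subtract the fitted age/sex trend from every subject, dx- and fold-blind."""
    features = np.asarray(features, dtype=np.float64)
    if features.shape != (len(cohort), model.n_features):
        raise ValueError("features shape does not match cohort / fitted model")
    age_c = cohort["age"].to_numpy() - model.age_center
    sex = cohort["sex"].to_numpy().astype(np.float64)
    predicted = (model.intercept[None, :]
                 + np.outer(age_c, model.age_coef)
                 + np.outer(sex, model.sex_coef))
    return features - predicted
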