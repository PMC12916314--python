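"""The two 10-fold cross-validation partitions compared in multi-site studies.

``age_sex`` mixes every site across all folds while balancing age, sex,
diagnosis and per-site counts — the optimistic mixed-site protocol.
``site`` keeps each acquisition site intact inside a single fold (greedy
balanced number-partitioning of sites), so every test fold consists of sites
never seen in training — the leave-site-out protocol estimating transfer to
unseen scanners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

STRATEGIES = ("age_sex", "site")


@dataclass
class FoldPlan:
    """Subject -> fold assignment plus per-fold QC."""

    k: int
    assignment: pd.Series          # index subject_id, values fold int
    strategy: str

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        folds = self.assignment.to_numpy()
        if folds.min() < 0 or folds.max() >= self.k:
            raise ValueError("fold indices out of range")

    def fold_of(self, subject_ids) -> np.ndarray:
        return self.assignment.loc[subject_ids].to_numpy()

    def test_mask(self, cohort: pd.DataFrame, fold: int) -> np.ndarray:
        return self.fold_of(cohort["subject_id"]) == fold

    def save(self, path) -> None:
        self.assignment.rename("fold").rename_axis("subject_id").to_csv(path)

    @classmethod
    def load(cls, path, strategy: str) -> "FoldPlan":
        df = pd.read_csv(path).set_index("subject_id")
        s = df["fold"].astype(int)
        return cls(k=int(s.max()) + 1, assignment=s, strategy=strategy)


def split_age_sex(cohort: pd.DataFrame, k: int = 10, seed: int = 0) -> FoldPlan:
    """Covariate-balanced mixed-site folds.

    Within each site, subjects are stratified by (sex, dx), ordered by age
    (ties broken by a seeded shuffle) and dealt round-robin into folds with a
    per-site rolling counter starting at a seeded offset.  Consequences: each
    site's subjects are spread across folds as evenly as integer rounding
    allows, and age/sex/case ratios are balanced per fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(cohort) < k:
        raise ValueError(f"cohort has {len(cohort)} subjects, fewer than k={k}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for site in sorted(cohort["site"].unique()):
        site_rows = cohort[cohort["site"] == site]
        counter = int(rng.integers(k))        # seeded per-site starting fold
        for (sex, dx) in sorted(
            set(zip(site_rows["sex"].astype(int), site_rows["dx"].astype(int)))
        ):
            stratum = site_rows[
                (site_rows["sex"].astype(int) == sex) & (site_rows["dx"].astype(int) == dx)
            ]
            tiebreak = rng.permutation(len(stratum))
            order = np.lexsort((tiebreak, stratum["age"].to_numpy()))
            for sid in stratum["subject_id"].to_numpy()[order]:
                assignment[sid] = counter % k
                counter += 1
    series = pd.Series(assignment, name="fold").loc[cohort["subject_id"]].astype(int)
    return FoldPlan(k=k, assignment=series, strategy="age_sex")


def split_by_site(cohort: pd.DataFrame, k: int = 10) -> FoldPlan:
    """Greedy whole-site folds balancing subject counts.

    Sites sorted by size descending (ties by label); each goes to the
    currently smallest fold (ties to the lowest index).  Deterministic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sizes = cohort.groupby("site").size()
    if len(sizes) < k:
        raise ValueError(
            f"only {len(sizes)} sites for k={k} folds; use a smaller k"
        )
    order = sorted(sizes.index, key=lambda s: (-sizes[s], s))
    totals = np.zeros(k, dtype=int)
    site_fold: dict[str, int] = {}
    for site in order:
        f = int(np.argmin(totals))            # argmin takes the lowest index on ties
        site_fold[site] = f
        totals[f] += sizes[site]
    folds = cohort["site"].map(site_fold).astype(int)
    series = pd.Series(folds.to_numpy(), index=cohort["subject_id"], name="fold")
    return FoldPlan(k=k, assignment=series, strategy="site")


def validate_fold_plan(plan: FoldPlan, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-fold QC table: n, age mean/sd, female and case counts, site list.

    Raises on subjects not covered by the plan.  The returned frame carries
    cross-fold range statistics in ``df.attrs["ranges"]``.
    """
    missing = set(cohort["subject_id"]) - set(plan.assignment.index)
    if missing:
        raise ValueError(f"fold plan does not cover subjects: {sorted(missing)[:5]} ...")
    folds = plan.fold_of(cohort["subject_id"])
    rows = []
    for f in range(plan.k):
        sub = cohort[folds == f]
        rows.append({
            "fold": f,
            "n": len(sub),
            "age_mean": sub["age"].mean(),
            "age_sd": sub["age"].std(),
            "n_female": int(sub["sex"].sum()),
            "pct_female": 100.0 * sub["sex"].mean() if len(sub) else np.nan,
            "n_case": int(sub["dx"].sum()),
            "pct_case": 100.0 * sub["dx"].mean() if len(sub) else np.nan,
            "sites": sorted(sub["site"].unique()),
        })
    qc = pd.DataFrame(rows)
    qc.attrs["ranges"] = {
        "n_range": int(qc["n"].max() - qc["n"].min()),
        "age_mean_range": float(qc["age_mean"].max() - qc["age_mean"].min()),
        "female_frac_range": float((qc["pct_female"].max() - qc["pct_female"].min()) / 100.0),
        "case_frac_range": float((qc["pct_case"].max() - qc["pct_case"].min()) / 100.0),
    }
    return qc


def qc_report_json(plan: FoldPlan, cohort: pd.DataFrame) -> str:
    qc = validate_fold_plan(plan, cohort)
    payload = {
        "strategy": plan.strategy,
        "k": plan.k,
        "folds": qc.to_dict(orient="records"),
        "ranges": qc.attrs["ranges"],
    }
    return json.dumps(payload, indent=2, default=float)
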