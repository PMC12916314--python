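"""Parametric empirical-Bayes location/scale harmonization across sites (ComBat).

Model per feature v, subject j of batch (site) i::

    y_ijv = alpha_v + x_ij' beta_v + gamma_iv + delta_iv eps_ijv

Batch locations gamma_iv get a normal prior, batch scale factors delta_iv
(variances on the standardized scale) an inverse-gamma prior; hyperparameters
are method-of-moments estimates across features and the conditional posterior
modes (gamma*, delta*) are found by iterated conditional updates.  Variance
explained by the configured covariates (age, sex) is re-added after
adjustment, so harmonization never removes it.

Two modes:

* ``standard`` — all batches adjusted toward the weighted grand mean; the
  mixed-site protocol (parameters fit on training folds apply directly to
  test subjects, whose sites were seen in training).
* ``reference_batch`` — one batch is the fixed reference: standardization
  uses reference statistics, the reference's (gamma*, delta*) are pinned at
  (0, 1) and its data pass through bit-for-bit; non-reference batches are
  pulled toward it.  Combined with a standard first stage this gives the
  leave-site-out protocol: harmonize the training sites, then adjust each
  unseen test site toward the harmonized training data.

Constant features (e.g. pixels outside the projected cortex) are excluded
from standardization and pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE_LABEL = "__reference__"


class UnseenSiteError(ValueError):
    """A batch label at apply time was not fitted; use reference-batch mode."""


class LeakageError(ValueError):
    """Train and test site sets overlap in a leave-site-out harmonization."""


@dataclass(frozen=True)
class HarmonizationConfig:
    covariates: tuple[str, ...] = ("age", "sex")
    parametric: bool = True
    mode: str = "standard"                 # or "reference_batch"
    reference_batch: str | None = None
    eb_maxiter: int = 100
    eb_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "reference_batch"):
            raise ValueError("mode must be 'standard' or 'reference_batch'")
        if self.mode == "reference_batch" and self.reference_batch is None:
            raise ValueError("reference_batch mode needs a reference batch label")
        if self.eb_tol <= 0:
            raise ValueError("eb_tol must be > 0")
        if not self.parametric:
            raise ValueError("only the parametric formulation is implemented")


@dataclass
class CombatParameters:
    """Fitted location/scale model; arrays indexed (batch, feature)."""

    batches: list[str]
    n_per_batch: np.ndarray
    alpha: np.ndarray                      # (p,) grand location
    beta: np.ndarray                       # (q, p) covariate coefficients
    var_pooled: np.ndarray                 # (p,) pooled residual variance
    gamma_hat: np.ndarray                  # (B, p) raw standardized batch locations
    delta_hat: np.ndarray                  # (B, p) raw standardized batch variances
    gamma_star: np.ndarray                 # (B, p) EB-shrunken locations
    delta_star: np.ndarray                 # (B, p) EB-shrunken variances (> 0)
    hyper: dict                            # per-batch prior hyperparameters
    nonconstant: np.ndarray                # (p,) bool, features that were standardized
    covariate_names: tuple[str, ...]
    config: HarmonizationConfig
    reference_batch: str | None = None
    converged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_features(self) -> int:
        return self.alpha.shape[0]

    def batch_index(self, label: str) -> int:
        try:
            return self.batches.index(label)
        except ValueError:
            raise UnseenSiteError(
                f"site {label!r} was not in the fitted batches {self.batches}; "
                "use reference-batch mode to adjust unseen sites"
            ) from None

    def save(self, path) -> None:
        """Persist to HDF5 (per-feature arrays + JSON metadata attribute)."""
        import json

        import h5py

        with h5py.File(path, "w") as f:
            for name in ("n_per_batch", "alpha", "beta", "var_pooled", "gamma_hat",
                         "delta_hat", "gamma_star", "delta_star", "nonconstant",
                         "converged"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["meta"] = json.dumps({
                "batches": self.batches,
                "hyper": self.hyper,
                "covariate_names": list(self.covariate_names),
                "reference_batch": self.reference_batch,
                "config": {
                    "covariates": list(self.config.covariates),
                    "parametric": self.config.parametric,
                    "mode": self.config.mode,
                    "reference_batch": self.config.reference_batch,
                    "eb_maxiter": self.config.eb_maxiter,
                    "eb_tol": self.config.eb_tol,
                },
            })

    @classmethod
    def load(cls, path) -> "CombatParameters":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            cfg = meta["config"]
            return cls(
                batches=list(meta["batches"]),
                n_per_batch=f["n_per_batch"][()],
                alpha=f["alpha"][()], beta=f["beta"][()],
                var_pooled=f["var_pooled"][()],
                gamma_hat=f["gamma_hat"][()], delta_hat=f["delta_hat"][()],
                gamma_star=f["gamma_star"][()], delta_star=f["delta_star"][()],
                hyper=meta["hyper"],
                nonconstant=f["nonconstant"][()].astype(bool),
                covariate_names=tuple(meta["covariate_names"]),
                config=HarmonizationConfig(
                    covariates=tuple(cfg["covariates"]), parametric=cfg["parametric"],
                    mode=cfg["mode"], reference_batch=cfg["reference_batch"],
                    eb_maxiter=cfg["eb_maxiter"], eb_tol=cfg["eb_tol"]),
                reference_batch=meta["reference_batch"],
                converged=f["converged"][()].astype(bool),
            )


def design_from_cohort(cohort: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    """Covariate design columns (no intercept) from the cohort table."""
    return cohort.loc[:, list(covariates)].to_numpy(dtype=np.float64)


def _as_2d(features: np.ndarray) -> np.ndarray:
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("features must be (subjects, features)")
    return f


def _eb_iterate(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a_prior: float,
    b_prior: float,
    maxiter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iterated conditional modes for one batch's (gamma*, delta*)."""
    n = z_batch.shape[0]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    converged = False
    for _ in range(maxiter):
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (b_prior + 0.5 * sum2) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            converged = True
            break
    return g_old, d_old, converged


def fit_combat(
    features: np.ndarray,
    batch: np.ndarray,
    covariates: np.ndarray | None,
    config: HarmonizationConfig | None = None,
) -> CombatParameters:
    """Fit the parametric EB location/scale model on (subjects, features) data."""
    config = config or HarmonizationConfig()
    y = _as_2d(features)
    batch = np.asarray(batch)
    if batch.shape[0] != y.shape[0]:
        raise ValueError("batch labels must align with feature rows")
    batches = sorted(str(b) for b in np.unique(batch))
    if config.mode == "standard" and len(batches) < 2:
        raise ValueError("standard mode needs at least 2 batches")
    if config.mode == "reference_batch" and str(config.reference_batch) not in batches:
        raise ValueError(f"reference batch {config.reference_batch!r} not present in data")
    idx_by_batch = [np.flatnonzero(batch.astype(str) == b) for b in batches]
    n_i = np.array([len(ix) for ix in idx_by_batch])
    if np.any(n_i < 2):
        small = [b for b, n in zip(batches, n_i) if n < 2]
        raise ValueError(f"every batch needs >= 2 subjects; too small: {small}")
    n, p = y.shape

    if covariates is not None:
        x_cov = _as_2d(covariates)
        if x_cov.shape[0] != n:
            raise ValueError("covariates must align with feature rows")
    else:
        x_cov = np.empty((n, 0))
    q = x_cov.shape[1]

    onehot = np.zeros((n, len(batches)))
    for i, ix in enumerate(idx_by_batch):
        onehot[ix, i] = 1.0
    design = np.hstack([onehot, x_cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design: covariates are collinear with batch")

    # pass constant features through untouched
    nonconstant = y.std(axis=0) > 1e-12

    b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    batch_locs = b_hat[: len(batches)]           # (B, p)
    beta = b_hat[len(batches):]                  # (q, p)

    ref_idx: int | None = None
    if config.mode == "reference_batch":
        ref_idx = batches.index(str(config.reference_batch))
        alpha = batch_locs[ref_idx].copy()
        resid_ref = y[idx_by_batch[ref_idx]] - design[idx_by_batch[ref_idx]] @ b_hat
        var_pooled = (resid_ref ** 2).mean(axis=0)
    else:
        alpha = (n_i / n) @ batch_locs
        resid = y - design @ b_hat
        var_pooled = (resid ** 2).mean(axis=0)

    nonconstant &= var_pooled > 1e-24
    sd = np.sqrt(np.where(nonconstant, var_pooled, 1.0))

    stand_mean = alpha[None, :] + x_cov @ beta
    z = (y - stand_mean) / sd[None, :]

    gamma_hat = np.zeros((len(batches), p))
    delta_hat = np.ones((len(batches), p))
    gamma_star = np.zeros((len(batches), p))
    delta_star = np.ones((len(batches), p))
    converged = np.ones(len(batches), dtype=bool)
    hyper: dict[str, dict[str, float]] = {}

    cols = np.flatnonzero(nonconstant)
    for i, ix in enumerate(idx_by_batch):
        z_i = z[np.ix_(ix, cols)]
        g_hat = z_i.mean(axis=0)
        d_hat = z_i.var(axis=0, ddof=1)
        gamma_hat[i, cols] = g_hat
        delta_hat[i, cols] = d_hat

        gamma_bar = float(g_hat.mean())
        tau2 = float(g_hat.var(ddof=1)) if len(cols) > 1 else 1.0
        m = float(d_hat.mean())
        s2 = float(d_hat.var(ddof=1)) if len(cols) > 1 else 1.0
        if s2 < 1e-24:
            s2 = 1e-24
        a_prior = (2.0 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2
        hyper[batches[i]] = {
            "gamma_bar": gamma_bar, "tau2": tau2, "a_prior": a_prior, "b_prior": b_prior,
        }
        g_star, d_star, conv = _eb_iterate(
            z_i, g_hat, d_hat, gamma_bar, tau2, a_prior, b_prior,
            config.eb_maxiter, config.eb_tol,
        )
        gamma_star[i, cols] = g_star
        delta_star[i, cols] = d_star
        converged[i] = conv
        if not conv:
            warnings.warn(
                f"EB updates for batch {batches[i]!r} did not converge in "
                f"{config.eb_maxiter} iterations", RuntimeWarning, stacklevel=2,
            )

    if ref_idx is not None:
        gamma_star[ref_idx] = 0.0
        delta_star[ref_idx] = 1.0

    return CombatParameters(
        batches=batches, n_per_batch=n_i, alpha=alpha, beta=beta,
        var_pooled=var_pooled, gamma_hat=gamma_hat, delta_hat=delta_hat,
        gamma_star=gamma_star, delta_star=delta_star, hyper=hyper,
        nonconstant=nonconstant, covariate_names=tuple(config.covariates),
        config=config, reference_batch=(None if ref_idx is None else batches[ref_idx]),
        converged=converged,
    )


def apply_combat(
    params: CombatParameters,
    features: np.ndarray,
    batch: np.ndarray,
    covariates: np.ndarray | None,
) -> np.ndarray:
    """Adjust features with fitted parameters; covariate effects are re-added.

    In reference-batch mode the reference rows are returned bit-for-bit.
    Raises :class:`UnseenSiteError` for batch labels absent from the fit.
    """
    y = _as_2d(features)
    if y.shape[1] != params.n_features:
        raise ValueError("feature count does not match fitted parameters")
    batch = np.asarray(batch).astype(str)
    if covariates is not None:
        x_cov = _as_2d(covariates)
    else:
        x_cov = np.empty((y.shape[0], 0))
    if x_cov.shape[1] != params.beta.shape[0]:
        raise ValueError("covariate columns do not match fitted parameters")

    b_idx = np.array([params.batch_index(b) for b in batch])
    sd = np.sqrt(np.where(params.nonconstant, params.var_pooled, 1.0))
    stand_mean = params.alpha[None, :] + x_cov @ params.beta
    z = (y - stand_mean) / sd[None, :]
    adj = (z - params.gamma_star[b_idx]) / np.sqrt(params.delta_star[b_idx])
    out = adj * sd[None, :] + stand_mean
    out[:, ~params.nonconstant] = y[:, ~params.nonconstant]
    if params.reference_batch is not None:
        ref_rows = batch == params.reference_batch
        out[ref_rows] = y[ref_rows]
    return out


def harmonize_leave_site_out(
    train_features: np.ndarray,
    train_batch: np.ndarray,
    train_covariates: np.ndarray | None,
    test_features: np.ndarray,
    test_batch: np.ndarray,
    test_covariates: np.ndarray | None,
    config: HarmonizationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-stage harmonization for unseen test sites.

    Stage 1 harmonizes the training sites with the standard model; stage 2
    fits a reference-batch model in which all harmonized training data form
    the single reference batch and each test site is a non-reference batch,
    adjusting only the test sites.  Training output is identical to the
    stage-1 output by construction.

    Returns (harmonized train, harmonized test, fitted parameter dict).
    """
    config = config or HarmonizationConfig()
    train_sites = set(np.asarray(train_batch).astype(str))
    test_sites = set(np.asarray(test_batch).astype(str))
    overlap = train_sites & test_sites
    if overlap:
        raise LeakageError(f"train and test share sites: {sorted(overlap)}")
    if REFERENCE_LABEL in test_sites:
        raise ValueError(f"{REFERENCE_LABEL!r} is a reserved batch label")

    stage1 = fit_combat(train_features, train_batch, train_covariates, config)
    train_h = apply_combat(stage1, train_features, train_batch, train_covariates)

    y = np.vstack([train_h, _as_2d(test_features)])
    labels = np.concatenate([
        np.full(train_h.shape[0], REFERENCE_LABEL, dtype=object),
        np.asarray(test_batch).astype(object),
    ])
    if train_covariates is None and test_covariates is None:
        cov = None
    else:
        cov = np.vstack([_as_2d(train_covariates), _as_2d(test_covariates)])
    ref_config = HarmonizationConfig(
        covariates=config.covariates, parametric=config.parametric,
        mode="reference_batch", reference_batch=REFERENCE_LABEL,
        eb_maxiter=config.eb_maxiter, eb_tol=config.eb_tol,
    )
    stage2 = fit_combat(y, labels, cov, ref_config)
    adjusted = apply_combat(stage2, y, labels, cov)
    test_h = adjusted[train_h.shape[0]:]
    return train_h, test_h, {"stage1": stage1, "stage2": stage2}
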