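"""Desk-scale benchmark runs reproducing the site-effect phenomena.

Each function regenerates its synthetic cohort from scratch, executes the
full pipeline (project -> split -> [harmonize] -> residualize -> nested-CV
SVM) and returns the measured quantities.  Fixed study conditions: 10 sites
x 60 subjects, icosphere level 3 (642 vertices/hemisphere), 64 x 64
equal-area images, thickness maps for both hemispheres (8,192 pixel
features), noise SD 1.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chisquare

from .combat import HarmonizationConfig, apply_combat, fit_combat, harmonize_leave_site_out
from .evaluation import ClassifierSpec, EvalReport, assemble_feature_vector, run_outer_cv
from .mesh import make_icosphere
from .projection import (
    ProjectionGrid,
    build_projection,
    equal_area_coords,
    latlong_coords,
    project_features,
    stack_images,
    znormalize_images,
)
from .scenarios import confound_scenario, null_scenario, power_scenario, recovery_scenario
from .splitting import split_age_sex, split_by_site
from .synthetic import EffectSpec, SiteProfile, simulate_cohort

MESH_LEVEL = 3
GRID_SIZE = 64
HEMISPHERES = ("lh", "rh")


def render_pipeline_features(sites, spec, seed, method="equal_area"):
    """Generate a cohort and its flattened normalized pixel features."""
    mesh = make_icosphere(MESH_LEVEL)
    cohort, feats = simulate_cohort(sites, spec, mesh, seed, hemispheres=HEMISPHERES)
    grid = ProjectionGrid(GRID_SIZE, GRID_SIZE, method)
    planes, masks = {}, {}
    for hemi in HEMISPHERES:
        pmap = build_projection(mesh, grid)
        for mod in spec.modalities:
            label = f"{mod}_{hemi}"
            planes[label] = project_features(pmap, feats[(mod, hemi)].values)
            masks[label] = pmap.valid
    stack = znormalize_images(stack_images(planes, masks))
    return cohort, feats, assemble_feature_vector(stack)


def evaluate(cohort, features, strategy, combat, seed) -> EvalReport:
    if strategy == "age_sex":
        plan = split_age_sex(cohort, 10, seed)
    else:
        plan = split_by_site(cohort, 10)
    return run_outer_cv(cohort, features, plan, ClassifierSpec(seed=seed),
                        combat_mode="on" if combat else "off", seed=seed)


def null_chance_level(seeds) -> dict[str, list[float]]:
    """Balanced-accuracy of both strategies under the exact null, per seed."""
    out: dict[str, list[float]] = {"age_sex": [], "site": []}
    for seed in seeds:
        sites, spec = null_scenario()
        cohort, _, x = render_pipeline_features(sites, spec, seed)
        for strategy in ("age_sex", "site"):
            rep = evaluate(cohort, x, strategy, combat=False, seed=seed)
            out[strategy].append(rep.metric_mean("balanced_accuracy"))
    return out


def confound_inflation(seed: int) -> dict[str, float]:
    """Site-diagnosis confound: mixed-site inflation and its ComBat deflation."""
    sites, spec = confound_scenario()
    cohort, _, x = render_pipeline_features(sites, spec, seed)
    bacc = {}
    for strategy in ("age_sex", "site"):
        for combat in (False, True):
            rep = evaluate(cohort, x, strategy, combat, seed)
            bacc[(strategy, combat)] = rep.metric_mean("balanced_accuracy")
    return {
        "bacc_age_sex": bacc[("age_sex", False)],
        "bacc_site": bacc[("site", False)],
        "bacc_age_sex_combat": bacc[("age_sex", True)],
        "bacc_site_combat": bacc[("site", True)],
        "gap_no_combat": bacc[("age_sex", False)] - bacc[("site", False)],
        "gap_combat": bacc[("age_sex", True)] - bacc[("site", True)],
    }


POWER_AMPLITUDES = (0.0, 0.5, 1.0, 1.5)


def power_curve(seed: int) -> dict[float, float]:
    """Mixed-site balanced accuracy as the diagnosis effect grows (units of noise SD)."""
    out = {}
    for amp in POWER_AMPLITUDES:
        sites, spec = power_scenario(amp)
        cohort, _, x = render_pipeline_features(sites, spec, seed)
        rep = evaluate(cohort, x, "age_sex", combat=False, seed=seed)
        out[amp] = rep.metric_mean("balanced_accuracy")
    return out


def combat_parameter_recovery(seed: int, n_features: int = 200) -> dict[str, float]:
    """Recover known site location/scale effects and check covariate preservation.

    2 sites x 100 subjects; ComBat fits the first `n_features` vertex columns
    (per-feature independence makes the subset exact).
    """
    sites, spec = recovery_scenario(n_per_site=100)
    mesh = make_icosphere(MESH_LEVEL)
    cohort, feats = simulate_cohort(sites, spec, mesh, seed, hemispheres=("lh",))
    fs = feats[("thickness", "lh")]
    y = fs.values[:, :n_features]
    cov = cohort[["age", "sex"]].to_numpy(float)
    site = cohort["site"].to_numpy()
    params = fit_combat(y, site, cov, HarmonizationConfig())
    harmonized = apply_combat(params, y, site, cov)

    gt = fs.ground_truth
    n = params.n_per_batch
    gamma_dev = gt["gamma"][:, :n_features] - (n / n.sum()) @ gt["gamma"][:, :n_features]
    gamma_corr = min(
        float(np.corrcoef(params.gamma_star[i] * np.sqrt(params.var_pooled),
                          gamma_dev[i])[0, 1])
        for i in range(2)
    )
    est_delta = np.sqrt(params.delta_star * params.var_pooled[None, :]) / spec.noise_sd
    rel = (est_delta - gt["delta"][:, None]) / gt["delta"][:, None]
    delta_rrmse = float(np.sqrt((rel ** 2).mean()))

    design = np.column_stack([np.ones(len(cohort)), cov])
    pre = np.linalg.lstsq(design, y, rcond=None)[0][1]
    post = np.linalg.lstsq(design, harmonized, rcond=None)[0][1]
    # "clearly nonzero" slopes: above the slope map's RMS, where per-feature
    # OLS sampling noise (~1% absolute) stays well inside the 10% band
    big = np.abs(gt["beta_age"][:n_features]) > spec.age_slope_amp
    slope_err = float(np.abs((post[big] - pre[big]) / pre[big]).max())
    return {
        "gamma_corr": gamma_corr,
        "delta_relative_rmse": delta_rrmse,
        "slope_max_rel_err": slope_err,
    }


def reference_batch_contract(seed: int, shift: float = 2.0) -> dict[str, float]:
    """Leave-site-out harmonization: training untouched, known test shift removed."""
    rng = np.random.default_rng(seed)
    n, p = 100, 150
    gamma = rng.standard_normal((2, p)) * 0.6
    train_y = np.vstack([rng.standard_normal((n, p)) + gamma[i] for i in range(2)])
    train_b = np.array(["A"] * n + ["B"] * n)
    test_y = rng.standard_normal((n, p)) + gamma.mean(axis=0) + shift
    test_b = np.array(["C"] * n)
    train_h, test_h, params = harmonize_leave_site_out(
        train_y, train_b, None, test_y, test_b, None)
    reference = apply_combat(params["stage1"], train_y, train_b, None)
    gap_before = np.abs(test_y.mean(axis=0) - train_h.mean(axis=0)).mean()
    gap_after = np.abs(test_h.mean(axis=0) - train_h.mean(axis=0)).mean()
    return {
        "train_rows_altered": int(not np.array_equal(train_h, reference)),
        "shift_reduction": float(1.0 - gap_after / gap_before),
        "n_test": n,
    }


def projection_uniformity(seed: int, n_points: int = 10_000, n_bands: int = 8) -> dict[str, float]:
    """Chi-square uniformity of row-band occupancy for both projections."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    grid_ea = ProjectionGrid(GRID_SIZE, GRID_SIZE, "equal_area")
    grid_ll = ProjectionGrid(GRID_SIZE, GRID_SIZE, "latlong")
    edges = np.linspace(0, GRID_SIZE - 1, n_bands + 1)
    rows_ea, _ = equal_area_coords(pts, grid_ea)
    rows_ll, _ = latlong_coords(pts, grid_ll)
    return {
        "p_equal_area": float(chisquare(np.histogram(rows_ea, bins=edges)[0]).pvalue),
        "p_latlong": float(chisquare(np.histogram(rows_ll, bins=edges)[0]).pvalue),
    }
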