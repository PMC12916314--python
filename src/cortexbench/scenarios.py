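"""Packaged study scenarios with fixed generator conditions.

Each builder returns (site profiles, effect spec) encoding one study
condition.  Magnitudes are scenario constants, chosen once (see
docs/methods.md for the reasoning), with noise SD 1 as the unit:

* ``null``      — site effects present but independent of diagnosis;
                  case ratio 0.5 everywhere; no diagnosis effect.
* ``confound``  — no diagnosis effect, but per-site case probability
                  increases with per-site additive effect magnitude, the
                  textbook site-diagnosis confound that inflates mixed-site
                  accuracy.
* ``power``     — genuine diagnosis effect on a contiguous 20% cap, with
                  configurable amplitude in units of the noise SD.
* ``recovery``  — two equal-age sites with distinct location/scale effects,
                  for harmonization parameter-recovery checks.
* ``sex``       — no site effects, a clear sex effect; the auxiliary
                  male-vs-female task used to compare the two projections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import EffectSpec, SiteProfile

THICKNESS_ONLY = ("thickness",)


def _pipeline_effect_spec(dx_effect_amp: float = 0.0, sex_effect_amp: float = 0.3) -> EffectSpec:
    return EffectSpec(
        modalities=THICKNESS_ONLY,
        baseline_amp={"thickness": 2.5},
        harmonic_degree_max=8,
        age_slope_amp=0.02,
        sex_effect_amp=sex_effect_amp,
        dx_effect_amp=dx_effect_amp,
        dx_effect_support=0.2,
        noise_sd=1.0,
    )


def null_scenario(n_sites: int = 10, n_per_site: int = 60) -> tuple[list[SiteProfile], EffectSpec]:
    """Heterogeneous demographics, moderate uniform site effects, no confound."""
    age_means = np.linspace(18.0, 60.0, n_sites)
    female_probs = np.linspace(0.35, 0.70, n_sites)
    sites = [
        SiteProfile(
            site_id=f"site{i:02d}", n_subjects=n_per_site,
            age_mean=float(age_means[i]), age_sd=8.0,
            female_prob=float(female_probs[i]), case_prob=0.5,
            site_loc_sd=0.5, site_scale_low=0.8, site_scale_high=1.25,
            balance_cases=True,
        )
        for i in range(n_sites)
    ]
    return sites, _pipeline_effect_spec(dx_effect_amp=0.0)


def confound_scenario(n_sites: int = 10, n_per_site: int = 60) -> tuple[list[SiteProfile], EffectSpec]:
    """No diagnosis effect; case probability rank-correlated with site-effect size.

    Demographic profiles stay heterogeneous across sites but are assigned in a
    fixed scrambled order so the diagnosis confound runs through the *site
    effect* only — a case-age confound would be a different phenomenon (one
    that covariate-preserving harmonization is not meant to remove).
    """
    scramble = np.array([3, 8, 1, 6, 0, 9, 2, 7, 4, 5]) % n_sites
    age_means = np.linspace(18.0, 60.0, n_sites)[scramble[:n_sites]]
    female_probs = np.linspace(0.35, 0.70, n_sites)[scramble[:n_sites]]
    case_probs = np.linspace(0.2, 0.8, n_sites)
    loc_sds = np.linspace(0.3, 1.5, n_sites)
    sites = [
        SiteProfile(
            site_id=f"site{i:02d}", n_subjects=n_per_site,
            age_mean=float(age_means[i]), age_sd=8.0,
            female_prob=float(female_probs[i]), case_prob=float(case_probs[i]),
            site_loc_sd=float(loc_sds[i]), site_scale_low=0.8, site_scale_high=1.25,
        )
        for i in range(n_sites)
    ]
    return sites, _pipeline_effect_spec(dx_effect_amp=0.0)


def power_scenario(
    dx_effect_amp: float, n_sites: int = 10, n_per_site: int = 60
) -> tuple[list[SiteProfile], EffectSpec]:
    """Diagnosis effect of `dx_effect_amp` (units of noise SD) on a 20% cap."""
    sites, _ = null_scenario(n_sites, n_per_site)
    return sites, _pipeline_effect_spec(dx_effect_amp=dx_effect_amp)


def recovery_scenario(n_per_site: int = 100) -> tuple[list[SiteProfile], EffectSpec]:
    """Two sites, equal age distributions, distinct location/scale site effects."""
    sites = [
        SiteProfile(site_id="siteA", n_subjects=n_per_site, age_mean=40.0, age_sd=12.0,
                    female_prob=0.5, case_prob=0.5, site_loc_sd=0.8,
                    site_scale_low=0.6, site_scale_high=0.9),
        SiteProfile(site_id="siteB", n_subjects=n_per_site, age_mean=40.0, age_sd=12.0,
                    female_prob=0.5, case_prob=0.5, site_loc_sd=0.8,
                    site_scale_low=1.1, site_scale_high=1.6),
    ]
    spec = EffectSpec(
        modalities=THICKNESS_ONLY,
        baseline_amp={"thickness": 2.5},
        harmonic_degree_max=8,
        age_slope_amp=0.2,
        sex_effect_amp=0.4,
        dx_effect_amp=0.0,
        dx_effect_support=0.2,
        noise_sd=1.0,
    )
    return sites, spec


def sex_scenario(n_per_site: int = 100) -> tuple[list[SiteProfile], EffectSpec]:
    """Single-cohort sex classification: two site-effect-free halves of one cohort."""
    sites = [
        SiteProfile(site_id=f"cohort_{h}", n_subjects=n_per_site, age_mean=35.0,
                    age_sd=10.0, female_prob=0.5, case_prob=0.0,
                    site_loc_sd=0.0, site_scale_low=1.0, site_scale_high=1.0)
        for h in ("a", "b")
    ]
    return sites, _pipeline_effect_spec(dx_effect_amp=0.0, sex_effect_amp=0.6)


def as_sex_classification(cohort: pd.DataFrame) -> pd.DataFrame:
    """Recode a cohort so that sex becomes the classification target.

    The returned table carries sex in the ``dx`` column (target) and zeros in
    ``sex`` so that normative residualization only removes the age trend and
    never the target itself.
    """
    out = cohort.copy()
    out["dx"] = out["sex"].astype(int)
    out["sex"] = 0
    return out
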