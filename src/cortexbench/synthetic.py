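"""Synthetic multi-site cohorts of vertex-wise cortical morphometry.

Real multi-site case-control samples mix three kinds of structure that matter
for classification benchmarks: smooth anatomical maps shared by everyone,
linear demographic (age, sex) dependencies, and site effects — an additive
per-site offset map plus a multiplicative residual-scale factor, exactly the
location/scale form ComBat models.  The generator draws all of these with
known ground truth so harmonization and classification behaviour can be
asserted, not eyeballed.

Generative model for subject j at site i, vertex v::

    y_ijv = mu_v + b_age_v (age_j - mean_age) + b_sex_v sex_j + b_dx_v dx_j
            + gamma_iv + delta_i * eps_ijv

with mu, b_age, b_sex and each gamma_i spatially smooth (random band-limited
spherical-harmonic fields), b_dx supported on a contiguous spherical cap, and
eps iid standard normal times ``noise_sd``.  The noise stream is keyed
independently of the diagnosis labels, so under ``dx_effect_amp = 0`` the
features are bit-identical under any relabelling of dx — the exact null.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

from .mesh import SphereMesh

MODALITIES = ("sulc", "curv", "thickness")
HEMISPHERES = ("lh", "rh")


def _rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic child stream keyed by (seed, tags); strings hashed stably."""
    ints = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            ints.append(int.from_bytes(hashlib.sha256(t.encode()).digest()[:4], "big"))
        else:
            ints.append(int(t) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


@dataclass(frozen=True)
class SiteProfile:
    """Demographic and site-effect configuration for one acquisition site."""

    site_id: str
    n_subjects: int
    age_mean: float = 40.0
    age_sd: float = 12.0
    female_prob: float = 0.5
    case_prob: float = 0.5
    site_loc_sd: float = 0.5        # spread of the additive site map gamma_i
    site_scale_low: float = 0.8     # bounds for the multiplicative delta_i
    site_scale_high: float = 1.25
    balance_cases: bool = False     # exact round(n * case_prob) cases per site

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"site {self.site_id!r}: n_subjects must be >= 1")
        for name in ("female_prob", "case_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"site {self.site_id!r}: {name} must be in [0, 1]")
        if self.site_loc_sd < 0:
            raise ValueError("site_loc_sd must be non-negative")
        if not (0 < self.site_scale_low <= self.site_scale_high):
            raise ValueError("site scale bounds must be positive with low <= high")
        if self.age_sd < 0:
            raise ValueError("age_sd must be non-negative")


@dataclass(frozen=True)
class EffectSpec:
    """Amplitudes and smoothness of the generative effects, in feature units."""

    modalities: tuple[str, ...] = MODALITIES
    baseline_amp: Mapping[str, float] = field(
        default_factory=lambda: {"sulc": 1.5, "curv": 0.5, "thickness": 2.5}
    )
    harmonic_degree_max: int = 8
    age_slope_amp: float = 0.02      # units per year (spread of the slope map)
    sex_effect_amp: float = 0.3
    dx_effect_amp: float = 0.0       # default near-zero diagnosis effect
    dx_effect_support: float = 0.2   # fraction of vertices inside the dx cap
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for m in self.modalities:
            if m not in self.baseline_amp:
                raise ValueError(f"baseline_amp missing modality {m!r}")
            if self.baseline_amp[m] < 0:
                raise ValueError("baseline amplitudes must be >= 0")
        for name in ("age_slope_amp", "sex_effect_amp", "dx_effect_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dx_effect_support <= 1.0:
            raise ValueError("dx_effect_support must be in [0, 1]")
        if self.harmonic_degree_max < 0:
            raise ValueError("harmonic_degree_max must be >= 0")


@dataclass
class VertexFeatureSet:
    """Subjects x vertices scalar maps for one (modality, hemisphere)."""

    values: np.ndarray
    modality: str
    hemisphere: str
    ground_truth: dict | None = None

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]


def _real_sph_harm_basis(mesh: SphereMesh, degree_max: int) -> np.ndarray:
    """Real spherical-harmonic design matrix, (n_vertices, (degree_max+1)^2)."""
    x, y, z = mesh.vertices.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))   # polar angle
    phi = np.arctan2(y, x)                     # azimuth
    cols = []
    for n in range(degree_max + 1):
        for m in range(-n, n + 1):
            ynm = sph_harm_y(n, abs(m), theta, phi)
            if m == 0:
                cols.append(ynm.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * (-1) ** m * ynm.real)
            else:
                cols.append(np.sqrt(2.0) * (-1) ** m * ynm.imag)
    return np.column_stack(cols)


def sample_smooth_map(
    mesh: SphereMesh,
    degree_max: int,
    amplitude: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Random band-limited scalar field on the mesh with spatial SD `amplitude`.

    A random linear combination of real spherical harmonics up to `degree_max`,
    rescaled so that its standard deviation across vertices equals `amplitude`.
    ``degree_max = 0`` yields a spatially constant map (value ~ amplitude * N(0,1)),
    ``amplitude = 0`` an all-zero map.
    """
    if degree_max < 0:
        raise ValueError("degree_max must be >= 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coeffs = rng.standard_normal((degree_max + 1) ** 2)
    if amplitude == 0.0:
        return np.zeros(mesh.n_vertices)
    if degree_max == 0:
        return np.full(mesh.n_vertices, amplitude * coeffs[0])
    basis = _real_sph_harm_basis(mesh, degree_max)
    m = basis @ coeffs
    sd = m.std()
    if sd < 1e-12:  # vanishing draw; fall back to the constant term
        return np.full(mesh.n_vertices, amplitude * coeffs[0])
    return m * (amplitude / sd)


def _spherical_cap_mask(mesh: SphereMesh, axis: np.ndarray, support: float) -> np.ndarray:
    """Boolean mask of the contiguous cap around `axis` covering `support` of the sphere.

    A cap of colatitude t has area fraction (1 - cos t)/2, so the threshold on
    the dot product with the axis is 1 - 2*support.
    """
    if support <= 0.0:
        return np.zeros(mesh.n_vertices, dtype=bool)
    axis = axis / np.linalg.norm(axis)
    return mesh.vertices @ axis >= 1.0 - 2.0 * support


def simulate_cohort(
    sites: Sequence[SiteProfile],
    spec: EffectSpec,
    mesh: SphereMesh,
    seed: int,
    hemispheres: Sequence[str] = HEMISPHERES,
    dx_override: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], VertexFeatureSet]]:
    """Draw a multi-site cohort and its vertex-wise features.

    Returns the cohort table (columns subject_id, site, age, sex, dx; one row
    per subject, site blocks in the given site order) and a dict mapping
    (modality, hemisphere) to a :class:`VertexFeatureSet` whose ``ground_truth``
    records every drawn component, enabling exact reconstruction.

    ``dx_override`` replaces the drawn diagnosis labels *after* all random
    draws, leaving every random stream untouched — the counterfactual hook for
    null-purity checks.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError("site_id labels must be unique")
    total = sum(s.n_subjects for s in sites)
    if total < 10:
        raise ValueError("need at least 10 subjects in total")

    # --- demographics, one stream per site ---------------------------------
    rows = []
    for i, site in enumerate(sites):
        rng = _rng(seed, "demo", i)
        ages = np.maximum(rng.normal(site.age_mean, site.age_sd, site.n_subjects), 10.0)
        sex = (rng.random(site.n_subjects) < site.female_prob).astype(np.int64)
        if site.balance_cases:
            # exact within-site case ratio: no realized site-diagnosis association
            n_case = int(round(site.n_subjects * site.case_prob))
            dx = np.zeros(site.n_subjects, dtype=np.int64)
            dx[rng.permutation(site.n_subjects)[:n_case]] = 1
        else:
            dx = (rng.random(site.n_subjects) < site.case_prob).astype(np.int64)
        for j in range(site.n_subjects):
            rows.append((f"{site.site_id}_{j:04d}", site.site_id, float(ages[j]),
                         int(sex[j]), int(dx[j])))
    cohort = pd.DataFrame(rows, columns=["subject_id", "site", "age", "sex", "dx"])
    if dx_override is not None:
        dx_override = np.asarray(dx_override, dtype=np.int64)
        if dx_override.shape != (total,):
            raise ValueError("dx_override must have one label per subject")
        cohort["dx"] = dx_override

    age_center = float(cohort["age"].mean())
    site_idx = np.asarray([ids.index(s) for s in cohort["site"]])
    age_c = cohort["age"].to_numpy() - age_center
    sex_v = cohort["sex"].to_numpy().astype(np.float64)
    dx_v = cohort["dx"].to_numpy().astype(np.float64)

    # --- per (modality, hemisphere) features -------------------------------
    features: dict[tuple[str, str], VertexFeatureSet] = {}
    deg = spec.harmonic_degree_max
    for mod in spec.modalities:
        for hemi in hemispheres:
            erng = _rng(seed, "effects", mod, hemi)
            mu = sample_smooth_map(mesh, deg, spec.baseline_amp[mod], erng)
            b_age = sample_smooth_map(mesh, deg, spec.age_slope_amp, erng)
            b_sex = sample_smooth_map(mesh, deg, spec.sex_effect_amp, erng)
            cap_axis = erng.standard_normal(3)
            cap = _spherical_cap_mask(mesh, cap_axis, spec.dx_effect_support)
            b_dx = np.where(cap, spec.dx_effect_amp, 0.0)

            gamma = np.empty((len(sites), mesh.n_vertices))
            delta = np.empty(len(sites))
            for i, site in enumerate(sites):
                srng = _rng(seed, "site", mod, hemi, i)
                gamma[i] = sample_smooth_map(mesh, deg, site.site_loc_sd, srng)
                delta[i] = srng.uniform(site.site_scale_low, site.site_scale_high)

            nrng = _rng(seed, "noise", mod, hemi)
            eps = nrng.standard_normal((total, mesh.n_vertices)) * spec.noise_sd

            y = (mu[None, :]
                 + np.outer(age_c, b_age)
                 + np.outer(sex_v, b_sex)
                 + np.outer(dx_v, b_dx)
                 + gamma[site_idx]
                 + delta[site_idx, None] * eps)
            features[(mod, hemi)] = VertexFeatureSet(
                values=y,
                modality=mod,
                hemisphere=hemi,
                ground_truth={
                    "mu": mu, "beta_age": b_age, "beta_sex": b_sex, "beta_dx": b_dx,
                    "dx_cap_mask": cap, "gamma": gamma, "delta": delta, "eps": eps,
                    "age_center": age_center, "site_order": list(ids),
                },
            )
    return cohort, features


# --- demographics CSV interchange (sex: M/F, dx: HC/MDD) -------------------

def write_demographics_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["sex"] = np.where(out["sex"].astype(int) == 1, "F", "M")
    out["dx"] = np.where(out["dx"].astype(int) == 1, "MDD", "HC")
    out.to_csv(path, index=False)


def read_demographics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["subject_id", "site", "age", "sex", "dx"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"demographics CSV missing columns: {missing}")
    bad_sex = set(df["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex column must be M/F, found {sorted(bad_sex)}")
    bad_dx = set(df["dx"].unique()) - {"HC", "MDD"}
    if bad_dx:
        raise ValueError(f"dx column must be HC/MDD, found {sorted(bad_dx)}")
    df = df[required].copy()
    df["sex"] = (df["sex"] == "F").astype(np.int64)
    df["dx"] = (df["dx"] == "MDD").astype(np.int64)
    return df
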