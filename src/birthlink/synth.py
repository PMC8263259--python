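"""Synthetic facility-census / household-survey world generator.

Emulates the structure of a DHS-style household survey linked to an SPA-style
facility census: ~540 birth-service facilities with six-domain dichotomous
readiness indicators, ~850 household clusters with confidentiality-displaced
GPS centroids and design weights, ~6,000 most-recent births with covariates
and six binary newborn-care interventions, and a friction raster for
travel-time work. Every configured quantity has a known ground truth, so the
downstream linking, co-coverage and regression stages can be tested for
recovery without restricted microdata.

The outcome model is marginal and log-linear: the binary "appropriate care"
indicator is drawn with probability

    p = baseline * prod(RR_k ** x_k)

over the configured covariate effects, then the six intervention booleans are
filled consistently with that indicator (5 or 6 true when appropriate, 0-4
otherwise). This construction makes the modelled outcome follow the
configured risk ratios exactly, which is what the parameter-recovery tests
rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cocoverage import INTERVENTIONS
from .geolink import (
    FrictionSurface,
    attach_scores_and_terciles,
    buffer_link,
    linkage_frame,
)
from .readiness import DOMAINS, ValidationError, score_table, tercile_cut

# DHS confidentiality displacement rule
URBAN_MAX_KM = 2.0
RURAL_MAX_KM = 5.0
RURAL_FAR_MAX_KM = 10.0
RURAL_FAR_PROB = 0.01

_M_PER_DEG = 6371.0e3 * np.pi / 180.0

# Covariate margins emulating the survey's background-characteristics table
WEALTH_PROBS = (0.259, 0.233, 0.196, 0.168, 0.144)
AGE_GROUPS = ("<20", "20-34", "35+")
AGE_PROBS = (0.200, 0.673, 0.127)
P_EDUCATION = 0.196
P_PARITY_FIRST = 0.26
P_HOME_BIRTH = 0.069


@dataclass
class EffectConfig:
    """Ground-truth risk ratios for the appropriate-care outcome model.

    Defaults follow the adjusted distance-model estimates the generator is
    calibrated to: a strong protective-of-facility-birth effect (home birth
    RR 0.32), modest service-environment tercile effects (1.17 / 1.24) and a
    small education effect (1.08); all other covariates are null by default.
    ``baseline_prevalence`` is the outcome probability in the joint reference
    category (facility birth, lowest tercile, lowest density, poorest
    quintile, age <20, no secondary education).
    """

    baseline_prevalence: float = 0.60
    rr_home_birth: float = 0.32
    rr_tercile_mid: float = 1.17
    rr_tercile_high: float = 1.24
    rr_no_facility: float = 1.0
    rr_education: float = 1.08
    rr_density_mid: float = 1.0
    rr_density_high: float = 1.0
    rr_wealth: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    rr_age: tuple[float, float] = (1.0, 1.0)
    max_probability: float = 0.995

    def validate(self) -> None:
        ratios = [
            self.rr_home_birth, self.rr_tercile_mid, self.rr_tercile_high,
            self.rr_no_facility, self.rr_education, self.rr_density_mid,
            self.rr_density_high, *self.rr_wealth, *self.rr_age,
        ]
        if any(r <= 0 for r in ratios):
            raise ValidationError("all risk ratios must be positive")
        if not 0 < self.baseline_prevalence <= 1:
            raise ValidationError("baseline prevalence must lie in (0, 1]")

    def as_dict(self) -> dict:
        return {
            "baseline_prevalence": self.baseline_prevalence,
            "rr_home_birth": self.rr_home_birth,
            "rr_tercile_mid": self.rr_tercile_mid,
            "rr_tercile_high": self.rr_tercile_high,
            "rr_no_facility": self.rr_no_facility,
            "rr_education": self.rr_education,
            "rr_density_mid": self.rr_density_mid,
            "rr_density_high": self.rr_density_high,
            "rr_wealth": list(self.rr_wealth),
            "rr_age": list(self.rr_age),
        }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world; a pure function of (config, seed)."""

    n_clusters: int = 850
    n_facilities: int = 540
    urban_fraction: float = 0.125
    n_births: int = 6000
    # (lat_min, lat_max, lon_min, lon_max), decimal degrees WGS84; a
    # Malawi-sized rectangle (~278 x 215 km) by default
    region_bbox: tuple[float, float, float, float] = (-15.5, -13.0, 33.5, 35.5)
    friction_resolution: float = 1000.0  # metres per cell
    domain_sizes: tuple[int, ...] = (6, 8, 7, 12, 14, 9)
    effect_config: EffectConfig = field(default_factory=EffectConfig)
    seed: int = 0
    # facility generation
    birth_service_fraction: float = 1.0
    readiness_beta: tuple[float, float] = (12.0, 6.0)
    domain_concentration: float = 35.0
    # cluster generation
    households_urban: int = 30
    households_rural: int = 33
    cluster_weight_sigma: float = 0.4
    # friction surface
    friction_mean_min_per_m: float = 0.0018
    friction_log_sd: float = 0.5
    barrier_fraction: float = 0.02
    friction_constant: float | None = None
    # co-coverage shape given the appropriate-care indicator
    p_six_given_appropriate: float = 0.45
    count_probs_not_appropriate: tuple[float, ...] = (0.08, 0.10, 0.18, 0.28, 0.36)

    def validate(self) -> None:
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValidationError("urban_fraction must lie in [0, 1]")
        for name in ("n_clusters", "n_facilities", "n_births"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if len(self.domain_sizes) != 6 or any(
            not 4 <= s <= 15 for s in self.domain_sizes
        ):
            raise ValidationError("domain_sizes must be six counts, each in [4, 15]")
        lat_min, lat_max, lon_min, lon_max = self.region_bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ValidationError("degenerate region bbox")
        if self.friction_resolution <= 0:
            raise ValidationError("friction_resolution must be positive")
        self.effect_config.validate()

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def default_manifest(cfg: GeneratorConfig) -> dict[str, list[str]]:
    """Domain -> indicator-column names for the generated facility table."""
    return {
        dom: [f"{dom}_{i + 1:02d}" for i in range(size)]
        for dom, size in zip(DOMAINS, cfg.domain_sizes)
    }


def generate_facilities(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Facility census: uniform locations, Beta-mixed dichotomous indicators.

    Each facility draws a latent mean readiness from ``Beta(*readiness_beta)``;
    per-domain indicator probabilities are drawn from a Beta centred on that
    latent mean (concentration ``domain_concentration``), and indicators are
    Bernoulli. With the defaults, overall readiness scores span roughly
    25-99.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lat_min, lat_max, lon_min, lon_max = cfg.region_bbox
    n = cfg.n_facilities
    df = pd.DataFrame(
        {
            "facility_id": [f"F{i:04d}" for i in range(n)],
            "lat": rng.uniform(lat_min, lat_max, n),
            "lon": rng.uniform(lon_min, lon_max, n),
            "provides_birth_services": rng.random(n) < cfg.birth_service_fraction,
        }
    )
    a, b = cfg.readiness_beta
    m = rng.beta(a, b, n)
    kappa = cfg.domain_concentration
    for dom, size in zip(DOMAINS, cfg.domain_sizes):
        p_dom = rng.beta(np.maximum(kappa * m, 1e-12), np.maximum(kappa * (1 - m), 1e-12))
        for i in range(size):
            df[f"{dom}_{i + 1:02d}"] = (rng.random(n) < p_dom).astype(int)
    return df


def displace_cluster(
    true_lat: float,
    true_lon: float,
    urban: bool,
    rng: np.random.Generator,
    bbox: tuple[float, float, float, float] | None = None,
) -> tuple[float, float]:
    """DHS-style confidentiality displacement of one cluster centroid.

    Uniform random bearing; displacement distance uniform on [0, 2 km] for
    urban clusters, and for rural clusters uniform on [0, 5 km] with
    probability 0.99, else (the 1% long tail, displaced beyond the usual cap)
    uniform on (5, 10] km. The displaced point is clipped to the bbox (a
    proxy for the rule that points stay within administrative boundaries).
    """
    bearing = rng.uniform(0.0, 2.0 * np.pi)
    if urban:
        dist_km = rng.uniform(0.0, URBAN_MAX_KM)
    elif rng.random() < RURAL_FAR_PROB:
        dist_km = rng.uniform(RURAL_MAX_KM, RURAL_FAR_MAX_KM)
    else:
        dist_km = rng.uniform(0.0, RURAL_MAX_KM)
    dlat = dist_km * 1000.0 * np.cos(bearing) / _M_PER_DEG
    dlon = dist_km * 1000.0 * np.sin(bearing) / (
        _M_PER_DEG * np.cos(np.radians(true_lat))
    )
    lat, lon = true_lat + dlat, true_lon + dlon
    if bbox is not None:
        lat_min, lat_max, lon_min, lon_max = bbox
        lat = float(np.clip(lat, lat_min, lat_max))
        lon = float(np.clip(lon, lon_min, lon_max))
    return float(lat), float(lon)


def generate_clusters(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Household clusters: true + displaced centroids, weights, density."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    lat_min, lat_max, lon_min, lon_max = cfg.region_bbox
    n = cfg.n_clusters
    n_urban = int(round(cfg.urban_fraction * n))
    urban = np.zeros(n, dtype=bool)
    urban[rng.choice(n, n_urban, replace=False)] = True
    true_lat = rng.uniform(lat_min, lat_max, n)
    true_lon = rng.uniform(lon_min, lon_max, n)
    displaced = [
        displace_cluster(la, lo, u, rng, cfg.region_bbox)
        for la, lo, u in zip(true_lat, true_lon, urban)
    ]
    w = rng.lognormal(0.0, cfg.cluster_weight_sigma, n)
    w /= w.mean()
    # persons/km^2, urban areas an order of magnitude denser
    density = np.where(
        urban,
        rng.lognormal(np.log(1500.0), 0.5, n),
        rng.lognormal(np.log(150.0), 0.7, n),
    )
    return pd.DataFrame(
        {
            "cluster_id": [f"C{i:04d}" for i in range(n)],
            "urban": urban,
            "true_lat": true_lat,
            "true_lon": true_lon,
            "lat": [p[0] for p in displaced],
            "lon": [p[1] for p in displaced],
            "design_weight": w,
            "population_density": density,
        }
    )


def generate_friction_surface(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> FrictionSurface:
    """Smoothed log-normal friction field over the bbox, in minutes per metre.

    ``friction_constant`` forces a flat surface; ``barrier_fraction`` marks
    the highest-scoring cells of an independent smooth field as impassable
    (``inf``), mimicking water bodies.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    lat_min, lat_max, lon_min, lon_max = cfg.region_bbox
    mid_lat = 0.5 * (lat_min + lat_max)
    height_m = (lat_max - lat_min) * _M_PER_DEG
    width_m = (lon_max - lon_min) * _M_PER_DEG * np.cos(np.radians(mid_lat))
    nrows = max(1, int(np.ceil(height_m / cfg.friction_resolution)))
    ncols = max(1, int(np.ceil(width_m / cfg.friction_resolution)))
    if cfg.friction_constant is not None:
        values = np.full((nrows, ncols), float(cfg.friction_constant))
    else:
        z = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=3.0, mode="nearest")
        sd = z.std() or 1.0
        z = z / sd * cfg.friction_log_sd
        values = cfg.friction_mean_min_per_m * np.exp(z - 0.5 * cfg.friction_log_sd**2)
        if cfg.barrier_fraction > 0:
            zb = gaussian_filter(
                rng.standard_normal((nrows, ncols)), sigma=3.0, mode="nearest"
            )
            cut = np.quantile(zb, 1.0 - cfg.barrier_fraction)
            values[zb > cut] = np.inf
    return FrictionSurface(lat0=lat_min, lon0=lon_min,
                           cell_size_m=cfg.friction_resolution, values=values)


def _fill_interventions(
    appropriate: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-birth co-coverage counts consistent with the binary outcome,
    then pick which of the six interventions were received, uniformly."""
    n = appropriate.size
    counts = np.empty(n, dtype=int)
    app = appropriate.astype(bool)
    counts[app] = np.where(rng.random(app.sum()) < cfg.p_six_given_appropriate, 6, 5)
    probs = np.asarray(cfg.count_probs_not_appropriate, dtype=float)
    probs = probs / probs.sum()
    counts[~app] = rng.choice(5, size=(~app).sum(), p=probs)
    # uniformly choose `counts[i]` of the six interventions: rank random keys
    ranks = rng.random((n, 6)).argsort(axis=1).argsort(axis=1)
    received = ranks < counts[:, None]
    return counts, received


def generate_births(
    cfg: GeneratorConfig,
    clusters: pd.DataFrame,
    linkage: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Most-recent births with covariates, outcome and intervention booleans.

    ``linkage`` is the per-cluster linkage table (one linking method) whose
    ``score_tercile`` drives the service-environment effect; the generated
    outcome therefore follows the configured risk ratios *with respect to that
    linkage*, which is also what the modelling stage sees. Returns the births
    table and a ground-truth sidecar dict.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    eff = cfg.effect_config

    cl = clusters.set_index("cluster_id")
    hh = np.where(cl["urban"].to_numpy(bool), cfg.households_urban, cfg.households_rural)
    p_birth = min(1.0, cfg.n_births / hh.sum())
    births_per_cluster = rng.binomial(hh, p_birth)

    cluster_ids = np.repeat(cl.index.to_numpy(), births_per_cluster)
    n = cluster_ids.size
    df = pd.DataFrame(
        {
            "birth_id": [f"B{i:05d}" for i in range(n)],
            "cluster_id": cluster_ids,
        }
    )
    df["urban"] = cl["urban"].reindex(cluster_ids).to_numpy()
    df["wealth_quintile"] = rng.choice([1, 2, 3, 4, 5], size=n, p=WEALTH_PROBS)
    df["maternal_age_group"] = rng.choice(AGE_GROUPS, size=n, p=AGE_PROBS)
    df["education_secondary_plus"] = rng.random(n) < P_EDUCATION
    df["parity_first"] = rng.random(n) < P_PARITY_FIRST
    df["home_birth"] = rng.random(n) < P_HOME_BIRTH

    # cluster-level exposures
    dens_terc = pd.Series(
        tercile_cut(cl["population_density"], cl["design_weight"]).astype(str),
        index=cl.index,
    )
    df["population_density_tercile"] = dens_terc.reindex(cluster_ids).to_numpy()
    lk = linkage.set_index("cluster_id")
    terc = lk["score_tercile"].fillna("no_facility").reindex(cluster_ids)
    df["score_tercile"] = terc.to_numpy()
    df["count_category"] = lk["count_category"].reindex(cluster_ids).to_numpy()

    # marginal log-link outcome model
    lp = np.full(n, np.log(eff.baseline_prevalence))
    lp += np.log(eff.rr_home_birth) * df["home_birth"].to_numpy()
    lp += np.log(eff.rr_tercile_mid) * (df["score_tercile"] == "middle").to_numpy()
    lp += np.log(eff.rr_tercile_high) * (df["score_tercile"] == "high").to_numpy()
    lp += np.log(eff.rr_no_facility) * (df["score_tercile"] == "no_facility").to_numpy()
    lp += np.log(eff.rr_education) * df["education_secondary_plus"].to_numpy()
    lp += np.log(eff.rr_density_mid) * (
        df["population_density_tercile"] == "middle"
    ).to_numpy()
    lp += np.log(eff.rr_density_high) * (
        df["population_density_tercile"] == "high"
    ).to_numpy()
    wq = df["wealth_quintile"].to_numpy()
    for q, rr in zip((2, 3, 4, 5), eff.rr_wealth):
        lp += np.log(rr) * (wq == q)
    ag = df["maternal_age_group"].to_numpy()
    for a, rr in zip(("20-34", "35+"), eff.rr_age):
        lp += np.log(rr) * (ag == a)

    p = np.exp(lp)
    truncated = p > eff.max_probability
    if truncated.any():
        warnings.warn(
            f"{truncated.mean():.2%} of birth probabilities truncated to "
            f"{eff.max_probability}",
            stacklevel=2,
        )
    p = np.minimum(p, eff.max_probability)
    if not np.all((p > 0) & (p <= 1)):
        raise ValidationError("invalid outcome probability after truncation")
    appropriate = rng.random(n) < p
    counts, received = _fill_interventions(appropriate, cfg, rng)
    for j, name in enumerate(INTERVENTIONS):
        df[name] = received[:, j]
    df["co_coverage"] = counts
    df["appropriate_care"] = appropriate.astype(int)

    w = cl["design_weight"].reindex(cluster_ids).to_numpy() * rng.lognormal(0.0, 0.15, n)
    df["individual_weight"] = w / w.mean()

    truth = {
        "seed": int(cfg.seed),
        "effects": eff.as_dict(),
        "n_births": int(n),
        "truncated_fraction": float(truncated.mean()),
    }
    return df, truth


def generate_world(cfg: GeneratorConfig) -> dict:
    """Generate the full linked synthetic study: facilities (scored), clusters,
    buffer linkage with terciles, and births.

    Returns a dict with keys ``facilities``, ``manifest``, ``scores``,
    ``clusters``, ``linkage`` (per-cluster frame, 5/10 km buffer method),
    ``births``, ``truth``.
    """
    cfg.validate()
    facilities = generate_facilities(cfg)
    manifest = default_manifest(cfg)
    scores = score_table(facilities, manifest)
    clusters = generate_clusters(cfg)
    birth_fac = facilities[facilities["provides_birth_services"]]
    links = buffer_link(clusters, birth_fac)
    score_s = scores.set_index("facility_id")["readiness_score"]
    weight_s = clusters.set_index("cluster_id")["design_weight"]
    attach_scores_and_terciles(links, score_s, weight_s)
    lk = linkage_frame(links)
    births, truth = generate_births(cfg, clusters, lk)
    return {
        "facilities": facilities,
        "manifest": manifest,
        "scores": scores,
        "clusters": clusters,
        "linkage": lk,
        "births": births,
        "truth": truth,
    }
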