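"""Synthetic world generator: displacement, calibration, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from birthlink.cocoverage import INTERVENTIONS
from birthlink.geolink import haversine_km
from birthlink.readiness import ValidationError
from birthlink.synth import (
    EffectConfig,
    GeneratorConfig,
    default_manifest,
    displace_cluster,
    generate_births,
    generate_clusters,
    generate_facilities,
    generate_friction_surface,
    generate_world,
)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kw",
    [
        {"urban_fraction": 1.2},
        {"n_clusters": 0},
        {"domain_sizes": (4, 4, 4, 4, 4)},          # five domains
        {"domain_sizes": (3, 4, 4, 4, 4, 4)},       # below the 4-15 range
        {"domain_sizes": (16, 4, 4, 4, 4, 4)},      # above it
        {"region_bbox": (-14.0, -14.0, 34.0, 35.0)},  # degenerate
        {"friction_resolution": 0.0},
        {"effect_config": EffectConfig(rr_home_birth=-1.0)},
    ],
)
def test_invalid_configs_rejected(kw):
    with pytest.raises(ValidationError):
        GeneratorConfig(**kw).validate()


# ---------------------------------------------------------------------------
# facilities
# ---------------------------------------------------------------------------

def test_facilities_dichotomous_indicators_and_count():
    cfg = GeneratorConfig(n_facilities=10, seed=1)
    fac = generate_facilities(cfg)
    assert len(fac) == 10
    manifest = default_manifest(cfg)
    for cols in manifest.values():
        assert fac[cols].isin([0, 1]).all().all()


def test_facilities_all_yes_beta_scores_100():
    from birthlink.readiness import score_table

    cfg = GeneratorConfig(
        n_facilities=20, seed=2,
        domain_sizes=(4, 4, 4, 4, 4, 4),
        readiness_beta=(1e8, 1e-8),  # all Beta mass at 1
    )
    fac = generate_facilities(cfg)
    scores = score_table(fac, default_manifest(cfg))
    assert (scores["readiness_score"] == 100.0).all()


def test_facilities_deterministic_under_seed():
    cfg = GeneratorConfig(n_facilities=25, seed=5)
    a = generate_facilities(cfg)
    b = generate_facilities(cfg)
    pd.testing.assert_frame_equal(a, b)


def test_facility_scores_span_plausible_readiness_range():
    cfg = GeneratorConfig(seed=3)
    from birthlink.readiness import score_table

    scores = score_table(generate_facilities(cfg), default_manifest(cfg))
    s = scores["readiness_score"]
    assert 15.0 < s.min() < 40.0
    assert 90.0 < s.max() <= 100.0
    assert 60.0 < s.mean() < 75.0


# ---------------------------------------------------------------------------
# displacement
# ---------------------------------------------------------------------------

def test_urban_displacement_never_exceeds_2km(rng):
    origin = (-14.0, 34.5)
    for _ in range(1000):
        moved = displace_cluster(*origin, True, rng)
        assert haversine_km(origin, moved) <= 2.0 + 1e-6


def test_rural_displacement_bounds_and_far_fraction(rng):
    origin = (-14.0, 34.5)
    d = np.array(
        [haversine_km(origin, displace_cluster(*origin, False, rng))
         for _ in range(10_000)]
    )
    assert d.max() <= 10.0 + 1e-6
    assert (d <= 5.0 + 1e-6).mean() >= 0.98


def test_displacement_bearing_uniform(rng):
    """Bearings over repeated draws are consistent with uniform(0, 2*pi)."""
    origin = (-14.0, 34.5)
    angles = []
    for _ in range(10_000):
        lat, lon = displace_cluster(*origin, True, rng)
        dy = lat - origin[0]
        dx = (lon - origin[1]) * np.cos(np.radians(origin[0]))
        angles.append(np.arctan2(dy, dx) % (2 * np.pi))
    counts, _ = np.histogram(angles, bins=36, range=(0, 2 * np.pi))
    p = stats.chisquare(counts).pvalue
    assert p > 0.01


def test_displacement_clipped_to_bbox(rng):
    bbox = (-14.0, -13.9, 34.0, 34.1)
    for _ in range(200):
        lat, lon = displace_cluster(-14.0, 34.0, False, rng, bbox)
        assert bbox[0] <= lat <= bbox[1]
        assert bbox[2] <= lon <= bbox[3]


# ---------------------------------------------------------------------------
# clusters, friction
# ---------------------------------------------------------------------------

def test_clusters_structure(small_cfg):
    cl = generate_clusters(small_cfg)
    assert len(cl) == small_cfg.n_clusters
    assert cl["urban"].sum() == round(small_cfg.urban_fraction * small_cfg.n_clusters)
    assert (cl["design_weight"] > 0).all()
    assert cl["design_weight"].mean() == pytest.approx(1.0)


def test_friction_constant_surface():
    cfg = GeneratorConfig(friction_constant=0.02, friction_resolution=5000.0)
    s = generate_friction_surface(cfg)
    assert (s.values == 0.02).all()


def test_friction_no_barriers_all_finite():
    cfg = GeneratorConfig(barrier_fraction=0.0, friction_resolution=5000.0, seed=4)
    s = generate_friction_surface(cfg)
    assert np.isfinite(s.values).all()
    assert (s.values > 0).all()


def test_friction_deterministic():
    cfg = GeneratorConfig(friction_resolution=5000.0, seed=9)
    a = generate_friction_surface(cfg)
    b = generate_friction_surface(cfg)
    assert np.array_equal(a.values, b.values)


# ---------------------------------------------------------------------------
# births and calibration
# ---------------------------------------------------------------------------

def test_births_deterministic_and_consistent(small_world, small_cfg):
    births = small_world["births"]
    again = generate_world(small_cfg)["births"]
    pd.testing.assert_frame_equal(births, again)
    # intervention booleans consistent with the binary outcome
    counts = births[list(INTERVENTIONS)].sum(axis=1)
    assert (counts == births["co_coverage"]).all()
    assert ((counts >= 5) == births["appropriate_care"].astype(bool)).all()


def test_null_model_prevalence_matches_baseline():
    cfg = GeneratorConfig(
        n_clusters=300, n_facilities=60, n_births=4000, seed=21,
        effect_config=EffectConfig(
            baseline_prevalence=0.60, rr_home_birth=1.0, rr_tercile_mid=1.0,
            rr_tercile_high=1.0, rr_education=1.0,
        ),
    )
    births = generate_world(cfg)["births"]
    prev = np.average(births["appropriate_care"], weights=births["individual_weight"])
    assert prev == pytest.approx(0.60, abs=0.025)


def test_home_birth_risk_ratio_recovered_by_tabulation():
    """Crude RR home vs facility converges to the configured 0.32."""
    logs = []
    for seed in range(40, 48):
        births = generate_world(
            GeneratorConfig(n_clusters=400, n_births=6000, seed=seed)
        )["births"]
        hb = births["home_birth"].to_numpy(bool)
        y = births["appropriate_care"].to_numpy()
        logs.append(np.log(y[hb].mean() / y[~hb].mean()))
    assert np.exp(np.mean(logs)) == pytest.approx(0.32, abs=0.03)


def test_probability_truncation_flagged():
    cfg = GeneratorConfig(
        n_clusters=50, n_facilities=30, n_births=300, seed=6,
        effect_config=EffectConfig(baseline_prevalence=0.9, rr_tercile_high=1.3),
    )
    clusters = generate_clusters(cfg)
    world = generate_world(cfg)
    assert world["truth"]["truncated_fraction"] > 0


def test_truth_sidecar_records_effects(small_world, small_cfg):
    truth = small_world["truth"]
    assert truth["seed"] == small_cfg.seed
    assert truth["effects"]["rr_home_birth"] == pytest.approx(0.32)
    assert truth["effects"]["rr_tercile_high"] == pytest.approx(1.24)
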