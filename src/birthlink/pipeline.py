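"""End-to-end orchestration: synth -> score -> link -> co-coverage -> weights
-> models -> report.

A run is a pure function of (RunConfig, seed): it emits scored facilities,
per-cluster linkage summaries for each linking method, a background-
characteristics table, a linkage/score summary table, the co-coverage
distribution, crude and adjusted model tables, and a JSON manifest recording
the configuration, seed, package versions and warnings. Rerunning with the
same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .cocoverage import coverage_table
from .geolink import (
    SyntheticWalkRouter,
    attach_scores_and_terciles,
    buffer_link,
    link_within_time,
    linkage_frame,
    pairwise_distance_km,
    travel_time_matrix,
    walking_time_chain,
)
from .models import ModelSpec, assemble_model_frame, crude_ratios, fit_model
from .readiness import score_table, weighted_quantile
from .survey_weights import split_weights
from .synth import (
    GeneratorConfig,
    default_manifest,
    generate_births,
    generate_clusters,
    generate_facilities,
    generate_friction_surface,
)

log = logging.getLogger("birthlink")

METHODS = ("buffer_5_10km", "fastest_2h", "walk_2h")


@dataclass
class RunConfig:
    """Configuration of a full synthetic run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    urban_radius_km: float = 5.0
    rural_radius_km: float = 10.0
    cutoff_minutes: float = 120.0
    methods: tuple[str, ...] = METHODS
    walk_speed_kmh: float = 5.0
    walk_detour_factor: float = 1.4
    walk_primary_failure_rate: float = 0.10
    weight_alpha: float = 0.5
    write_pairs: bool = True
    write_geojson: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if isinstance(gen, dict):
            eff = gen.pop("effect_config", None)
            if isinstance(eff, dict):
                from .synth import EffectConfig

                gen["effect_config"] = EffectConfig(**eff)
            for k in ("region_bbox", "domain_sizes"):
                if k in gen:
                    gen[k] = tuple(gen[k])
            gen = GeneratorConfig(**gen)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(generator=gen, **d)


def _wmed_iqr(values: np.ndarray, weights: np.ndarray) -> str:
    if len(values) == 0:
        return ""
    q = weighted_quantile(np.asarray(values, float), np.asarray(weights, float),
                          np.array([0.25, 0.5, 0.75]))
    return f"{q[1]:.1f} ({q[0]:.1f},{q[2]:.1f})"


def _strata(births: pd.DataFrame):
    home = births["home_birth"].to_numpy(bool)
    return [("all", np.ones(len(births), bool)), ("facility", ~home), ("home", home)]


def background_table(births: pd.DataFrame) -> pd.DataFrame:
    """Background characteristics (counts and weighted %) by place of birth."""
    w = births["individual_weight"].to_numpy(float)
    rows = []

    def add(characteristic, level, mask):
        rec = {"characteristic": characteristic, "level": level}
        for name, smask in _strata(births):
            m = mask & smask
            denom = w[smask].sum()
            rec[f"n_{name}"] = int(m.sum())
            rec[f"pct_{name}"] = 100.0 * w[m].sum() / denom if denom else np.nan
        rows.append(rec)

    add("residence", "urban", births["urban"].to_numpy(bool))
    add("residence", "rural", ~births["urban"].to_numpy(bool))
    for lv in ("low", "middle", "high"):
        add("population_density", lv,
            (births["population_density_tercile"] == lv).to_numpy())
    for q in (1, 2, 3, 4, 5):
        add("wealth_quintile", str(q), (births["wealth_quintile"] == q).to_numpy())
    add("parity", "first_birth", births["parity_first"].to_numpy(bool))
    add("parity", "second_or_higher", ~births["parity_first"].to_numpy(bool))
    for lv in ("<20", "20-34", "35+"):
        add("maternal_age", lv, (births["maternal_age_group"] == lv).to_numpy())
    add("education", "secondary_plus",
        births["education_secondary_plus"].to_numpy(bool))
    add("education", "none_or_primary",
        ~births["education_secondary_plus"].to_numpy(bool))
    return pd.DataFrame(rows)


def linkage_summary_table(
    births: pd.DataFrame, linkages: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-method linkage summary (weighted): facility-count categories,
    linked-count median/IQR, nearest travel time, maximum linked score."""
    w = births["individual_weight"].to_numpy(float)
    rows = []
    for method, lk in linkages.items():
        merged = births[["cluster_id", "home_birth", "individual_weight"]].merge(
            lk, on="cluster_id", how="left"
        )
        for name, smask in _strata(births):
            sub = merged[smask]
            sw = w[smask]
            denom = sw.sum()
            rec = {"method": method, "stratum": name,
                   "n_births": int(smask.sum())}
            for cat in ("none", "one", "two_plus"):
                m = (sub["count_category"] == cat).to_numpy()
                rec[f"pct_{cat}"] = 100.0 * sw[m].sum() / denom
            rec["n_linked_median_iqr"] = _wmed_iqr(
                sub["n_linked"].to_numpy(float), sw
            )
            near = sub["nearest_minutes"].to_numpy(float)
            ok = np.isfinite(near)
            rec["nearest_minutes_median_iqr"] = (
                _wmed_iqr(near[ok], sw[ok]) if ok.any() else ""
            )
            score = sub["max_linked_score"].to_numpy(float)
            ok = np.isfinite(score)
            rec["max_score_median_iqr"] = (
                _wmed_iqr(score[ok], sw[ok]) if ok.any() else ""
            )
            rows.append(rec)
    return pd.DataFrame(rows)


def _synthetic_walk_times(
    clusters: pd.DataFrame,
    facilities: pd.DataFrame,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Walking-minute matrix through the router chain with seeded failures.

    The primary router fails for a random subset of pairs (emulating gaps in
    a road network); failed pairs under 50 km fall back to a slightly more
    direct router, the rest stay unreachable.
    """
    n_c, n_f = len(clusters), len(facilities)
    fail = rng.random((n_c, n_f)) < cfg.walk_primary_failure_rate
    dist = pairwise_distance_km(clusters, facilities)
    primary = dist * cfg.walk_detour_factor / cfg.walk_speed_kmh * 60.0
    fallback = dist * (cfg.walk_detour_factor * 0.95) / cfg.walk_speed_kmh * 60.0
    times = np.where(fail, np.where(dist < 50.0, fallback, np.inf), primary)
    return times


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full synthetic pipeline into ``out_dir``; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = cfg.generator
    gen.validate()
    run_warnings: list[str] = []

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        current = stage("synth")
        facilities = generate_facilities(gen)
        manifest = default_manifest(gen)
        clusters = generate_clusters(gen)
        surface = generate_friction_surface(gen)

        current = stage("score")
        scores = score_table(facilities, manifest)
        fac_scores = facilities[
            ["facility_id", "lat", "lon", "provides_birth_services"]
        ].merge(scores, on="facility_id")
        fac_scores.to_csv(out / "facilities_scores.csv", index=False)
        io.write_manifest(manifest, out / "indicator_manifest.yaml")
        facilities.to_csv(out / "facilities.csv", index=False)
        clusters.to_csv(out / "clusters.csv", index=False)
        io.write_esri_ascii(surface, out / "friction.asc")
        if cfg.write_geojson:
            io.write_geojson_points(fac_scores, out / "facilities.geojson")
            io.write_geojson_points(
                clusters.drop(columns=["true_lat", "true_lon"]),
                out / "clusters.geojson",
            )

        current = stage("link")
        birth_fac = facilities[facilities["provides_birth_services"]].reset_index(
            drop=True
        )
        score_s = scores.set_index("facility_id")["readiness_score"]
        weight_s = clusters.set_index("cluster_id")["design_weight"]
        rng = np.random.default_rng(gen.seed + 4)
        linkages: dict[str, pd.DataFrame] = {}
        pair_frames = []
        fac_ids = birth_fac["facility_id"].to_numpy()
        cl_ids = clusters["cluster_id"].to_numpy()

        if "buffer_5_10km" in cfg.methods:
            links = buffer_link(
                clusters, birth_fac,
                urban_radius_km=cfg.urban_radius_km,
                rural_radius_km=cfg.rural_radius_km,
            )
            attach_scores_and_terciles(links, score_s, weight_s)
            linkages["buffer_5_10km"] = linkage_frame(links)
            if cfg.write_pairs:
                dist = pairwise_distance_km(clusters, birth_fac)
                radii = np.where(clusters["urban"], cfg.urban_radius_km,
                                 cfg.rural_radius_km)
                ci, fi = np.nonzero(dist <= radii[:, None])
                pair_frames.append(pd.DataFrame({
                    "cluster_id": cl_ids[ci], "facility_id": fac_ids[fi],
                    "method": "buffer_5_10km", "km": dist[ci, fi].round(3),
                    "minutes": np.nan, "linked": True,
                }))

        time_mats = {}
        if "fastest_2h" in cfg.methods:
            origins = list(zip(clusters["lat"], clusters["lon"]))
            dests = list(zip(birth_fac["lat"], birth_fac["lon"]))
            times = travel_time_matrix(surface, origins, dests)
            time_mats["fastest_2h"] = times
            n_unreach = int((~np.isfinite(times)).sum())
            if n_unreach:
                run_warnings.append(
                    f"fastest_2h: travel time could not be calculated for "
                    f"{n_unreach} of {times.size} pairs "
                    f"({100 * n_unreach / times.size:.1f}%)"
                )
        if "walk_2h" in cfg.methods:
            time_mats["walk_2h"] = _synthetic_walk_times(
                clusters, birth_fac, cfg, rng
            )
        for method, times in time_mats.items():
            links = link_within_time(
                clusters, birth_fac, times,
                cutoff_minutes=cfg.cutoff_minutes, method_name=method,
            )
            attach_scores_and_terciles(links, score_s, weight_s)
            linkages[method] = linkage_frame(links)
            if cfg.write_pairs:
                ci, fi = np.nonzero(np.isfinite(times))
                pair_frames.append(pd.DataFrame({
                    "cluster_id": cl_ids[ci], "facility_id": fac_ids[fi],
                    "method": method, "km": np.nan,
                    "minutes": times[ci, fi].round(2),
                    "linked": times[ci, fi] <= cfg.cutoff_minutes,
                }))
        for method, lk in linkages.items():
            lk.to_csv(out / f"linkage_{method}.csv", index=False)
        if pair_frames:
            pd.concat(pair_frames, ignore_index=True).to_csv(
                out / "pairs.csv", index=False
            )

        current = stage("births")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            births, truth = generate_births(gen, clusters, linkages["buffer_5_10km"])
            run_warnings.extend(str(c.message) for c in caught)
        births.to_csv(out / "births.csv", index=False)
        io.write_truth(truth, out / "truth.json")

        current = stage("cocoverage")
        cov = coverage_table(
            births, births["individual_weight"], by_place_of_birth=True
        )
        cov.to_csv(out / "cocoverage.csv", index=False)

        current = stage("weights")
        sw = split_weights(
            births["individual_weight"], births["cluster_id"], alpha=cfg.weight_alpha
        )
        sw.insert(0, "birth_id", births["birth_id"])
        sw.to_csv(out / "weights.csv", index=False)

        current = stage("tables")
        background_table(births).to_csv(out / "table1_background.csv", index=False)
        linkage_summary_table(births, linkages).to_csv(
            out / "table2_linkage_summary.csv", index=False
        )

        current = stage("models")
        model_frames = []
        for method, lk in linkages.items():
            for exposure in ("facility_count_category", "service_environment_tercile"):
                spec = ModelSpec(exposure=exposure, linking_method=method)
                frame = assemble_model_frame(births, lk, alpha=cfg.weight_alpha)
                for kind, fit_fn in (("adjusted", fit_model), ("crude", crude_ratios)):
                    try:
                        fit = fit_fn(spec, frame)
                    except Exception as e:  # separation etc. on tiny configs
                        run_warnings.append(
                            f"model {method}/{exposure}/{kind} failed: {e}"
                        )
                        continue
                    tab = fit.to_frame()
                    tab.insert(0, "model", kind)
                    tab.insert(0, "exposure", exposure)
                    tab.insert(0, "linking_method", method)
                    model_frames.append(tab)
                    run_warnings.extend(
                        f"{method}/{exposure}/{kind}: {m}" for m in fit.warnings
                    )
        if model_frames:
            pd.concat(model_frames, ignore_index=True).to_csv(
                out / "table3_models.csv", index=False
            )
    except Exception:
        log.error("pipeline aborted at stage %r", current)
        raise

    manifest_obj = {
        "seed": gen.seed,
        "config": dataclasses.asdict(cfg),
        "versions": {
            "birthlink": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "warnings": run_warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest_obj, indent=1, default=str))
    return out
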