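"""Geographic linking: haversine, buffers, least-cost times, walking chain."""

import math

import numpy as np
import pandas as pd
import pytest

from birthlink.geolink import (
    EARTH_RADIUS_KM,
    FrictionSurface,
    LinkageSummary,
    SyntheticWalkRouter,
    UNREACHABLE,
    attach_scores_and_terciles,
    buffer_link,
    haversine_km,
    link_within_time,
    max_linked_score,
    travel_time_matrix,
    travel_time_minutes,
    walking_time_chain,
)
from birthlink.readiness import ValidationError


# ---------------------------------------------------------------------------
# haversine
# ---------------------------------------------------------------------------

def test_haversine_zero_for_identical_points():
    assert haversine_km((12.3, -4.5), (12.3, -4.5)) == 0.0


def test_haversine_equatorial_degree():
    # one degree of longitude on the equator = R * pi / 180
    expected = EARTH_RADIUS_KM * math.pi / 180.0
    assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(expected, rel=1e-9)


def test_haversine_antipodal():
    assert haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
        EARTH_RADIUS_KM * math.pi, rel=1e-9
    )


def test_haversine_symmetry_and_validation(rng):
    a = (rng.uniform(-60, 60), rng.uniform(-170, 170))
    b = (rng.uniform(-60, 60), rng.uniform(-170, 170))
    assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))
    with pytest.raises(ValidationError):
        haversine_km((95.0, 0.0), (0.0, 0.0))


# ---------------------------------------------------------------------------
# buffer linkage
# ---------------------------------------------------------------------------

def _clusters(lats, lons, urban):
    return pd.DataFrame(
        {
            "cluster_id": [f"C{i}" for i in range(len(lats))],
            "lat": lats, "lon": lons, "urban": urban,
        }
    )


def _facilities(lats, lons):
    return pd.DataFrame(
        {
            "facility_id": [f"F{i}" for i in range(len(lats))],
            "lat": lats, "lon": lons,
        }
    )


def test_buffer_boundaries_inclusive_urban_exclusive_beyond():
    km_per_deg = EARTH_RADIUS_KM * math.pi / 180.0
    cl = _clusters([0.0, 0.0], [0.0, 0.0], [True, False])
    fac = _facilities([4.999 / km_per_deg, 10.001 / km_per_deg], [0.0, 0.0])
    links = buffer_link(cl, fac)
    assert "F0" in links[0].linked_facility_ids  # urban, 4.999 km inside 5 km
    assert "F1" not in links[1].linked_facility_ids  # rural, 10.001 km outside


def test_buffer_matches_brute_force_over_random_configs():
    for trial in range(100):
        rng = np.random.default_rng(trial)
        n_c, n_f = rng.integers(1, 12, 2)
        cl = _clusters(
            rng.uniform(-1, 1, n_c), rng.uniform(-1, 1, n_c),
            rng.random(n_c) < 0.3,
        )
        fac = _facilities(rng.uniform(-1, 1, n_f), rng.uniform(-1, 1, n_f))
        links = buffer_link(cl, fac)
        for i, lk in enumerate(links):
            radius = 5.0 if cl["urban"][i] else 10.0
            expected = {
                fac["facility_id"][j]
                for j in range(n_f)
                if haversine_km(
                    (cl["lat"][i], cl["lon"][i]), (fac["lat"][j], fac["lon"][j])
                ) <= radius
            }
            assert lk.linked_facility_ids == expected
            assert lk.count_category == (
                "none" if not expected else ("one" if len(expected) == 1 else "two_plus")
            )


def test_buffer_monotone_in_radius(rng):
    cl = _clusters(rng.uniform(-1, 1, 8), rng.uniform(-1, 1, 8), rng.random(8) < 0.5)
    fac = _facilities(rng.uniform(-1, 1, 30), rng.uniform(-1, 1, 30))
    small = buffer_link(cl, fac, urban_radius_km=5, rural_radius_km=10)
    big = buffer_link(cl, fac, urban_radius_km=8, rural_radius_km=15)
    for s, b in zip(small, big):
        assert s.linked_facility_ids <= b.linked_facility_ids


# ---------------------------------------------------------------------------
# least-cost travel time
# ---------------------------------------------------------------------------

def uniform_surface(f=0.01, nrows=6, ncols=8, cell=1000.0):
    return FrictionSurface(lat0=0.0, lon0=0.0, cell_size_m=cell,
                           values=np.full((nrows, ncols), f))


def bellman_ford(surface, src):
    """Independent shortest-path oracle on the 8-connected cost graph."""
    f = surface.values
    nrows, ncols = f.shape
    dist = {src: 0.0}
    changed = True
    while changed:
        changed = False
        for r in range(nrows):
            for c in range(ncols):
                if (r, c) not in dist or not math.isfinite(f[r, c]):
                    continue
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < nrows and 0 <= cc < ncols):
                            continue
                        if not math.isfinite(f[rr, cc]):
                            continue
                        step = surface.cell_size_m * (
                            math.sqrt(2) if dr and dc else 1.0
                        )
                        cand = dist[(r, c)] + 0.5 * (f[r, c] + f[rr, cc]) * step
                        if cand < dist.get((rr, cc), math.inf) - 1e-12:
                            dist[(rr, cc)] = cand
                            changed = True
    return dist


def test_same_cell_is_zero_minutes():
    s = uniform_surface()
    a = s.cell_center(2, 3)
    b = s.cell_center(2, 3)
    assert travel_time_minutes(s, a, b) == 0.0


def test_uniform_surface_row_closed_form():
    f, cell, k = 0.02, 1000.0, 5
    s = uniform_surface(f=f, cell=cell)
    a, b = s.cell_center(3, 1), s.cell_center(3, 1 + k)
    assert travel_time_minutes(s, a, b) == pytest.approx(k * cell * f, rel=1e-9)


def test_random_grids_match_bellman_ford_oracle():
    for trial in range(60):
        rng = np.random.default_rng(trial)
        nrows, ncols = rng.integers(2, 7, 2)
        vals = rng.uniform(0.001, 0.05, (nrows, ncols))
        if trial % 3 == 0:  # sprinkle barriers
            vals[rng.random((nrows, ncols)) < 0.15] = np.inf
        s = FrictionSurface(0.0, 0.0, 1000.0, vals)
        src = (int(rng.integers(nrows)), int(rng.integers(ncols)))
        if not math.isfinite(vals[src]):
            continue
        oracle = bellman_ford(s, src)
        dests = [(int(rng.integers(nrows)), int(rng.integers(ncols))) for _ in range(4)]
        times = travel_time_matrix(
            s, [s.cell_center(*src)], [s.cell_center(*d) for d in dests]
        )[0]
        for t, d in zip(times, dests):
            expected = oracle.get(d, math.inf)
            if not math.isfinite(vals[d]):
                expected = math.inf
            if math.isinf(expected):
                assert math.isinf(t)
            else:
                assert t == pytest.approx(expected, rel=1e-9)


def test_travel_time_metric_properties(rng):
    vals = rng.uniform(0.005, 0.03, (6, 6))
    s = FrictionSurface(0.0, 0.0, 1000.0, vals)
    pts = [s.cell_center(*rc) for rc in [(0, 0), (3, 4), (5, 1)]]
    t = travel_time_matrix(s, pts, pts)
    assert np.allclose(t, t.T)
    assert np.allclose(np.diag(t), 0.0)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                assert t[i, j] <= t[i, k] + t[k, j] + 1e-9


def test_cost_monotonicity(rng):
    vals = rng.uniform(0.005, 0.03, (5, 7))
    s1 = FrictionSurface(0.0, 0.0, 1000.0, vals)
    vals2 = vals.copy()
    vals2[2, 3] *= 5.0
    s2 = FrictionSurface(0.0, 0.0, 1000.0, vals2)
    pts = [s1.cell_center(r, c) for r in range(0, 5, 2) for c in range(0, 7, 3)]
    t1 = travel_time_matrix(s1, pts, pts)
    t2 = travel_time_matrix(s2, pts, pts)
    assert (t2 >= t1 - 1e-9).all()


def test_refinement_changes_uniform_times_under_ten_percent():
    f = 0.012
    coarse = FrictionSurface(0.0, 0.0, 2000.0, np.full((10, 14), f))
    fine = FrictionSurface(0.0, 0.0, 1000.0, np.full((20, 28), f))
    a, b = coarse.cell_center(1, 1), coarse.cell_center(8, 12)
    tc = travel_time_minutes(coarse, a, b)
    tf = travel_time_minutes(fine, a, b)
    assert abs(tf - tc) / tc < 0.10


def test_endpoints_on_barrier_or_outside_are_unreachable():
    vals = np.full((4, 4), 0.01)
    vals[1, 1] = np.inf
    s = FrictionSurface(0.0, 0.0, 1000.0, vals)
    on_barrier = s.cell_center(1, 1)
    inside = s.cell_center(0, 0)
    outside = (5.0, 5.0)
    assert math.isinf(travel_time_minutes(s, on_barrier, inside))
    assert math.isinf(travel_time_minutes(s, inside, outside))


# ---------------------------------------------------------------------------
# time-cutoff linking
# ---------------------------------------------------------------------------

def test_link_within_time_inclusive_cutoff_and_unreachable():
    cl = _clusters([0.0], [0.0], [False])
    fac = _facilities([0.0, 0.0, 0.0], [0.1, 0.2, 0.3])
    times = np.array([[120.0, 120.0001, np.inf]])
    links = link_within_time(cl, fac, times)
    assert links[0].linked_facility_ids == {"F0"}
    assert links[0].nearest_minutes == 120.0

    links = link_within_time(cl, fac, np.array([[np.inf, np.inf, np.inf]]))
    assert links[0].count_category == "none"
    assert links[0].nearest_minutes is None


def test_link_within_time_matches_thresholding_oracle(rng):
    n_c, n_f = 15, 9
    cl = _clusters(np.zeros(n_c), np.zeros(n_c), np.zeros(n_c, bool))
    fac = _facilities(np.zeros(n_f), np.zeros(n_f))
    times = rng.uniform(0, 300, (n_c, n_f))
    times[rng.random((n_c, n_f)) < 0.2] = np.inf
    links = link_within_time(cl, fac, times, cutoff_minutes=120)
    for i, lk in enumerate(links):
        expected = {f"F{j}" for j in range(n_f) if times[i, j] <= 120}
        assert lk.linked_facility_ids == expected
        if expected:
            assert lk.nearest_minutes == pytest.approx(
                min(times[i, j] for j in range(n_f) if times[i, j] <= 120)
            )


# ---------------------------------------------------------------------------
# walking chain
# ---------------------------------------------------------------------------

def test_walking_chain_semantics():
    km_per_deg = EARTH_RADIUS_KM * math.pi / 180.0
    near = ((0.0, 0.0), (0.0, 10.0 / km_per_deg))    # 10 km apart
    far = ((0.0, 0.0), (0.0, 60.0 / km_per_deg))     # 60 km apart

    primary_ok = SyntheticWalkRouter(speed_kmh=5, detour_factor=1.4)
    fallback = SyntheticWalkRouter(speed_kmh=6, detour_factor=1.0)

    # primary succeeds: its value is used
    t = walking_time_chain(primary_ok, fallback, [near])
    assert t[0] == pytest.approx(10.0 * 1.4 / 5.0 * 60.0, rel=1e-6)

    calls = []

    class FailingPrimary:
        def route(self, a, b):
            return None

    class RecordingFallback:
        def route(self, a, b):
            calls.append((a, b))
            return 130.0

    # primary fails at 60 km: unreachable, fallback never consulted
    t = walking_time_chain(FailingPrimary(), RecordingFallback(), [far])
    assert math.isinf(t[0])
    assert calls == []

    # primary fails at 10 km: fallback value recorded
    t = walking_time_chain(FailingPrimary(), RecordingFallback(), [near])
    assert t[0] == 130.0
    assert len(calls) == 1


def test_walking_chain_rejects_negative_times():
    class BadRouter:
        def route(self, a, b):
            return -5.0

    with pytest.raises(ValidationError):
        walking_time_chain(BadRouter(), None, [((0, 0), (0, 1))])


# ---------------------------------------------------------------------------
# max linked score
# ---------------------------------------------------------------------------

def test_max_linked_score_examples():
    scores = {"A": 77.5, "B": 60.2}
    lk = LinkageSummary("C0", "buffer_5_10km", frozenset({"A", "B"}), "two_plus")
    assert max_linked_score(lk, scores) == 77.5
    empty = LinkageSummary("C1", "buffer_5_10km", frozenset(), "none")
    assert max_linked_score(empty, scores) is None
    with pytest.raises(ValidationError):
        max_linked_score(
            LinkageSummary("C2", "buffer_5_10km", frozenset({"Z"}), "one"), scores
        )


def test_max_linked_score_matches_naive_max(rng):
    fac_ids = [f"F{i}" for i in range(20)]
    scores = {f: float(rng.uniform(0, 100)) for f in fac_ids}
    for _ in range(30):
        chosen = frozenset(rng.choice(fac_ids, size=rng.integers(1, 8), replace=False))
        lk = LinkageSummary("C", "buffer_5_10km", chosen,
                            "one" if len(chosen) == 1 else "two_plus")
        assert max_linked_score(lk, scores) == max(scores[f] for f in chosen)


def test_linkage_summary_consistency_enforced():
    with pytest.raises(ValidationError):
        LinkageSummary("C0", "buffer_5_10km", frozenset({"A"}), "two_plus")
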