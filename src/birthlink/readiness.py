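"""Facility service-readiness scoring for birth and newborn care.

A facility's readiness is summarized with a SARA-style equal-weighting score
over six domains: (1) basic emergency obstetric care, (2) newborn signal
functions and immediate care, (3) general requirements, (4) equipment,
(5) medicines and commodities, (6) guidelines, staff training and supervision.
Each domain holds dichotomous availability indicators; a domain subscore is the
percentage of indicators present, and the overall score is the unweighted mean
of the six domain subscores, so a 4-indicator domain and a 15-indicator domain
contribute equally. Scores read as "percent readiness": 100 means every
measured indicator is available, 0 means none are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DOMAINS: tuple[str, ...] = (
    "bemoc",
    "newborn_signal_functions",
    "general_requirements",
    "equipment",
    "medicines_commodities",
    "guidelines_training_supervision",
)

TERCILE_LABELS: tuple[str, ...] = ("low", "middle", "high")


class ValidationError(ValueError):
    """Raised when a record or input violates a structural contract."""


@dataclass
class FacilityRecord:
    """One health facility with its six-domain indicator battery.

    ``indicators`` maps each domain name in :data:`DOMAINS` to an ordered
    mapping of indicator name -> value in {0, 1}.
    """

    facility_id: str
    lat: float
    lon: float
    provides_birth_services: bool = True
    indicators: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.indicators) != set(DOMAINS):
            raise ValidationError(
                f"facility {self.facility_id}: expected domains {DOMAINS}, "
                f"got {tuple(self.indicators)}"
            )
        for dom, vals in self.indicators.items():
            if len(vals) == 0:
                raise ValidationError(
                    f"facility {self.facility_id}: empty domain {dom!r}"
                )
            for name, v in vals.items():
                if v not in (0, 1):
                    raise ValidationError(
                        f"facility {self.facility_id}: indicator {name!r} "
                        f"has non-dichotomous value {v!r}"
                    )


@dataclass
class ReadinessScore:
    facility_id: str
    domain_subscores: dict[str, float]
    overall: float


def score_facility(facility: FacilityRecord, *, pooled: bool = False) -> ReadinessScore:
    """Score one facility on the 0-100 readiness scale.

    Each domain subscore is ``100 * (yes count) / (indicator count)``. With the
    default equal-weighting construction the overall score is the mean of the
    six domain subscores; with ``pooled=True`` it is instead the percentage of
    all indicators pooled across domains (sensitivity variant).
    """
    facility.validate()
    subs: dict[str, float] = {}
    n_yes = 0
    n_total = 0
    for dom in DOMAINS:
        vals = list(facility.indicators[dom].values())
        subs[dom] = 100.0 * sum(vals) / len(vals)
        n_yes += sum(vals)
        n_total += len(vals)
    if pooled:
        overall = 100.0 * n_yes / n_total
    else:
        overall = float(np.mean([subs[d] for d in DOMAINS]))
    return ReadinessScore(facility.facility_id, subs, overall)


def score_table(
    facilities: pd.DataFrame,
    manifest: Mapping[str, Sequence[str]],
    *,
    pooled: bool = False,
    missing_as_no: bool = True,
) -> pd.DataFrame:
    """Score a facility table whose indicator values live in columns.

    Parameters
    ----------
    facilities
        One row per facility; must contain ``facility_id`` plus every column
        named in the manifest.
    manifest
        Maps each domain in :data:`DOMAINS` to the list of indicator columns
        belonging to it (the configurable indicator battery).
    missing_as_no
        Treat missing indicator values as "not available" (the conservative
        readiness reading). With ``False``, the domain denominator is instead
        renormalized to the observed indicators.

    Returns a frame with ``facility_id``, one ``score_<domain>`` column per
    domain, and ``readiness_score``.
    """
    if set(manifest) != set(DOMAINS):
        raise ValidationError(f"manifest must define exactly the domains {DOMAINS}")
    out = pd.DataFrame({"facility_id": facilities["facility_id"].to_numpy()})
    sub_cols = []
    pooled_yes = np.zeros(len(facilities))
    pooled_n = np.zeros(len(facilities))
    for dom in DOMAINS:
        cols = list(manifest[dom])
        if not cols:
            raise ValidationError(f"empty domain {dom!r} in manifest")
        block = facilities[cols].to_numpy(dtype=float)
        present = ~np.isnan(block)
        yes = np.nansum(block, axis=1)
        if missing_as_no:
            denom = np.full(len(facilities), float(len(cols)))
        else:
            denom = present.sum(axis=1).astype(float)
            if (denom == 0).any():
                raise ValidationError(
                    f"domain {dom!r}: some facility has no observed indicators"
                )
        out[f"score_{dom}"] = 100.0 * yes / denom
        sub_cols.append(f"score_{dom}")
        pooled_yes += yes
        pooled_n += denom
    if pooled:
        out["readiness_score"] = 100.0 * pooled_yes / pooled_n
    else:
        out["readiness_score"] = out[sub_cols].mean(axis=1)
    return out


def weighted_quantile(
    values: np.ndarray, weights: np.ndarray, q: float | np.ndarray
) -> float | np.ndarray:
    """Lower weighted quantile: smallest v with cumulative weight fraction >= q."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValidationError("empty values")
    if (weights < 0).any():
        raise ValidationError("negative weights")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("weights sum to zero")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order]) / total
    # guard against fp undershoot at the top
    cw[-1] = 1.0
    idx = np.searchsorted(cw, np.asarray(q) - 1e-12, side="left")
    return v[np.minimum(idx, v.size - 1)]


def tercile_cut(
    values: Sequence[float], weights: Sequence[float] | None = None
) -> pd.Categorical:
    """Assign each value to a weighted tercile {low, middle, high}.

    Boundaries sit at cumulative weight fractions 1/3 and 2/3; a value exactly
    on a boundary goes to the lower tercile, so identical inputs all land in
    "low".
    """
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValidationError("values and weights must align")
    t1, t2 = weighted_quantile(v, w, np.array([1 / 3, 2 / 3]))
    labels = np.where(v <= t1, "low", np.where(v <= t2, "middle", "high"))
    return pd.Categorical(labels, categories=list(TERCILE_LABELS), ordered=True)
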