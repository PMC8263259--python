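"""Newborn-care co-coverage index and the "appropriate care" outcome.

Co-coverage counts how many of six provider-initiated early newborn
interventions a newborn received: weighing at birth, counselling on
breastfeeding, counselling on danger signs, a breastfeeding episode observed,
umbilical cord examined, and temperature taken. A newborn with at least five
of the six is classified as having received appropriate care (all six =
optimal, any five = pragmatic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readiness import ValidationError

INTERVENTIONS: tuple[str, ...] = (
    "weighed_at_birth",
    "breastfeeding_counselled",
    "danger_signs_counselled",
    "breastfeeding_observed",
    "cord_examined",
    "temperature_taken",
)

APPROPRIATE_THRESHOLD = 5


@dataclass
class BirthRecord:
    """One most-recent birth with covariates and intervention receipt."""

    birth_id: str
    cluster_id: str
    interventions: dict[str, bool]
    home_birth: bool
    wealth_quintile: int
    maternal_age_group: str  # "<20", "20-34", "35+"
    education_secondary_plus: bool
    parity_first: bool
    urban: bool
    individual_weight: float = 1.0

    def validate(self) -> None:
        missing = [k for k in INTERVENTIONS if self.interventions.get(k) is None]
        if missing:
            raise ValidationError(
                f"birth {self.birth_id}: missing intervention values {missing}"
            )
        if self.individual_weight <= 0:
            raise ValidationError(f"birth {self.birth_id}: non-positive weight")
        if self.wealth_quintile not in (1, 2, 3, 4, 5):
            raise ValidationError(f"birth {self.birth_id}: wealth quintile out of range")


def co_coverage(birth: BirthRecord) -> int:
    """Number of the six interventions received (0-6)."""
    birth.validate()
    return sum(bool(birth.interventions[k]) for k in INTERVENTIONS)


def appropriate_care(birth: BirthRecord) -> bool:
    """True iff the newborn received at least five of the six interventions."""
    return co_coverage(birth) >= APPROPRIATE_THRESHOLD


def co_coverage_counts(births: pd.DataFrame) -> pd.Series:
    """Vectorized co-coverage count per row of a births table."""
    missing = [c for c in INTERVENTIONS if c not in births.columns]
    if missing:
        raise ValidationError(f"births table lacks intervention columns {missing}")
    block = births[list(INTERVENTIONS)]
    if block.isna().any().any():
        raise ValidationError("missing intervention values; clean or drop upstream")
    return block.astype(int).sum(axis=1)


def coverage_table(
    births: pd.DataFrame,
    weights: np.ndarray | pd.Series | None = None,
    by_place_of_birth: bool = False,
) -> pd.DataFrame:
    """Weighted distribution of co-coverage (0-6) and the appropriate-care share.

    Returns one row per stratum ("all", and optionally "facility"/"home") with
    columns ``p0``..``p6`` (weighted proportions summing to 1) and
    ``appropriate`` (= p5 + p6).
    """
    if len(births) == 0:
        raise ValidationError("empty births table")
    w = np.ones(len(births)) if weights is None else np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValidationError("zero total weight")
    counts = co_coverage_counts(births).to_numpy()

    def row(mask, label):
        wm = w[mask]
        if wm.sum() <= 0:
            raise ValidationError(f"zero total weight in stratum {label!r}")
        cm = counts[mask]
        p = np.array([wm[cm == k].sum() for k in range(7)]) / wm.sum()
        rec = {"stratum": label, **{f"p{k}": p[k] for k in range(7)}}
        rec["appropriate"] = p[5] + p[6]
        return rec

    rows = [row(np.ones(len(births), bool), "all")]
    if by_place_of_birth:
        home = births["home_birth"].to_numpy(bool)
        if (~home).any():
            rows.append(row(~home, "facility"))
        if home.any():
            rows.append(row(home, "home"))
    return pd.DataFrame(rows)
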