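"""Survey-weighted multilevel modified-Poisson regression for binary outcomes.

The outcome (appropriate newborn care, a 0/1 indicator) is modelled with a
Poisson distribution and a logarithm link so exponentiated coefficients are
risk ratios rather than odds ratios ("modified Poisson"). Individuals are
nested in sampling clusters; a cluster-level random intercept absorbs within-
cluster correlation and cluster-robust (sandwich) standard errors guard
against the working-model misspecification inherent in using Poisson for a
binary outcome.

Estimation is penalized quasi-likelihood (PQL): iteratively reweighted least
squares on the linearized model with the random intercepts profiled out
through a per-cluster Schur complement, which keeps each iteration O(n p^2)
even with hundreds of clusters. Observations carry two-level survey weights
(cluster weight x conditional individual weight). When the PQL loop fails to
converge the model is refit as a weighted exchangeable-correlation GEE
(statsmodels) and flagged: for cluster-level exposures both routes target the
same marginal risk ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .readiness import ValidationError, tercile_cut

Z95 = 1.959963984540054


class SeparationError(ValidationError):
    """A model term has no outcome variation (or no variation at all)."""


# column name, ordered levels, default reference
CATEGORICAL_TERMS: dict[str, tuple[list, object]] = {
    "count_category": (["none", "one", "two_plus"], "none"),
    "score_tercile": (["low", "middle", "high", "no_facility"], "low"),
    "population_density_tercile": (["low", "middle", "high"], "low"),
    "wealth_quintile": ([1, 2, 3, 4, 5], 1),
    "maternal_age_group": (["<20", "20-34", "35+"], "<20"),
}
BINARY_TERMS = ("home_birth", "education_secondary_plus")

EXPOSURE_COLUMNS = {
    "facility_count_category": "count_category",
    "service_environment_tercile": "score_tercile",
}

DEFAULT_COVARIATES = (
    "home_birth",
    "population_density_tercile",
    "wealth_quintile",
    "maternal_age_group",
    "education_secondary_plus",
)


@dataclass
class ModelSpec:
    """What to regress on what.

    ``exposure`` is one of ``facility_count_category`` or
    ``service_environment_tercile``; for the tercile exposure, clusters that
    link to no facility enter as the distinct ``no_facility`` level when
    ``include_no_facility_level`` is set (reference stays the lowest tercile).
    """

    exposure: str | None = "service_environment_tercile"
    linking_method: str = "buffer_5_10km"
    covariates: Sequence[str] = DEFAULT_COVARIATES
    include_no_facility_level: bool = True
    reference_levels: dict = field(default_factory=dict)

    def exposure_column(self) -> str | None:
        if self.exposure is None:
            return None
        try:
            return EXPOSURE_COLUMNS[self.exposure]
        except KeyError:
            raise ValidationError(f"unknown exposure {self.exposure!r}") from None


@dataclass
class ModelFit:
    """Tidy fit result: log-RR estimates with cluster-robust Wald intervals."""

    terms: list[str]
    estimates: np.ndarray
    robust_se: np.ndarray
    random_intercept_var: float
    n_births: int
    n_clusters: int
    converged: bool
    method: str = "pql_random_intercept"
    warnings: list[str] = field(default_factory=list)

    @property
    def arr(self) -> np.ndarray:
        return np.exp(self.estimates)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.estimates - Z95 * self.robust_se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.estimates + Z95 * self.robust_se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "robust_se": self.robust_se,
                "ARR": self.arr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_births": self.n_births,
                "n_clusters": self.n_clusters,
                "method": self.method,
                "converged": self.converged,
            }
        )

    def __getitem__(self, term: str) -> float:
        return float(self.arr[self.terms.index(term)])


def _dummies(frame: pd.DataFrame, col: str, ref) -> tuple[np.ndarray, list[str]]:
    levels, default_ref = CATEGORICAL_TERMS[col]
    ref = default_ref if ref is None else ref
    if ref not in levels:
        raise ValidationError(f"reference {ref!r} not a level of {col}")
    observed = frame[col]
    bad = ~observed.isin(levels)
    if bad.any():
        raise ValidationError(
            f"{col}: unexpected levels {sorted(observed[bad].unique().tolist())}"
        )
    cols, names = [], []
    for lv in levels:
        if lv == ref:
            continue
        cols.append((observed == lv).to_numpy(float))
        names.append(f"{col}[{lv}]")
    return np.column_stack(cols), names


def build_design(
    frame: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Outcome vector and design matrix (with intercept) for a model frame."""
    y = frame["appropriate_care"].to_numpy(float)
    blocks = [np.ones((len(frame), 1))]
    names = ["intercept"]
    terms = [t for t in (spec.exposure_column(), *spec.covariates) if t is not None]
    for t in terms:
        if t in BINARY_TERMS:
            blocks.append(frame[t].to_numpy(float)[:, None])
            names.append(t)
        elif t in CATEGORICAL_TERMS:
            X, nm = _dummies(frame, t, spec.reference_levels.get(t))
            blocks.append(X)
            names.extend(nm)
        else:
            raise ValidationError(f"unknown model term {t!r}")
    return y, np.hstack(blocks), names


def _check_separation(y: np.ndarray, X: np.ndarray, names: list[str]) -> None:
    for j, nm in enumerate(names):
        if nm == "intercept":
            continue
        col = X[:, j]
        if col.min() == col.max():
            raise SeparationError(f"term {nm!r} has no variation")
        in_level = col > 0
        if y[in_level].sum() == 0:
            raise SeparationError(f"term {nm!r}: no positive outcomes at that level")


def _pql_poisson(
    y: np.ndarray,
    X: np.ndarray,
    group_codes: np.ndarray,
    w_obs: np.ndarray,
    w_cluster: np.ndarray,
    *,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    """Weighted PQL for a log-link Poisson with one random intercept per group.

    Returns (beta, robust covariance, sigma2, u, converged). ``w_obs`` is the
    total per-observation weight (level1 x level2); ``w_cluster`` the level-2
    weight per group. Robust covariance is the cluster sandwich on the
    marginal estimating equations.
    """
    n, p = X.shape
    J = int(group_codes.max()) + 1
    beta = np.zeros(p)
    beta[0] = np.log(max(np.average(y, weights=w_obs), 1e-6))
    u = np.zeros(J)
    sigma2 = 0.05
    converged = False
    A = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta + u[group_codes], -30.0, 30.0)
        mu = np.exp(eta)
        W = w_obs * mu
        z = eta + (y - mu) / mu
        # per-cluster aggregates for the Schur complement
        S = np.bincount(group_codes, W, minlength=J) + w_cluster / max(sigma2, 1e-10)
        CX = np.zeros((J, p))
        np.add.at(CX, group_codes, W[:, None] * X)
        cz = np.bincount(group_codes, W * z, minlength=J)
        A = X.T @ (W[:, None] * X) - CX.T @ (CX / S[:, None])
        rhs = X.T @ (W * z) - CX.T @ (cz / S)
        beta_new = np.linalg.solve(A, rhs)
        u_new = (cz - CX @ beta_new) / S
        sigma2_new = float(np.mean(u_new**2 + 1.0 / S))
        sigma2_new = min(max(sigma2_new, 1e-10), 25.0)
        beta_done = np.abs(beta_new - beta).max() < tol * (1.0 + np.abs(beta).max())
        s2_done = abs(sigma2_new - sigma2) < 1e-6 * (1.0 + sigma2)
        beta, u, sigma2 = beta_new, u_new, sigma2_new
        if beta_done and s2_done:
            converged = True
            break
    # cluster-robust sandwich: bread = profiled working information
    eta = np.clip(X @ beta + u[group_codes], -30.0, 30.0)
    mu = np.exp(eta)
    score = w_obs[:, None] * X * (y - mu)[:, None]
    G = np.zeros((J, p))
    np.add.at(G, group_codes, score)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ (G.T @ G) @ Ainv
    if sigma2 <= 1e-8:
        sigma2 = 0.0
    return beta, cov, sigma2, u, converged


def _gee_fallback(y, X, group_codes, w_obs):
    import statsmodels.api as sm
    from statsmodels.genmod.cov_struct import Exchangeable

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y, X, groups=group_codes, family=sm.families.Poisson(),
            cov_struct=Exchangeable(), weights=w_obs,
        )
        res = model.fit(maxiter=200)
    return np.asarray(res.params), np.asarray(res.cov_params())


def fit_model(
    spec: ModelSpec,
    frame: pd.DataFrame,
    *,
    max_iter: int = 500,
) -> ModelFit:
    """Fit the weighted cluster-random-intercept modified-Poisson model.

    ``frame`` is an assembled model frame (see :func:`assemble_model_frame`)
    with columns ``appropriate_care``, ``cluster_id``, ``level1_weight``,
    ``level2_weight``, the exposure column and every covariate. Rows with
    missing values in any used column are dropped listwise (count recorded in
    ``ModelFit.warnings``).
    """
    used = ["appropriate_care", "cluster_id", "level1_weight", "level2_weight",
            *([] if spec.exposure_column() is None else [spec.exposure_column()]),
            *spec.covariates]
    data = frame[used]
    n_before = len(data)
    data = data.dropna()
    notes = []
    if len(data) < n_before:
        notes.append(f"listwise deletion dropped {n_before - len(data)} rows")
    if len(data) == 0:
        raise ValidationError("no complete cases")

    y, X, names = build_design(data, spec)
    _check_separation(y, X, names)
    codes, _ = pd.factorize(data["cluster_id"], sort=True)
    w1 = data["level1_weight"].to_numpy(float)
    w2 = data["level2_weight"].to_numpy(float)
    w_obs = w1 * w2
    # normalization convention: estimates are invariant to rescaling either
    # weight level by a positive constant
    w_obs = w_obs / w_obs.mean()
    J = int(codes.max()) + 1
    w_cluster = np.zeros(J)
    w_cluster[codes] = w2
    w_cluster = w_cluster / w_cluster.mean()

    method = "pql_random_intercept"
    sigma2 = 0.0
    try:
        beta, cov, sigma2, _, converged = _pql_poisson(
            y, X, codes, w_obs, w_cluster, max_iter=max_iter
        )
        if not (converged and np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))):
            raise FloatingPointError("PQL did not converge")
    except (FloatingPointError, np.linalg.LinAlgError) as e:
        notes.append(f"mixed fit failed ({e}); weighted exchangeable GEE fallback used")
        beta, cov = _gee_fallback(y, X, codes, w_obs)
        method = "gee_exchangeable_fallback"
        converged = True

    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return ModelFit(
        terms=names,
        estimates=beta,
        robust_se=se,
        random_intercept_var=float(sigma2),
        n_births=len(data),
        n_clusters=J,
        converged=bool(converged),
        method=method,
        warnings=notes,
    )


def crude_ratios(spec: ModelSpec, frame: pd.DataFrame) -> ModelFit:
    """Single-exposure ("crude") model: same pipeline, no covariates."""
    crude_spec = ModelSpec(
        exposure=spec.exposure,
        linking_method=spec.linking_method,
        covariates=(),
        include_no_facility_level=spec.include_no_facility_level,
        reference_levels=spec.reference_levels,
    )
    return fit_model(crude_spec, frame)


def sensitivity_exclude_home_births(spec: ModelSpec, frame: pd.DataFrame) -> ModelFit:
    """Refit on facility births only, with the home-birth term dropped."""
    sub = frame[~frame["home_birth"].astype(bool)]
    if len(sub) == 0:
        raise ValidationError("no facility births")
    new_spec = ModelSpec(
        exposure=spec.exposure,
        linking_method=spec.linking_method,
        covariates=tuple(c for c in spec.covariates if c != "home_birth"),
        include_no_facility_level=spec.include_no_facility_level,
        reference_levels=spec.reference_levels,
    )
    return fit_model(new_spec, sub)


def population_density_terciles(
    density_values: Sequence[float], weights: Sequence[float] | None = None
) -> pd.Categorical:
    """Weighted terciles of cluster population density (low/middle/high)."""
    return tercile_cut(density_values, weights)


def assemble_model_frame(
    births: pd.DataFrame,
    linkage: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Merge births with per-cluster linkage and attach two-level weights.

    ``linkage`` is a :func:`birthlink.geolink.linkage_frame` table for one
    linking method. Unlinked clusters get ``score_tercile = "no_facility"``.
    When no explicit weight pair is supplied, the births' ``individual_weight``
    is split with :func:`birthlink.survey_weights.split_weights`.
    """
    from .survey_weights import split_weights

    lk = linkage[["cluster_id", "count_category", "score_tercile"]].copy()
    lk["score_tercile"] = lk["score_tercile"].fillna("no_facility")
    base = births.drop(columns=["count_category", "score_tercile"], errors="ignore")
    out = base.merge(lk, on="cluster_id", how="left", validate="many_to_one")
    if weights is not None:
        out = out.join(weights[["level2_weight", "level1_weight"]])
    else:
        sw = split_weights(out["individual_weight"], out["cluster_id"], alpha=alpha)
        out["level2_weight"] = sw["level2_weight"].to_numpy()
        out["level1_weight"] = sw["level1_weight"].to_numpy()
    return out
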