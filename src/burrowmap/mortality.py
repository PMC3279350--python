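"""Colony mortality-risk modelling and the spatial thinning survival test.

Covers: the neighbourhood influence index (sum over neighbouring colonies of
disc diameter over distance, within a cohort-specific radius), logistic
regression of death on colony covariates with all-subsets AIC selection and
Wald tests, the cohort-mortality contingency test, and the random- vs
logistic-thinning comparison of surviving-colony spatial patterns.

The logistic fit is presented in the Model/Results idiom (`MortalityModel` /
`MortalityResults`) and is backed by statsmodels' Logit.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from scipy.stats import chi2_contingency

from .gof import EnvelopeResult, critical_envelope, cvm_statistic
from .pattern import TypedPointPattern, Window
from .summaries import SummaryFunction, center_l, k_translation

__all__ = [
    "influence_index",
    "build_colony_records",
    "MortalityModel",
    "MortalityResults",
    "all_subsets_aic",
    "pearson_chi_square",
    "ThinningTestResult",
    "thinning_survival_test",
    "compare_mortality_models",
]

#: cohort-specific neighbourhood radii (meters) for the influence index
DEFAULT_INFLUENCE_RADIUS = {"recent": 10.0, "established": 20.0}


def influence_index(
    focal_xy,
    neighbor_xy,
    neighbor_diameter,
    radius: float,
) -> float:
    """Competitive influence on a focal colony: sum of D_n / dist_{n,f} over
    neighbouring colonies strictly closer than ``radius`` (cm/m).

    The focal colony must not appear among the neighbours; a neighbour at
    distance 0 is invalid (coincident structures cannot exist).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    neighbor_xy = np.atleast_2d(np.asarray(neighbor_xy, dtype=float))
    D = np.atleast_1d(np.asarray(neighbor_diameter, dtype=float))
    if len(neighbor_xy) == 0:
        return 0.0
    d = np.hypot(neighbor_xy[:, 0] - focal_xy[0], neighbor_xy[:, 1] - focal_xy[1])
    within = d < radius
    if np.any(d[within] == 0):
        raise ValueError("neighbour at distance 0 from focal colony")
    return float(np.sum(D[within] / d[within]))


def build_colony_records(
    colonies: pd.DataFrame,
    mound_xy,
    influence_radius: Mapping[str, float] | float = None,
) -> pd.DataFrame:
    """Attach model covariates to a colony table.

    ``colonies`` needs columns x, y, disc_diameter_cm and (unless a scalar
    radius is given) cohort; death outcomes, if present, ride along in a
    ``died`` column. Adds ``influence_index`` (cm/m, neighbours = all other
    colonies within the cohort-specific radius) and ``nearest_mound_distance``
    (m, to the nearest occupied mound).
    """
    if influence_radius is None:
        influence_radius = DEFAULT_INFLUENCE_RADIUS
    out = colonies.reset_index(drop=True).copy()
    xy = out[["x", "y"]].to_numpy(float)
    D = out["disc_diameter_cm"].to_numpy(float)
    infl = np.zeros(len(out))
    for i in range(len(out)):
        if np.isscalar(influence_radius):
            radius = float(influence_radius)
        else:
            radius = float(influence_radius[out.loc[i, "cohort"]])
        others = np.ones(len(out), dtype=bool)
        others[i] = False
        infl[i] = influence_index(xy[i], xy[others], D[others], radius)
    out["influence_index"] = infl
    mound_xy = np.atleast_2d(np.asarray(mound_xy, dtype=float))
    tree = cKDTree(mound_xy)
    out["nearest_mound_distance"], _ = tree.query(xy, k=1)
    return out


class MortalityResults:
    """Fitted logistic mortality model (wraps a statsmodels Logit fit)."""

    def __init__(self, model, sm_results, predictors, converged=True):
        self.model = model
        self._res = sm_results
        self.predictors = tuple(predictors)
        self.converged = bool(converged)
        self.param_names = ["intercept", *predictors]

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._res.params)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._res.bse)

    @property
    def wald_z(self) -> np.ndarray:
        return np.asarray(self._res.tvalues)

    @property
    def wald_p(self) -> np.ndarray:
        """Two-sided normal-approximation Wald p-values."""
        return np.asarray(self._res.pvalues)

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def fitted_probabilities(self) -> np.ndarray:
        """Fitted per-colony death probabilities."""
        return np.asarray(self._res.predict())

    def summary(self) -> str:
        lines = [
            "Logistic colony-mortality model (maximum likelihood)",
            "=" * 60,
            f"n = {int(self._res.nobs)}   deaths = "
            f"{int(self.model.died.sum())}   k = {self.k}",
            f"log L = {self.llf:.1f}   AIC = {self.aic:.1f}   "
            f"converged: {self.converged}",
            "-" * 60,
            f"{'term':<24}{'coef':>10}{'SE':>10}{'z':>8}{'P':>10}",
        ]
        for name, b, se, z, p in zip(self.param_names, self.params, self.bse,
                                     self.wald_z, self.wald_p):
            lines.append(f"{name:<24}{b:>10.4f}{se:>10.4f}{z:>8.2f}{p:>10.4f}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<MortalityResults predictors={list(self.predictors)} "
                f"logL={self.llf:.1f} AIC={self.aic:.1f}>")


class MortalityModel:
    """Logistic regression of colony death on colony covariates.

    ``records`` must contain a boolean/0-1 ``died`` column plus the predictor
    columns. Needs at least one death and one survival.
    """

    def __init__(self, records: pd.DataFrame, predictors: Sequence[str] = ()):
        self.records = records.reset_index(drop=True)
        self.predictors = tuple(predictors)
        self.died = self.records["died"].astype(float).to_numpy()
        if self.died.sum() == 0 or self.died.sum() == len(self.died):
            raise ValueError("need at least one death and one survival")

    def fit(self) -> MortalityResults:
        X = sm.add_constant(
            self.records[list(self.predictors)].to_numpy(float)
            if self.predictors else np.empty((len(self.died), 0)),
            has_constant="add",
        )
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.died, X).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception as exc:  # perfect separation raises in statsmodels
                raise RuntimeError(
                    f"logistic fit failed (possible perfect separation): {exc}"
                ) from exc
        if not converged:
            warnings.warn(
                "logistic fit did not converge (possible perfect separation)",
                stacklevel=2,
            )
        return MortalityResults(self, res, self.predictors, converged)


def all_subsets_aic(
    records: pd.DataFrame,
    candidate_predictors: Sequence[str],
) -> tuple[pd.DataFrame, list[MortalityResults]]:
    """Fit every predictor subset (including intercept-only) and rank by AIC.

    Returns a ranking table (predictors, logL, k, AIC, akaike_weight) and the
    fitted results in the same order. At most 20 candidates (2^p enumeration).
    """
    candidates = list(candidate_predictors)
    if len(candidates) > 20:
        raise ValueError("too many candidate predictors for exhaustive search")
    fits = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            fits.append(MortalityModel(records, subset).fit())
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2)
    w /= w.sum()
    order = np.argsort(aics, kind="stable")
    table = pd.DataFrame({
        "predictors": [" + ".join(fits[i].predictors) or "(intercept)" for i in order],
        "logL": [fits[i].llf for i in order],
        "k": [fits[i].k for i in order],
        "AIC": aics[order],
        "akaike_weight": w[order],
    })
    return table, [fits[i] for i in order]


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test on a 2x2 count table, no continuity correction.

    Returns (chi2, df, p). All expected counts must be positive.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# thinning survival test
# ---------------------------------------------------------------------------

@dataclass
class ThinningTestResult:
    """Envelope + CvM of survivor L(r) under one mortality model."""

    mortality_model: str
    envelope: EnvelopeResult
    cvm: float
    n_survivors: int


def _survivor_l_statistic(r_grid):
    def stat(pat: TypedPointPattern) -> SummaryFunction:
        t = pat.type_labels()[0]
        return center_l(k_translation(pat, t, t, r_grid))
    return stat


def thinning_survival_test(
    colonies_xy,
    window: Window,
    observed_survivor_xy,
    deletion_probs=None,
    r_grid=None,
    nsim: int = 999,
    seed: int = 0,
) -> ThinningTestResult:
    """Does a mortality model predict the surviving colonies' spatial pattern?

    Each replicate deletes exactly ``n_dead = n - n_survivors`` colonies from
    the full pattern by weighted sampling without replacement with weights
    proportional to the per-colony deletion probabilities (``deletion_probs``;
    None means the random mortality model: equal weights). The survivor
    pattern's centered L(r) is computed per replicate and compared with the
    observed 2009 survivor pattern via a 95% envelope and the curvewise CvM.
    """
    colonies_xy = np.asarray(colonies_xy, dtype=float)
    observed_survivor_xy = np.asarray(observed_survivor_xy, dtype=float)
    n = len(colonies_xy)
    n_survivors = len(observed_survivor_xy)
    if not 0 < n_survivors < n:
        raise ValueError("need 0 < n_survivors < n colonies")
    n_dead = n - n_survivors
    if deletion_probs is None:
        label = "random"
        weights = np.full(n, 1.0 / n)
    else:
        label = "logistic"
        weights = np.asarray(deletion_probs, dtype=float)
        if weights.shape != (n,):
            raise ValueError("deletion_probs must have one entry per colony")
        if np.all(weights == 0):
            raise ValueError("all deletion weights are zero")
        weights = weights / weights.sum()
    if r_grid is None:
        r_grid = np.linspace(0.0, 20.0, 201)
    observed = TypedPointPattern(
        window, observed_survivor_xy[:, 0], observed_survivor_xy[:, 1],
        np.full(n_survivors, "A", dtype=object), check_duplicates=False,
    )

    def sampler(s: int) -> TypedPointPattern:
        rng = np.random.default_rng(s)
        dead = rng.choice(n, size=n_dead, replace=False, p=weights)
        keep = np.ones(n, dtype=bool)
        keep[dead] = False
        xy = colonies_xy[keep]
        return TypedPointPattern(
            window, xy[:, 0], xy[:, 1],
            np.full(n_survivors, "A", dtype=object), check_duplicates=False,
        )

    env = critical_envelope(
        observed, sampler, _survivor_l_statistic(r_grid), r_grid,
        nsim=nsim, seed=seed,
    )
    return ThinningTestResult(label, env, cvm_statistic(env.observed, env.sims),
                              n_survivors)


def compare_mortality_models(
    colonies_xy,
    window: Window,
    observed_survivor_xy,
    logistic_probs,
    r_grid=None,
    nsim: int = 999,
    seed: int = 0,
) -> dict[str, ThinningTestResult]:
    """Random vs logistic thinning, independent simulation streams."""
    random_res = thinning_survival_test(
        colonies_xy, window, observed_survivor_xy, None, r_grid, nsim, seed,
    )
    logistic_res = thinning_survival_test(
        colonies_xy, window, observed_survivor_xy, logistic_probs, r_grid,
        nsim, seed + 7_777_777,
    )
    return {"random": random_res, "logistic": logistic_res}
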