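"""Maximum pseudolikelihood fitting of multitype Strauss hard-core models.

The intractable Gibbs likelihood is replaced by the log pseudolikelihood

    log PL(theta) = sum_{data} log lambda_theta(x_i)
                    - sum_{nodes} w_j lambda_theta(u_j),

discretized with the Berman-Turner device: quadrature nodes are the data
points plus a regular dummy grid per type, with counting weights (tile area
divided by the number of same-type nodes in the tile). Because lambda is
log-linear in (log beta, covariate coefficients, log gamma) for fixed
irregular parameters (h, r), the objective is a weighted Poisson log-linear
score maximized by Newton iterations. Irregular parameters are profiled by
grid search and not counted as estimated parameters for AICc.

The public surface follows the Model/Results idiom: build a
`MultiTypeStraussModel` from a pattern and a `ModelSpec`, call `.fit(...)`,
inspect the returned `MSHCResults`.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .mshc import (
    Interaction,
    MSHCParams,
    ModelSpec,
    pair_key,
    simulate_mshc,
)
from .pattern import DistanceCovariate, TypedPointPattern, Window

__all__ = [
    "QuadratureScheme",
    "make_quadrature",
    "MultiTypeStraussModel",
    "MSHCResults",
    "ProfileResult",
    "aicc",
    "akaike_weights",
    "pl_ratio",
    "adapt_h_to_pattern",
    "monte_carlo_lr_test",
    "MonteCarloLRResult",
]


@dataclass
class QuadratureScheme:
    """Berman-Turner nodes: data points plus a per-type dummy grid.

    ``data_index`` is the row of the originating pattern point for data nodes
    and -1 for dummy nodes. Weights are counting weights in square meters and
    sum to the window area within each type.
    """

    x: np.ndarray
    y: np.ndarray
    types: np.ndarray          # type label per node
    is_data: np.ndarray        # bool
    data_index: np.ndarray     # int, -1 for dummies
    weights: np.ndarray        # m^2
    window: Window
    dummy_spacing: float

    def n_nodes(self) -> int:
        return len(self.x)


def make_quadrature(
    pattern: TypedPointPattern,
    window: Window,
    dummy_spacing: float,
    types: Sequence[str] | None = None,
) -> QuadratureScheme:
    """Build a counting-weight quadrature scheme.

    The window is tiled with cells of side ~``dummy_spacing`` (the grid is the
    smallest regular grid with cell sides <= spacing); one dummy node per type
    sits at each tile center, and each node's weight is its tile's area
    divided by the number of same-type nodes in that tile.
    """
    if dummy_spacing <= 0:
        raise ValueError("dummy_spacing must be positive")
    if dummy_spacing > min(window.width, window.height):
        raise ValueError("dummy_spacing exceeds window size")
    if types is None:
        types = pattern.type_labels()
    nx = int(np.ceil(window.width / dummy_spacing))
    ny = int(np.ceil(window.height / dummy_spacing))
    tile_area = (window.width / nx) * (window.height / ny)
    cx = window.x_min + (np.arange(nx) + 0.5) * window.width / nx
    cy = window.y_min + (np.arange(ny) + 0.5) * window.height / ny
    gx, gy = np.meshgrid(cx, cy)
    gx, gy = gx.ravel(), gy.ravel()

    def tile_of(x, y):
        ix = np.clip(((x - window.x_min) / window.width * nx).astype(int), 0, nx - 1)
        iy = np.clip(((y - window.y_min) / window.height * ny).astype(int), 0, ny - 1)
        return iy * nx + ix

    xs, ys, ts, isd, didx, wts = [], [], [], [], [], []
    for t in types:
        sel = np.flatnonzero(pattern.types == t)
        dx, dy = pattern.x[sel], pattern.y[sel]
        node_x = np.concatenate([dx, gx])
        node_y = np.concatenate([dy, gy])
        tiles = tile_of(node_x, node_y)
        counts = np.bincount(tiles, minlength=nx * ny)
        w = tile_area / counts[tiles]
        xs.append(node_x)
        ys.append(node_y)
        ts.append(np.full(len(node_x), t, dtype=object))
        isd.append(np.concatenate([np.ones(len(dx), bool), np.zeros(len(gx), bool)]))
        didx.append(np.concatenate([sel, np.full(len(gx), -1)]))
        wts.append(w)
    return QuadratureScheme(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(ts),
        np.concatenate(isd), np.concatenate(didx).astype(int),
        np.concatenate(wts), window, dummy_spacing,
    )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _annulus_counts(quad, pattern, node_sel, other_type, h, r):
    """Counts of pattern points of ``other_type`` in (h, r] around the
    selected nodes, plus counts at d <= h excluding self (hard-core check)."""
    pts = pattern.coords(other_type)
    nx = quad.x[node_sel]
    ny = quad.y[node_sel]
    t_col = np.zeros(len(nx))
    hard = np.zeros(len(nx), dtype=int)
    if len(pts) == 0:
        return t_col, hard
    tree = cKDTree(pts)
    nodes = np.column_stack([nx, ny])
    in_r = tree.query_ball_point(nodes, r, return_length=True)
    # the annulus is open at h: points at d <= h (including d = 0, i.e. self
    # for data nodes) belong to the hard-core count, not the annulus count
    in_h = tree.query_ball_point(nodes, h, return_length=True)
    self_mask = (quad.types[node_sel] == other_type) & quad.is_data[node_sel]
    t_col = (in_r - in_h).astype(float)
    hard = in_h - self_mask.astype(int)
    return t_col, np.maximum(hard, 0)


@dataclass
class _Design:
    Z: np.ndarray
    w: np.ndarray
    is_data: np.ndarray
    names: list
    dropped_terms: list
    data_hardcore_violation: bool
    n_data: int


def build_design(
    quad: QuadratureScheme,
    pattern: TypedPointPattern,
    spec: ModelSpec,
    covariates: Mapping[str, DistanceCovariate] | None,
    h_r: Mapping[tuple[str, str], tuple[float, float]],
    edge_correction: str = "border",
) -> _Design:
    """Assemble the log-linear design at the quadrature nodes.

    Columns: one intercept per type (log beta), one column per covariate term,
    one annulus-count column per interaction pair (log gamma). Dummy nodes in
    hard-core violation are dropped (their conditional intensity is exactly 0
    and contributes nothing to the integral); a data point in violation makes
    the pattern impossible under the model (log PL = -inf).
    """
    n_nodes = quad.n_nodes()
    cols: list[np.ndarray] = []
    names: list = []
    for t in spec.types:
        cols.append((quad.types == t).astype(float))
        names.append(("log_beta", t))
    for term in spec.covariate_terms:
        if covariates is None or term.name not in covariates:
            raise ValueError(f"covariate {term.name!r} not supplied")
        vals = covariates[term.name](np.column_stack([quad.x, quad.y]))
        mask = np.isin(quad.types.astype(str), term.types)
        cols.append(vals * mask)
        names.append(("covariate", term))
    hard_violation = np.zeros(n_nodes, dtype=bool)
    for pair in spec.pairs:
        pair = pair_key(*pair)
        if pair not in h_r:
            raise ValueError(f"no (h, r) supplied for pair {pair}")
        h, r = h_r[pair]
        if not 0 <= h < r:
            raise ValueError(f"need 0 <= h < r for pair {pair}")
        t_col = np.zeros(n_nodes)
        for m in set(pair):
            other = pair[0] if pair[1] == m else pair[1]
            sel = quad.types == m
            if not np.any(sel):
                continue
            cnt, hard = _annulus_counts(quad, pattern, sel, other, h, r)
            t_col[sel] += cnt
            hard_violation[sel] |= hard > 0
        cols.append(t_col)
        names.append(("log_gamma", pair))
    Z = np.column_stack(cols)
    keep = np.ones(n_nodes, dtype=bool)
    data_violation = bool(np.any(hard_violation & quad.is_data))
    keep &= ~hard_violation
    if edge_correction == "border":
        r_max = max((hr[1] for hr in h_r.values()), default=0.0)
        if r_max > 0:
            bdist = quad.window.boundary_distance(quad.x, quad.y)
            keep &= bdist >= r_max
    elif edge_correction != "none":
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    Z = Z[keep]
    w = quad.weights[keep]
    is_data = quad.is_data[keep]
    # drop interaction columns that are identically zero on the kept nodes
    dropped = []
    active = np.ones(Z.shape[1], dtype=bool)
    for name, j in zip(names, range(Z.shape[1])):
        if name[0] == "log_gamma" and not np.any(Z[:, j] != 0):
            warnings.warn(
                f"interaction term {name[1]} has no pairs in range; "
                "dropping (gamma fixed at 1)", stacklevel=2,
            )
            dropped.append(name[1])
            active[j] = False
    return _Design(
        Z[:, active], w, is_data,
        [n for n, a in zip(names, active) if a],
        dropped, data_violation, int(np.sum(quad.is_data)),
    )


def _newton_poisson(Z, w, is_data, max_iter=100, tol=1e-10):
    """Maximize sum_data Z theta - sum w exp(Z theta) by damped Newton."""
    n, p = Z.shape
    theta = np.zeros(p)
    # crude intercept initialization: log(total data / total weight)
    s_data = Z[is_data].sum(axis=0)

    def objective(th):
        eta = np.clip(Z @ th, -500, 500)
        return float(np.sum(eta[is_data]) - np.sum(w * np.exp(eta)))

    obj = objective(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Z @ theta, -500, 500)
        mu = w * np.exp(eta)
        grad = s_data - Z.T @ mu
        H = (Z * mu[:, None]).T @ Z
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # backtracking line search
        lam = 1.0
        for _ in range(40):
            cand = theta + lam * step
            new_obj = objective(cand)
            if new_obj >= obj - 1e-14:
                break
            lam *= 0.5
        theta = theta + lam * step
        if abs(new_obj - obj) < tol * (1 + abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    return theta, obj, converged, it


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class ProfileResult:
    """Grid profile over irregular parameters (h, r) for one pair."""

    pair: tuple[str, str]
    grid: list = field(default_factory=list)   # (h, r, logpl) triples
    best: tuple[float, float] | None = None
    best_logpl: float = -np.inf


class MSHCResults:
    """Fitted MSHC model: parameter estimates, pseudolikelihood, AICc.

    Attributes
    ----------
    params : MSHCParams
        Fitted parameters (including the fixed/profiled irregular h, r).
    logpl : float
        Maximized log pseudolikelihood (-inf for infeasible hard cores).
    k : int
        Number of regular parameters estimated (log betas, covariate
        coefficients, log gammas); irregular (h, r) are not counted.
    nobs : int
        Number of data points, used as the AICc sample size.
    """

    def __init__(self, model, params, logpl, k, nobs, converged, iterations,
                 dropped_terms=(), h_r=None, profile=None):
        self.model = model
        self.params = params
        self.logpl = float(logpl)
        self.k = int(k)
        self.nobs = int(nobs)
        self.converged = bool(converged)
        self.iterations = int(iterations)
        self.dropped_terms = tuple(dropped_terms)
        self.h_r = dict(h_r or {})
        self.profile = profile

    @property
    def aicc(self) -> float:
        return aicc(self.logpl, self.k, self.nobs)

    @property
    def aic(self) -> float:
        return -2.0 * self.logpl + 2.0 * self.k

    def simulate(self, seed=0, n_steps=100_000, n_draws=1, thin=None, **kw):
        """Draw pattern(s) from the fitted model (unconditional MH)."""
        return simulate_mshc(
            self.params, self.model.pattern.window,
            covariates=self.model.covariates,
            sim_types=self.model.spec.types,
            n_steps=n_steps, seed=seed, n_draws=n_draws, thin=thin, **kw,
        )

    def summary(self) -> str:
        lines = [
            "Multitype Strauss hard-core model (maximum pseudolikelihood)",
            "=" * 62,
            f"types: {', '.join(self.model.spec.types)}   "
            f"n = {self.nobs}   k = {self.k}",
            f"log PL = {self.logpl:.1f}   AICc = {self.aicc:.1f}   "
            f"converged: {self.converged} ({self.iterations} iter)",
            "-" * 62,
            f"{'parameter':<34}{'estimate':>12}",
        ]
        for t in self.model.spec.types:
            lines.append(f"{'log beta_' + t:<34}{self.params.log_beta[t]:>12.4f}")
        for name, coefs in self.params.covariates.items():
            for t, c in coefs.items():
                lines.append(f"{name + ' [' + t + ']':<34}{c:>12.4f}")
        for pair, inter in self.params.interactions.items():
            tag = "".join(pair)
            lines.append(
                f"{'gamma_' + tag:<34}{inter.gamma:>12.4f}"
                f"   (h = {inter.h:g} m, r = {inter.r:g} m)"
            )
        if self.dropped_terms:
            lines.append(f"dropped (no pairs in range): {self.dropped_terms}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MSHCResults logPL={self.logpl:.1f} k={self.k} "
            f"nobs={self.nobs} converged={self.converged}>"
        )


class MultiTypeStraussModel:
    """Multitype Strauss hard-core Gibbs model bound to an observed pattern.

    Parameters
    ----------
    pattern :
        The observed typed point pattern.
    spec :
        Which interaction pairs and covariate terms the model carries
        (`ModelSpec.reduced` / `ModelSpec.full` are the common cases).
    covariates :
        Named `DistanceCovariate` fields referenced by the spec.
    dummy_spacing :
        Berman-Turner dummy grid spacing in meters (default: window side /
        20, capped so the grid has at least 10x10 tiles).
    edge_correction :
        'border' restricts the pseudolikelihood score to nodes at least
        r_max from the boundary; 'none' uses all nodes.
    """

    def __init__(
        self,
        pattern: TypedPointPattern,
        spec: ModelSpec,
        covariates: Mapping[str, DistanceCovariate] | None = None,
        dummy_spacing: float | None = None,
        edge_correction: str = "border",
        quad: QuadratureScheme | None = None,
    ) -> None:
        self.pattern = pattern
        self.spec = spec
        self.covariates = dict(covariates or {})
        if dummy_spacing is None:
            dummy_spacing = min(pattern.window.width, pattern.window.height) / 20
        self.dummy_spacing = dummy_spacing
        self.edge_correction = edge_correction
        self.quad = quad or make_quadrature(
            pattern, pattern.window, dummy_spacing, types=spec.types
        )
        self._nobs = int(np.sum(np.isin(pattern.types.astype(str), spec.types)))

    # -- fitting -----------------------------------------------------------
    def fit(self, h_r: Mapping[tuple[str, str], tuple[float, float]] | None = None,
            max_iter: int = 100) -> MSHCResults:
        """Maximize the pseudolikelihood at fixed irregular parameters.

        ``h_r`` maps each interaction pair in the spec to its (hard-core,
        interaction-range) pair in meters. A data pattern violating a hard
        core yields an infeasible result with log PL = -inf.
        """
        h_r = {pair_key(*k): v for k, v in (h_r or {}).items()}
        design = build_design(
            self.quad, self.pattern, self.spec, self.covariates, h_r,
            self.edge_correction,
        )
        if design.data_hardcore_violation:
            params = self._assemble_params(None, design.names, h_r)
            return MSHCResults(self, params, -np.inf, len(design.names),
                               self._nobs, False, 0, design.dropped_terms, h_r)
        theta, logpl, converged, iters = _newton_poisson(
            design.Z, design.w, design.is_data, max_iter=max_iter
        )
        params = self._assemble_params(theta, design.names, h_r)
        return MSHCResults(self, params, logpl, len(theta), self._nobs,
                           converged, iters, design.dropped_terms, h_r)

    def fit_profile(
        self,
        pair: tuple[str, str],
        h_candidates: Sequence[float],
        r_candidates: Sequence[float],
        h_r_fixed: Mapping[tuple[str, str], tuple[float, float]] | None = None,
        max_iter: int = 100,
    ) -> MSHCResults:
        """Profile the irregular (h, r) of one pair over a grid, refitting the
        regular parameters at each grid point; returns the best fit with the
        profile attached as ``.profile``."""
        pair = pair_key(*pair)
        base = {pair_key(*k): v for k, v in (h_r_fixed or {}).items()}
        prof = ProfileResult(pair)
        best_fit = None
        for h, r in itertools.product(h_candidates, r_candidates):
            if not 0 <= h < r:
                continue
            res = self.fit({**base, pair: (float(h), float(r))}, max_iter=max_iter)
            prof.grid.append((float(h), float(r), res.logpl))
            if res.logpl > prof.best_logpl:
                prof.best_logpl = res.logpl
                prof.best = (float(h), float(r))
                best_fit = res
        if best_fit is None:
            raise RuntimeError("all profile grid points were infeasible")
        best_fit.profile = prof
        return best_fit

    def _assemble_params(self, theta, names, h_r) -> MSHCParams:
        log_beta = {t: 0.0 for t in self.spec.types}
        covs: dict[str, dict[str, float]] = {}
        inters: dict[tuple[str, str], Interaction] = {}
        for pair in self.spec.pairs:
            p = pair_key(*pair)
            if p in h_r:
                inters[p] = Interaction(h_r[p][0], h_r[p][1], 1.0)
        if theta is not None:
            for (kind, key), val in zip(names, theta):
                if kind == "log_beta":
                    log_beta[key] = float(val)
                elif kind == "covariate":
                    covs.setdefault(key.name, {})
                    for t in key.types:
                        covs[key.name][t] = float(val)
                elif kind == "log_gamma":
                    h, r = h_r[key]
                    inters[key] = Interaction(h, r, float(np.exp(val)))
        return MSHCParams(self.spec.types, log_beta, covs, inters)


# ---------------------------------------------------------------------------
# information criteria, model comparison
# ---------------------------------------------------------------------------

def aicc(logpl: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction:
    -2 logPL + 2k + 2k(k+1)/(n-k-1). Requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logpl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aic_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)."""
    a = np.asarray(aic_values, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two models")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def pl_ratio(full, reduced) -> float:
    """Log-pseudolikelihood ratio Delta = 2 (logPL_full - logPL_reduced).

    Accepts MSHCResults or raw log-pseudolikelihood floats. A negative Delta
    indicates optimizer failure on the full model and triggers a warning.
    """
    lf = full.logpl if hasattr(full, "logpl") else float(full)
    lr = reduced.logpl if hasattr(reduced, "logpl") else float(reduced)
    delta = 2.0 * (lf - lr)
    if delta < 0:
        warnings.warn(
            f"negative pseudolikelihood ratio ({delta:.3f}): the full-model "
            "optimizer did not reach the reduced-model optimum", stacklevel=2,
        )
    return delta


def adapt_h_to_pattern(pattern: TypedPointPattern, h_r: Mapping) -> dict:
    """Clamp each pair's hard core below the minimum observed pair distance.

    Hard-core distances are irregular parameters whose natural data-driven
    estimate is (just below) the smallest observed interpoint distance for the
    pair; a fixed h larger than that makes the pattern impossible under the
    model. Returns a copy of ``h_r`` with each h replaced by
    min(h, 0.999 * d_min) for that pair (r is unchanged).
    """
    from .pattern import nn_distance

    out = {}
    for pair, (h, r) in h_r.items():
        a, b = pair_key(*pair)
        if h > 0:
            d = nn_distance(pattern, a, b)
            if d.size:
                h = min(h, 0.999 * float(d.min()))
        out[pair_key(a, b)] = (h, r)
    return out


@dataclass
class MonteCarloLRResult:
    """Outcome of the Monte-Carlo log-pseudolikelihood-ratio test."""

    delta_obs: float
    p_value: float
    delta_sims: np.ndarray
    n_failed: int
    reduced_fit: MSHCResults
    full_fit: MSHCResults


def monte_carlo_lr_test(
    pattern: TypedPointPattern,
    reduced_spec: ModelSpec,
    full_spec: ModelSpec,
    h_r_reduced: Mapping,
    h_r_full: Mapping,
    covariates: Mapping[str, DistanceCovariate] | None = None,
    nsim: int = 99,
    seed: int = 0,
    sim_steps: int = 20_000,
    dummy_spacing: float | None = None,
    edge_correction: str = "border",
) -> MonteCarloLRResult:
    """Parametric Monte-Carlo test of the interspecific interaction.

    Fits the reduced and full models to the data (Delta_obs), simulates
    ``nsim`` patterns from the fitted reduced model, refits both models to
    each, and reports p = (1 + #{Delta_sim >= Delta_obs}) / (nsim + 1).
    Replicates whose fits fail (non-convergence or empty types) are dropped
    with a warning; more than 10% failures aborts.
    """
    if nsim < 19:
        raise ValueError("nsim must be at least 19")
    if not reduced_spec.is_nested_in(full_spec):
        raise ValueError("reduced spec must be nested in the full spec")

    def fit_both(pat):
        mk = dict(covariates=covariates, dummy_spacing=dummy_spacing,
                  edge_correction=edge_correction)
        red = MultiTypeStraussModel(pat, reduced_spec, **mk).fit(
            adapt_h_to_pattern(pat, h_r_reduced))
        ful = MultiTypeStraussModel(pat, full_spec, **mk).fit(
            adapt_h_to_pattern(pat, h_r_full))
        return red, ful

    red_obs, full_obs = fit_both(pattern)
    delta_obs = pl_ratio(full_obs, red_obs)
    deltas = []
    n_failed = 0
    for i in range(nsim):
        sim = simulate_mshc(
            red_obs.params, pattern.window, covariates=covariates,
            sim_types=reduced_spec.types, n_steps=sim_steps, seed=seed * 100_003 + i,
        )
        try:
            counts = sim.n_by_type()
            if any(counts.get(t, 0) == 0 for t in reduced_spec.types):
                raise RuntimeError("simulated pattern lost a type")
            r, f = fit_both(sim)
            if not (np.isfinite(r.logpl) and np.isfinite(f.logpl)):
                raise RuntimeError("non-finite simulated fit")
            deltas.append(2.0 * (f.logpl - r.logpl))
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            warnings.warn(f"replicate {i} dropped: {exc}", stacklevel=2)
    if n_failed > 0.1 * nsim:
        raise RuntimeError(f"{n_failed}/{nsim} simulation fits failed")
    deltas = np.asarray(deltas)
    p = (1.0 + np.sum(deltas >= delta_obs)) / (len(deltas) + 1.0)
    return MonteCarloLRResult(delta_obs, float(p), deltas, n_failed,
                              red_obs, full_obs)
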