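"""Multitype Strauss hard-core (MSHC) Gibbs model: parameters, conditional
intensity, and Metropolis-Hastings simulation.

The model describes a multitype point pattern through its Papangelou
conditional intensity

    lambda(u, m | x) = beta_m * exp(sum_c coef_c * covariate_c(u))
                       * prod_p gamma_p ^ t_p(u, m | x)

where, for each active unordered type pair p = {m, m'}, t_p counts points of
the opposing type in the annulus h_p < d <= r_p around u, and lambda is 0 when
any point of the paired type lies at distance d <= h_p (hard core: structures
cannot physically coexist closer than h_p). gamma_p > 1 encodes attraction,
gamma_p = 1 no interaction, 0 <= gamma_p < 1 repulsion; all pair parameters
are symmetric across the pair.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import _sampler
from .pattern import DistanceCovariate, TypedPointPattern, Window

__all__ = [
    "Interaction",
    "MSHCParams",
    "CovariateTerm",
    "ModelSpec",
    "pair_key",
    "pair_count",
    "conditional_intensity",
    "simulate_mshc",
    "simulate_conditional_on_n",
]


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered type pair."""
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class Interaction:
    """Symmetric pairwise interaction: hard core h, range r, strength gamma."""

    h: float
    r: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h < self.r):
            raise ValueError(f"need 0 <= h < r, got h={self.h}, r={self.r}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


@dataclass
class MSHCParams:
    """Full parameter set of a multitype Strauss hard-core model.

    ``log_beta`` maps type label to log first-order intensity (log points per
    square meter); ``covariates`` maps covariate name to a per-type
    coefficient map (types absent from the map have coefficient zero);
    ``interactions`` maps unordered pair keys to Interaction triples.
    """

    types: tuple[str, ...]
    log_beta: dict[str, float]
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    interactions: dict[tuple[str, str], Interaction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.types = tuple(self.types)
        self.interactions = {pair_key(*k): v for k, v in self.interactions.items()}
        for t in self.types:
            if t not in self.log_beta:
                raise ValueError(f"missing log_beta for type {t!r}")

    def beta(self, m: str) -> float:
        return math.exp(self.log_beta[m])

    def interaction(self, a: str, b: str) -> Interaction | None:
        return self.interactions.get(pair_key(a, b))

    def max_range(self) -> float:
        """Largest interaction range over active pairs (0 when none)."""
        return max((i.r for i in self.interactions.values()), default=0.0)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "types": list(self.types),
            "log_beta": {k: float(v) for k, v in self.log_beta.items()},
            "covariates": {k: {t: float(c) for t, c in v.items()}
                           for k, v in self.covariates.items()},
            "interactions": {
                "|".join(k): {"h": float(v.h), "r": float(v.r),
                              "gamma": float(v.gamma)}
                for k, v in self.interactions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MSHCParams":
        inter = {
            tuple(k.split("|")): Interaction(**v)
            for k, v in d.get("interactions", {}).items()
        }
        return cls(
            types=tuple(d["types"]),
            log_beta=dict(d["log_beta"]),
            covariates={k: dict(v) for k, v in d.get("covariates", {}).items()},
            interactions=inter,  # type: ignore[arg-type]
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "MSHCParams":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class CovariateTerm:
    """A covariate entering the log-intensity of the listed types with one
    shared coefficient."""

    name: str
    types: tuple[str, ...]


@dataclass(frozen=True)
class ModelSpec:
    """Which interaction pairs and covariate terms a model carries.

    The reduced model (intraspecific interactions only) is nested in the full
    model (intra- plus interspecific interaction).
    """

    types: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    covariate_terms: tuple[CovariateTerm, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(pair_key(*p) for p in self.pairs))

    @classmethod
    def reduced(cls, types=("K", "A"), covariate_terms=()) -> "ModelSpec":
        """Intraspecific interactions only."""
        return cls(tuple(types), tuple((t, t) for t in types), tuple(covariate_terms))

    @classmethod
    def full(cls, types=("K", "A"), covariate_terms=()) -> "ModelSpec":
        """Intra- plus all interspecific pair interactions."""
        types = tuple(types)
        pairs = [(t, t) for t in types]
        pairs += [(a, b) for i, a in enumerate(types) for b in types[i + 1:]]
        return cls(types, tuple(pairs), tuple(covariate_terms))

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            set(self.pairs) <= set(other.pairs)
            and set(self.covariate_terms) <= set(other.covariate_terms)
            and set(self.types) <= set(other.types)
        )


# ---------------------------------------------------------------------------
# conditional intensity (reference numpy implementation)
# ---------------------------------------------------------------------------

def pair_count(
    u,
    m: str,
    pattern: TypedPointPattern,
    pair: tuple[str, str],
    h: float,
    r: float,
    exclude_index: int | None = None,
) -> int:
    """Number of pattern points of the pair-opposing type at distance
    h < d <= r from location u (self excluded via ``exclude_index``)."""
    if h >= r:
        raise ValueError("need h < r")
    pair = pair_key(*pair)
    if m not in pair:
        return 0
    other = pair[0] if pair[1] == m else pair[1]
    sel = pattern.types == other
    if exclude_index is not None:
        sel = sel.copy()
        sel[exclude_index] = False
    pts = np.column_stack([pattern.x[sel], pattern.y[sel]])
    if len(pts) == 0:
        return 0
    d = np.hypot(pts[:, 0] - u[0], pts[:, 1] - u[1])
    return int(np.sum((d > h) & (d <= r)))


def conditional_intensity(
    u,
    m: str,
    pattern: TypedPointPattern,
    params: MSHCParams,
    covariates: Mapping[str, DistanceCovariate] | None = None,
    exclude_index: int | None = None,
) -> float:
    """Papangelou conditional intensity lambda(u, m | pattern).

    Returns 0 when any relevant point violates a hard core around u. The
    gamma_p = 0 strong-inhibition limit with t_p > 0 also returns 0.
    """
    value = params.beta(m)
    for pair, inter in params.interactions.items():
        if m not in pair:
            continue
        other = pair[0] if pair[1] == m else pair[1]
        sel = pattern.types == other
        if exclude_index is not None:
            sel = sel.copy()
            sel[exclude_index] = False
        xs, ys = pattern.x[sel], pattern.y[sel]
        if len(xs) == 0:
            continue
        d = np.hypot(xs - u[0], ys - u[1])
        if np.any(d <= inter.h):
            return 0.0
        t = int(np.sum((d > inter.h) & (d <= inter.r)))
        if t:
            if inter.gamma == 0.0:
                return 0.0
            value *= inter.gamma ** t
    for name, coefs in params.covariates.items():
        coef = coefs.get(m, 0.0)
        if coef and covariates is not None and name in covariates:
            value *= math.exp(coef * float(covariates[name](np.asarray(u, float))))
    return value


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _pack_arrays(params: MSHCParams, covariates):
    """Flatten params/covariates into the arrays the numba kernel consumes."""
    types = list(params.types)
    nt = len(types)
    code = {t: i for i, t in enumerate(types)}
    log_beta = np.array([params.log_beta[t] for t in types])
    h2 = np.zeros((nt, nt))
    r2 = np.zeros((nt, nt))
    gamma = np.ones((nt, nt))
    for (a, b), inter in params.interactions.items():
        ia, ib = code[a], code[b]
        h2[ia, ib] = h2[ib, ia] = inter.h ** 2
        r2[ia, ib] = r2[ib, ia] = inter.r ** 2
        gamma[ia, ib] = gamma[ib, ia] = inter.gamma
    cov_names = [n for n in params.covariates if covariates and n in covariates]
    cov_coef = np.zeros((len(cov_names), nt))
    rx, ry, off = [], [], [0]
    for ci, name in enumerate(cov_names):
        for t, c in params.covariates[name].items():
            if t in code:
                cov_coef[ci, code[t]] = c
        refs = covariates[name].reference_points
        rx.extend(refs[:, 0])
        ry.extend(refs[:, 1])
        off.append(len(rx))
    cov_rx = np.asarray(rx, dtype=float)
    cov_ry = np.asarray(ry, dtype=float)
    cov_off = np.asarray(off, dtype=np.int64)
    return code, log_beta, h2, r2, gamma, cov_coef, cov_rx, cov_ry, cov_off


def _chain(
    params: MSHCParams,
    window: Window,
    covariates,
    sim_types,
    seed: int,
    n_burn: int,
    n_draws: int,
    thin: int,
    fixed_pattern: TypedPointPattern | None,
    initial: np.ndarray | None,
    initial_types: np.ndarray | None,
    fixed_n: bool,
    capacity: int | None,
    proposal_probs=(0.35, 0.35, 0.30),
):
    code, log_beta, h2, r2, gamma, cov_coef, cov_rx, cov_ry, cov_off = _pack_arrays(
        params, covariates
    )
    sim_codes = np.asarray([code[t] for t in sim_types], dtype=np.int64)
    if fixed_pattern is not None:
        fx = fixed_pattern.x
        fy = fixed_pattern.y
        ft = np.asarray([code[t] for t in fixed_pattern.types], dtype=np.int64)
    else:
        fx = np.zeros(0)
        fy = np.zeros(0)
        ft = np.zeros(0, dtype=np.int64)
    n_fixed = len(fx)
    n0 = 0 if initial is None else len(initial)
    if capacity is None:
        expected = sum(params.beta(t) for t in sim_types) * window.area
        capacity = max(int(20 * max(expected, 1.0)), n0 + 10, 200)
    px = np.zeros(n_fixed + capacity)
    py = np.zeros(n_fixed + capacity)
    pt = np.zeros(n_fixed + capacity, dtype=np.int64)
    px[:n_fixed] = fx
    py[:n_fixed] = fy
    pt[:n_fixed] = ft
    if initial is not None:
        px[n_fixed:n_fixed + n0] = initial[:, 0]
        py[n_fixed:n_fixed + n0] = initial[:, 1]
        pt[n_fixed:n_fixed + n0] = initial_types
    p_birth, p_death, _ = proposal_probs
    status, out_n, out_x, out_y, out_t, trace = _sampler.run_chain(
        int(seed) % (2**31 - 1), int(n_burn), int(n_draws), int(thin), int(capacity),
        px, py, pt, n_fixed, n0, sim_codes,
        window.x_min, window.x_max, window.y_min, window.y_max,
        log_beta, h2, r2, gamma,
        cov_coef, cov_rx, cov_ry, cov_off,
        float(p_birth), float(p_death), fixed_n,
    )
    if status == _sampler.CAPACITY_EXCEEDED:
        raise RuntimeError(
            f"sampler exceeded safety capacity {capacity}; trace of active "
            f"counts (every 100 proposals): {trace[:20].tolist()}..."
        )
    inv = {v: k for k, v in code.items()}
    draws = []
    for k in range(n_draws):
        n = out_n[k]
        draws.append(
            TypedPointPattern(
                window, out_x[k, :n].copy(), out_y[k, :n].copy(),
                np.asarray([inv[c] for c in out_t[k, :n]], dtype=object),
                check_duplicates=False,
            )
        )
    return draws


def simulate_mshc(
    params: MSHCParams,
    window: Window,
    covariates: Mapping[str, DistanceCovariate] | None = None,
    sim_types: tuple[str, ...] | None = None,
    n_steps: int = 100_000,
    seed: int = 0,
    fixed_pattern: TypedPointPattern | None = None,
    n_draws: int = 1,
    thin: int | None = None,
    capacity: int | None = None,
) -> TypedPointPattern | list[TypedPointPattern]:
    """Approximate draw(s) from the MSHC model by birth/death/shift MH.

    ``fixed_pattern`` supplies conditioning points (e.g. a mound layer held
    fixed while colonies are simulated). With ``n_draws > 1`` a single chain
    is run and thinned (default thin = n_steps // 4), returning a list.
    Hard cores are respected exactly in every returned pattern.
    """
    if sim_types is None:
        sim_types = params.types
    if thin is None:
        thin = max(n_steps // 4, 1)
    draws = _chain(
        params, window, covariates, tuple(sim_types), seed,
        n_burn=n_steps, n_draws=n_draws, thin=thin,
        fixed_pattern=fixed_pattern, initial=None, initial_types=None,
        fixed_n=False, capacity=capacity,
    )
    return draws[0] if n_draws == 1 else draws


def _feasible_start(params, window, covariates, n_per_type, fixed_pattern, seed):
    """Random sequential placement respecting all hard cores."""
    rng = np.random.default_rng(seed)
    placed_xy: list[tuple[float, float]] = []
    placed_t: list[str] = []
    scratch = fixed_pattern
    order = [t for t, n in n_per_type.items() for _ in range(n)]
    for t in order:
        ok = False
        for _ in range(2000):
            u = (
                rng.uniform(window.x_min, window.x_max),
                rng.uniform(window.y_min, window.y_max),
            )
            lam = _start_ok(u, t, placed_xy, placed_t, scratch, params)
            if lam:
                placed_xy.append(u)
                placed_t.append(t)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {n_per_type} points under the hard cores "
                "(infeasible packing)"
            )
    return np.asarray(placed_xy), np.asarray(placed_t, dtype=object)


def _start_ok(u, m, placed_xy, placed_t, fixed_pattern, params) -> bool:
    for (x, y), t in zip(placed_xy, placed_t):
        inter = params.interaction(m, t)
        if inter and math.hypot(x - u[0], y - u[1]) <= inter.h:
            return False
    if fixed_pattern is not None:
        for x, y, t in zip(fixed_pattern.x, fixed_pattern.y, fixed_pattern.types):
            inter = params.interaction(m, t)
            if inter and math.hypot(x - u[0], y - u[1]) <= inter.h:
                return False
    return True


def simulate_conditional_on_n(
    params: MSHCParams,
    window: Window,
    n_per_type: Mapping[str, int],
    seed: int = 0,
    covariates: Mapping[str, DistanceCovariate] | None = None,
    n_steps: int = 100_000,
    fixed_pattern: TypedPointPattern | None = None,
    n_draws: int = 1,
    thin: int | None = None,
) -> TypedPointPattern | list[TypedPointPattern]:
    """Fixed-count MSHC simulation: shift-only MH at the given counts.

    Useful for envelope tests conditioned on the observed numbers of points.
    Raises if the requested counts cannot be packed under the hard cores.
    """
    init_xy, init_t = _feasible_start(
        params, window, covariates, dict(n_per_type), fixed_pattern, seed
    )
    if thin is None:
        thin = max(n_steps // 4, 1)
    n0 = len(init_xy)
    code = {t: i for i, t in enumerate(params.types)}
    initial_types = np.asarray([code[t] for t in init_t], dtype=np.int64)
    draws = _chain(
        params, window, covariates, tuple(n_per_type.keys()), seed + 1,
        n_burn=n_steps, n_draws=n_draws, thin=thin,
        fixed_pattern=fixed_pattern,
        initial=init_xy if n0 else None,
        initial_types=initial_types if n0 else None,
        fixed_n=True, capacity=max(n0 + 1, 10),
    )
    return draws[0] if n_draws == 1 else draws
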