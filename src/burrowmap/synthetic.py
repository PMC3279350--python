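"""Synthetic mound/colony datasets with known ground truth.

The field coordinates behind the original survey are not publicly deposited,
so this generator emulates the study system: a near-regular layer of occupied
kangaroo-rat mounds (strong intraspecific repulsion out to ~30 m), an
independent unoccupied-mound layer used only to build a spatial covariate, a
harvester-ant colony layer with intraspecific repulsion out to ~20 m and a
small-scale cross-type attraction to occupied mounds (<10 m), lognormal disc
diameter marks on the cohort scale of the field tables, and mortality
outcomes drawn from a known logistic model whose covariates are computed by
the same operations the analysis uses. Every stage is reproducible from the
config seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .mortality import build_colony_records
from .mshc import Interaction, MSHCParams, simulate_conditional_on_n, simulate_mshc
from .pattern import DistanceCovariate, TypedPointPattern, Window

__all__ = ["SyntheticConfig", "generate_structures", "generate_mortality",
           "generate_dataset"]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _pure_hard_core(h: float) -> Interaction:
    """Hard core at h with no Strauss interaction (gamma = 1)."""
    return Interaction(h, h * 1.001 + 1e-9, 1.0)


@dataclass
class SyntheticConfig:
    """Ground-truth configuration of the synthetic study system.

    Defaults are anchored to the published study system: a 397 x 220 m plot,
    48 occupied mounds, intraspecific repulsion to 30 m (mounds) and 20 m
    (colonies), cross-type attraction gamma_KA = 3.7 on the annulus
    (1, 5.1] m, cohort disc-diameter means of ~109 cm (established) and
    ~33 cm (recent), and recent-cohort mortality coefficients
    (intercept 1.275, disc -0.029, influence +0.073, mound distance +0.037).
    """

    window: Window = field(default_factory=lambda: Window(0.0, 397.0, 0.0, 220.0))
    n_occupied_mounds: int = 48
    n_unoccupied_mounds: int = 20
    colony_log_intensity: float = -5.0    # log colonies per m^2 -> ~200 colonies
    mound_interaction: Interaction = field(
        default_factory=lambda: Interaction(10.0, 30.0, 0.2))
    colony_interaction: Interaction = field(
        default_factory=lambda: Interaction(4.0, 20.0, 0.5))
    cross_interaction: Interaction = field(
        default_factory=lambda: Interaction(1.0, 5.1, 3.7))  # published-scale cross attraction
    unoccupied_covariate_coef: float = 0.01   # colony repulsion from unoccupied mounds
    p_recent: float = 0.44                    # 162 of 366 colonies were recent
    disc_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "established": (109.4, 41.0),  # cohort mean; sd from SE 2.9 * sqrt(204)
            "recent": (33.3, 34.0),        # cohort mean; sd from SE 2.7 * sqrt(162)
        })
    mortality_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 1.275,               # recent-cohort fitted values
            "disc_diameter_cm": -0.029,
            "influence_index": 0.073,  
            "nearest_mound_distance": 0.037,
        })
    sampler_steps: int = 100_000
    seed: int = 0


def generate_structures(config: SyntheticConfig) -> TypedPointPattern:
    """Draw one synthetic structure map: occupied mounds (K), colonies (A),
    and unoccupied mounds (U, covariate layer only).

    Mounds are simulated at fixed counts (shift-only chain); colonies are an
    unconditional draw from the MSHC model given the mound layers, with the
    cross attraction to occupied mounds and a mild repulsion covariate from
    unoccupied mounds. Disc-diameter marks and cohorts are attached to
    colonies.
    """
    w = config.window
    seed = config.seed
    kk = config.mound_interaction
    # unoccupied mounds: independent pure hard-core layer
    unocc_params = MSHCParams(("U",), {"U": 0.0},
                              interactions={("U", "U"): _pure_hard_core(kk.h)})
    unocc = simulate_conditional_on_n(
        unocc_params, w, {"U": config.n_unoccupied_mounds}, seed=seed,
        n_steps=config.sampler_steps // 4,
    )
    # occupied mounds: intraspecific Strauss hard core, fixed count,
    # hard core against the unoccupied layer so mounds never overlap
    mound_params = MSHCParams(
        ("K", "U"), {"K": 0.0, "U": 0.0},
        interactions={
            ("K", "K"): kk,
            ("K", "U"): _pure_hard_core(kk.h),
        })
    mounds = simulate_conditional_on_n(
        mound_params, w, {"K": config.n_occupied_mounds}, seed=seed + 1,
        n_steps=config.sampler_steps, fixed_pattern=unocc,
    )
    # colonies: unconditional draw given the mound layers
    colony_params = MSHCParams(
        ("A", "K", "U"),
        {"A": config.colony_log_intensity, "K": 0.0, "U": 0.0},
        covariates={"dist_unoccupied_mound": {"A": config.unoccupied_covariate_coef}},
        interactions={
            ("A", "A"): config.colony_interaction,
            ("A", "K"): config.cross_interaction,
        })
    cov = {"dist_unoccupied_mound": DistanceCovariate(unocc.coords("U"))}
    fixed = TypedPointPattern(
        w,
        np.concatenate([mounds.x, unocc.x]),
        np.concatenate([mounds.y, unocc.y]),
        np.concatenate([mounds.types, unocc.types]),
        check_duplicates=False,
    )
    colonies = simulate_mshc(
        colony_params, w, covariates=cov, sim_types=("A",),
        n_steps=config.sampler_steps, seed=seed + 2, fixed_pattern=fixed,
    )
    # assemble with marks
    rng = np.random.default_rng(seed + 3)
    n_a = colonies.n
    cohort = np.where(rng.random(n_a) < config.p_recent, "recent", "established")
    disc = np.empty(n_a)
    for coh, (mean, sd) in config.disc_mean_sd.items():
        mu, sigma = _lognormal_params(mean, sd)
        sel = cohort == coh
        disc[sel] = rng.lognormal(mu, sigma, int(sel.sum()))
    x = np.concatenate([mounds.x, unocc.x, colonies.x])
    y = np.concatenate([mounds.y, unocc.y, colonies.y])
    types = np.concatenate([
        np.full(mounds.n, "K", dtype=object),
        np.full(unocc.n, "U", dtype=object),
        colonies.types,
    ])
    marks = pd.DataFrame({
        "disc_diameter_cm": np.concatenate(
            [np.full(mounds.n + unocc.n, np.nan), disc]),
        "occupied": np.concatenate(
            [np.ones(mounds.n, bool), np.zeros(unocc.n, bool),
             np.zeros(n_a, bool)]),
        "cohort": np.concatenate(
            [np.full(mounds.n + unocc.n, "", dtype=object), cohort]),
    })
    return TypedPointPattern(w, x, y, types, marks=marks, check_duplicates=False)


def generate_mortality(
    pattern: TypedPointPattern,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Draw colony death outcomes from the configured logistic model.

    Covariates (influence index, nearest-occupied-mound distance) are computed
    with the same operations the analysis pipeline uses, then
    died ~ Bernoulli(expit(linear predictor)). Returns the colony records with
    covariates, death probabilities, and outcomes attached.
    """
    colonies = pattern.to_frame().query("type == 'A'").reset_index(drop=True)
    records = build_colony_records(colonies, pattern.coords("K"))
    coefs = dict(config.mortality_coefficients)
    lp = np.full(len(records), coefs.get("intercept", 0.0))
    for name, c in coefs.items():
        if name != "intercept":
            lp += c * records[name].to_numpy(float)
    p = expit(lp)
    rng = np.random.default_rng(config.seed + 4)
    records["death_probability"] = p
    records["died"] = rng.random(len(records)) < p
    return records


def generate_dataset(config: SyntheticConfig | None = None):
    """Structures plus mortality outcomes in one call.

    Returns ``(pattern, records)``: the full structure map and the colony
    records table with ground-truth death probabilities and outcomes.
    """
    config = config or SyntheticConfig()
    pattern = generate_structures(config)
    records = generate_mortality(pattern, config)
    return pattern, records
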