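"""Synthetic inputs for every analysis stage, with known ground truth.

All generators are pure functions of (spec, seed): replicate-level DOE
outcome tables with planted factor main effects, toy stoichiometric
networks with closed-form optima, resonator mode observations from the
densitometry forward model, and linear regression datasets on the
process-factor grid.

Replicate noise on concentrations is multiplicative log-normal by
default — measured concentrations span four orders of magnitude across
runs, so a relative noise scale is the realistic choice — with additive
gaussian noise available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import density as rmm
from .datasets import hydrolysis_design, load_snr_reference
from .fba import MetabolicModel, Reaction, Transporter
from .taguchi import DesignMatrix, OutcomeTable

# --------------------------------------------------------------------- DOE


@dataclass
class DOESimSpec:
    """Planted-effect specification for a DOE outcome table.

    `effects` maps factor → {level: effect}; effects are expressed in dB
    of the larger-the-better S/N statistic (i.e. multiplicatively,
    10^(effect/20)) by default, or added to the baseline directly with
    ``scale="additive"``.
    """

    baseline: float = 1000.0
    effects: dict[str, dict[float, float]] = field(default_factory=dict)
    noise_sd: float = 0.05
    replicates: int = 2
    scale: str = "db"
    noise: str = "lognormal"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.scale not in ("db", "additive"):
            raise ValueError("scale must be 'db' or 'additive'")
        if self.noise not in ("lognormal", "gaussian"):
            raise ValueError("noise must be 'lognormal' or 'gaussian'")


def screen_like_effects(outcome: str = "r_total") -> dict[str, dict[float, float]]:
    """Planted dB-scale effects mirroring the screen's observed structure.

    Derived from the packaged per-level S/N averages of the chosen
    reference outcome column (centered per factor), so the planted
    ordering of factor importances matches the published screen
    (%Acid ≫ %Solid > time > temperature for every sugar outcome).
    """
    ref = load_snr_reference()
    design = hydrolysis_design()
    snr = ref[outcome].to_numpy(dtype=float)
    effects: dict[str, dict[float, float]] = {}
    for f in design.factors:
        per_level = {
            level: float(np.mean([snr[j] for j in design.runs_at(f.name, level)]))
            for level in f.levels
        }
        center = float(np.mean(list(per_level.values())))
        effects[f.name] = {lv: v - center for lv, v in per_level.items()}
    return effects


def gen_doe_dataset(
    spec: DOESimSpec, seed: int, design: DesignMatrix | None = None
) -> tuple[OutcomeTable, dict[str, dict[float, float]]]:
    """An outcome table over `design` with planted effects, plus the truth."""
    rng = np.random.default_rng(seed)
    if design is None:
        design = hydrolysis_design()
    means = np.empty(design.n_runs)
    for j, run in enumerate(design.runs):
        total = sum(
            spec.effects.get(name, {}).get(level, 0.0)
            for name, level in run.items()
        )
        if spec.scale == "db":
            means[j] = spec.baseline * 10.0 ** (total / 20.0)
        else:
            means[j] = spec.baseline + total
    reps = np.empty((design.n_runs, spec.replicates))
    for j in range(design.n_runs):
        z = rng.standard_normal(spec.replicates)
        if spec.noise == "lognormal":
            reps[j] = means[j] * np.exp(spec.noise_sd * z)
        else:
            reps[j] = means[j] + spec.noise_sd * z
    reps = np.maximum(reps, 0.0)
    return OutcomeTable(outcome="synthetic", replicates=reps), spec.effects


# --------------------------------------------------------------- toy models


@dataclass
class ToyModelExpectation:
    """Closed-form reference values recorded with a generated toy model."""

    max_growth: float
    fva: dict[str, tuple[float, float]] = field(default_factory=dict)


def linear_chain_model(uptake_cap: float = 10.0) -> tuple[MetabolicModel, ToyModelExpectation]:
    """Substrate → A → biomass chain; MaxGrowth equals the uptake cap."""
    model = MetabolicModel(
        metabolites=["s", "a"],
        reactions=[
            Reaction("EX_s", {"s": -1.0}, lb=-uptake_cap, ub=0.0),
            Reaction("conv", {"s": -1.0, "a": 1.0}, lb=0.0),
            Reaction("growth", {"a": -1.0}, lb=0.0),
        ],
        growth_reaction="growth",
        media_transporters=[Transporter("EX_s", "substrate", 100.0)],
    )
    return model, ToyModelExpectation(max_growth=uptake_cap)


def branched_model(
    uptake_cap: float = 10.0,
    biomass_per_precursor: float = 1.0,
    growth_cap: float = float("inf"),
) -> tuple[MetabolicModel, ToyModelExpectation]:
    """Biomass and a product compete for one precursor.

    Growth yields `biomass_per_precursor` per precursor consumed.  With
    unlimited growth capacity the optimum feeds the whole uptake to
    biomass and the product FVA range is (0, 0); capping growth leaves
    precursor spare at the optimum, opening the range to
    (0, uptake − growth/yield).
    """
    model = MetabolicModel(
        metabolites=["s", "p"],
        reactions=[
            Reaction("EX_s", {"s": -1.0}, lb=-uptake_cap, ub=0.0),
            Reaction("to_p", {"s": -1.0, "p": 1.0}, lb=0.0),
            Reaction("growth", {"p": -1.0 / biomass_per_precursor},
                     lb=0.0, ub=growth_cap),
            Reaction("EX_prod", {"p": -1.0}, lb=0.0),
        ],
        growth_reaction="growth",
        media_transporters=[Transporter("EX_s", "substrate", 100.0)],
        targets={"product": Transporter("EX_prod", "product", 46.07)},
    )
    growth = min(uptake_cap * biomass_per_precursor, growth_cap)
    spare = uptake_cap - growth / biomass_per_precursor
    expect = ToyModelExpectation(
        max_growth=growth, fva={"product": (0.0, spare)}
    )
    return model, expect


def fermenter_model(
    glucose_mw: float = 180.16,
    ethanol_mw: float = 46.07,
    ethanol_per_glucose: float = 2.0,
    growth_glucose_fraction: float = 0.0,
) -> tuple[MetabolicModel, ToyModelExpectation]:
    """Glucose → `ethanol_per_glucose`·ethanol fermenter with optional growth
    demand.

    With a glucose-only medium at 1 g·gDW⁻¹·h⁻¹ total uptake the molar
    glucose cap is 1000/MW; growth consumes `growth_glucose_fraction` of
    it at the optimum and the rest may (but need not) go to ethanol, so
    the expected FVA range is (0, (1−fraction)·cap·2) and the mass-yield
    ceiling is 2·(46.07/180.16)·1000 ≈ 511.5 g ethanol per kg glucose.
    """
    if not 0 <= growth_glucose_fraction < 1:
        raise ValueError("growth fraction must be in [0, 1)")
    cap = 1000.0 / glucose_mw
    model = MetabolicModel(
        metabolites=["glc", "etoh"],
        reactions=[
            Reaction("EX_glc", {"glc": -1.0}, lb=-cap, ub=0.0),
            Reaction(
                "ferment", {"glc": -1.0, "etoh": ethanol_per_glucose}, lb=0.0
            ),
            Reaction("growth", {"glc": -1.0}, lb=0.0,
                     ub=growth_glucose_fraction * cap if growth_glucose_fraction else 0.0),
            Reaction("EX_etoh", {"etoh": -1.0}, lb=0.0),
        ],
        growth_reaction="growth" if growth_glucose_fraction else "ferment",
        media_transporters=[Transporter("EX_glc", "glucose", glucose_mw)],
        targets={"ethanol": Transporter("EX_etoh", "ethanol", ethanol_mw)},
    )
    if growth_glucose_fraction:
        growth = growth_glucose_fraction * cap
        vmax = (cap - growth) * ethanol_per_glucose
    else:
        growth = cap  # "growth" proxy is the fermentation flux itself
        vmax = cap * ethanol_per_glucose
    expect = ToyModelExpectation(
        max_growth=growth,
        fva={"ethanol": (vmax if not growth_glucose_fraction else 0.0, vmax)},
    )
    return model, expect


def gen_random_network(
    seed: int,
    n_metabolites: int = 4,
    n_reactions: int = 8,
    bound_scale: float = 10.0,
) -> MetabolicModel:
    """A random bounded stoichiometric network for oracle cross-checks.

    All bounds are finite (so every LP is bounded) and straddle or start
    at zero (so v = 0 is feasible).  The first exchange reaction is the
    medium transporter and the last internal reaction the growth proxy;
    a product exchange is designated as FVA target.  The stoichiometric
    matrix is regenerated until it has full row rank.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        S = np.round(rng.integers(-2, 3, size=(n_metabolites, n_reactions)) * 1.0)
        # sparsify
        mask = rng.random(S.shape) < 0.4
        S[mask] = 0.0
        if np.linalg.matrix_rank(S) == n_metabolites and not (S == 0).all(axis=0).any():
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("could not generate a full-rank network")
    mets = [f"m{i}" for i in range(n_metabolites)]
    reactions = []
    for j in range(n_reactions):
        stoich = {mets[i]: float(S[i, j]) for i in range(n_metabolites) if S[i, j]}
        if rng.random() < 0.5:
            lb, ub = -float(rng.uniform(0, bound_scale)), float(rng.uniform(0, bound_scale))
        else:
            lb, ub = 0.0, float(rng.uniform(0, bound_scale))
        reactions.append(Reaction(f"r{j}", stoich, lb=lb, ub=ub))
    growth = reactions[rng.integers(0, n_reactions)].id
    target = reactions[rng.integers(0, n_reactions)].id
    return MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        growth_reaction=growth,
        targets={"product": Transporter(target, "product", 46.07)},
    )


# --------------------------------------------------------------- resonator


def gen_resonator_obs(
    load: rmm.DropletLoad,
    seed: int,
    spec: rmm.MembraneSpec | None = None,
    modes: tuple[rmm.Mode, ...] = ((0, 1), (3, 4)),
    noise_sd: float = 0.0,
) -> list[rmm.ModeObservation]:
    """Mode observations from the forward model with multiplicative noise.

    `noise_sd` is the relative gaussian scale applied to the loaded
    frequencies (the dry calibration is taken as exact).
    """
    rng = np.random.default_rng(seed)
    if spec is None:
        spec = rmm.MembraneSpec.calibrated(modes=modes)
    obs = []
    for o in rmm.simulate_observations(spec, load, modes):
        f_wet = o.f_wet_hz * (1.0 + noise_sd * rng.standard_normal())
        obs.append(
            rmm.ModeObservation(
                mode=o.mode, f_dry_hz=o.f_dry_hz, f_wet_hz=min(f_wet, o.f_dry_hz)
            )
        )
    return obs


# --------------------------------------------------------------------- PLS


def gen_pls_data(
    coefficients: dict[str, float],
    intercept: float,
    noise_sd: float,
    seed: int,
    n: int | None = None,
    design: DesignMatrix | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """A linear response on the process-factor grid, plus the noise-free X.

    With `n` unset, X is the design grid itself (16 runs); otherwise `n`
    rows are sampled uniformly over each factor's level range.  Returns a
    frame with factor columns and a ``y`` column.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = hydrolysis_design()
    names = [f.name for f in design.factors]
    if n is None:
        X = np.array([[run[name] for name in names] for run in design.runs])
    else:
        if n < 5:
            raise ValueError("need at least 5 samples")
        X = np.column_stack(
            [
                rng.uniform(min(f.levels), max(f.levels), size=n)
                for f in design.factors
            ]
        )
    beta = np.array([coefficients.get(name, 0.0) for name in names])
    y = intercept + X @ beta + noise_sd * rng.standard_normal(X.shape[0])
    frame = pd.DataFrame(X, columns=names)
    frame["y"] = y
    return frame, X
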