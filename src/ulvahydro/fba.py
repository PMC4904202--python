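"""Flux balance / flux variability analysis of fermentation product yields.

Given a stoichiometric model and a feedstock-derived medium (component
mass fractions, g per kg), the pipeline is the standard two-stage LP:

1. *Max growth* — maximise the flux through the biomass reaction subject
   to steady-state mass balance S·v = 0, reaction bounds, and media
   uptake bounds scaled so the total permitted mass uptake is
   1 g·gDW⁻¹·h⁻¹.
2. *Product range* — with growth fixed at its optimum (organisms with
   MaxGrowth below the viability threshold ε = 1e-5 are non-viable and
   produce nothing), minimise and maximise the flux through each product
   transporter (flux variability analysis).

Fluxes are mmol·gDW⁻¹·h⁻¹; with the 1 g·gDW⁻¹·h⁻¹ media normalisation a
product flux converts to g product per kg consumed feedstock as
flux · MW.  Uptake follows the exchange-reaction convention: an
exchange reaction consumes its metabolite at negative flux, so media
availability enters as negative lower bounds.

LPs are solved with HiGHS through :func:`scipy.optimize.linprog`.  Only
objective values are contract outputs — flux vectors at alternate
optima are degenerate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: growth threshold below which an organism is treated as non-viable (h^-1)
VIABILITY_EPSILON = 1e-5
#: total permitted media mass uptake, g per gDW per h
TOTAL_UPTAKE_G = 1.0
INF = float("inf")


@dataclass
class Reaction:
    """One reaction: stoichiometry (metabolite → coefficient) and bounds."""

    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = INF

    @property
    def reversible(self) -> bool:
        return self.lb < 0


@dataclass
class Transporter:
    """An exchange reaction tied to a medium component or product."""

    reaction_id: str
    component: str
    mw: float  # g/mol

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular mass must be positive")


@dataclass
class MetabolicModel:
    """A stoichiometric model with growth, media and target transporters."""

    metabolites: list[str]
    reactions: list[Reaction]
    growth_reaction: str
    media_transporters: list[Transporter] = field(default_factory=list)
    targets: dict[str, Transporter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        mets = set(self.metabolites)
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            unknown = set(r.stoichiometry) - mets
            if unknown:
                raise ValueError(f"reaction {r.id} references unknown metabolites {unknown}")
            if r.lb > r.ub:
                raise ValueError(f"reaction {r.id} has lb > ub")
        rset = set(rids)
        if self.growth_reaction not in rset:
            raise ValueError("growth reaction missing from the model")
        for t in self.media_transporters + list(self.targets.values()):
            if t.reaction_id not in rset:
                raise ValueError(f"transporter reaction {t.reaction_id} missing")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def stoichiometric_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        midx = {m: i for i, m in enumerate(self.metabolites)}
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[midx[met], j] = coef
        return S

    # ------------------------------------------------------------------ io
    def to_json(self, path: str | Path) -> None:
        doc = {
            "metabolites": self.metabolites,
            "reactions": [
                {"id": r.id, "stoichiometry": r.stoichiometry,
                 "lb": None if r.lb == -INF else r.lb,
                 "ub": None if r.ub == INF else r.ub}
                for r in self.reactions
            ],
            "growth_reaction": self.growth_reaction,
            "media_transporters": [
                {"reaction": t.reaction_id, "component": t.component, "mw": t.mw}
                for t in self.media_transporters
            ],
            "targets": {
                name: {"reaction": t.reaction_id, "component": t.component, "mw": t.mw}
                for name, t in self.targets.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            metabolites=doc["metabolites"],
            reactions=[
                Reaction(
                    id=r["id"], stoichiometry=r["stoichiometry"],
                    lb=-INF if r.get("lb") is None else r["lb"],
                    ub=INF if r.get("ub") is None else r["ub"],
                )
                for r in doc["reactions"]
            ],
            growth_reaction=doc["growth_reaction"],
            media_transporters=[
                Transporter(t["reaction"], t["component"], t["mw"])
                for t in doc.get("media_transporters", [])
            ],
            targets={
                name: Transporter(t["reaction"], t["component"], t["mw"])
                for name, t in doc.get("targets", {}).items()
            },
        )

    @classmethod
    def from_sbml(cls, path: str | Path, growth_reaction: str,
                  media_transporters: list[Transporter] | None = None,
                  targets: dict[str, Transporter] | None = None) -> "MetabolicModel":
        """Map an SBML model onto this schema (requires cobra)."""
        import cobra  # optional dependency

        cm = cobra.io.read_sbml_model(str(path))
        return cls(
            metabolites=[m.id for m in cm.metabolites],
            reactions=[
                Reaction(
                    id=r.id,
                    stoichiometry={m.id: c for m, c in r.metabolites.items()},
                    lb=r.lower_bound, ub=r.upper_bound,
                )
                for r in cm.reactions
            ],
            growth_reaction=growth_reaction,
            media_transporters=media_transporters or [],
            targets=targets or {},
        )


def build_media_bounds(
    model: MetabolicModel,
    media: Mapping[str, float],
    total_uptake_g: float = TOTAL_UPTAKE_G,
    mode: str = "proportional",
) -> dict[str, float]:
    """Per-exchange molar uptake caps (mmol·gDW⁻¹·h⁻¹) from media mass fractions.

    Each component's cap is proportional to its share of the *total*
    supplied media mass, scaled so that a medium consumed at its caps
    amounts to `total_uptake_g` g·gDW⁻¹·h⁻¹ (``mode="proportional"``,
    the default).  Components without a model transporter are dropped
    from the caps with a log message but still count toward the total
    media mass the organism ingests — a trace nutrient in a large medium
    stays a trace nutrient.  With ``mode="shared_pool"`` every component
    is individually unlimited up to the total and the pool cap is
    enforced as a linear constraint in the LPs instead.
    """
    if mode not in ("proportional", "shared_pool"):
        raise ValueError(f"unknown media mode {mode!r}")
    by_component = {t.component: t for t in model.media_transporters}
    usable = {c: w for c, w in media.items() if w > 0 and c in by_component}
    for c, w in media.items():
        if w > 0 and c not in by_component:
            logger.info("media component %r has no transporter; dropped", c)
    if not usable:
        raise ValueError("no consumable components")
    total_mass = sum(w for w in media.values() if w > 0)
    caps: dict[str, float] = {}
    for c, w in usable.items():
        t = by_component[c]
        if mode == "proportional":
            mass_allow = total_uptake_g * w / total_mass  # g gDW^-1 h^-1
        else:
            mass_allow = total_uptake_g
        caps[t.reaction_id] = mass_allow / t.mw * 1000.0  # mmol gDW^-1 h^-1
    return caps


@dataclass
class LPSolution:
    objective: float
    fluxes: np.ndarray
    status: str


def _solve(
    model: MetabolicModel,
    media_bounds: Mapping[str, float],
    objective_rid: str,
    sense: str = "max",
    fixed: Mapping[str, tuple[float, float]] | None = None,
    media_mode: str = "proportional",
    total_uptake_g: float = TOTAL_UPTAKE_G,
) -> LPSolution:
    """One LP over the flux polytope with media uptake caps applied."""
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    # media caps tighten exchange lower bounds: uptake = -flux <= cap
    media_rids = {t.reaction_id for t in model.media_transporters}
    for rid in media_rids:
        j = model.reaction_index(rid)
        cap = media_bounds.get(rid, 0.0)
        lb[j] = max(lb[j], -cap)
    if fixed:
        for rid, (lo, hi) in fixed.items():
            j = model.reaction_index(rid)
            lb[j], ub[j] = max(lb[j], lo), min(ub[j], hi)
    A_ub = b_ub = None
    if media_mode == "shared_pool":
        row = np.zeros(n)
        for t in model.media_transporters:
            row[model.reaction_index(t.reaction_id)] = -t.mw / 1000.0
        A_ub, b_ub = row[None, :], np.array([total_uptake_g])
    c = np.zeros(n)
    c[model.reaction_index(objective_rid)] = -1.0 if sense == "max" else 1.0
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if res.status == 3:
        raise RuntimeError(f"LP unbounded maximizing {objective_rid}: model leak")
    if res.status != 0 or res.x is None:
        raise RuntimeError(
            f"LP failed for {objective_rid} ({sense}): {res.message}"
        )
    obj = float(res.x[model.reaction_index(objective_rid)])
    return LPSolution(objective=obj, fluxes=res.x, status="optimal")


def max_growth(
    model: MetabolicModel,
    media_bounds: Mapping[str, float],
    media_mode: str = "proportional",
) -> LPSolution:
    """Maximal growth rate under the given media (h⁻¹)."""
    return _solve(model, media_bounds, model.growth_reaction, "max",
                  media_mode=media_mode)


def target_flux_range(
    model: MetabolicModel,
    media_bounds: Mapping[str, float],
    growth: float,
    target: str,
    epsilon: float = VIABILITY_EPSILON,
    fix_tol: float = 1e-9,
    media_mode: str = "proportional",
) -> tuple[float, float]:
    """FVA range (v_min, v_max) of a product transporter at fixed optimal growth.

    Non-viable organisms (growth < ε) produce nothing.  If fixing growth
    at exactly its optimum is infeasible (solver tolerance), the fixation
    is relaxed by a factor (1 − 1e-6) and the retry logged.
    """
    if target not in model.targets:
        raise KeyError(f"unknown target {target!r}")
    if growth < epsilon:
        return (0.0, 0.0)
    rid = model.targets[target].reaction_id
    grid = model.growth_reaction
    for factor in (1.0, 1.0 - 1e-6):
        fixed = {grid: (growth * factor - fix_tol, growth + fix_tol)}
        try:
            lo = _solve(model, media_bounds, rid, "min", fixed, media_mode).objective
            hi = _solve(model, media_bounds, rid, "max", fixed, media_mode).objective
            if factor != 1.0:
                logger.warning("growth fixation relaxed by 1e-6 for %s", target)
            return (min(lo, hi), max(lo, hi))
        except RuntimeError:
            if factor != 1.0:
                raise
    raise AssertionError("unreachable")


def yield_g_per_kg(flux_mmol: float, mw: float) -> float:
    """Convert a product flux to g product per kg consumed feedstock.

    With media uptake normalised to 1 g·gDW⁻¹·h⁻¹, a product flux of
    `flux_mmol` mmol·gDW⁻¹·h⁻¹ amounts to flux·MW/1000 g product per g
    of medium, i.e. flux·MW g per kg.
    """
    if mw <= 0:
        raise ValueError("molecular mass must be positive")
    return flux_mmol * mw


@dataclass
class YieldRange:
    """Predicted product yield range for one run and one target."""

    run: object
    target: str
    growth: float
    viable: bool
    min_g_per_kg: float
    max_g_per_kg: float


def run_experiment_panel(
    model: MetabolicModel,
    base_media: Mapping[str, float],
    run_sugars: pd.DataFrame,
    targets: Sequence[str],
    sugar_components: Mapping[str, str] | None = None,
    epsilon: float = VIABILITY_EPSILON,
    media_mode: str = "proportional",
) -> pd.DataFrame:
    """Per-run growth and product yield ranges from measured sugar releases.

    `run_sugars` carries one row per run with a ``run`` column and
    per-sugar g kg⁻¹ columns (``<sugar>_g_per_kg``); those overwrite the
    matching carbohydrate components of `base_media` (mapped through
    `sugar_components`, default identity).  Per-run LP failures are
    recorded and the panel continues.
    """
    sugar_components = dict(sugar_components or {})
    rows = []
    for _, row in run_sugars.iterrows():
        media = dict(base_media)
        for col in run_sugars.columns:
            if not col.endswith("_g_per_kg"):
                continue
            sugar = col[: -len("_g_per_kg")]
            component = sugar_components.get(sugar, sugar)
            media[component] = float(row[col])
        rec: dict[str, object] = {"run": row["run"]}
        try:
            bounds = build_media_bounds(model, media, mode=media_mode)
            growth = max_growth(model, bounds, media_mode=media_mode).objective
            rec["growth"] = growth
            rec["viable"] = growth >= epsilon
            for t in targets:
                lo, hi = target_flux_range(
                    model, bounds, growth, t, epsilon=epsilon, media_mode=media_mode
                )
                mw = model.targets[t].mw
                rec[f"{t}_min_g_per_kg"] = yield_g_per_kg(lo, mw)
                rec[f"{t}_max_g_per_kg"] = yield_g_per_kg(hi, mw)
            rec["status"] = "ok"
        except (ValueError, RuntimeError) as exc:
            logger.error("run %s failed: %s", row["run"], exc)
            rec.setdefault("growth", float("nan"))
            rec["viable"] = False
            for t in targets:
                rec.setdefault(f"{t}_min_g_per_kg", float("nan"))
                rec.setdefault(f"{t}_max_g_per_kg", float("nan"))
            rec["status"] = f"failed: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows)
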