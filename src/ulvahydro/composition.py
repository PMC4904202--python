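"""Hydrolysate mass accounting: released sugar mass and percent yield.

Concentrations of the four quantified monosaccharides (μg ml⁻¹ in the
hydrolysate) are turned into a total released mass over the reaction
volume and into the percent-yield statistic

    yield% = Total(μg) / (m_dw(mg) · 1000) · 100,

where m_dw is the dry biomass loaded into the reaction (solid load %
times reaction volume).  The printed per-run totals are a constant 2.7×
the concentration sums; that factor is carried as an explicit effective
dilution (post-neutralisation volume change and/or dilution before
injection) and is configurable, never baked into the formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .datasets import SUGARS

#: effective dilution between hydrolysate concentrations and reported totals
DEFAULT_DILUTION = 2.7


@dataclass(frozen=True)
class HydrolysisRun:
    """Process settings of one hydrolysis reaction."""

    run_id: int
    temperature_c: float
    time_min: float
    acid_pct: float
    solid_pct: float
    volume_ml: float = 1.0
    dilution: float = DEFAULT_DILUTION

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("reaction volume must be positive")
        if self.solid_pct <= 0:
            raise ValueError("solid load must be positive")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


def dry_weight(run: HydrolysisRun) -> float:
    """Dry biomass in the reaction, mg: solid% of the volume in water-mass terms."""
    return run.solid_pct / 100.0 * run.volume_ml * 1000.0


def total_released_mass(conc: Mapping[str, float], run: HydrolysisRun) -> float:
    """Total released carbohydrate mass (μg) over the effective volume.

    `conc` maps sugar name → concentration in μg ml⁻¹; only non-negative
    values are admissible.
    """
    for sugar, c in conc.items():
        if c < 0:
            raise ValueError(f"negative concentration for {sugar}")
    return float(sum(conc.values())) * run.volume_ml * run.dilution


def percent_yield(total_ug: float, m_dw_mg: float) -> float:
    """Percent of the dry biomass recovered as quantified sugars."""
    if m_dw_mg <= 0:
        raise ValueError("dry weight must be positive")
    return total_ug / (m_dw_mg * 1000.0) * 100.0


def sugars_g_per_kg(conc: Mapping[str, float], run: HydrolysisRun) -> dict[str, float]:
    """Per-sugar release normalised to feedstock dry weight (g per kg).

    This is the bridge from chromatography concentrations to the
    fermentation-medium carbohydrate content: mass of sugar i over the
    effective volume divided by the dry biomass loaded.
    """
    m_dw = dry_weight(run)
    # μg released per mg dry biomass is numerically g per kg
    return {
        sugar: c * run.volume_ml * run.dilution / m_dw for sugar, c in conc.items()
    }


def yield_table(
    runs: pd.DataFrame, dilution: float = DEFAULT_DILUTION, volume_ml: float = 1.0
) -> pd.DataFrame:
    """Per-run mass/yield summary from a design+outcome table.

    Expects the packaged run-table schema (factor columns plus
    ``<sugar>_mean`` concentration columns).  Returns run id, dry weight
    (mg), total released mass (μg), percent yield, and per-sugar g kg⁻¹.
    """
    rows = []
    for _, row in runs.iterrows():
        run = HydrolysisRun(
            run_id=int(row["run"]),
            temperature_c=row["temperature_c"],
            time_min=row["time_min"],
            acid_pct=row["acid_pct"],
            solid_pct=row["solid_pct"],
            volume_ml=volume_ml,
            dilution=dilution,
        )
        conc = {s: float(row[f"{s}_mean"]) for s in SUGARS}
        m_dw = dry_weight(run)
        total = total_released_mass(conc, run)
        rec = {
            "run": run.run_id,
            "dry_weight_mg": m_dw,
            "total_ug": total,
            "yield_pct": percent_yield(total, m_dw),
        }
        rec.update(
            {f"{s}_g_per_kg": v for s, v in sugars_g_per_kg(conc, run).items()}
        )
        rows.append(rec)
    return pd.DataFrame(rows)
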