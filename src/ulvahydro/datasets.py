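"""Packaged reference data for the 16-run Ulva hydrolysis screen.

Ships three small CSV tables transcribed from the published study:

* ``hydrolysis_runs.csv`` — process settings and duplicate-summarised
  outcomes (mean, sample sd) for all 16 runs;
* ``snr_reference.csv``   — the published larger-the-better S/N values;
* ``biomass_composition.csv`` — whole-biomass composition (g per kg dry
  weight) used as the base fermentation medium.

Two outcome cells are typographically suspect in the source; they are
annotated in ``data_notes.json`` and handled as described there.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .taguchi import DesignMatrix, FactorSpec, OutcomeTable, reconstruct_duplicates

#: outcomes measured per run, in table order
OUTCOMES = (
    "rhamnose",
    "glucose",
    "xylose",
    "glucuronic_acid",
    "total",
    "yield_pct",
    "density",
)

#: the four quantified monosaccharides
SUGARS = ("rhamnose", "glucose", "xylose", "glucuronic_acid")

MOLECULAR_WEIGHTS = {
    "glucose": 180.16,
    "rhamnose": 164.16,
    "xylose": 150.13,
    "glucuronic_acid": 194.14,
    "ethanol": 46.07,
    "acetone": 58.08,
    "butanol": 74.12,
}

#: Table-1 compound name per sugar column, for media substitution
SUGAR_COMPOUNDS = {
    "glucose": "D-Glucose",
    "rhamnose": "L-Rhamnose",
    "xylose": "D-Xylose",
    "glucuronic_acid": "Glucuronic Acid",
}


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("ulvahydro").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_hydrolysis_runs() -> pd.DataFrame:
    """The 16-run design with mean/sd outcome columns."""
    return _read_csv("hydrolysis_runs.csv")


def load_snr_reference() -> pd.DataFrame:
    """Published per-run S/N values (dB) for six outcomes."""
    return _read_csv("snr_reference.csv")


def load_biomass_composition() -> pd.DataFrame:
    """Whole-biomass composition (compound, g_per_kg, class)."""
    return _read_csv("biomass_composition.csv")


def load_data_notes() -> dict:
    """Units, replicate counts and suspect-cell annotations."""
    with resources.files("ulvahydro").joinpath("data", "data_notes.json").open() as fh:
        return json.load(fh)


def hydrolysis_design(runs: pd.DataFrame | None = None) -> DesignMatrix:
    """The mixed-level orthogonal array of the hydrolysis screen."""
    if runs is None:
        runs = load_hydrolysis_runs()
    factors = tuple(
        FactorSpec(name, tuple(sorted(runs[name].unique())))
        for name in ("temperature_c", "time_min", "acid_pct", "solid_pct")
    )
    assignments = tuple(
        {f.name: float(row[f.name]) for f in factors} for _, row in runs.iterrows()
    )
    return DesignMatrix(factors=factors, runs=assignments)


def outcome_table(outcome: str, runs: pd.DataFrame | None = None) -> OutcomeTable:
    """Duplicate replicates of one outcome, reconstructed from mean ± sd."""
    if runs is None:
        runs = load_hydrolysis_runs()
    pairs = np.array(
        [
            reconstruct_duplicates(m, s)
            for m, s in zip(runs[f"{outcome}_mean"], runs[f"{outcome}_sd"])
        ]
    )
    return OutcomeTable(outcome=outcome, replicates=pairs)
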