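"""Taguchi robust-design signal-to-noise analysis for mixed-level arrays.

The hydrolysis screen is a 16-run mixed-level orthogonal design (three
3-level factors and one 4-level factor) with duplicate outcome
measurements per run.  Every outcome here is of the "larger the better"
kind (released sugar concentration, yield), so the per-run
signal-to-noise statistic is

    R_j = -10 * log10( (1/n_rep) * sum_rep 1 / m_rep^2 )   [dB]

Small replicate values are floored at a configurable detection floor
before the reciprocal square, which pins all-below-floor runs at
-10*log10(1/floor^2) (−60 dB for the default floor of 0.001).

Factor effects are summarised per level by averaging R over the runs
that used that level (per-level counts, so unbalanced mixed-level
arrays are handled), the factor sensitivity Δ is the range of those
level averages, factors are ranked by Δ descending, and the optimum
setting per factor is the level with the highest average R.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 0.001
#: canonical factor order of the hydrolysis screen; also the tie-break order
FACTOR_ORDER = ("temperature_c", "time_min", "acid_pct", "solid_pct")


@dataclass(frozen=True)
class FactorSpec:
    """A process factor and its admissible levels (ascending)."""

    name: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = tuple(float(x) for x in self.levels)
        if len(lv) < 2:
            raise ValueError(f"factor {self.name!r} needs at least 2 levels")
        if len(set(lv)) != len(lv):
            raise ValueError(f"factor {self.name!r} has duplicate levels")
        object.__setattr__(self, "levels", tuple(sorted(lv)))


@dataclass(frozen=True)
class DesignMatrix:
    """K experimental runs, each assigning one level to every factor."""

    factors: tuple[FactorSpec, ...]
    runs: tuple[Mapping[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("a design needs at least 2 runs")
        by_name = {f.name: f for f in self.factors}
        for j, run in enumerate(self.runs):
            for f in self.factors:
                if f.name not in run:
                    raise ValueError(f"run {j} is missing factor {f.name!r}")
                if float(run[f.name]) not in by_name[f.name].levels:
                    raise ValueError(
                        f"run {j}: level {run[f.name]} not admissible for {f.name!r}"
                    )

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def runs_at(self, factor: str, level: float) -> list[int]:
        """Indices of the runs that applied `factor` at `level`."""
        return [
            j for j, run in enumerate(self.runs) if float(run[factor]) == float(level)
        ]


@dataclass(frozen=True)
class OutcomeTable:
    """Replicate measurements of one outcome across all runs (K x n_rep)."""

    outcome: str
    replicates: np.ndarray

    def __post_init__(self) -> None:
        reps = np.asarray(self.replicates, dtype=float)
        if reps.ndim != 2:
            raise ValueError("replicates must be a 2-D (runs x replicates) array")
        if not np.isfinite(reps).all():
            raise ValueError(f"outcome {self.outcome!r} has non-finite measurements")
        if (reps < 0).any():
            raise ValueError(f"outcome {self.outcome!r} has negative measurements")
        object.__setattr__(self, "replicates", reps)

    @property
    def n_runs(self) -> int:
        return self.replicates.shape[0]


@dataclass
class SNAnalysis:
    """Full S/N analysis of one outcome over a design."""

    outcome: str
    snr: np.ndarray
    level_avg: dict[tuple[str, float], float]
    delta: dict[str, float]
    rank: dict[str, int]
    optimum: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def snr_larger_better(
    measurements: Sequence[float], floor: float = DEFAULT_FLOOR
) -> float:
    """Larger-the-better S/N ratio (dB) of one run's replicates.

    Each replicate is floored at `floor` before the reciprocal square, so
    zero measurements map to a finite (very negative) ratio.
    """
    m = np.asarray(measurements, dtype=float)
    if m.size == 0:
        raise ValueError("no replicates")
    if (m < 0).any():
        raise ValueError("negative measurement")
    if floor <= 0:
        raise ValueError("floor must be positive")
    m = np.maximum(m, floor)
    return float(-10.0 * math.log10(float(np.mean(1.0 / m**2))))


def reconstruct_duplicates(mean: float, sd: float) -> tuple[float, float]:
    """Invert a (mean, sample sd) summary of a duplicate measurement.

    For two replicates the sample standard deviation (n−1 denominator) is
    |x1 − x2|/√2, so the unique pair (up to order) with the given summary
    is mean ± sd/√2.  A negative reconstructed concentration is clamped
    at zero and logged (the summary then cannot be reproduced exactly).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half = sd / math.sqrt(2.0)
    hi, lo = mean + half, mean - half
    if lo < 0:
        logger.warning(
            "reconstructed replicate clamped at 0 (mean=%g, sd=%g)", mean, sd
        )
        lo = 0.0
    return (hi, lo)


def level_averages(
    design: DesignMatrix, snr: Sequence[float]
) -> dict[tuple[str, float], float]:
    """Mean S/N per (factor, level), averaged over the runs using that level.

    Per-level run counts are used directly, so mixed-level (unbalanced)
    arrays are averaged correctly.  Declared levels that no run uses are
    excluded with a warning.
    """
    r = np.asarray(snr, dtype=float)
    if r.shape != (design.n_runs,):
        raise ValueError("need exactly one S/N value per run")
    out: dict[tuple[str, float], float] = {}
    for f in design.factors:
        for level in f.levels:
            idx = design.runs_at(f.name, level)
            if not idx:
                logger.warning("level %g of %r unused in design; skipped", level, f.name)
                continue
            out[(f.name, level)] = float(r[idx].mean())
    return out


def sensitivity(level_avg_one_factor: Mapping[float, float]) -> float:
    """Sensitivity Δ of a factor: range (max − min) of its level averages."""
    vals = list(level_avg_one_factor.values())
    if len(vals) < 2:
        raise ValueError("factor not varied")
    return float(max(vals) - min(vals))


def rank_factors(
    deltas: Mapping[str, float], order: Sequence[str] = FACTOR_ORDER
) -> dict[str, int]:
    """Rank factors by Δ descending; rank 1 is the most influential.

    Ties are broken by the declared factor order and logged.
    """
    names = sorted(deltas, key=lambda n: list(order).index(n) if n in order else 1e9)
    if len(set(deltas.values())) < len(names):
        logger.warning("tied sensitivities %s; tie broken by factor order", dict(deltas))
    ranked = sorted(names, key=lambda n: -deltas[n])
    return {name: i + 1 for i, name in enumerate(ranked)}


def optimum_settings(
    level_avg: Mapping[tuple[str, float], float]
) -> dict[str, float]:
    """Per factor, the level with the maximal average S/N (ties → lower level)."""
    by_factor: dict[str, dict[float, float]] = {}
    for (name, level), val in level_avg.items():
        by_factor.setdefault(name, {})[level] = val
    best: dict[str, float] = {}
    for name, lv in by_factor.items():
        top = max(lv.values())
        winners = sorted(l for l, v in lv.items() if v == top)
        if len(winners) > 1:
            logger.warning("tied optimum levels %s for %r; lower level kept", winners, name)
        best[name] = winners[0]
    return best


def analyze(
    design: DesignMatrix, outcome: OutcomeTable, floor: float = DEFAULT_FLOOR
) -> SNAnalysis:
    """Run the full larger-the-better analysis of one outcome."""
    if outcome.n_runs != design.n_runs:
        raise ValueError("outcome table and design disagree on run count")
    snr = np.array(
        [snr_larger_better(row, floor=floor) for row in outcome.replicates]
    )
    lav = level_averages(design, snr)
    per_factor: dict[str, dict[float, float]] = {}
    for (name, level), val in lav.items():
        per_factor.setdefault(name, {})[level] = val
    deltas = {name: sensitivity(vals) for name, vals in per_factor.items()}
    return SNAnalysis(
        outcome=outcome.outcome,
        snr=snr,
        level_avg=lav,
        delta=deltas,
        rank=rank_factors(deltas, order=[f.name for f in design.factors]),
        optimum=optimum_settings(lav),
    )


def snr_smaller_better(measurements: Sequence[float]) -> float:
    """Smaller-the-better S/N variant (not used by this screen)."""
    raise NotImplementedError("smaller-the-better S/N is not implemented")


def snr_nominal_best(measurements: Sequence[float], target: float) -> float:
    """Nominal-the-best S/N variant (not used by this screen)."""
    raise NotImplementedError("nominal-the-best S/N is not implemented")
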