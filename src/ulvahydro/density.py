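"""Resonating-micromembrane (RMM) densitometry of liquid droplets.

A thin circular membrane under tensile strain vibrates at mode
frequencies

    f_mn = α_mn / (2π R_m) · sqrt(Y ε / ρ_eff),

inversely proportional to the square root of an effective mass density
ρ_eff.  A droplet deposited on the membrane adds mass and pulls the mode
frequencies down; the dry-vs-loaded shift of each mode therefore encodes
the droplet's average density ρ₁ and volume V₁.

Forward model
-------------
The droplet is treated as a centered thin liquid film of configurable
layer thickness whose footprint covers part of the membrane.  The added
mass participates in mode (m, n) in proportion to the mean-square modal
displacement over the footprint, so the loaded state of each mode is a
per-mode effective density

    ρ_mn = ρ_f · (1 + c_mn(a) · ρ₁V₁ / (ρ_f V_f)),

where c_mn(a) is the footprint-averaged mode-shape participation of a
droplet of contact radius a(V₁) (c → 1 for full coverage, recovering the
uniform mass-loading limit Δf/f ≈ ρ₁V₁ / (2 ρ_f V_f)).  Because a
centered droplet loads azimuthally symmetric modes far more strongly
than high-azimuthal-order modes, observing two modes of different
azimuthal index separates ρ₁ from V₁; with a single mode, the droplet
volume must be known.

The absolute mode factors α_mn of a real device are not taken from
tabulated Bessel zeros: the published device geometry is not
self-consistent with them, so the factor table is back-calibrated from
one measured dry frequency, with the Bessel-zero *ratios* fixing the
relative spacing of the other modes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special

logger = logging.getLogger(__name__)

PICOLITER = 1e-15  # m^3
#: default droplet layer thickness (m); chosen so pL-scale droplets wet a
#: footprint inside the first radial lobe of the high-order modes, where the
#: per-mode participation ratio is monotone and the 2-mode inversion is
#: single-valued
DEFAULT_LAYER_THICKNESS = 80e-9
Mode = tuple[int, int]


def bessel_mode_factor(mode: Mode) -> float:
    """n-th zero of the Bessel function J_m, the ideal-membrane factor α_mn."""
    m, n = mode
    if n < 1:
        raise ValueError("radial index n must be >= 1")
    return float(special.jn_zeros(m, n)[-1])


@dataclass(frozen=True)
class MembraneSpec:
    """Geometry, material and calibrated mode factors of one RMM device."""

    radius_m: float = 250e-6
    film_density: float = 2650.0          # kg m^-3 (silicon)
    film_volume_m3: float = 0.59 * PICOLITER
    youngs_modulus_pa: float = 130e9
    strain: float = 4e-6
    layer_thickness_m: float = DEFAULT_LAYER_THICKNESS
    mode_factors: dict[Mode, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("radius_m", "film_density", "film_volume_m3",
                     "youngs_modulus_pa", "strain", "layer_thickness_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def thickness_m(self) -> float:
        """Film thickness consistent with V_f = π R² h."""
        return self.film_volume_m3 / (math.pi * self.radius_m**2)

    @classmethod
    def calibrated(
        cls,
        calibration_mode: Mode = (3, 4),
        dry_frequency_hz: float = 82e3,
        modes: tuple[Mode, ...] = ((0, 1), (1, 1), (2, 1), (3, 4)),
        **kwargs,
    ) -> "MembraneSpec":
        """Build a spec whose factor table reproduces one measured dry frequency.

        α of the calibration mode is back-solved from `dry_frequency_hz`
        at the dry (film) density; the other modes' factors keep the
        ideal Bessel-zero ratios to it.
        """
        base = cls(**kwargs)
        wave = math.sqrt(base.youngs_modulus_pa * base.strain / base.film_density)
        alpha_cal = dry_frequency_hz * 2 * math.pi * base.radius_m / wave
        ref = bessel_mode_factor(calibration_mode)
        factors = {
            mode: alpha_cal * bessel_mode_factor(mode) / ref
            for mode in set(modes) | {calibration_mode}
        }
        return cls(
            radius_m=base.radius_m,
            film_density=base.film_density,
            film_volume_m3=base.film_volume_m3,
            youngs_modulus_pa=base.youngs_modulus_pa,
            strain=base.strain,
            layer_thickness_m=base.layer_thickness_m,
            mode_factors=factors,
        )


@dataclass(frozen=True)
class DropletLoad:
    """A deposited droplet: average density ρ₁ (kg m⁻³) and volume V₁ (m³)."""

    density: float
    volume_m3: float
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("droplet density must be positive")
        if self.volume_m3 < 0:
            raise ValueError("droplet volume must be non-negative")


@dataclass(frozen=True)
class ModeObservation:
    """Dry and droplet-loaded frequency of one vibration mode."""

    mode: Mode
    f_dry_hz: float
    f_wet_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.f_wet_hz <= self.f_dry_hz:
            raise ValueError("need 0 < f_wet <= f_dry")


def effective_density(spec: MembraneSpec, load: DropletLoad) -> float:
    """Volume-weighted composite density of film plus droplet.

    A convex combination of ρ_f and ρ₁ — equals ρ_f for V₁ = 0 and tends
    to ρ₁ as the droplet dwarfs the film.
    """
    vf, v1 = spec.film_volume_m3, load.volume_m3
    return (spec.film_density * vf + load.density * v1) / (vf + v1)


def mode_frequency(spec: MembraneSpec, mode: Mode, rho_eff: float) -> float:
    """Resonance frequency (Hz) of `mode` at effective density `rho_eff`."""
    if mode not in spec.mode_factors:
        raise KeyError(f"mode {mode} not in the spec's factor table")
    if rho_eff <= 0:
        raise ValueError("effective density must be positive")
    alpha = spec.mode_factors[mode]
    return alpha / (2 * math.pi * spec.radius_m) * math.sqrt(
        spec.youngs_modulus_pa * spec.strain / rho_eff
    )


def footprint_radius(spec: MembraneSpec, volume_m3: float) -> float:
    """Contact radius of a droplet spread as a thin centered film (≤ R)."""
    if volume_m3 <= 0:
        return 0.0
    a = math.sqrt(volume_m3 / (math.pi * spec.layer_thickness_m))
    return min(a, spec.radius_m)


def mode_participation(mode: Mode, a_over_r: float) -> float:
    """Footprint-averaged mass participation c_mn of a centered droplet.

    Ratio of the mean-square modal displacement over the droplet
    footprint (fractional radius `a_over_r`) to its mean over the whole
    membrane; 1 at full coverage, > 1 for center-heavy (m = 0) modes and
    → 0 for high-azimuthal-order modes under small droplets.
    """
    if not 0 <= a_over_r <= 1:
        raise ValueError("a_over_r must lie in [0, 1]")
    if a_over_r == 0:
        m = mode[0]
        beta = bessel_mode_factor(mode)
        if m == 0:
            denom = integrate.quad(
                lambda x: special.jv(0, beta * x) ** 2 * x, 0, 1
            )[0]
            return 0.5 / denom
        return 0.0
    m = mode[0]
    beta = bessel_mode_factor(mode)

    def integrand(x: float) -> float:
        return special.jv(m, beta * x) ** 2 * x

    num = integrate.quad(integrand, 0, a_over_r)[0]
    denom = integrate.quad(integrand, 0, 1)[0]
    return (num / a_over_r**2) / denom


def loaded_mode_density(spec: MembraneSpec, mode: Mode, load: DropletLoad) -> float:
    """Per-mode effective density of the droplet-loaded membrane."""
    a = footprint_radius(spec, load.volume_m3)
    c = mode_participation(mode, a / spec.radius_m)
    mu = c * load.density * load.volume_m3 / (
        spec.film_density * spec.film_volume_m3
    )
    return spec.film_density * (1.0 + mu)


def frequency_shift(spec: MembraneSpec, mode: Mode, load: DropletLoad) -> float:
    """Downward shift f_dry − f_wet (Hz) caused by the droplet load.

    Computed through the per-mode loaded density and the 1/√ρ frequency
    law; zero for a zero load and monotonically increasing in ρ₁V₁.
    """
    f_dry = mode_frequency(spec, mode, spec.film_density)
    f_wet = mode_frequency(spec, mode, loaded_mode_density(spec, mode, load))
    return f_dry - f_wet


def simulate_observations(
    spec: MembraneSpec, load: DropletLoad, modes: tuple[Mode, ...]
) -> list[ModeObservation]:
    """Noise-free forward-model observations for a droplet load."""
    out = []
    for m in modes:
        f_dry = mode_frequency(spec, m, spec.film_density)
        out.append(
            ModeObservation(mode=m, f_dry_hz=f_dry, f_wet_hz=f_dry - frequency_shift(spec, m, load))
        )
    return out


def invert_load(
    spec: MembraneSpec,
    observations: list[ModeObservation],
    known_volume_m3: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[DropletLoad, float]:
    """Recover (ρ₁, V₁) from mode frequency shifts by damped least squares.

    Solves the forward model in (log ρ₁, log V₁) — positivity enforced by
    the parametrisation — with Levenberg–Marquardt.  With a single mode
    the droplet volume must be supplied (closed-form solve for ρ₁); zero
    observed shift returns V₁ = 0 with the density flagged
    unidentifiable.  Returns the load and the relative residual norm.
    """
    if not observations:
        raise ValueError("no observations")
    modes = [o.mode for o in observations]
    f_wet = np.array([o.f_wet_hz for o in observations])
    shifts = np.array([o.f_dry_hz - o.f_wet_hz for o in observations])
    if np.allclose(shifts, 0.0, atol=1e-9 * f_wet.max()):
        logger.warning("zero frequency shift: droplet density unidentifiable")
        return DropletLoad(density=spec.film_density, volume_m3=0.0,
                           identifiable=False), 0.0
    if known_volume_m3 is not None:
        a = footprint_radius(spec, known_volume_m3)
        masses = []
        for o in observations:
            c = mode_participation(o.mode, a / spec.radius_m)
            if c == 0:
                continue
            rho_mode = spec.film_density * (o.f_dry_hz / o.f_wet_hz) ** 2
            mu = rho_mode / spec.film_density - 1.0
            masses.append(mu * spec.film_density * spec.film_volume_m3 / c)
        if not masses:
            raise ValueError("no observed mode is sensitive to this droplet")
        rho1 = float(np.mean(masses) / known_volume_m3)
        load = DropletLoad(density=rho1, volume_m3=known_volume_m3)
        pred = np.array(
            [o.f_dry_hz - frequency_shift(spec, o.mode, load) for o in observations]
        )
        return load, float(np.linalg.norm(pred - f_wet) / np.linalg.norm(f_wet))
    if len(observations) < 2:
        raise ValueError("underdetermined: one mode and unknown droplet volume")

    def residuals(theta: np.ndarray) -> np.ndarray:
        # clamp the log-parameters to a physically meaningful box so a wild
        # damped-Newton step cannot overflow exp()
        t0 = min(max(theta[0], math.log(1e-2)), math.log(1e7))
        t1 = min(max(theta[1], math.log(1e-24)), math.log(1e-6))
        load = DropletLoad(density=math.exp(t0), volume_m3=math.exp(t1))
        pred = np.array(
            [o.f_dry_hz - frequency_shift(spec, o.mode, load) for o in observations]
        )
        return pred - f_wet

    # deterministic multi-start over initial volumes; keep the solution with
    # the smallest residual (then the smallest volume, to resolve spurious
    # large-footprint branches)
    best: tuple[float, float, np.ndarray] | None = None
    for frac in (0.05, 0.2, 0.5, 1.0, 2.0):
        x0 = np.array([math.log(1000.0), math.log(frac * spec.film_volume_m3)])
        sol = optimize.least_squares(
            residuals, x0, method="lm", xtol=tol, ftol=tol, gtol=tol,
            max_nfev=max_iter * 10,
        )
        resid = float(np.linalg.norm(sol.fun))
        x_clamped = np.array([
            min(max(sol.x[0], math.log(1e-2)), math.log(1e7)),
            min(max(sol.x[1], math.log(1e-24)), math.log(1e-6)),
        ])
        vol = math.exp(x_clamped[1])
        if best is None or resid < best[0] * (1 - 1e-9) or (
            resid <= best[0] * (1 + 1e-9) and vol < best[1]
        ):
            best = (resid, vol, x_clamped)
    rel_resid = float(best[0] / np.linalg.norm(f_wet))
    if rel_resid > 1e-3:
        raise RuntimeError(
            f"inversion did not converge (relative residual {rel_resid:.3g})"
        )
    load = DropletLoad(density=math.exp(best[2][0]), volume_m3=math.exp(best[2][1]))
    return load, rel_resid
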