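"""Deterministic fascicle mechanics.

A tendon fascicle is modeled as a two-phase composite: stiff collagen fibers
(area fraction ``f_r``, wound at a helix angle ``theta`` measured from the
plane perpendicular to the tendon axis) embedded in a soft, nearly
incompressible matrix.  The fibers carry a standard-linear-solid (SLS)
viscoelastic response — an equilibrium spring ``E_inf`` in parallel with a
Maxwell arm ``E_R``–``eta_f`` — while the matrix is treated as elastic and
time-constant.  Three observables are predicted per model class:

``q1``
    the initial (t = 0) fascicle elastic modulus in MPa,
``q2``
    the fascicle Poisson's ratio (lateral contraction per axial strain,
    which exceeds classical bounds because of the helical architecture),
``q3``
    the normalized stress-relaxation curve ``Ebar(t) = E_fasc(t)/E_fasc(0)``.

The elastic homogenization is a pluggable surrogate; the default is the plain
rule of mixtures with angle factor ``g(theta) = 1``.  The Poisson surrogate is
a blended helical-constraint formula that interpolates between the matrix
Poisson ratio and the rigid-fiber kinematic limit ``cot^2(90deg - theta)``.

Units are SI-consistent internally: MPa for moduli, MPa.s for viscosity,
seconds for time.  Fiber viscosity is reported externally in GPa.s
(1 GPa.s = 1000 MPa.s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CONTENT_GRID",
    "DEFAULT_ANGLE_GRID",
    "DEFAULT_POISSON_KAPPA",
    "DEFAULT_MATRIX_POISSON",
    "FascicleClass",
    "MaterialParams",
    "ObservablePrediction",
    "enumerate_model_classes",
    "elastic_modulus",
    "poisson_ratio",
    "relaxation_modulus",
    "normalized_relaxation",
    "predict_observables",
    "unit_angle_factor",
    "mpa_s_to_gpa_s",
    "gpa_s_to_mpa_s",
]

# Model-class grids: fiber contents 35%..65% in 5% steps, helix angles
# 70..76 degrees in 1-degree steps -> 7 x 7 = 49 classes.
DEFAULT_CONTENT_GRID: tuple[float, ...] = tuple(
    round(0.35 + 0.05 * i, 2) for i in range(7)
)
DEFAULT_ANGLE_GRID: tuple[float, ...] = tuple(float(a) for a in range(70, 77))

# Poisson surrogate constants: near-incompressible matrix and a blending
# constant kappa controlling how fast the helical-constraint limit is lost
# as the matrix stiffens relative to the fibers.
DEFAULT_MATRIX_POISSON: float = 0.5
DEFAULT_POISSON_KAPPA: float = 4.0e4

GPA_S_PER_MPA_S = 1.0e-3


def mpa_s_to_gpa_s(eta_mpa_s: float) -> float:
    """Convert a viscosity from MPa.s to GPa.s."""
    return eta_mpa_s * GPA_S_PER_MPA_S


def gpa_s_to_mpa_s(eta_gpa_s: float) -> float:
    """Convert a viscosity from GPa.s to MPa.s."""
    return eta_gpa_s / GPA_S_PER_MPA_S


def unit_angle_factor(helix_angle_deg: float) -> float:
    """Default elastic angle factor g(theta) = 1 (plain rule of mixtures)."""
    return 1.0


@dataclass(frozen=True)
class FascicleClass:
    """One fascicle model class: a (fiber content, helix angle) pair.

    Parameters
    ----------
    fiber_content
        Area fraction of the fascicle cross-section occupied by fibers,
        ``A_f / A_t``; must lie strictly in (0, 1).
    helix_angle_deg
        Fiber helix angle in degrees, measured from the plane perpendicular
        to the tendon axis (the angle from the axis is ``90 - theta``);
        must lie in [0, 90).
    """

    fiber_content: float
    helix_angle_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fiber_content <= 1.0:
            raise ValueError(
                f"fiber_content must lie in (0, 1]; got {self.fiber_content!r}"
            )
        if not 0.0 <= self.helix_angle_deg < 90.0:
            raise ValueError(
                f"helix_angle_deg must lie in [0, 90); got {self.helix_angle_deg!r}"
            )

    @property
    def axial_angle_deg(self) -> float:
        """Fiber angle measured from the tendon axis, 90 - theta."""
        return 90.0 - self.helix_angle_deg

    @property
    def label(self) -> str:
        return f"M{self.fiber_content * 100:.0f}_{self.helix_angle_deg:.0f}"


@dataclass(frozen=True)
class MaterialParams:
    """The inferred physical parameter vector plus the noise scale.

    Parameters
    ----------
    fiber_modulus
        Fiber elastic modulus ``E_f`` in MPa.
    fiber_viscosity
        Embedded-fiber viscosity ``eta_f`` in MPa.s (use
        :meth:`fiber_viscosity_gpa_s` / ``from_vector`` for GPa.s).
    matrix_modulus
        Matrix elastic modulus ``E_m`` in MPa.
    retained_fraction
        ``r_inf = E_inf / E_f``: the fraction of the fiber modulus surviving
        full relaxation; ``E_R = (1 - r_inf) E_f`` is the relaxing branch.
    error_scale
        Dimensionless proportional-error scale ``sigma_n``.
    """

    fiber_modulus: float
    fiber_viscosity: float
    matrix_modulus: float
    retained_fraction: float
    error_scale: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fiber_modulus", "fiber_viscosity", "matrix_modulus",
                     "retained_fraction", "error_scale"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0.0):
                raise ValueError(f"{name} must be finite and > 0; got {value!r}")
        if self.retained_fraction > 1.0:
            raise ValueError(
                f"retained_fraction must be <= 1; got {self.retained_fraction!r}"
            )

    @property
    def equilibrium_modulus(self) -> float:
        """E_inf = r_inf * E_f in MPa."""
        return self.retained_fraction * self.fiber_modulus

    @property
    def relaxing_modulus(self) -> float:
        """E_R = (1 - r_inf) * E_f in MPa."""
        return (1.0 - self.retained_fraction) * self.fiber_modulus

    @property
    def relaxation_time(self) -> float:
        """tau = eta_f / E_R in seconds (inf when r_inf = 1)."""
        e_r = self.relaxing_modulus
        return math.inf if e_r == 0.0 else self.fiber_viscosity / e_r

    @property
    def fiber_viscosity_gpa_s(self) -> float:
        return mpa_s_to_gpa_s(self.fiber_viscosity)

    # Vector convention used by the samplers: [E_f MPa, eta_f GPa.s, E_m MPa,
    # r_inf, sigma_n] — viscosity in GPa.s to match the prior statement.
    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.fiber_modulus,
                self.fiber_viscosity_gpa_s,
                self.matrix_modulus,
                self.retained_fraction,
                self.error_scale,
            ]
        )

    @classmethod
    def from_vector(cls, theta: Sequence[float]) -> "MaterialParams":
        e_f, eta_gpa_s, e_m, r_inf, sigma_n = (float(v) for v in theta)
        return cls(
            fiber_modulus=e_f,
            fiber_viscosity=gpa_s_to_mpa_s(eta_gpa_s),
            matrix_modulus=e_m,
            retained_fraction=r_inf,
            error_scale=sigma_n,
        )


PARAM_NAMES: tuple[str, ...] = ("E_f_MPa", "eta_f_GPa_s", "E_m_MPa", "r_inf", "sigma_n")


@dataclass(frozen=True)
class ObservablePrediction:
    """The three quantities of interest for one (params, class) pair."""

    elastic_modulus: float          # q1, MPa
    poisson_ratio: float            # q2, dimensionless
    times: np.ndarray = field(repr=False)        # seconds
    normalized_curve: np.ndarray = field(repr=False)  # q3, dimensionless

    @property
    def absolute_curve(self) -> np.ndarray:
        """Absolute relaxation curve anchored at q1: q1 * Ebar(t), MPa."""
        return self.elastic_modulus * self.normalized_curve


def enumerate_model_classes(
    content_grid: Sequence[float] = DEFAULT_CONTENT_GRID,
    angle_grid: Sequence[float] = DEFAULT_ANGLE_GRID,
) -> list[FascicleClass]:
    """Enumerate the fascicle model-class grid.

    Returns the Cartesian product of fiber contents and helix angles,
    content-major then angle; the default grids give 49 classes.
    """
    if len(content_grid) == 0 or len(angle_grid) == 0:
        raise ValueError("content_grid and angle_grid must be non-empty")
    for f_r in content_grid:
        if not 0.0 < f_r < 1.0:
            raise ValueError(f"fiber content {f_r!r} outside the open interval (0, 1)")
    for theta in angle_grid:
        if not 0.0 <= theta < 90.0:
            raise ValueError(f"helix angle {theta!r} outside [0, 90) degrees")
    return [
        FascicleClass(fiber_content=float(f_r), helix_angle_deg=float(theta))
        for f_r in content_grid
        for theta in angle_grid
    ]


def elastic_modulus(
    params: MaterialParams,
    cls: FascicleClass,
    angle_factor: Callable[[float], float] = unit_angle_factor,
) -> float:
    """Initial fascicle elastic modulus q1 in MPa.

    Rule-of-mixtures surrogate ``E = f_r * E_f * g(theta) + (1 - f_r) * E_m``
    with the default angle factor ``g = 1``.  With g = 1 the result is Voigt-
    bounded between ``min(E_f, E_m)`` and ``max(E_f, E_m)``.
    """
    f_r = cls.fiber_content
    g = angle_factor(cls.helix_angle_deg)
    return f_r * params.fiber_modulus * g + (1.0 - f_r) * params.matrix_modulus


def poisson_ratio(
    params: MaterialParams,
    cls: FascicleClass,
    kappa: float = DEFAULT_POISSON_KAPPA,
    matrix_poisson: float = DEFAULT_MATRIX_POISSON,
) -> float:
    """Fascicle Poisson's ratio q2 (helical-constraint surrogate).

    Interpolates between the matrix Poisson ratio ``nu_m`` (stiff-matrix
    limit) and the rigid-fiber kinematic limit ``nu_h = cot^2(90 - theta)``:

        nu = nu_m + (nu_h - nu_m) / (1 + kappa * x),
        x  = (E_m / E_f) * (1 - f_r) / f_r.

    Strictly decreasing in ``E_m`` and strictly increasing in ``theta``.
    """
    theta = cls.helix_angle_deg
    if theta >= 90.0:  # unreachable through FascicleClass, kept for raw use
        raise ValueError("helix angle of 90 degrees gives an undefined rigid limit")
    axial = math.radians(90.0 - theta)
    if axial <= 0.0:
        raise ValueError("helix angle of 90 degrees gives an undefined rigid limit")
    nu_h = 1.0 / math.tan(axial) ** 2
    f_r = cls.fiber_content
    x = (params.matrix_modulus / params.fiber_modulus) * (1.0 - f_r) / f_r
    return matrix_poisson + (nu_h - matrix_poisson) / (1.0 + kappa * x)


def relaxation_modulus(
    params: MaterialParams,
    cls: FascicleClass,
    times: Sequence[float],
) -> np.ndarray:
    """Absolute fascicle relaxation modulus E_fasc(t) in MPa.

    SLS fibers in an elastic, time-constant matrix:

        E_fasc(t) = f_r * (E_inf + E_R * exp(-(E_R / eta_f) * t))
                    + (1 - f_r) * E_m

    with ``E_inf = r_inf * E_f`` and ``E_R = (1 - r_inf) * E_f``.  Strictly
    decreasing in t whenever ``E_R, eta_f > 0``.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("relaxation times must be non-negative")
    f_r = cls.fiber_content
    e_inf = params.equilibrium_modulus
    e_r = params.relaxing_modulus
    if e_r == 0.0:
        fiber = np.full_like(t, e_inf)
    else:
        fiber = e_inf + e_r * np.exp(-(e_r / params.fiber_viscosity) * t)
    return f_r * fiber + (1.0 - f_r) * params.matrix_modulus


def normalized_relaxation(
    params: MaterialParams,
    cls: FascicleClass,
    times: Sequence[float],
) -> np.ndarray:
    """Normalized relaxation curve q3: Ebar(t) = E_fasc(t) / E_fasc(0).

    Starts at 1 at t = 0, is non-increasing, and decays toward the asymptote
    ``(f_r * E_inf + (1 - f_r) * E_m) / E_fasc(0)``.
    """
    initial = relaxation_modulus(params, cls, [0.0])[0]
    if initial <= 0.0:
        raise ValueError("initial fascicle modulus is non-positive; cannot normalize")
    return relaxation_modulus(params, cls, times) / initial


def predict_observables(
    params: MaterialParams,
    cls: FascicleClass,
    times: Sequence[float],
    angle_factor: Callable[[float], float] = unit_angle_factor,
    kappa: float = DEFAULT_POISSON_KAPPA,
    matrix_poisson: float = DEFAULT_MATRIX_POISSON,
) -> ObservablePrediction:
    """Bundle the three observables (q1, q2, q3) for one model class.

    The normalized curve is computed from the SLS mixture; the absolute curve
    exposed by the prediction is anchored as ``q1 * Ebar(t)`` so that a
    non-default elastic surrogate can never disagree with the t = 0 value.
    """
    t = np.asarray(times, dtype=float)
    return ObservablePrediction(
        elastic_modulus=elastic_modulus(params, cls, angle_factor=angle_factor),
        poisson_ratio=poisson_ratio(
            params, cls, kappa=kappa, matrix_poisson=matrix_poisson
        ),
        times=t,
        normalized_curve=normalized_relaxation(params, cls, t),
    )
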