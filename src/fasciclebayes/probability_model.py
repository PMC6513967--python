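"""Statistical model: uniform priors, proportional-error likelihood, posterior.

One fascicle dataset combines heterogeneous observations — a handful of
replicate elastic moduli, a single Poisson's ratio value, and ~30 points of a
normalized stress-relaxation curve.  Every datum ``d`` is modeled as Gaussian
around the forward prediction ``F`` with standard deviation proportional to
the prediction,

    d = F + F * eps,   eps ~ N(0, sigma_n^2),

so the likelihood standard deviation is ``sigma_n * F`` and residuals are
scale-free.  A single shared ``sigma_n`` covers all observable blocks; which
blocks enter the likelihood is selectable so that inference can be run
independently of the Poisson surrogate.

Priors are independent uniforms on a closed box (the paper-range defaults:
E_f in [500, 2500] MPa, eta_f in [0.1, 2500] GPa.s, E_m in [0.01, 5] MPa,
plus r_inf in [0.05, 0.95] and sigma_n in [0.001, 0.3]).

The module also owns the on-disk dataset format: a CSV with a small ``#``
header block (dataset id, Poisson value, semicolon-separated elastic moduli)
followed by ``time_s,Ebar`` columns.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from .forward_model import (
    DEFAULT_MATRIX_POISSON,
    DEFAULT_POISSON_KAPPA,
    FascicleClass,
    MaterialParams,
    PARAM_NAMES,
)

__all__ = [
    "OBSERVABLE_BLOCKS",
    "PriorSpec",
    "FascicleDataset",
    "log_prior",
    "prior_sample",
    "log_likelihood",
    "log_posterior",
    "make_log_prior_fn",
    "make_prior_sampler",
    "make_log_likelihood_fn",
    "read_dataset",
    "write_dataset",
]

logger = logging.getLogger(__name__)

OBSERVABLE_BLOCKS: tuple[str, ...] = ("elastic", "poisson", "relaxation")

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

# Raw proportional noise can push a normalized modulus slightly above 1
# (especially at t = 0); the upper validation bound tolerates that overshoot.
EBAR_UPPER_BOUND = 1.25


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior box, one (lower, upper) pair per parameter.

    Bounds are in reporting units: MPa for the moduli, GPa.s for the fiber
    viscosity, dimensionless for ``r_inf`` and ``sigma_n``.  The box is
    closed: boundary values carry finite prior density.
    """

    fiber_modulus: tuple[float, float] = (500.0, 2500.0)
    fiber_viscosity_gpa_s: tuple[float, float] = (0.1, 2500.0)
    matrix_modulus: tuple[float, float] = (0.01, 5.0)
    retained_fraction: tuple[float, float] = (0.05, 0.95)
    error_scale: tuple[float, float] = (0.001, 0.3)

    def __post_init__(self) -> None:
        for lo, hi in self.bounds():
            if not lo < hi:
                raise ValueError(f"prior bounds must satisfy lower < upper; got ({lo}, {hi})")

    def bounds(self) -> tuple[tuple[float, float], ...]:
        """Bounds in the sampler's vector order (matches PARAM_NAMES)."""
        return (
            self.fiber_modulus,
            self.fiber_viscosity_gpa_s,
            self.matrix_modulus,
            self.retained_fraction,
            self.error_scale,
        )

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds()])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds()])

    @property
    def log_volume(self) -> float:
        return float(np.sum(np.log(self.upper - self.lower)))


@dataclass(frozen=True)
class FascicleDataset:
    """One group of fascicle observations (an emulated Table-1 row).

    Attributes
    ----------
    dataset_id
        Short identifier, e.g. ``"D1"``.
    elastic_moduli
        Replicate fascicle elastic moduli in MPa.
    poisson_value
        Single fascicle Poisson's ratio value.
    times, ebar
        The normalized relaxation curve: strictly increasing times in
        seconds and the corresponding normalized moduli.
    provenance
        ``"fixture"`` for generated data, ``"file"`` for data read from disk.
    """

    dataset_id: str
    elastic_moduli: np.ndarray
    poisson_value: float
    times: np.ndarray
    ebar: np.ndarray
    provenance: str = "fixture"

    def __post_init__(self) -> None:
        object.__setattr__(self, "elastic_moduli",
                           np.asarray(self.elastic_moduli, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "ebar", np.asarray(self.ebar, dtype=float))
        if self.elastic_moduli.size == 0 or np.any(self.elastic_moduli <= 0):
            raise ValueError("elastic moduli must be a non-empty positive list")
        if not np.isfinite(self.poisson_value) or self.poisson_value <= 0:
            raise ValueError(f"poisson_value must be positive; got {self.poisson_value!r}")
        if self.times.shape != self.ebar.shape or self.times.ndim != 1:
            raise ValueError("times and ebar must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("relaxation times must be strictly increasing")
        if np.any(self.ebar <= 0) or np.any(self.ebar > EBAR_UPPER_BOUND):
            raise ValueError(
                f"normalized moduli must lie in (0, {EBAR_UPPER_BOUND}]"
            )

    @property
    def n_observations(self) -> int:
        return int(self.elastic_moduli.size) + 1 + int(self.times.size)


# ---------------------------------------------------------------------------
# Prior
# ---------------------------------------------------------------------------

def log_prior(params: MaterialParams, spec: PriorSpec = PriorSpec()) -> float:
    """Log-density of the uniform prior box at one parameter point.

    Returns ``-sum(log(width))`` inside (or on the boundary of) the box and
    ``-inf`` outside.
    """
    theta = params.to_vector()
    if np.all(theta >= spec.lower) and np.all(theta <= spec.upper):
        return -spec.log_volume
    return -np.inf


def prior_sample(
    spec: PriorSpec = PriorSpec(),
    n: int = 1,
    seed: int | np.random.Generator | None = None,
) -> list[MaterialParams]:
    """Draw ``n`` independent parameter vectors uniformly from the prior box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = rng.uniform(spec.lower, spec.upper, size=(n, len(PARAM_NAMES)))
    return [MaterialParams.from_vector(row) for row in draws]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _normalize_observables(observables: Iterable[str] | None) -> tuple[str, ...]:
    if observables is None:
        return OBSERVABLE_BLOCKS
    blocks = tuple(observables)
    unknown = set(blocks) - set(OBSERVABLE_BLOCKS)
    if unknown:
        raise ValueError(f"unknown observable blocks: {sorted(unknown)}")
    if not blocks:
        raise ValueError("at least one observable block must be enabled")
    return blocks


def _proportional_loglik(d: np.ndarray, f: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Sum of Gaussian log-densities with sd sigma * f, vectorized over rows.

    ``f`` has shape (n, k) (predictions for n parameter vectors, k data),
    ``d`` shape (k,), ``sigma`` shape (n,).  Rows with any non-positive
    prediction get -inf.
    """
    bad = np.any(f <= 0.0, axis=1)
    f_safe = np.where(f <= 0.0, 1.0, f)
    sd = sigma[:, None] * f_safe
    z = (d[None, :] - f_safe) / sd
    out = np.sum(-LOG_SQRT_2PI - np.log(sd) - 0.5 * z * z, axis=1)
    out[bad] = -np.inf
    return out


def make_log_likelihood_fn(
    data: FascicleDataset,
    cls: FascicleClass,
    observables: Iterable[str] | None = None,
    kappa: float = DEFAULT_POISSON_KAPPA,
    matrix_poisson: float = DEFAULT_MATRIX_POISSON,
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized log-likelihood over (n, 5) parameter-vector arrays.

    The returned callable evaluates the proportional-error Gaussian
    log-likelihood of ``data`` for every row of a parameter array in the
    sampler's vector convention ``[E_f, eta_f(GPa.s), E_m, r_inf, sigma_n]``.
    This is the hot path of the sampler, hence the array-level formulation;
    :func:`log_likelihood` is the scalar, dataclass-level wrapper.
    """
    blocks = _normalize_observables(observables)
    f_r = cls.fiber_content
    axial_rad = np.radians(90.0 - cls.helix_angle_deg)
    if axial_rad <= 0.0:
        raise ValueError("helix angle of 90 degrees gives an undefined rigid limit")
    nu_h = 1.0 / np.tan(axial_rad) ** 2
    t = data.times

    def loglik(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        e_f = theta[:, 0]
        eta = theta[:, 1] * 1000.0  # GPa.s -> MPa.s
        e_m = theta[:, 2]
        r_inf = theta[:, 3]
        sigma = theta[:, 4]

        total = np.zeros(theta.shape[0])
        q1 = f_r * e_f + (1.0 - f_r) * e_m

        if "elastic" in blocks:
            total += _proportional_loglik(data.elastic_moduli, q1[:, None], sigma)
        if "poisson" in blocks:
            x = (e_m / e_f) * (1.0 - f_r) / f_r
            q2 = matrix_poisson + (nu_h - matrix_poisson) / (1.0 + kappa * x)
            total += _proportional_loglik(
                np.array([data.poisson_value]), q2[:, None], sigma
            )
        if "relaxation" in blocks:
            e_r = (1.0 - r_inf) * e_f
            with np.errstate(divide="ignore", invalid="ignore"):
                rate = np.where(e_r > 0.0, e_r / eta, 0.0)
            fiber = r_inf[:, None] * e_f[:, None] + e_r[:, None] * np.exp(
                -rate[:, None] * t[None, :]
            )
            curve = (f_r * fiber + (1.0 - f_r) * e_m[:, None]) / q1[:, None]
            total += _proportional_loglik(data.ebar, curve, sigma)

        n_bad = int(np.sum(~np.isfinite(total) & (total != -np.inf)))
        if n_bad:
            logger.warning("%d parameter rows produced non-finite log-likelihoods", n_bad)
            total = np.where(np.isfinite(total) | (total == -np.inf), total, -np.inf)
        return total

    return loglik


def log_likelihood(
    params: MaterialParams,
    data: FascicleDataset,
    cls: FascicleClass,
    observables: Iterable[str] | None = None,
    **surrogate_kwargs,
) -> float:
    """Proportional-error Gaussian log-likelihood of one dataset.

    Independent Gaussians per datum with mean ``F`` and standard deviation
    ``sigma_n * F``, summed over the enabled observable blocks with one
    shared ``sigma_n``.  Returns ``-inf`` (with a logged warning) if any
    forward prediction is non-positive.
    """
    fn = make_log_likelihood_fn(data, cls, observables, **surrogate_kwargs)
    value = float(fn(params.to_vector()[None, :])[0])
    if value == -np.inf:
        logger.warning(
            "non-positive forward prediction at %s; proportional error undefined",
            params,
        )
    return value


def log_posterior(
    params: MaterialParams,
    data: FascicleDataset,
    cls: FascicleClass,
    spec: PriorSpec = PriorSpec(),
    observables: Iterable[str] | None = None,
    **surrogate_kwargs,
) -> float:
    """Unnormalized log-posterior: log-prior + log-likelihood."""
    lp = log_prior(params, spec)
    if lp == -np.inf:
        return -np.inf
    return lp + log_likelihood(params, data, cls, observables, **surrogate_kwargs)


def make_log_prior_fn(spec: PriorSpec = PriorSpec()) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized uniform-box log-prior over (n, 5) parameter arrays."""
    lower, upper, log_vol = spec.lower, spec.upper, spec.log_volume

    def logprior(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        inside = np.all((theta >= lower) & (theta <= upper), axis=1)
        return np.where(inside, -log_vol, -np.inf)

    return logprior


def make_prior_sampler(
    spec: PriorSpec = PriorSpec(),
) -> Callable[[int, np.random.Generator], np.ndarray]:
    """Vectorized uniform sampler over the prior box for the TMCMC driver."""
    lower, upper = spec.lower, spec.upper

    def sampler(n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(lower, upper, size=(n, lower.size))

    return sampler


# ---------------------------------------------------------------------------
# Dataset file format
# ---------------------------------------------------------------------------

def write_dataset(data: FascicleDataset, path: str | Path) -> None:
    """Write a dataset to the columnar text format.

    A ``#`` header block (dataset id, Poisson value, semicolon-separated
    elastic moduli) followed by ``time_s,Ebar`` rows; all numbers at 17
    significant digits so the round-trip is bit-exact.
    """
    buf = io.StringIO()
    moduli = ";".join(f"{v:.17g}" for v in data.elastic_moduli)
    buf.write(f"# dataset_id: {data.dataset_id}\n")
    buf.write(f"# poisson_value: {data.poisson_value:.17g}\n")
    buf.write(f"# elastic_moduli_MPa: {moduli}\n")
    buf.write("time_s,Ebar\n")
    for t, e in zip(data.times, data.ebar):
        buf.write(f"{t:.17g},{e:.17g}\n")
    Path(path).write_text(buf.getvalue())


def read_dataset(path: str | Path) -> FascicleDataset:
    """Read a dataset written by :func:`write_dataset`, validating invariants."""
    header: dict[str, str] = {}
    times: list[float] = []
    ebar: list[float] = []
    lines = Path(path).read_text().splitlines()
    body = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            header[key.strip()] = value.strip()
        else:
            body.append(line)
    for key in ("dataset_id", "poisson_value", "elastic_moduli_MPa"):
        if key not in header:
            raise ValueError(f"dataset file {path} is missing header field {key!r}")
    if not body or body[0] != "time_s,Ebar":
        raise ValueError(f"dataset file {path} is missing the 'time_s,Ebar' column header")
    for line in body[1:]:
        t_str, _, e_str = line.partition(",")
        times.append(float(t_str))
        ebar.append(float(e_str))
    return FascicleDataset(
        dataset_id=header["dataset_id"],
        elastic_moduli=np.array([float(v) for v in header["elastic_moduli_MPa"].split(";")]),
        poisson_value=float(header["poisson_value"]),
        times=np.array(times),
        ebar=np.array(ebar),
        provenance="file",
    )
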