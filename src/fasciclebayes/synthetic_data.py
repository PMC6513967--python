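"""Synthetic fascicle datasets with known ground truth.

The experimental relaxation curves this analysis was designed for exist only
as published figures, so the generator emulates their statistical structure:
replicate elastic moduli, one Poisson's ratio value, and a ~30-point
normalized relaxation curve, all perturbed by the same proportional noise
model the likelihood assumes (d = F * (1 + eps), eps ~ N(0, sigma_gen^2)).
Noisy relaxation points are kept raw — no clipping to 1 and no
re-monotonization — because handling noise is the likelihood's job, not the
data's.

:func:`make_fixture_suite` ships five datasets mirroring the study layout:
every dataset carries the three printed fascicle elastic moduli
{640, 480, 550} MPa verbatim, Poisson's ratio 1 (datasets 1, 3-5) or 3
(dataset 2), and relaxation curves whose ground truths are chosen inside the
experimentally reported envelope — a 40-70 % loss of the initial modulus
over horizons of 200-500 s and fiber viscosities of tens of GPa.s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import (
    FascicleClass,
    MaterialParams,
    gpa_s_to_mpa_s,
    predict_observables,
)
from .probability_model import FascicleDataset

__all__ = [
    "GeneratorSpec",
    "generate_dataset",
    "make_fixture_suite",
    "FIXTURE_TRUTHS",
    "FIXTURE_CLASS",
    "PRINTED_ELASTIC_MODULI",
    "PRINTED_POISSON_VALUES",
]

# Elastic moduli (MPa) and Poisson's ratios of the five study datasets.
PRINTED_ELASTIC_MODULI: tuple[float, ...] = (640.0, 480.0, 550.0)
PRINTED_POISSON_VALUES: dict[str, float] = {
    "D1": 1.0, "D2": 3.0, "D3": 1.0, "D4": 1.0, "D5": 1.0,
}

# Model class used to generate fixture relaxation curves.
FIXTURE_CLASS = FascicleClass(fiber_content=0.35, helix_angle_deg=70.0)


def _truth(e_f: float, eta_gpa_s: float, e_m: float, r_inf: float,
           sigma: float = 0.05) -> MaterialParams:
    return MaterialParams(
        fiber_modulus=e_f,
        fiber_viscosity=gpa_s_to_mpa_s(eta_gpa_s),
        matrix_modulus=e_m,
        retained_fraction=r_inf,
        error_scale=sigma,
    )


# Versioned fixture ground truths.  D1/D2 share one faster, deeper curve
# (tau = 50 s over a 300 s horizon); D3-D5 are slower variants with
# different retained fractions and relaxation times on 400-500 s horizons.
# All satisfy 1 - Ebar(horizon) in [0.40, 0.70].
FIXTURE_TRUTHS: dict[str, tuple[MaterialParams, float]] = {
    # dataset_id -> (ground truth, time horizon in seconds)
    "D1": (_truth(1400.0, 42.0, 0.4, 0.40), 300.0),
    "D2": (_truth(1400.0, 42.0, 0.4, 0.40), 300.0),
    "D3": (_truth(1400.0, 84.0, 0.4, 0.50), 400.0),
    "D4": (_truth(1400.0, 91.0, 0.4, 0.35), 400.0),
    "D5": (_truth(1400.0, 69.3, 0.4, 0.45), 500.0),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    ``noise_scale`` is the proportional noise sigma_gen applied to every
    generated datum; ``n_time_points`` equally spaced times span
    ``[0, time_horizon]``.
    """

    truth: MaterialParams
    cls: FascicleClass = FIXTURE_CLASS
    dataset_id: str = "synthetic"
    n_elastic_replicates: int = 3
    n_time_points: int = 30
    time_horizon: float = 300.0
    noise_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_time_points < 2:
            raise ValueError("n_time_points must be >= 2")
        if self.time_horizon <= 0:
            raise ValueError("time_horizon must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.n_elastic_replicates < 1:
            raise ValueError("n_elastic_replicates must be >= 1")


def generate_dataset(spec: GeneratorSpec) -> FascicleDataset:
    """Generate one dataset from known ground truth plus proportional noise.

    Elastic replicates are ``q1 * (1 + eps_k)``, the Poisson value is
    ``q2 * (1 + eps)``, and the relaxation curve is ``q3(t_j) * (1 + eps_j)``
    at ``n_time_points`` equally spaced times from 0 to the horizon.  The
    noise is kept raw (no clipping or re-monotonization) and the draw is
    deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(0.0, spec.time_horizon, spec.n_time_points)
    pred = predict_observables(spec.truth, spec.cls, times)

    def noisy(values: np.ndarray, n: int) -> np.ndarray:
        return values * (1.0 + spec.noise_scale * rng.standard_normal(n))

    elastic = noisy(np.full(spec.n_elastic_replicates, pred.elastic_modulus),
                    spec.n_elastic_replicates)
    poisson = float(noisy(np.array([pred.poisson_ratio]), 1)[0])
    ebar = noisy(pred.normalized_curve, spec.n_time_points)
    return FascicleDataset(
        dataset_id=spec.dataset_id,
        elastic_moduli=elastic,
        poisson_value=poisson,
        times=times,
        ebar=ebar,
        provenance="fixture",
    )


def make_fixture_suite(
    seed: int = 0,
    noise_scale: float = 0.05,
    n_time_points: int = 30,
) -> list[tuple[FascicleDataset, MaterialParams]]:
    """Build the five-dataset fixture suite emulating the study's Table 1.

    Each entry pairs a dataset with its relaxation-curve ground truth so
    recovery tests can score the inference.  The elastic block reuses the
    three printed study means {640, 480, 550} MPa verbatim and the Poisson
    values are exactly 1 or 3 as printed; only the relaxation curve carries
    generated (noisy) values.
    """
    suite: list[tuple[FascicleDataset, MaterialParams]] = []
    for i, (dataset_id, (truth, horizon)) in enumerate(FIXTURE_TRUTHS.items()):
        gen = GeneratorSpec(
            truth=truth,
            cls=FIXTURE_CLASS,
            dataset_id=dataset_id,
            n_time_points=n_time_points,
            time_horizon=horizon,
            noise_scale=noise_scale,
            seed=(int(seed) * 1000 + 7 * i) % (2**31),
        )
        generated = generate_dataset(gen)
        dataset = FascicleDataset(
            dataset_id=dataset_id,
            elastic_moduli=np.array(PRINTED_ELASTIC_MODULI),
            poisson_value=PRINTED_POISSON_VALUES[dataset_id],
            times=generated.times,
            ebar=generated.ebar,
            provenance="fixture",
        )
        suite.append((dataset, truth))
    return suite
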