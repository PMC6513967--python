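"""Grid orchestration: inference over model classes x datasets.

Runs one independent TMCMC inference per (fascicle class, dataset) cell,
collects MAP values, 95 % central credible intervals, evidence and stage
diagnostics into a flat table (the machine twin of the study's supplementary
MAP tables), aggregates per-parameter MAP ranges across the grid, exports
everything to CSV with a run manifest, and replays fitted relaxation curves
against the data they were fitted to.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .forward_model import (
    FascicleClass,
    MaterialParams,
    PARAM_NAMES,
    normalized_relaxation,
)
from .probability_model import (
    FascicleDataset,
    PriorSpec,
    make_log_likelihood_fn,
    make_log_prior_fn,
    make_prior_sampler,
)
from .tmcmc import PosteriorEnsemble, TmcmcConfig, TmcmcError, map_estimate, run_tmcmc

__all__ = [
    "GridResultTable",
    "RangeSummary",
    "cell_seed",
    "run_cell",
    "run_inference_grid",
    "summarize_ranges",
    "export_tables",
    "replay_fit",
    "load_config",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"

# Soft / hard bounds on the inferred proportional error for 5 %-noise data:
# warn above 8 % (the narrative bound), treat above 12 % as suspect.
SIGMA_SOFT_BOUND = 0.08
SIGMA_HARD_BOUND = 0.12


def cell_seed(master_seed: int, cls: FascicleClass, dataset_id: str) -> int:
    """Stable per-cell seed derived from the master seed and cell identity."""
    key = f"{master_seed}|{cls.fiber_content:.6f}|{cls.helix_angle_deg:.6f}|{dataset_id}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _cell_key(cls: FascicleClass, dataset_id: str) -> str:
    return f"fr{cls.fiber_content * 100:.0f}_th{cls.helix_angle_deg:.0f}_{dataset_id}"


@dataclass
class GridResultTable:
    """MAP/interval summaries per (class x dataset) plus posterior samples.

    ``table`` has one row per requested cell with columns ``f_r``,
    ``theta_deg``, ``dataset_id``, ``seed``, ``success``, ``message``,
    ``log_evidence``, ``n_stages`` and, per parameter, ``<name>_map``,
    ``<name>_lo`` and ``<name>_hi`` (95 % central interval).  ``samples``
    maps a cell key to its final-stage posterior sample frame.
    """

    table: pd.DataFrame
    samples: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def successful(self) -> pd.DataFrame:
        return self.table[self.table["success"]]


@dataclass(frozen=True)
class RangeSummary:
    """Per-parameter min/max of MAP values across all grid cells."""

    table: pd.DataFrame  # columns: parameter, map_min, map_max


def run_cell(
    dataset: FascicleDataset,
    cls: FascicleClass,
    prior: PriorSpec,
    config: TmcmcConfig,
    observables: Iterable[str] | None = None,
    refine: bool = True,
    **surrogate_kwargs,
) -> PosteriorEnsemble:
    """Run one TMCMC inference for a single (class, dataset) cell."""
    ensemble = run_tmcmc(
        make_log_prior_fn(prior),
        make_log_likelihood_fn(dataset, cls, observables, **surrogate_kwargs),
        make_prior_sampler(prior),
        config,
        param_names=PARAM_NAMES,
    )
    map_estimate(ensemble, refine=refine)
    return ensemble


def run_inference_grid(
    datasets: Iterable[FascicleDataset],
    classes: Iterable[FascicleClass],
    prior: PriorSpec = PriorSpec(),
    config: TmcmcConfig = TmcmcConfig(),
    observables: Iterable[str] | None = None,
    refine: bool = True,
    keep_samples: bool = True,
    **surrogate_kwargs,
) -> GridResultTable:
    """Independent TMCMC inference for every (class, dataset) cell.

    Each cell runs with its own derived seed (:func:`cell_seed`), so results
    are reproducible and order-independent.  A failing cell is flagged in
    its row (``success = False`` plus a message) without aborting the grid.
    """
    datasets = list(datasets)
    classes = list(classes)
    if not datasets or not classes:
        raise ValueError("datasets and classes must be non-empty")

    rows = []
    samples: dict[str, pd.DataFrame] = {}
    for cls in classes:
        for dataset in datasets:
            seed = cell_seed(config.seed, cls, dataset.dataset_id)
            cell_cfg = TmcmcConfig(
                samples_per_stage=config.samples_per_stage,
                target_weight_cov=config.target_weight_cov,
                proposal_scale=config.proposal_scale,
                max_stages=config.max_stages,
                mh_steps_per_sample=config.mh_steps_per_sample,
                seed=seed,
            )
            row: dict[str, object] = {
                "f_r": cls.fiber_content,
                "theta_deg": cls.helix_angle_deg,
                "dataset_id": dataset.dataset_id,
                "seed": seed,
            }
            try:
                ensemble = run_cell(
                    dataset, cls, prior, cell_cfg, observables,
                    refine=refine, **surrogate_kwargs,
                )
            except TmcmcError as exc:
                logger.error("cell %s failed: %s", _cell_key(cls, dataset.dataset_id), exc)
                row.update({"success": False, "message": str(exc),
                            "log_evidence": np.nan, "n_stages": len(exc.stage_record)})
                for name in PARAM_NAMES:
                    row.update({f"{name}_map": np.nan, f"{name}_lo": np.nan,
                                f"{name}_hi": np.nan})
                rows.append(row)
                continue

            interval = ensemble.credible_interval(0.95)
            map_theta = ensemble.map_sample
            row.update({
                "success": True,
                "message": "",
                "log_evidence": ensemble.log_evidence,
                "n_stages": ensemble.n_stages,
            })
            for k, name in enumerate(PARAM_NAMES):
                row[f"{name}_map"] = float(map_theta[k])
                row[f"{name}_lo"] = float(interval[k, 0])
                row[f"{name}_hi"] = float(interval[k, 1])
            sigma_map = float(map_theta[PARAM_NAMES.index("sigma_n")])
            if sigma_map > SIGMA_SOFT_BOUND:
                logger.warning(
                    "cell %s inferred sigma_n = %.3f above the %.0f%% bound",
                    _cell_key(cls, dataset.dataset_id), sigma_map,
                    100 * SIGMA_SOFT_BOUND,
                )
            rows.append(row)
            if keep_samples:
                frame = pd.DataFrame(ensemble.samples, columns=list(PARAM_NAMES))
                frame["log_prior"] = ensemble.log_prior_values
                frame["log_likelihood"] = ensemble.log_likelihood_values
                samples[_cell_key(cls, dataset.dataset_id)] = frame

    return GridResultTable(table=pd.DataFrame(rows), samples=samples)


def summarize_ranges(result: GridResultTable) -> RangeSummary:
    """Per-parameter min/max of MAP values over all successful cells."""
    ok = result.successful
    if ok.empty:
        raise ValueError("no successful cells to summarize")
    rows = [
        {
            "parameter": name,
            "map_min": float(ok[f"{name}_map"].min()),
            "map_max": float(ok[f"{name}_map"].max()),
        }
        for name in PARAM_NAMES
    ]
    return RangeSummary(table=pd.DataFrame(rows))


def export_tables(
    result: GridResultTable,
    summary: RangeSummary,
    out_dir: str | Path,
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Write grid results, range summary, per-cell samples and a manifest.

    Output is deterministic: identical inputs re-export byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    grid_path = out / "grid_results.csv"
    result.table.to_csv(grid_path, index=False, float_format=_FLOAT_FMT)
    paths["grid_results"] = grid_path

    summary_path = out / "range_summary.csv"
    summary.table.to_csv(summary_path, index=False, float_format=_FLOAT_FMT)
    paths["range_summary"] = summary_path

    samples_dir = out / "samples"
    samples_dir.mkdir(exist_ok=True)
    for key in sorted(result.samples):
        sample_path = samples_dir / f"{key}.csv"
        result.samples[key].to_csv(sample_path, index=False, float_format=_FLOAT_FMT)
        paths[f"samples/{key}"] = sample_path

    from . import __version__

    manifest = {
        "package_version": __version__,
        "cells": [
            {
                "f_r": float(r["f_r"]),
                "theta_deg": float(r["theta_deg"]),
                "dataset_id": str(r["dataset_id"]),
                "seed": int(r["seed"]),
                "success": bool(r["success"]),
            }
            for r in result.table.to_dict("records")
        ],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths


def replay_fit(
    row: pd.Series,
    dataset: FascicleDataset,
    times: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Replay a fitted relaxation curve against the observed one.

    Recomputes the normalized relaxation curve at the row's MAP parameters
    at the dataset's time points and pairs it with the observed values.
    Returns the paired frame together with the maximum absolute and maximum
    relative deviation (reported, never asserted).
    """
    if not bool(row["success"]):
        raise ValueError("cannot replay a failed cell")
    cls = FascicleClass(fiber_content=float(row["f_r"]),
                        helix_angle_deg=float(row["theta_deg"]))
    params = MaterialParams.from_vector([row[f"{n}_map"] for n in PARAM_NAMES])
    t = dataset.times if times is None else np.asarray(times, dtype=float)
    predicted = normalized_relaxation(params, cls, t)
    frame = pd.DataFrame({"time_s": t, "observed": np.interp(t, dataset.times, dataset.ebar)
                          if times is not None else dataset.ebar,
                          "predicted": predicted})
    dev = frame["observed"] - frame["predicted"]
    max_abs = float(np.max(np.abs(dev)))
    max_rel = float(np.max(np.abs(dev) / frame["predicted"]))
    return frame, max_abs, max_rel


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration.

    Recognized top-level keys: ``prior`` (PriorSpec fields), ``tmcmc``
    (TmcmcConfig fields), ``surrogate`` (``kappa``, ``matrix_poisson``) and
    ``observables`` (list of block names).  Returns a dict with constructed
    ``prior`` / ``tmcmc`` objects and pass-through extras.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    prior_cfg = raw.get("prior", {})
    prior = PriorSpec(**{k: tuple(v) if isinstance(v, (list, tuple)) else v
                         for k, v in prior_cfg.items()})
    tmcmc_cfg = TmcmcConfig(**raw.get("tmcmc", {}))
    return {
        "prior": prior,
        "tmcmc": tmcmc_cfg,
        "surrogate": raw.get("surrogate", {}),
        "observables": raw.get("observables"),
    }
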