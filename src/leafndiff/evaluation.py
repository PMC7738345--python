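"""Metrics and the reduction x model experiment grid.

``run_grid`` realizes the full study matrix: one synthetic field campaign,
one standard-field reference and train/validation split, then every
requested reduction (dwmd / spa / pca / iriv) feeding every requested
model (plsr / elm / gaelm) on byte-identical features per reduction.
Every random draw descends from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import models as _models
from .band_selection import iriv_features, pca_extract, spa_features
from .differencing import (build_reference, compute_differences,
                           select_standard, split_train_validation)
from .features import FeatureSet
from .simulate import SimulationConfig, generate_samples, generate_yields
from .wavelets import WaveletSpec, extract_features, select_wavelet_and_level

logger = logging.getLogger("leafndiff")

__all__ = [
    "r_squared",
    "rmse",
    "FitReport",
    "ExperimentConfig",
    "ExperimentGrid",
    "run_grid",
    "load_config",
]

REDUCTIONS = ("dwmd", "spa", "pca", "iriv")
MODELS = ("plsr", "elm", "gaelm")


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SST."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in y_true")
    sse = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - sse / sst


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error, in the units of the target (mg/g for ΔN)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size < 1:
        raise ValueError("need at least 1 sample")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


@dataclass(frozen=True)
class FitReport:
    """Per-cell accuracy of the experiment grid."""

    reduction: str
    model: str
    r2_train: float | None = None
    rmse_train: float | None = None
    r2_val: float | None = None
    rmse_val: float | None = None
    seed: int | None = None
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    error: str | None = None


@dataclass(frozen=True)
class ExperimentConfig:
    """One master seed plus the stage settings of the pipeline."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    split_fraction: float = 0.73
    reductions: tuple[str, ...] = REDUCTIONS
    models: tuple[str, ...] = MODELS
    wavelet_family: str | None = "sym8"   # None -> select from the data
    wavelet_level: int = 10
    pca_components: int = 5
    spa_candidate_n: tuple[int, ...] = (5,)
    hidden_nodes: int = 20
    plsr_latent: int | None = None
    ga: _models.GaParams = field(default_factory=_models.GaParams)

    def __post_init__(self) -> None:
        for r in self.reductions:
            if r not in REDUCTIONS:
                raise ValueError(f"unknown reduction {r!r}")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")


@dataclass(frozen=True)
class ExperimentGrid:
    config: ExperimentConfig
    reports: tuple[FitReport, ...]
    features: dict[str, FeatureSet]
    standard_treatment: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            row = asdict(r)
            row["hyperparameters"] = repr(r.hyperparameters)
            rows.append(row)
        return pd.DataFrame(rows)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ["simulate", "split", "spa", "iriv", "model"]
    states = ss.generate_state(len(names))
    return {name: int(s % (2**31 - 1)) for name, s in zip(names, states)}


def _fit_cell(model_name: str, feats: FeatureSet, y_train: np.ndarray,
              config: ExperimentConfig, seed: int):
    Xtr = feats.X_train
    if model_name == "plsr":
        m = _models.plsr_fit(Xtr, y_train, n_latent=config.plsr_latent,
                             seed=seed)
        hp = {"n_latent": m.n_latent}
    elif model_name == "elm":
        m = _models.elm_fit(Xtr, y_train, s2=config.hidden_nodes, seed=seed)
        hp = {"s2": config.hidden_nodes}
    elif model_name == "gaelm":
        m = _models.ga_elm_fit(Xtr, y_train, s2=config.hidden_nodes,
                               ga_params=config.ga, seed=seed)
        hp = {"s2": config.hidden_nodes,
              "population": config.ga.population,
              "generations": config.ga.generations}
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(model_name)
    return m, hp


def run_grid(config: ExperimentConfig) -> ExperimentGrid:
    """Run the full pipeline for every requested reduction x model cell."""
    seeds = _stage_seeds(config.seed)
    sim = replace(config.simulation, seed=seeds["simulate"])
    samples = generate_samples(sim)
    yields = generate_yields(sim)
    std = select_standard(yields)
    reference = build_reference(samples, std)
    diffs = compute_differences(samples, reference)
    diffs = split_train_validation(diffs, config.split_fraction,
                                   seed=seeds["split"])
    y_train = diffs.delta_n[diffs.train_mask]
    y_val = diffs.delta_n[diffs.validation_mask]
    logger.info("simulated %d samples; standard treatment %d kg/ha; "
                "split %d/%d", len(samples), std, len(y_train), len(y_val))

    features: dict[str, FeatureSet] = {}
    reports: list[FitReport] = []
    for red in config.reductions:
        try:
            if red == "dwmd":
                if config.wavelet_family is None:
                    spec, _ = select_wavelet_and_level(
                        diffs.delta_r[diffs.train_mask])
                else:
                    spec = WaveletSpec(config.wavelet_family,
                                       config.wavelet_level)
                feats = extract_features(diffs, spec)
            elif red == "spa":
                feats = spa_features(diffs,
                                     candidate_N_range=config.spa_candidate_n,
                                     seed=seeds["spa"])
            elif red == "pca":
                _, feats = pca_extract(diffs,
                                       n_components=config.pca_components)
            elif red == "iriv":
                feats = iriv_features(diffs, seed=seeds["iriv"])
            features[red] = feats
            logger.info("reduction %s -> %d features", red, feats.n_features)
        except Exception as exc:  # record, keep going
            logger.warning("reduction %s failed: %s", red, exc)
            for model_name in config.models:
                reports.append(FitReport(reduction=red, model=model_name,
                                         error=f"reduction failed: {exc}"))
            continue

        for model_name in config.models:
            try:
                m, hp = _fit_cell(model_name, feats, y_train, config,
                                  seeds["model"])
                pred_tr = _models.predict(m, feats.X_train)
                pred_va = _models.predict(m, feats.X_val)
                reports.append(FitReport(
                    reduction=red, model=model_name,
                    r2_train=r_squared(y_train, pred_tr),
                    rmse_train=rmse(y_train, pred_tr),
                    r2_val=r_squared(y_val, pred_va),
                    rmse_val=rmse(y_val, pred_va),
                    seed=seeds["model"], hyperparameters=hp))
            except Exception as exc:
                logger.warning("cell %s x %s failed: %s", red, model_name, exc)
                reports.append(FitReport(reduction=red, model=model_name,
                                         error=str(exc)))
    return ExperimentGrid(config=config, reports=tuple(reports),
                          features=features, standard_treatment=std)


def load_config(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    Sections: ``simulate`` (SimulationConfig fields), ``difference``
    (split fraction), ``reduce`` (methods, wavelet, pca, spa settings),
    ``model`` (models, hidden nodes, GA settings) and a top-level ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = dict(raw.get("simulate", {}))
    for key in ("treatments", "n_mean_by_treatment"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    red = raw.get("reduce", {})
    mod = raw.get("model", {})
    kwargs: dict[str, Any] = {
        "seed": int(raw.get("seed", 0)),
        "simulation": SimulationConfig(**sim_kwargs),
        "split_fraction": float(raw.get("difference", {})
                                .get("fraction", 0.73)),
    }
    if "methods" in red:
        kwargs["reductions"] = tuple(red["methods"])
    if "wavelet_family" in red:
        kwargs["wavelet_family"] = red["wavelet_family"]
    if "wavelet_level" in red:
        kwargs["wavelet_level"] = int(red["wavelet_level"])
    if "pca_components" in red:
        kwargs["pca_components"] = int(red["pca_components"])
    if "spa_candidate_n" in red:
        kwargs["spa_candidate_n"] = tuple(red["spa_candidate_n"])
    if "models" in mod:
        kwargs["models"] = tuple(mod["models"])
    if "hidden_nodes" in mod:
        kwargs["hidden_nodes"] = int(mod["hidden_nodes"])
    if "plsr_latent" in mod:
        kwargs["plsr_latent"] = mod["plsr_latent"]
    ga_kwargs = mod.get("ga", {})
    if ga_kwargs:
        kwargs["ga"] = _models.GaParams(**ga_kwargs)
    return ExperimentConfig(**kwargs)
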