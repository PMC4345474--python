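"""End-to-end fidelity-augmentation experiment.

The experiment mirrors the published protocol: solve the transport problem on
a nested refinement hierarchy (baseline L0 plus refinements L1..L3), train a
Kriging surrogate whose inputs are L0 neighbourhood features and whose
targets are the L1 solution at the same (nested) nodes, deploy it on L1
features, and score the deployed predictions against the highest-density
solution (L3, the "truth") at the L1 nodes.  Two reference errors anchor the
comparison: RMSE_03 (baseline vs truth, over L0 nodes) and RMSE_13 (L1 vs
truth, over L1 nodes).  A surrogate beats raw refinement when its deployed
RMSE is below RMSE_13.  Model fidelity during training is reported by
k-fold cross-validation (k = 5) repeated over s shuffles (s = 10).

Every RMSE is computed over the coarser member's node set, which nested
refinement makes exact (no interpolation); the deployed-surrogate RMSE and
RMSE_13 therefore share the same node set and are directly comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    SUPPORTED_METRICS,
    build_feature_table,
    build_training_set,
    nearest_neighbors,
)
from .gp import DEFAULT_LOG10_BOUNDS, fit_surrogate, predict
from .mesh import DomainGeometry, build_hierarchy, common_nodes
from .transport import ConcentrationField, SolverSettings, TransportParameters, solve_transient

__all__ = [
    "CVConfig",
    "ExperimentConfig",
    "FidelityReport",
    "PipelineError",
    "rmse",
    "reference_rmses",
    "crossvalidate",
    "run_experiment",
    "sweep",
]

log = logging.getLogger("meshlift")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference between two equal-length vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 1:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class CVConfig:
    """k-fold cross-validation repeated over s shuffles."""

    k: int = 5
    s: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.s < 1:
            raise ValueError("s must be >= 1")


def reference_rmses(
    fields: list[ConcentrationField], output_kind: str
) -> tuple[float, float]:
    """(RMSE_03, RMSE_13): baseline and first-refinement solutions against
    the highest-density solution, each over the coarser level's node set."""
    if len(fields) < 4:
        raise PipelineError("reference_rmses: need a hierarchy of >= 4 levels")
    truth = fields[-1]
    out = []
    for lvl in (0, 1):
        pairs = common_nodes(fields[lvl].mesh, truth.mesh)
        out.append(
            rmse(
                fields[lvl].values(output_kind)[pairs[:, 0]],
                truth.values(output_kind)[pairs[:, 1]],
            )
        )
    return out[0], out[1]


def crossvalidate(train, cv: CVConfig, **fit_kwargs) -> dict:
    """Shuffled k-fold CV of the surrogate on a training set.

    Shuffle i uses seed ``cv.seed + i``; each shuffle is partitioned into k
    folds whose sizes differ by at most one.  Returns the (s, k) array of
    per-fold RMSEs and their grand mean.
    """
    l = train.l
    if l < cv.k:
        raise ValueError(f"need at least k={cv.k} samples, got {l}")
    from .features import TrainingSet

    raw = np.zeros((cv.s, cv.k))
    for i in range(cv.s):
        rng = np.random.default_rng(cv.seed + i)
        perm = rng.permutation(l)
        folds = np.array_split(perm, cv.k)
        for j, hold in enumerate(folds):
            keep = np.setdiff1d(perm, hold, assume_unique=True)
            sub = TrainingSet(
                X=train.X[keep], y=train.y[keep], J=train.J,
                metric=train.metric, output_kind=train.output_kind,
            )
            model, _ = fit_surrogate(sub, **fit_kwargs)
            pred = predict(model, train.X[hold], return_var=False)
            raw[i, j] = rmse(pred, train.y[hold])
    return {"raw": raw, "mean": float(raw.mean()), "seeds": [cv.seed + i for i in range(cv.s)]}


@dataclass
class ExperimentConfig:
    """Resolved settings for one fidelity-augmentation experiment."""

    geometry: DomainGeometry = field(default_factory=DomainGeometry)
    transport: TransportParameters = field(default_factory=TransportParameters)
    solver: SolverSettings = field(default_factory=SolverSettings)
    target_elements: int = 600
    n_refinements: int = 3
    metrics: tuple = ("cityblock",)
    J_values: tuple = (10, 25, 50)
    output_kinds: tuple = ("free", "bound")
    cv: CVConfig | None = field(default_factory=CVConfig)
    gp_mode: str = "grouped"
    gp_budget: int = 2000
    cv_budget: int | None = 500   # smaller search budget inside the CV loop
    log10_bounds: tuple = DEFAULT_LOG10_BOUNDS
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        # the output location is environment, not science: keep it out of the
        # report snapshot so identical experiments produce identical reports
        d.pop("outdir", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = DomainGeometry(**d["geometry"])
        if "transport" in d and isinstance(d["transport"], dict):
            d["transport"] = TransportParameters(**d["transport"])
        if "solver" in d and isinstance(d["solver"], dict):
            d["solver"] = SolverSettings(**d["solver"])
        if "cv" in d and isinstance(d["cv"], dict):
            d["cv"] = CVConfig(**d["cv"])
        for key in ("metrics", "J_values", "output_kinds", "log10_bounds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


@dataclass
class FidelityReport:
    """All RMSE references and surrogate scores from one experiment."""

    rmse_03: dict
    rmse_13: dict
    cells: list          # one dict per (output_kind, metric, J)
    config: dict
    node_counts: dict

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        payload = clean(
            {
                "rmse_03": self.rmse_03,
                "rmse_13": self.rmse_13,
                "cells": self.cells,
                "config": self.config,
                "node_counts": self.node_counts,
            }
        )
        return json.dumps(payload, sort_keys=True, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "output_kind": c["output_kind"],
                    "metric": c["metric"],
                    "J": c["J"],
                    "rmse_cv_mean": c.get("rmse_cv_mean"),
                    "rmse_pred_vs_truth": c["rmse_pred_vs_truth"],
                    "rmse_03": self.rmse_03[c["output_kind"]],
                    "rmse_13": self.rmse_13[c["output_kind"]],
                }
            )
        return pd.DataFrame(rows)


def _solve_hierarchy(config: ExperimentConfig):
    try:
        meshes = build_hierarchy(
            config.geometry, config.target_elements, config.n_refinements, seed=config.seed
        )
    except Exception as exc:
        raise PipelineError(f"mesh stage failed: {exc}") from exc
    fields = []
    for m in meshes:
        log.info("solving level %d (%d elements)", m.level, m.n_elements)
        try:
            fields.append(solve_transient(m, config.transport, config.solver))
        except Exception as exc:
            raise PipelineError(f"solve stage failed at level {m.level}: {exc}") from exc
    return meshes, fields


def run_experiment(config: ExperimentConfig) -> FidelityReport:
    """Execute the full experiment described in the module docstring.

    When ``config.outdir`` is set, the resolved config, a run log, the report
    (JSON) and the tidy per-cell table (CSV) are written there.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    try:
        meshes, fields = _solve_hierarchy(config)
        truth = fields[-1]

        rmse03, rmse13 = {}, {}
        for kind in config.output_kinds:
            rmse03[kind], rmse13[kind] = reference_rmses(fields, kind)

        pairs_1T = common_nodes(meshes[1], truth.mesh)
        pairs_01 = common_nodes(meshes[0], meshes[1])

        cells = []
        for metric in config.metrics:
            if metric not in SUPPORTED_METRICS:
                raise PipelineError(f"feature stage: unsupported metric {metric!r}")
            for J in config.J_values:
                try:
                    nb0 = nearest_neighbors(meshes[0], J, metric)
                    nb1 = nearest_neighbors(meshes[1], J, metric)
                except Exception as exc:
                    raise PipelineError(f"feature stage failed (metric={metric}, J={J}): {exc}") from exc
                for kind in config.output_kinds:
                    log.info("cell metric=%s J=%d output=%s", metric, J, kind)
                    feats0 = build_feature_table(fields[0], nb0, kind)
                    train = build_training_set(feats0, fields[1], pairs_01)
                    cell = {"output_kind": kind, "metric": metric, "J": int(J)}
                    if config.cv is not None:
                        cv_seed = config.cv.seed if config.cv.seed else config.seed
                        cv_cfg = CVConfig(k=config.cv.k, s=config.cv.s, seed=cv_seed)
                        cv_res = crossvalidate(
                            train,
                            cv_cfg,
                            mode=config.gp_mode,
                            budget=config.cv_budget or config.gp_budget,
                            log10_bounds=config.log10_bounds,
                        )
                        cell["rmse_cv_mean"] = cv_res["mean"]
                        cell["rmse_cv_raw"] = cv_res["raw"].tolist()
                        cell["cv_seeds"] = cv_res["seeds"]
                    try:
                        model, mle = fit_surrogate(
                            train,
                            mode=config.gp_mode,
                            budget=config.gp_budget,
                            log10_bounds=config.log10_bounds,
                        )
                    except Exception as exc:
                        raise PipelineError(f"train stage failed: {exc}") from exc
                    feats1 = build_feature_table(fields[1], nb1, kind)
                    pred = predict(model, feats1.X, return_var=False)
                    cell["rmse_pred_vs_truth"] = rmse(
                        pred[pairs_1T[:, 0]], truth.values(kind)[pairs_1T[:, 1]]
                    )
                    cell["theta_hat"] = mle.theta_hat.tolist()
                    cell["beta_hat"] = mle.beta_hat
                    cell["sigma2_hat"] = mle.sigma2_hat
                    cells.append(cell)

        report = FidelityReport(
            rmse_03=rmse03,
            rmse_13=rmse13,
            cells=cells,
            config=config.to_dict(),
            node_counts={str(m.level): int(m.n_nodes) for m in meshes},
        )
        if outdir:
            (outdir / "report.json").write_text(report.to_json())
            report.to_frame().to_csv(outdir / "report.csv", index=False)
            (outdir / "config.json").write_text(
                json.dumps(report.config, sort_keys=True, indent=2, default=str)
            )
        return report
    finally:
        if outdir:
            log.removeHandler(handler)
            handler.close()


def sweep(metrics, J_values, config: ExperimentConfig) -> pd.DataFrame:
    """Grid of cross-validated and deployed RMSEs over metric x J cells."""
    if not metrics or not J_values:
        raise ValueError("metrics and J_values must be non-empty")
    from dataclasses import replace

    cfg = replace(config, metrics=tuple(metrics), J_values=tuple(J_values))
    return run_experiment(cfg).to_frame()
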