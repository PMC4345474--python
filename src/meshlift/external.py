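"""Learning pipeline on externally computed node/solution tables.

Any solver — including 3-D ones — can feed the surrogate: each refinement
level is a CSV node table with coordinate columns (``x, y`` or ``x, y, z``)
and a ``value`` column, and the nesting between consecutive levels is a JSON
list mapping each coarse node index to its (coordinate-identical) fine node
index.  The feature construction, Kriging training and RMSE protocol are
then exactly the ones used for the built-in transport solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import build_feature_table, build_training_set, nearest_neighbors
from .gp import fit_surrogate, predict
from .pipeline import rmse
from .transport import ConcentrationField

__all__ = ["PointCloud", "load_level_table", "load_nesting_map", "run_external"]


@dataclass
class PointCloud:
    """Duck-typed stand-in for a mesh in the learning pipeline: coordinates
    and a level index are all the feature construction needs."""

    node_coords: np.ndarray
    level: int = 0

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


def load_level_table(path: str, level: int = 0) -> tuple[PointCloud, ConcentrationField]:
    """Read one level's CSV (columns x, y[, z], value) into pipeline objects."""
    df = pd.read_csv(path)
    coord_cols = [c for c in ("x", "y", "z") if c in df.columns]
    if not coord_cols or "value" not in df.columns:
        raise ValueError(f"{path}: need coordinate columns (x, y[, z]) and 'value'")
    cloud = PointCloud(node_coords=df[coord_cols].to_numpy(dtype=float), level=level)
    fld = ConcentrationField(
        mesh=cloud, C=df["value"].to_numpy(dtype=float),
        B=np.zeros(cloud.n_nodes), time=float("nan"),
    )
    return cloud, fld


def load_nesting_map(path: str) -> np.ndarray:
    """JSON list: entry i is the fine-level node index of coarse node i."""
    fine = np.asarray(json.loads(Path(path).read_text()), dtype=np.int64)
    return np.column_stack([np.arange(fine.size), fine])


def run_external(
    level_csvs: list[str],
    nesting_jsons: list[str],
    J: int,
    metric: str = "cityblock",
    *,
    gp_mode: str = "grouped",
    budget: int = 2000,
) -> dict:
    """Train on level0 -> level1, deploy at level1, score against the last level.

    ``nesting_jsons[i]`` maps level-i nodes into level-(i+1); maps are
    composed to reach the final (truth) level.  Returns reference RMSEs and
    the deployed surrogate RMSE, as for the built-in experiment.
    """
    if len(level_csvs) < 3:
        raise ValueError("need at least 3 levels (train, deploy, truth)")
    if len(nesting_jsons) != len(level_csvs) - 1:
        raise ValueError("need one nesting map per consecutive level pair")
    levels = [load_level_table(p, level=i) for i, p in enumerate(level_csvs)]
    maps = [load_nesting_map(p)[:, 1] for p in nesting_jsons]

    def compose(start: int) -> np.ndarray:
        idx = np.arange(levels[start][0].n_nodes)
        for m in maps[start:]:
            idx = m[idx]
        return idx

    clouds = [lv[0] for lv in levels]
    flds = [lv[1] for lv in levels]
    truth_vals = flds[-1].values("free")

    ref = {}
    for lvl, name in ((0, "rmse_0T"), (1, "rmse_1T")):
        ref[name] = rmse(flds[lvl].values("free"), truth_vals[compose(lvl)])

    nb0 = nearest_neighbors(clouds[0], J, metric)
    feats0 = build_feature_table(flds[0], nb0, "free")
    pairs01 = np.column_stack([np.arange(clouds[0].n_nodes), maps[0]])
    train = build_training_set(feats0, flds[1], pairs01)
    model, _ = fit_surrogate(train, mode=gp_mode, budget=budget)

    nb1 = nearest_neighbors(clouds[1], J, metric)
    feats1 = build_feature_table(flds[1], nb1, "free")
    pred = predict(model, feats1.X, return_var=False)
    ref["rmse_pred_vs_truth"] = rmse(pred, truth_vals[compose(1)])
    return ref
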