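"""Cognitive-map reconstruction from leave-one-map-out decoder outputs.

Each analyzable trial of a held-out map receives three analogue predictions
-- one per upcoming-view-part decoder trained without that map -- and each
prediction is deposited on the grid square its view part points at from the
trial's post-move pose.  Square-wise analogue values are combined with a
sigmoidal rule, binarized so the number of predicted paths matches the true
map's path count, scored square-wise, and correlated with behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import slr
from .decoding import PART_TRUTH_CODE, balance_classes, make_folds, _audit_fold
from .maze_task import GRID_SIZE, MazeMap, Pose, VIEW_PARTS, view_part_cell
from .preprocessing import extract_samples
from .synthetic_fmri import VoxelDataset

logger = logging.getLogger(__name__)


@dataclass
class VisualizationConfig:
    beta: float = 5.0           # inverse temperature of the sigmoidal rule
    min_n: int = 1              # squares with fewer predictions are excluded
    form: str = "mean"          # "mean": sigma(beta*(mean(y)-1/2)); "sum": sigma(beta*sum(y-1/2))
    count_evaluable_only: bool = True  # matched path count over evaluable squares

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.min_n < 1:
            raise ValueError("min_n must be >= 1")
        if self.form not in ("mean", "sum"):
            raise ValueError("form must be 'mean' or 'sum'")


@dataclass
class SquareAccumulator:
    """Per-square analogue decoder outputs for one map."""

    map_id: int
    values: dict[tuple[int, int], list[float]] = field(default_factory=dict)
    sources: dict[tuple[int, int], list[tuple[int, str]]] = field(default_factory=dict)

    def add(self, row: int, col: int, y: float, trial_id: int, part: str) -> None:
        if not 0 <= row < GRID_SIZE or not 0 <= col < GRID_SIZE:
            raise ValueError(f"square ({row}, {col}) is off-grid")
        if not 0.0 < y < 1.0:
            raise ValueError(f"analogue output {y} outside (0, 1)")
        self.values.setdefault((row, col), []).append(float(y))
        self.sources.setdefault((row, col), []).append((trial_id, part))

    def counts(self) -> np.ndarray:
        n = np.zeros((GRID_SIZE, GRID_SIZE), dtype=int)
        for (r, c), ys in self.values.items():
            n[r, c] = len(ys)
        return n

    @property
    def n_predictions(self) -> int:
        return sum(len(v) for v in self.values.values())


@dataclass
class MapReconstruction:
    map_id: int
    analogue: np.ndarray   # (7, 7) in (0, 1); NaN = excluded
    binary: np.ndarray     # (7, 7) in {0., 1.}; NaN = excluded
    n_per_square: np.ndarray
    accuracy: float


def lomo_viewpart_predictions(
    dataset: VoxelDataset,
    trials: pd.DataFrame,
    slr_config: slr.SLRConfig | None = None,
    seed: int = 0,
    min_group: int = 4,
) -> pd.DataFrame:
    """Leave-one-map-out analogue predictions of all three view parts.

    For each held-out map and each view part, the part's decoder is trained
    on the part's trial group restricted to the other maps (class-balanced),
    then applied to every analyzable trial of the held-out map, so each
    evaluated trial yields three predictions.  Returns a tidy frame with one
    row per (trial, part).
    """
    X, meta = extract_samples(dataset, trials, "prechoice_mean")
    rows = []
    for train_rows, test_rows in make_folds(meta, "LOMO"):
        for i, part in enumerate(VIEW_PARTS):
            code = PART_TRUTH_CODE[part]
            grp = train_rows[(meta["flipped_part"].iloc[train_rows] == part).to_numpy()]
            _audit_fold(meta, grp, test_rows, "LOMO")
            y_train = meta[code].iloc[grp].to_numpy(dtype=int)
            if len(np.unique(y_train)) < 2 or len(grp) < min_group:
                logger.warning("LOMO fold map %s part %s: unusable training group",
                               meta['map_id'].iloc[test_rows[0]], part)
                continue
            rng = np.random.default_rng(np.random.SeedSequence([seed, i, 0xA9]))
            bal = balance_classes(y_train, rng)
            if len(bal) < 4:
                logger.warning("LOMO fold map %s part %s: only %d balanced "
                               "training samples; skipped",
                               meta['map_id'].iloc[test_rows[0]], part, len(bal))
                continue
            model = slr.fit(X[grp][bal], y_train[bal], slr_config)
            proba = slr.predict_proba(model, X[test_rows])
            sub = meta.iloc[test_rows]
            for p, (_, t) in zip(proba, sub.iterrows()):
                pose = Pose(int(t["post_row"]), int(t["post_col"]), t["post_heading"])
                r_cell, c_cell = view_part_cell(pose, part)
                if not (0 <= r_cell < GRID_SIZE and 0 <= c_cell < GRID_SIZE):
                    continue  # this part faces the wall surround: no square to fill
                rows.append({
                    "trial_id": int(t["trial_id"]), "map_id": int(t["map_id"]),
                    "part": part, "proba": float(p), "label": int(t[code]),
                    "post_row": int(t["post_row"]), "post_col": int(t["post_col"]),
                    "post_heading": t["post_heading"],
                })
    return pd.DataFrame(rows)


def accumulate(predictions: pd.DataFrame, map_id: int) -> SquareAccumulator:
    """Deposit each prediction on the grid square its view part targets."""
    acc = SquareAccumulator(map_id=map_id)
    sub = predictions[predictions["map_id"] == map_id]
    for _, row in sub.iterrows():
        pose = Pose(int(row["post_row"]), int(row["post_col"]), row["post_heading"])
        r, c = view_part_cell(pose, row["part"])
        if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
            raise RuntimeError(
                f"prediction for trial {row['trial_id']} part {row['part']} "
                f"targets off-grid square ({r}, {c})"
            )
        acc.add(r, c, row["proba"], int(row["trial_id"]), row["part"])
    return acc


def aggregate(acc: SquareAccumulator, config: VisualizationConfig | None = None) -> np.ndarray:
    """Square-wise path probability via the sigmoidal rule.

    Default form: v = sigma(beta * (mean(y) - 1/2)), so a mean analogue
    output of 0.5 maps to 0.5 and beta sharpens the decision.  Squares with
    fewer than ``min_n`` predictions are excluded (NaN).
    """
    config = config or VisualizationConfig()
    out = np.full((GRID_SIZE, GRID_SIZE), np.nan)
    for (r, c), ys in acc.values.items():
        if len(ys) < config.min_n:
            continue
        ys = np.asarray(ys)
        if config.form == "mean":
            z = config.beta * (ys.mean() - 0.5)
        else:
            z = config.beta * np.sum(ys - 0.5)
        out[r, c] = 1.0 / (1.0 + np.exp(-z))
    return out


def binarize_matched(
    analogue: np.ndarray,
    true_map: MazeMap,
    n_per_square: np.ndarray | None = None,
    count_evaluable_only: bool = True,
) -> np.ndarray:
    """Threshold the analogue map so predicted and true path counts match.

    Among evaluable squares the k largest analogue values become paths,
    where k is the true map's path count (over evaluable squares by
    default, over the whole grid otherwise).  Ties are broken by larger
    prediction count, then by row-major index.
    """
    evaluable = ~np.isnan(analogue)
    k_pool = true_map.grid[evaluable] if count_evaluable_only else true_map.grid
    k = int(k_pool.sum())
    coords = [tuple(rc) for rc in np.argwhere(evaluable)]
    n = n_per_square if n_per_square is not None else np.zeros_like(analogue, dtype=int)
    order = sorted(
        range(len(coords)),
        key=lambda i: (
            -analogue[coords[i]],
            -n[coords[i]],
            coords[i][0] * GRID_SIZE + coords[i][1],
        ),
    )
    binary = np.full((GRID_SIZE, GRID_SIZE), np.nan)
    for rank, i in enumerate(order):
        binary[coords[i]] = 1.0 if rank < min(k, len(coords)) else 0.0
    return binary


def score_map(binary: np.ndarray, true_map: MazeMap) -> float:
    """Square-wise agreement with the true map over evaluable squares."""
    evaluable = ~np.isnan(binary)
    if not evaluable.any():
        return float("nan")
    return float((binary[evaluable] == true_map.grid[evaluable].astype(float)).mean())


def reconstruct_map(
    predictions: pd.DataFrame,
    true_map: MazeMap,
    config: VisualizationConfig | None = None,
) -> MapReconstruction:
    """Full reconstruction of one map from LOMO predictions."""
    config = config or VisualizationConfig()
    acc = accumulate(predictions, true_map.map_id)
    analogue = aggregate(acc, config)
    n = acc.counts()
    binary = binarize_matched(analogue, true_map, n, config.count_evaluable_only)
    return MapReconstruction(
        map_id=true_map.map_id,
        analogue=analogue,
        binary=binary,
        n_per_square=n,
        accuracy=score_map(binary, true_map),
    )


def correlate_with_behavior(table: pd.DataFrame) -> dict[str, float]:
    """Correlation between map-visualization and behavioral accuracy.

    ``table`` needs columns ``vis_accuracy`` and ``behavior_accuracy`` with
    one row per (participant, map) point.  Spearman is the headline
    statistic; Pearson is reported alongside.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 (participant, map) points to correlate")
    rho, p_s = stats.spearmanr(table["behavior_accuracy"], table["vis_accuracy"])
    r, p_p = stats.pearsonr(table["behavior_accuracy"], table["vis_accuracy"])
    return {"spearman_rho": float(rho), "spearman_p": float(p_s),
            "pearson_r": float(r), "pearson_p": float(p_p), "n": int(len(table))}


def render_text(grid: np.ndarray) -> str:
    """Plain-text rendering: '.' path, '#' wall, '?' excluded."""
    def ch(v):
        if np.isnan(v):
            return "?"
        return "." if v >= 0.5 else "#"
    return "\n".join("".join(ch(grid[r, c]) for c in range(GRID_SIZE))
                     for r in range(GRID_SIZE))
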