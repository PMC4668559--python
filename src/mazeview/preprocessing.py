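"""Signal conditioning for ROI voxel time series.

The fixed pipeline order is: discard lead-in scans, per-session quadratic
detrend, per-session SVD noise reduction (subtracting the top-K singular
components, i.e. removing session-wide shared fluctuations), per-session
z-score normalization, then trial-sample extraction.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_fmri import VoxelDataset

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    n_discard: int = 6
    trend_degree: int = 2
    svd_k: int = 3
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.svd_k < 0:
            raise ValueError("svd_k must be >= 0")


def _session_slices(dataset: VoxelDataset):
    for session in np.unique(dataset.session):
        yield session, np.flatnonzero(dataset.session == session)


def _replaced(dataset: VoxelDataset, data: np.ndarray, stage: str, **mask) -> VoxelDataset:
    keep = mask.pop("keep", None)
    prov = dict(dataset.provenance)
    prov["stages"] = list(prov.get("stages", [])) + [stage]
    if keep is None:
        return dataclasses.replace(dataset, data=data, provenance=prov)
    return dataclasses.replace(
        dataset,
        data=data,
        session=dataset.session[keep],
        trial=dataset.trial[keep],
        scan_in_trial=dataset.scan_in_trial[keep],
        provenance=prov,
    )


def discard_lead_in(dataset: VoxelDataset, n_discard: int = 6) -> VoxelDataset:
    """Drop the first ``n_discard`` scans of every session."""
    keep = np.ones(dataset.n_scans, dtype=bool)
    for session, idx in _session_slices(dataset):
        if len(idx) <= n_discard:
            raise ValueError(
                f"session {session} has only {len(idx)} scans; cannot discard {n_discard}"
            )
        keep[idx[:n_discard]] = False
    return _replaced(dataset, dataset.data[keep], f"discard_lead_in({n_discard})", keep=keep)


def remove_trend(dataset: VoxelDataset, degree: int = 2) -> VoxelDataset:
    """Subtract a per-voxel, per-session least-squares polynomial trend.

    The regressor is the within-session scan index, so residuals are
    orthogonal to {1, t, ..., t^degree} in every session.
    """
    data = dataset.data.copy()
    for session, idx in _session_slices(dataset):
        if len(idx) < degree + 1:
            raise ValueError(
                f"session {session} has {len(idx)} scans; need > {degree} for detrending"
            )
        t = np.arange(len(idx), dtype=float)
        basis = np.vander(t, degree + 1, increasing=True)  # [1, t, t^2, ...]
        coef, *_ = np.linalg.lstsq(basis, data[idx], rcond=None)
        data[idx] -= basis @ coef
    return _replaced(dataset, data, f"remove_trend(degree={degree})")


def svd_denoise(dataset: VoxelDataset, k: int = 3) -> VoxelDataset:
    """Subtract the top-``k`` singular components of each session's matrix.

    This removes the strongest session-wide shared fluctuations; after the
    stage the k largest singular values of every session block are ~0.
    """
    if k == 0:
        return _replaced(dataset, dataset.data.copy(), "svd_denoise(k=0)")
    data = dataset.data.copy()
    for session, idx in _session_slices(dataset):
        block = data[idx]
        if k > min(block.shape):
            raise ValueError(
                f"svd_k={k} exceeds min(scans, voxels)={min(block.shape)} in session {session}"
            )
        u, s, vt = np.linalg.svd(block, full_matrices=False)
        data[idx] = block - (u[:, :k] * s[:k]) @ vt[:k]
    return _replaced(dataset, data, f"svd_denoise(k={k})")


def normalize_session(dataset: VoxelDataset) -> VoxelDataset:
    """Z-score every voxel within each session (mean 0, sd 1).

    Zero-variance voxels are set to all-zeros with a logged warning rather
    than raising, so degenerate synthetic inputs cannot abort a run.
    """
    data = dataset.data.copy()
    for session, idx in _session_slices(dataset):
        block = data[idx]
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        # relative tolerance: a numerically constant voxel has sd at rounding
        # level even though its values are bitwise identical
        flat = sd <= 1e-12 * (1.0 + np.abs(mean))
        if flat.any():
            logger.warning(
                "ROI %s session %s: %d zero-variance voxel(s) set to zero",
                dataset.roi, session, int(flat.sum()),
            )
        sd_safe = np.where(flat, 1.0, sd)
        block = (block - mean) / sd_safe
        block[:, flat] = 0.0
        data[idx] = block
    return _replaced(dataset, data, "normalize_session")


def preprocess(dataset: VoxelDataset, config: PreprocessConfig | None = None) -> VoxelDataset:
    """Run the full conditioning pipeline in its fixed order."""
    config = config or PreprocessConfig()
    out = discard_lead_in(dataset, config.n_discard) if config.n_discard else dataset
    out = remove_trend(out, config.trend_degree)
    out = svd_denoise(out, config.svd_k)
    if config.normalize:
        out = normalize_session(out)
    return out


def extract_samples(
    dataset: VoxelDataset,
    trials: pd.DataFrame,
    mode: str = "prechoice_mean",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build the trial-wise sample matrix and its metadata table.

    ``mode`` is either ``prechoice_mean`` -- the mean of scans 5 and 6, the
    two scans (2 x TR = 4 s) just before the choice options appear -- or
    ``scan<j>`` for the single scan ``j`` (1-based within trial).  Only
    analyzable trials enter the output: 5 s delay and non-MISS outcome.

    Returns ``(X, meta)`` where ``X`` has one row per analyzable trial and
    ``meta`` is the matching subset of ``trials`` (same row order).
    """
    if mode == "prechoice_mean":
        scans = (5, 6)
    elif mode.startswith("scan"):
        scans = (int(mode[4:]),)
    else:
        raise ValueError(f"unknown sample mode {mode!r}")
    spt = int(dataset.scan_in_trial.max())
    for s in scans:
        if not 1 <= s <= spt:
            raise ValueError(f"scan index {s} outside 1..{spt}")

    analyzable = trials[(trials["delay_s"] == 5) & (trials["outcome"] != "MISS")]
    rows = []
    keep_ids = []
    for tid in analyzable["trial_id"]:
        sel = np.flatnonzero(
            (dataset.trial == tid) & np.isin(dataset.scan_in_trial, scans)
        )
        if len(sel) != len(scans):
            raise ValueError(f"trial {tid}: expected {len(scans)} scans, found {len(sel)}")
        rows.append(dataset.data[sel].mean(axis=0))
        keep_ids.append(tid)
    X = np.array(rows) if rows else np.empty((0, dataset.n_voxels))
    meta = analyzable.set_index("trial_id").loc[keep_ids].reset_index()
    return X, meta
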