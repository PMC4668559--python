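"""Synthetic ROI voxel time series with scan-locked label encoding.

The generator emulates the acquisition geometry of the scene-choice
experiment -- TR = 2 s, eight scans per trial, six lead-in scans per
session -- and injects, for a configurable subset of the 12 binary status
codes, a sparse spatial activity pattern at chosen within-trial scans.
Nuisance structure mimics what the preprocessing stage is built to remove:
per-session quadratic drift, a few session-wide low-rank noise components,
and white noise.  No hemodynamic response function is convolved, mirroring
the analysis the data feed.

With ``subjective_mode`` on, the upcoming-view codes injected on INCORRECT
trials are those of the scene the simulated participant chose (the
distracter) rather than the objectively correct scene, so the voxel
patterns carry the participant's subjective expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .maze_task import CODE_NAMES, CODE_FAMILIES, MazeMap, Trial, derive_trial_labels

#: Mean ROI voxel counts over the eight study participants, rounded.
DEFAULT_ROI_VOXELS: Mapping[str, int] = {
    "mPFC": 577,
    "dPFC": 471,
    "precuneus": 645,
    "sPC": 671,
    "HC-paraHC": 367,
    "OC": 858,
}

ROI_NAMES = tuple(DEFAULT_ROI_VOXELS)


@dataclass
class ScanTimeline:
    """Mapping of trial events onto the 8-scan (16 s) trial grid.

    Scan indices are 1-based within the trial: map presentation falls in
    scan 2, the three movements in scans 3-4, the early delay in scan 5, the
    final pre-choice delay scan in 6 and the choice in scan 8.
    """

    tr_s: float = 2.0
    scans_per_trial: int = 8
    event_map: Mapping[str, int] = field(default_factory=lambda: {
        "map": 2, "move1": 3, "move2": 4, "early_delay": 5,
        "pre_choice": 6, "choice": 8,
    })

    def __post_init__(self) -> None:
        scans = list(self.event_map.values())
        if len(set(scans)) != len(scans):
            raise ValueError("event_map must be injective")
        if any(not 1 <= s <= self.scans_per_trial for s in scans):
            raise ValueError(f"event scans must lie in 1..{self.scans_per_trial}")


@dataclass
class ROISpec:
    """Signal-encoding configuration of one region of interest.

    ``encoded_labels`` lists the binary codes whose value modulates this
    ROI's activity; ``encode_scans`` the 1-based within-trial scans at which
    the modulation is added; ``snr`` scales the per-voxel signal amplitude
    relative to unit white noise; ``n_informative`` is the number of voxels
    carrying each code's pattern.
    """

    name: str
    n_voxels: int | None = None
    encoded_labels: tuple[str, ...] = ()
    encode_scans: tuple[int, ...] = (5, 6)
    snr: float = 0.0
    n_informative: int | None = None  # default: min(30, n_voxels)

    def __post_init__(self) -> None:
        if self.n_voxels is None:
            self.n_voxels = DEFAULT_ROI_VOXELS.get(self.name, 300)
        if self.n_informative is None:
            self.n_informative = min(30, self.n_voxels)
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if not 0 < self.n_informative <= self.n_voxels:
            raise ValueError(
                f"n_informative={self.n_informative} must lie in 1..{self.n_voxels}"
            )
        unknown = set(self.encoded_labels) - set(CODE_NAMES)
        if unknown:
            raise ValueError(f"unknown codes {sorted(unknown)}")


@dataclass
class NoiseSpec:
    """Nuisance model: quadratic session drift, low-rank structured noise
    and i.i.d. white noise."""

    drift_scale: float = 0.5
    n_structured_components: int = 3
    structured_scale: float = 5.0
    white_sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("drift_scale", "structured_scale", "white_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class VoxelDataset:
    """Scans x voxels array of one ROI with scan-level indexing.

    ``trial`` is -1 and ``scan_in_trial`` 0 on lead-in scans; otherwise
    ``scan_in_trial`` is the 1-based scan index within the trial.
    """

    roi: str
    data: np.ndarray
    session: np.ndarray
    trial: np.ndarray
    scan_in_trial: np.ndarray
    participant: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        for name in ("session", "trial", "scan_in_trial"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per scan")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _code_patterns(
    spec: ROISpec, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per encoded code: (informative voxel indices, +/-1 pattern weights)."""
    patterns = {}
    for code in spec.encoded_labels:
        voxels = rng.choice(spec.n_voxels, size=spec.n_informative, replace=False)
        weights = rng.choice([-1.0, 1.0], size=spec.n_informative)
        patterns[code] = (voxels, weights)
    return patterns


def generate_participant_data(
    trials: Sequence[Trial],
    maps: Sequence[MazeMap],
    roi_specs: Sequence[ROISpec],
    timeline: ScanTimeline | None = None,
    noise: NoiseSpec | None = None,
    subjective_mode: bool = False,
    seed: int = 0,
    participant: int = 0,
    n_lead_in: int = 6,
) -> dict[str, VoxelDataset]:
    """Simulate the voxel time series of one participant for every ROI.

    For each ROI the signal at its ``encode_scans`` of trial t is
    ``snr * sum_codes (2*label - 1) * pattern`` over the code's informative
    voxels; drift, structured and white noise are added everywhere, and
    ``n_lead_in`` signal-free lead-in scans are prepended to every session.
    """
    timeline = timeline or ScanTimeline()
    noise = noise or NoiseSpec()
    trials = list(trials)  # within-session presentation order is preserved
    sessions = sorted({t.session_id for t in trials})
    spt = timeline.scans_per_trial

    labels = {t.trial_id: derive_trial_labels(t, maps).as_dict() for t in trials}
    if subjective_mode:
        for t in trials:
            chosen = t.chosen_scene
            if t.outcome == "INCORRECT" and chosen is not None:
                labels[t.trial_id]["up_fl"] = int(chosen.fwd_left)
                labels[t.trial_id]["up_fc"] = int(chosen.fwd_center)
                labels[t.trial_id]["up_fr"] = int(chosen.fwd_right)

    root = np.random.SeedSequence([seed, participant, 0x666D7269])
    roi_seeds = root.spawn(len(roi_specs))
    out: dict[str, VoxelDataset] = {}
    for spec, roi_ss in zip(roi_specs, roi_seeds):
        rng = np.random.default_rng(roi_ss)
        patterns = _code_patterns(spec, rng)
        blocks, sess_idx, trial_idx, scan_idx = [], [], [], []
        for session in sessions:
            sess_trials = [t for t in trials if t.session_id == session]
            n_scans = n_lead_in + spt * len(sess_trials)
            block = rng.standard_normal((n_scans, spec.n_voxels)) * noise.white_sigma
            # quadratic drift per voxel on a normalized time axis
            if noise.drift_scale > 0:
                u = np.linspace(-1.0, 1.0, n_scans)[:, None]
                coef = rng.standard_normal((3, spec.n_voxels)) * noise.drift_scale
                block += coef[0] + coef[1] * u + coef[2] * u**2
            # session-wide low-rank structured noise
            for _ in range(noise.n_structured_components):
                tc = rng.standard_normal(n_scans)
                sp = rng.standard_normal(spec.n_voxels)
                sp /= np.linalg.norm(sp)
                block += noise.structured_scale * np.outer(tc, sp)
            # scan-locked label encoding
            for i, t in enumerate(sess_trials):
                for code in spec.encoded_labels:
                    voxels, weights = patterns[code]
                    contrast = 2.0 * labels[t.trial_id][code] - 1.0
                    for s in spec.encode_scans:
                        row = n_lead_in + i * spt + (s - 1)
                        block[row, voxels] += spec.snr * contrast * weights
            blocks.append(block)
            sess_idx.append(np.full(n_scans, session))
            tid = np.full(n_scans, -1)
            sid = np.zeros(n_scans, dtype=int)
            for i, t in enumerate(sess_trials):
                lo = n_lead_in + i * spt
                tid[lo : lo + spt] = t.trial_id
                sid[lo : lo + spt] = np.arange(1, spt + 1)
            trial_idx.append(tid)
            scan_idx.append(sid)
        out[spec.name] = VoxelDataset(
            roi=spec.name,
            data=np.vstack(blocks),
            session=np.concatenate(sess_idx),
            trial=np.concatenate(trial_idx),
            scan_in_trial=np.concatenate(scan_idx),
            participant=participant,
            provenance={"stages": [], "seed": seed, "subjective_mode": subjective_mode},
        )
    return out


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------

def write_dataset(path, datasets: Mapping[str, VoxelDataset]) -> None:
    """Write per-ROI datasets to one HDF5 container (group per ROI)."""
    with h5py.File(path, "w") as f:
        for name, ds in datasets.items():
            g = f.create_group(f"roi/{name}")
            g.create_dataset("data", data=ds.data)
            g.create_dataset("session", data=ds.session)
            g.create_dataset("trial", data=ds.trial)
            g.create_dataset("scan_in_trial", data=ds.scan_in_trial)
            g.attrs["participant"] = ds.participant
            g.attrs["provenance"] = json.dumps(ds.provenance)


def read_dataset(path) -> dict[str, VoxelDataset]:
    """Read an HDF5 container written by :func:`write_dataset`."""
    out: dict[str, VoxelDataset] = {}
    try:
        with h5py.File(path, "r") as f:
            if "roi" not in f:
                raise IOError(f"{path}: no 'roi' group; not a voxel dataset file")
            for name, g in f["roi"].items():
                out[name] = VoxelDataset(
                    roi=name,
                    data=g["data"][()],
                    session=g["session"][()],
                    trial=g["trial"][()],
                    scan_in_trial=g["scan_in_trial"][()],
                    participant=int(g.attrs.get("participant", 0)),
                    provenance=json.loads(g.attrs.get("provenance", "{}")),
                )
    except OSError as e:
        raise IOError(f"cannot read voxel dataset from {path}: {e}") from e
    return out
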