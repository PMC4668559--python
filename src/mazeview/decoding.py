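"""Multiple parallel decoding: the 12-decoder battery, class balancing,
LOSO / LOTO / LOMO cross-validation, time-course decoding, view-part-split
decoders, incorrect-trial dual labeling, and group statistics.

Every cross-validation fold asserts an empty train/test intersection of
trial ids (and of map ids for the leave-one-map-out scheme) before any model
is fitted, so information leakage is structurally impossible rather than
merely untested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import slr
from .maze_task import CODE_FAMILIES, CODE_NAMES, VIEW_PARTS
from .preprocessing import extract_samples
from .synthetic_fmri import VoxelDataset

logger = logging.getLogger(__name__)

CV_SCHEMES = ("LOSO", "LOTO", "LOMO")

#: truth and chosen-scene code columns per view part
PART_TRUTH_CODE = {"FL": "up_fl", "FC": "up_fc", "FR": "up_fr"}
PART_CHOICE_CODE = {"FL": "ch_fl", "FC": "ch_fc", "FR": "ch_fr"}


@dataclass(frozen=True)
class DecoderSpec:
    family: str
    code: str
    roi: str
    sample_mode: str = "prechoice_mean"

    def __post_init__(self) -> None:
        if self.family not in CODE_FAMILIES:
            raise ValueError(f"unknown family {self.family}")
        if self.code not in CODE_FAMILIES[self.family]:
            raise ValueError(f"code {self.code} is not in family {self.family}")


def full_battery(roi: str, sample_mode: str = "prechoice_mean") -> list[DecoderSpec]:
    """The 12 status-specific decoder specs for one ROI."""
    return [
        DecoderSpec(family=family, code=code, roi=roi, sample_mode=sample_mode)
        for family, codes in CODE_FAMILIES.items()
        for code in codes
    ]


@dataclass
class DecodingResult:
    """Pooled cross-validated predictions and accuracy for one binary code."""

    code: str
    scheme: str
    trial_ids: np.ndarray
    proba: np.ndarray
    pred: np.ndarray
    label: np.ndarray
    fold: np.ndarray
    skipped_folds: list = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        if len(self.label) == 0:
            return float("nan")
        return float((self.pred == self.label).mean())

    @property
    def n(self) -> int:
        return len(self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial_id": self.trial_ids, "code": self.code, "scheme": self.scheme,
            "fold": self.fold, "proba": self.proba, "pred": self.pred,
            "label": self.label,
        })


def balance_classes(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subset: the majority class is subsampled
    without replacement down to the minority count."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to balance")
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, neg]))


def make_folds(meta: pd.DataFrame, kind: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Row-index folds for a CV scheme, derived from session / trial / map ids."""
    if kind == "LOSO":
        key = meta["session_id"].to_numpy()
    elif kind == "LOTO":
        key = meta["trial_id"].to_numpy()
    elif kind == "LOMO":
        key = meta["map_id"].to_numpy()
    else:
        raise ValueError(f"unknown CV scheme {kind!r}; use one of {CV_SCHEMES}")
    folds = []
    for value in np.unique(key):
        test = np.flatnonzero(key == value)
        train = np.flatnonzero(key != value)
        folds.append((train, test))
    return folds


def _audit_fold(meta: pd.DataFrame, train: np.ndarray, test: np.ndarray, kind: str) -> None:
    tr_ids = set(meta["trial_id"].iloc[train])
    te_ids = set(meta["trial_id"].iloc[test])
    if tr_ids & te_ids:
        raise AssertionError(f"leakage: trials {sorted(tr_ids & te_ids)[:5]} in train and test")
    if kind == "LOMO":
        tr_maps = set(meta["map_id"].iloc[train])
        te_maps = set(meta["map_id"].iloc[test])
        if tr_maps & te_maps:
            raise AssertionError(f"LOMO leakage: maps {tr_maps & te_maps} shared")


def run_cv(
    X: np.ndarray,
    meta: pd.DataFrame,
    code: str,
    scheme: str = "LOSO",
    slr_config: slr.SLRConfig | None = None,
    seed: int = 0,
    labels: np.ndarray | None = None,
    eval_mask: np.ndarray | None = None,
) -> DecodingResult:
    """Cross-validated decoding of one binary code.

    Per fold the training set is class-rebalanced by subsampling (with a
    fold-derived seed), the sparse decoder is fitted, and the held-out
    samples are scored at the 0.5 threshold.  ``labels`` overrides the label
    column (e.g. permuted or choice-based labels); ``eval_mask`` restricts
    which held-out samples enter the pooled result (training still uses all
    samples).  Folds whose training set is single-class are skipped with a
    warning and recorded in ``skipped_folds``.
    """
    y = np.asarray(meta[code].to_numpy() if labels is None else labels, dtype=int)
    if len(y) != len(X):
        raise ValueError("labels and samples are inconsistent")
    folds = make_folds(meta, scheme)
    out_idx, out_proba, out_fold = [], [], []
    skipped = []
    for k, (train, test) in enumerate(folds):
        _audit_fold(meta, train, test, scheme)
        if eval_mask is not None and not np.asarray(eval_mask)[test].any():
            continue  # nothing from this fold would be scored
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            logger.warning("fold %d (%s, code %s): single-class training set; skipped",
                           k, scheme, code)
            skipped.append(k)
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, k, 0xCF]))
        bal = balance_classes(y_train, rng)
        if len(bal) < 4:
            logger.warning("fold %d (%s, code %s): only %d balanced training "
                           "samples; skipped", k, scheme, code, len(bal))
            skipped.append(k)
            continue
        model = slr.fit(X[train][bal], y_train[bal], slr_config)
        out_idx.append(test)
        out_proba.append(slr.predict_proba(model, X[test]))
        out_fold.append(np.full(len(test), k))
    if out_idx:
        idx = np.concatenate(out_idx)
        proba = np.concatenate(out_proba)
        fold = np.concatenate(out_fold)
    else:
        idx = np.array([], dtype=int)
        proba = np.array([])
        fold = np.array([], dtype=int)
    if eval_mask is not None:
        keep = np.asarray(eval_mask)[idx]
        idx, proba, fold = idx[keep], proba[keep], fold[keep]
    return DecodingResult(
        code=code,
        scheme=scheme,
        trial_ids=meta["trial_id"].to_numpy()[idx],
        proba=proba,
        pred=(proba >= 0.5).astype(int),
        label=y[idx],
        fold=fold,
        skipped_folds=skipped,
    )


def run_battery(
    X: np.ndarray,
    meta: pd.DataFrame,
    scheme: str = "LOSO",
    codes: Sequence[str] = CODE_NAMES,
    slr_config: slr.SLRConfig | None = None,
    seed: int = 0,
) -> dict[str, DecodingResult]:
    """Run the parallel battery of binary decoders on one sample matrix."""
    return {
        code: run_cv(X, meta, code, scheme, slr_config,
                     seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31))
        for i, code in enumerate(codes)
    }


def family_accuracies(results: Mapping[str, DecodingResult]) -> dict[str, float]:
    """Family accuracy = arithmetic mean over its constituent code decoders."""
    out = {}
    for family, codes in CODE_FAMILIES.items():
        accs = [results[c].accuracy for c in codes if c in results]
        if accs:
            out[family] = float(np.mean(accs))
    return out


def timecourse_decoding(
    datasets: Mapping[str, VoxelDataset],
    trials: pd.DataFrame,
    roi_list: Sequence[str],
    scans: Sequence[int] = tuple(range(1, 9)),
    codes: Sequence[str] = CODE_NAMES,
    slr_config: slr.SLRConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Scan-by-scan decoding accuracy under LOSO, per family and ROI.

    For each within-trial scan index the battery is run on that single
    scan's (unconvolved) samples.  Returns ``(acc, families)`` with ``acc``
    of shape ``(len(scans), 4, len(roi_list))``.
    """
    families = list(CODE_FAMILIES)
    acc = np.full((len(scans), len(families), len(roi_list)), np.nan)
    for r, roi in enumerate(roi_list):
        for si, scan in enumerate(scans):
            X, meta = extract_samples(datasets[roi], trials, f"scan{scan}")
            results = run_battery(X, meta, "LOSO", codes, slr_config,
                                  seed=(seed * 1009 + scan * 31 + r) % 2**31)
            fam_acc = family_accuracies(results)
            for fi, fam in enumerate(families):
                if fam in fam_acc:
                    acc[si, fi, r] = fam_acc[fam]
    return acc, families


def viewpart_split_decoding(
    dataset: VoxelDataset,
    trials: pd.DataFrame,
    slr_config: slr.SLRConfig | None = None,
    seed: int = 0,
    scheme: str = "LOTO",
    min_group: int = 10,
) -> dict[str, DecodingResult]:
    """Three view-part-dependent decoders on pre-choice (scans 5+6) samples.

    Samples are split by the trial's flipped view part; each group's decoder
    predicts the truth code of its own part.  Groups smaller than
    ``min_group`` are skipped with a warning.
    """
    X, meta = extract_samples(dataset, trials, "prechoice_mean")
    out: dict[str, DecodingResult] = {}
    for i, part in enumerate(VIEW_PARTS):
        sel = np.flatnonzero((meta["flipped_part"] == part).to_numpy())
        if len(sel) < min_group:
            logger.warning("view part %s: only %d trials (< %d); skipped",
                           part, len(sel), min_group)
            continue
        out[part] = run_cv(
            X[sel], meta.iloc[sel].reset_index(drop=True), PART_TRUTH_CODE[part],
            scheme, slr_config, seed=seed + i,
        )
    return out


def incorrect_trial_evaluation(
    dataset: VoxelDataset,
    trials: pd.DataFrame,
    slr_config: slr.SLRConfig | None = None,
    seed: int = 0,
    train_labeling: str = "choice",
    min_group: int = 10,
) -> dict[str, float] | None:
    """LOTO evaluation of the view-part decoders on incorrect trials only,
    scored under both labeling schemes.

    Decoders are trained on correct and incorrect trials together; training
    labels for incorrect trials follow ``train_labeling`` ("choice": the
    scene the participant chose, "truth": the objectively correct scene; the
    two coincide on correct trials).  Returns ``{"choice_based": acc,
    "truth_based": acc, "n_incorrect": n}`` over the pooled incorrect trials
    of this participant, or None if there are no incorrect trials.
    """
    if train_labeling not in ("choice", "truth"):
        raise ValueError("train_labeling must be 'choice' or 'truth'")
    X, meta = extract_samples(dataset, trials, "prechoice_mean")
    incorrect = (meta["outcome"] == "INCORRECT").to_numpy()
    if not incorrect.any():
        return None
    n_ok, n_choice, n_truth = 0, 0, 0
    for i, part in enumerate(VIEW_PARTS):
        sel = np.flatnonzero((meta["flipped_part"] == part).to_numpy())
        if len(sel) < min_group:
            continue
        sub = meta.iloc[sel].reset_index(drop=True)
        truth = sub[PART_TRUTH_CODE[part]].to_numpy(dtype=int)
        choice = sub[PART_CHOICE_CODE[part]].to_numpy(dtype=int)
        train_labels = choice if train_labeling == "choice" else truth
        res = run_cv(
            X[sel], sub, PART_TRUTH_CODE[part], "LOTO", slr_config,
            seed=seed + i, labels=train_labels,
            eval_mask=(sub["outcome"] == "INCORRECT").to_numpy(),
        )
        # res.label carries the training labels; rescore under both schemes
        pos = {tid: j for j, tid in enumerate(sub["trial_id"])}
        rows = np.array([pos[tid] for tid in res.trial_ids], dtype=int)
        n_ok += len(rows)
        n_choice += int((res.pred == choice[rows]).sum())
        n_truth += int((res.pred == truth[rows]).sum())
    if n_ok == 0:
        return None
    return {
        "choice_based": n_choice / n_ok,
        "truth_based": n_truth / n_ok,
        "n_incorrect": n_ok,
    }


# ---------------------------------------------------------------------------
# group-level statistics
# ---------------------------------------------------------------------------

def empirical_chance(labels: np.ndarray) -> float:
    """Majority-class rate of an evaluation set (the prior chance level)."""
    labels = np.asarray(labels)
    p = labels.mean()
    return float(max(p, 1.0 - p))


def group_stats(
    per_participant: np.ndarray,
    chance: float | np.ndarray = 0.5,
    n_comparisons: int | None = None,
    cell_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wilcoxon signed-rank test of per-participant accuracies against chance.

    ``per_participant`` has shape (n_participants, n_cells); ``chance`` may
    be scalar or per cell.  The Bonferroni-adjusted significance level is
    0.05 / n_comparisons (default: the number of cells).  Cells whose
    accuracies all tie with chance yield an undefined test, reported with a
    note instead of raising.
    """
    acc = np.atleast_2d(np.asarray(per_participant, dtype=float))
    if acc.shape[0] < 5:
        raise ValueError("need at least 5 participants for group statistics")
    n_cells = acc.shape[1]
    chance = np.broadcast_to(np.asarray(chance, dtype=float), (n_cells,))
    m = n_comparisons if n_comparisons is not None else n_cells
    names = list(cell_names) if cell_names is not None else [str(i) for i in range(n_cells)]
    rows = []
    for j in range(n_cells):
        diffs = acc[:, j] - chance[j]
        if np.allclose(diffs, 0.0):
            rows.append({"cell": names[j], "mean_accuracy": float(acc[:, j].mean()),
                         "chance": float(chance[j]), "p": np.nan,
                         "p_bonf": np.nan, "significant": False,
                         "note": "test undefined: all values tie with chance"})
            continue
        stat, p = stats.wilcoxon(diffs)
        p_bonf = min(p * m, 1.0)
        rows.append({"cell": names[j], "mean_accuracy": float(acc[:, j].mean()),
                     "chance": float(chance[j]), "p": float(p),
                     "p_bonf": float(p_bonf), "significant": bool(p_bonf < 0.05),
                     "note": ""})
    return pd.DataFrame(rows)


def compare_two_groups(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum test between two accuracy samples."""
    res = stats.ranksums(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman test over >= 3 matched conditions (columns).

    Degenerate all-tied inputs yield (nan, nan) rather than raising.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < 3:
        raise ValueError("Friedman test needs >= 3 conditions")
    try:
        res = stats.friedmanchisquare(*[matrix[:, j] for j in range(matrix.shape[1])])
    except ValueError:
        return float("nan"), float("nan")
    return float(res.statistic), float(res.pvalue)
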