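"""Run configuration, hierarchical seeding and the end-to-end runner.

The pipeline stages are: simulate the stimulus set and per-participant
behavior, synthesize ROI voxel data, preprocess, decode (LOSO battery,
view-part LOTO, incorrect-trial dual labeling), reconstruct maps from LOMO
predictions, and write a report bundle of TSV/JSON/HDF5 artifacts.

Every stochastic stage derives its seed from the master seed with a fixed
counter scheme (``SeedSequence([master, stage, participant])``), so any
stage can be re-run in isolation and reproduces the same result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding, map_visualization as mv, preprocessing as pp
from . import maze_task as mt
from . import synthetic_fmri as sf
from .slr import SLRConfig

logger = logging.getLogger(__name__)

#: stage counters for hierarchical seeding
_STAGE = {"maps": 1, "trials": 2, "behavior": 3, "fmri": 4, "decode": 5, "order": 6}


def stage_seed(master: int, stage: str, participant: int = 0) -> int:
    """Deterministic per-stage, per-participant child seed (< 2**31)."""
    ss = np.random.SeedSequence([master, _STAGE[stage], participant])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 8
    sessions: int = 5
    trials_per_session: int = 64
    delay5_per_session: int = 60
    coverage_min: float = 0.6
    rois: dict = field(default_factory=lambda: {
        "sPC": {"encoded_labels": ["up_fl", "up_fc", "up_fr"], "snr": 1.0},
        "dPFC": {},
    })
    noise: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    subjective_mode: bool = True
    preprocess: dict = field(default_factory=dict)
    slr: dict = field(default_factory=dict)
    visualization: dict = field(default_factory=dict)
    out_dir: str = "mazeview_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            obj = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def roi_specs(self) -> list[sf.ROISpec]:
        return [sf.ROISpec(name=name, **params) for name, params in self.rois.items()]

    def task_config(self) -> mt.TaskConfig:
        return mt.TaskConfig(
            sessions=self.sessions,
            trials_per_session=self.trials_per_session,
            delay5_per_session=self.delay5_per_session,
            coverage_min=self.coverage_min,
        )

    def slr_config(self) -> SLRConfig:
        return SLRConfig(**self.slr)


def make_cohort(
    n_participants: int,
    seed: int,
    snr_range: tuple[float, float] = (0.2, 1.0),
    p_correct_range: tuple[float, float] = (0.78, 0.97),
) -> list[dict]:
    """Participants whose signal quality and behavior are coupled.

    Ability is spaced evenly over the cohort (order shuffled by seed); a
    participant's ROI signal-to-noise and choice accuracy both increase
    linearly with ability, emulating the situation where a sharper cognitive
    map improves both the decodable signal and the behavioral choices.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    ability = np.linspace(0.0, 1.0, n_participants)
    rng.shuffle(ability)
    cohort = []
    for i, a in enumerate(ability):
        snr = snr_range[0] + a * (snr_range[1] - snr_range[0])
        pc = p_correct_range[0] + a * (p_correct_range[1] - p_correct_range[0])
        cohort.append({
            "participant": i + 1,
            "ability": float(a),
            "snr": float(snr),
            "p_correct": {"FL": pc, "FC": min(pc + 0.02, 0.99), "FR": pc},
        })
    return cohort


def simulate_participant(
    config: RunConfig,
    maps: list[mt.MazeMap],
    base_trials: list[mt.Trial],
    participant: int,
    snr_override: float | None = None,
    p_correct_override: dict | None = None,
):
    """Behavior + voxel data of one participant on the shared stimulus set.

    The shared trials are re-ordered within each session with a
    participant-specific permutation (the stimulus sets are common to the
    cohort; their presentation order is not).
    """
    order_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STAGE["order"], participant])
    )
    trials = []
    for session in sorted({t.session_id for t in base_trials}):
        block = [t for t in base_trials if t.session_id == session]
        order_rng.shuffle(block)
        trials.extend(dataclasses.replace(t) for t in block)

    beh_kwargs = dict(config.behavior)
    if p_correct_override is not None:
        beh_kwargs["p_correct_by_part"] = p_correct_override
    model = mt.BehaviorModel(seed=stage_seed(config.seed, "behavior", participant),
                             **beh_kwargs)
    trials = mt.simulate_behavior(trials, model)

    specs = config.roi_specs()
    if snr_override is not None:
        specs = [dataclasses.replace(s, snr=snr_override if s.encoded_labels else s.snr)
                 for s in specs]
    datasets = sf.generate_participant_data(
        trials, maps, specs,
        noise=sf.NoiseSpec(**config.noise),
        subjective_mode=config.subjective_mode,
        seed=stage_seed(config.seed, "fmri", participant),
        participant=participant,
    )
    return trials, datasets


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle; returns the summary."""
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise RuntimeError(f"stage setup: cannot create output dir {out}: {e}") from e

    summary: dict = {"config_hash": config.config_hash(), "participants": {}}
    stage = "simulate-task"
    try:
        maps = mt.generate_study_maps(stage_seed(config.seed, "maps"))
        base_trials = mt.generate_trial_set(
            maps, config.task_config(), stage_seed(config.seed, "trials"))
        for m in maps:
            (out / f"map{m.map_id}.txt").write_text(m.to_text() + "\n")

        pconf = pp.PreprocessConfig(**config.preprocess)
        sconf = config.slr_config()
        vconf = mv.VisualizationConfig(**config.visualization)
        battery_rows, vis_rows, incorrect_rows = [], [], []
        for participant in range(1, config.n_participants + 1):
            stage = f"simulate participant {participant}"
            trials, datasets = simulate_participant(config, maps, base_trials, participant)
            tdf = mt.trials_to_frame(trials, maps)
            tdf.to_csv(out / f"sub{participant:02d}_trials.tsv", sep="\t", index=False)
            sf.write_dataset(out / f"sub{participant:02d}_data.h5", datasets)

            stage = f"preprocess participant {participant}"
            prep = {roi: pp.preprocess(ds, pconf) for roi, ds in datasets.items()}

            stage = f"decode participant {participant}"
            dec_seed = stage_seed(config.seed, "decode", participant)
            beh_acc = float((tdf.outcome == "CORRECT").sum()
                            / max((tdf.outcome != "MISS").sum(), 1))
            summary["participants"][participant] = {"behavior_accuracy": beh_acc}
            for roi, ds in prep.items():
                X, meta = pp.extract_samples(ds, tdf, "prechoice_mean")
                results = decoding.run_battery(X, meta, "LOSO", seed=dec_seed)
                for code, res in results.items():
                    battery_rows.append({
                        "participant": participant, "roi": roi, "code": code,
                        "scheme": "LOSO", "accuracy": res.accuracy, "n": res.n,
                    })
                inc = decoding.incorrect_trial_evaluation(ds, tdf, sconf, seed=dec_seed)
                if inc is not None:
                    incorrect_rows.append({"participant": participant, "roi": roi, **inc})
                preds = mv.lomo_viewpart_predictions(ds, tdf, sconf, seed=dec_seed)
                if len(preds):
                    for m in maps:
                        rec = mv.reconstruct_map(preds, m, vconf)
                        vis_rows.append({
                            "participant": participant, "roi": roi, "map_id": m.map_id,
                            "vis_accuracy": rec.accuracy, "behavior_accuracy": beh_acc,
                        })
                        (out / f"sub{participant:02d}_{roi}_map{m.map_id}_recon.txt"
                         ).write_text(mv.render_text(rec.binary) + "\n")
    except Exception as e:
        raise RuntimeError(f"pipeline aborted at stage '{stage}': {e}") from e

    battery = pd.DataFrame(battery_rows)
    battery.to_csv(out / "battery_accuracy.tsv", sep="\t", index=False)
    vis = pd.DataFrame(vis_rows)
    vis.to_csv(out / "map_visualization.tsv", sep="\t", index=False)
    if incorrect_rows:
        pd.DataFrame(incorrect_rows).to_csv(out / "incorrect_trials.tsv",
                                            sep="\t", index=False)
    if len(battery):
        fam = (battery.groupby(["participant", "roi"]).accuracy.mean()
               .rename("mean_accuracy").reset_index())
        summary["battery_mean_accuracy"] = {
            roi: float(sub.mean_accuracy.mean()) for roi, sub in fam.groupby("roi")
        }
    if len(vis) >= 3 and vis.vis_accuracy.notna().all():
        summary["behavior_correlation"] = mv.correlate_with_behavior(vis)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s (config %s)", out, summary["config_hash"])
    return summary


def make_fixtures(size: str = "tiny", seed: int = 0) -> dict:
    """In-memory fixture bundle for tests and examples.

    ``tiny``: 1 participant, 2 sessions x 16 trials, 30-voxel ROIs -- runs
    end to end in well under a minute.  ``default``: the full study-scale
    configuration (8 participants, 5 sessions x 64 trials, study-mean ROI
    sizes); only the configuration is returned, not simulated data.
    """
    if size == "default":
        return {"config": RunConfig(seed=seed)}
    if size != "tiny":
        raise ValueError("size must be 'tiny' or 'default'")
    config = RunConfig(
        seed=seed, n_participants=1, sessions=2, trials_per_session=16,
        delay5_per_session=16, coverage_min=0.0,
        rois={"sPC": {"n_voxels": 30, "encoded_labels": ["up_fl", "up_fc", "up_fr"],
                      "snr": 1.0, "n_informative": 10},
              "dPFC": {"n_voxels": 30}},
    )
    maps = mt.generate_study_maps(stage_seed(seed, "maps"))
    base_trials = mt.generate_trial_set(maps, config.task_config(),
                                        stage_seed(seed, "trials"))
    trials, datasets = simulate_participant(config, maps, base_trials, participant=1)
    tdf = mt.trials_to_frame(trials, maps)
    prep = {roi: pp.preprocess(ds, pp.PreprocessConfig(**config.preprocess))
            for roi, ds in datasets.items()}
    return {"config": config, "maps": maps, "trials": trials, "trials_df": tdf,
            "datasets": datasets, "preprocessed": prep}
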