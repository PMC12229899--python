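"""Pipeline orchestration: run analysis stages in order with one root seed.

A :class:`RunConfig` lists the stages to execute and their parameters; every
stage receives a child seed derived by stable hashing of the root seed and
the stage name, so inserting a stage never shifts another stage's
randomness.  Outputs are TSV/JSON files in the output directory plus a
manifest stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, decoding, glm, placecells, remapping, signals, switchtime
from . import sequences as seqmod
from . import warp as warpmod
from .io import load_session, save_ground_truth, save_session
from .synthetic import SimConfig, simulate_session

STAGES = ("simulate", "behavior", "placecells", "remap", "sequences",
          "decode", "warp_ro", "glm", "switch_timing")


@dataclass
class RunConfig:
    stages: list
    seed: int = 0
    session_path: str = ""
    out_dir: str = "rewardremap_out"
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as f:
            d = yaml.safe_load(f)
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(dict(stages=list(self.stages), seed=self.seed,
                                session_path=self.session_path,
                                out_dir=self.out_dir, params=self.params), f)

    def digest(self):
        blob = json.dumps(dict(stages=list(self.stages), seed=self.seed,
                               params=self.params), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31)."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(config_hash=config.digest(), seed=config.seed, stages={})

    session = None
    if "simulate" in config.stages:
        p = dict(config.params.get("simulate", {}))
        p.setdefault("seed", stage_seed(config.seed, "simulate"))
        cfg = SimConfig(**p)
        session, gt = simulate_session(cfg)
        save_session(session, out / "session.h5")
        save_ground_truth(gt, out / "ground_truth.tsv")
        manifest["stages"]["simulate"] = dict(
            n_trials=session.n_trials, n_neurons=session.n_neurons,
            seed=cfg.seed)
    elif config.session_path:
        session = load_session(config.session_path)
    if session is None:
        raise RuntimeError("no session: add the simulate stage or a session_path")

    dff_tensor = signals.bin_session(session, signal="dff")
    place = None
    labels = None

    for stage in config.stages:
        if stage == "simulate":
            continue
        seed = stage_seed(config.seed, stage)
        rng = np.random.default_rng(seed)
        if stage == "behavior":
            lm = behavior.session_lick_map(session)
            blocks = behavior.lick_ratio_blocks(lm, session.switch_trial)
            blocks.to_csv(out / "lick_ratio_blocks.tsv", sep="\t", index=False)
            manifest["stages"]["behavior"] = dict(
                n_blocks=len(blocks),
                overall_ratio=float(behavior.anticipatory_lick_ratio(lm)))
        elif stage == "placecells":
            n_sh = config.params.get("placecells", {}).get("n_shuffles", 100)
            place = placecells.find_place_cells(session, n_sh, rng)
            place.to_csv(out / "place_cells.tsv", sep="\t")
            manifest["stages"]["placecells"] = dict(
                n_place=int(place["place_cell"].sum()), n_shuffles=n_sh,
                seed=seed)
        elif stage == "remap":
            if place is None:
                raise RuntimeError("remap requires the placecells stage")
            n_sh = config.params.get("remap", {}).get("n_shuffles", 500)
            labels = remapping.classify_session(session, place, dff_tensor,
                                                rr_shuffles=n_sh, rng=rng)
            labels.to_csv(out / "remap_labels.tsv", sep="\t")
            manifest["stages"]["remap"] = dict(
                counts=labels["category"].value_counts().to_dict(), seed=seed)
        elif stage == "sequences":
            if labels is None:
                raise RuntimeError("sequences requires the remap stage")
            pre, post = session.trial_sets()
            cells = labels.index[labels["category"] == "RR"].to_numpy()
            res = seqmod.cross_validated_sequence(
                dff_tensor.values, pre, post, cells=cells, rng=rng)
            manifest["stages"]["sequences"] = dict(
                rho=None if np.isnan(res.rho) else float(res.rho),
                p=None if np.isnan(res.p_perm) else float(res.p_perm),
                n_cells=res.n_cells, seed=seed)
        elif stage == "decode":
            if labels is None:
                raise RuntimeError("decode requires the remap stage")
            p = config.params.get("decode", {})
            cells = labels.index[labels["category"] == "RR"].to_numpy()
            if len(cells) == 0:
                manifest["stages"]["decode"] = dict(skipped="no RR cells")
                continue
            res = decoding.decode_protocol(
                session, cells, mode=p.get("mode", "before_after"),
                n_shuffles=p.get("n_shuffles", 100), rng=rng)
            manifest["stages"]["decode"] = dict(
                mean_score=float(res.mean_score), z=float(res.z), seed=seed)
        elif stage == "warp_ro":
            ev_tensor = signals.bin_session(session, signal="events")
            pre, post = session.trial_sets()
            sm = signals.speed_map(
                session.frames["speed_cms"].to_numpy(),
                session.frames["position_cm"].to_numpy(),
                session.frames["trial"].to_numpy(), session.bin_edges,
                teleport=session.frames["teleport"].to_numpy())
            model = warpmod.fit_timewarp(
                np.nan_to_num(sm[pre]), "piecewise-3",
                restarts=config.params.get("warp_ro", {}).get("restarts", 3),
                rng=rng)
            warped = warpmod.apply_warp(
                model, np.nan_to_num(ev_tensor.values[pre]))
            rewarded = session.trials["rewarded"].to_numpy()[pre]
            bw = session.track_length_cm / session.n_bins
            zb = int(session.trials["zone_start_cm"].iloc[pre[0]] // bw)
            ro = warpmod.reward_omission_index(warped, rewarded, zb)
            pd.DataFrame(dict(ro_index=ro.ro_index,
                              eligible=ro.eligible)).to_csv(
                out / "ro_index.tsv", sep="\t")
            manifest["stages"]["warp_ro"] = dict(
                mse=model.mse, n_omissions=ro.n_omissions, seed=seed)
        elif stage == "glm":
            p = config.params.get("glm", {})
            cells = np.asarray(p.get("neurons", np.arange(min(10, session.n_neurons))))
            design = glm.build_design_matrix(session)
            Y = session.events[cells][:, design.frame_index].T.astype(float)
            fit = glm.fit_poisson_glm(design, Y, rng=rng)
            table = glm.contribution_table(fit, design, Y)
            table.to_csv(out / "glm_contributions.tsv", sep="\t")
            manifest["stages"]["glm"] = dict(
                median_fde=float(np.median(fit.fde_test)), seed=seed)
        elif stage == "switch_timing":
            if labels is None:
                raise RuntimeError("switch_timing requires the remap stage")
            cells = labels.index[labels["category"] == "RR"].to_numpy()
            ev_tensor = signals.bin_session(session, signal="events")
            sm_vals = signals.smooth_tuning(ev_tensor.values, 10.0,
                                            session.track_length_cm / session.n_bins,
                                            axis=1)
            restarts = config.params.get("switch_timing", {}).get("restarts", 20)
            pv, _ = switchtime.remap_trial_pipeline(
                np.nan_to_num(sm_vals[:, :, cells]), restarts=restarts, rng=rng)
            lm = behavior.session_lick_map(session)
            lick, _ = switchtime.remap_trial_pipeline(
                np.nan_to_num(lm.rate), restarts=restarts, rng=rng)
            spm = behavior.speed_map(
                session.frames["speed_cms"].to_numpy(),
                session.frames["position_cm"].to_numpy(),
                session.frames["trial"].to_numpy(), session.bin_edges,
                teleport=session.frames["teleport"].to_numpy())
            spd, _ = switchtime.remap_trial_pipeline(
                np.nan_to_num(spm), restarts=restarts, rng=rng)
            lags = switchtime.lag_table(dict(
                neural_PV=pv.remap_trial, licking=lick.remap_trial,
                speed=spd.remap_trial))
            lags.to_csv(out / "remap_lags.tsv", sep="\t", index=False)
            manifest["stages"]["switch_timing"] = dict(
                neural=pv.remap_trial, licking=lick.remap_trial,
                speed=spd.remap_trial, seed=seed)

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=float)
    return manifest
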