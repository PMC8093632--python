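"""End-to-end orchestration: simulate → (render → track) → kinematics →
step cycles → phase statistics → cohort comparison.

A pipeline run compares a control cohort against a lesion cohort of
synthetic walkers (or user-supplied trial CSVs), writing every stage's
output as CSV plus a JSON run manifest. Reruns with the same configuration
and seed reproduce the outputs exactly.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (AnimalSamples, bootstrap_median_ci, compare_cohorts,
                     summarize_lesion_effects)
from .config import LEG_IDS, WalkerConfig, default_walker_config
from .coordination import (PhaseSample, kuiper_two_sample, mean_vector,
                           per_animal_phase_stats, phase_in_reference,
                           watson_williams, HIST_BIN_DEG)
from .kinematics import body_frame, body_velocities, protraction_angles
from .stepcycle import cycles_table, detect_events, step_cycles
from .walker import Trial, generate_cohort

log = logging.getLogger("hexawalk")

#: (receiver, sender) pairs analysed by default: ipsilateral posterior
#: senders plus right-side receivers against their intact-side homologues
DEFAULT_PAIRS = (("L1", "L2"), ("L2", "L3"), ("R1", "R2"), ("R2", "R3"),
                 ("R1", "L1"), ("R2", "L2"), ("R3", "L3"))

STEP_PARAMETERS = (("aep_deg", "deg"), ("pep_deg", "deg"),
                   ("length_deg", "deg"), ("period_s", "s"),
                   ("stance_s", "s"))


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for a full synthetic comparison run."""

    outdir: str = "hexawalk_run"
    seed: int = 0
    lesion_site: str = "T2_right"
    n_animals: int = 5
    trials_per_animal: int = 3
    duration_s: float = 30.0
    between_animal_sd: dict = field(default_factory=lambda: {
        "aep_deg": 3.0, "pep_deg": 3.0, "period_s": 0.03})
    walker: WalkerConfig | None = None   # template; lesion applied per cohort
    render_and_track: bool = False       # go through pixels, not shortcuts
    intensity_threshold: float = 100.0
    min_pixels: int = 4
    max_jump_px: float = 15.0
    window_ms: float = 60.0
    min_prominence_deg: float = 5.0
    min_separation_s: float = 0.1
    pairs: tuple = DEFAULT_PAIRS
    n_boot: int = 2000
    stages: tuple = ("simulate", "kinematics", "steps", "phases", "compare")


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    row_counts: dict
    warnings: list


def _trial_angles(trial: Trial, cfg: PipelineConfig):
    body = body_frame(trial)
    return body, protraction_angles(trial, body)


def _rendered_roundtrip(trial: Trial, cfg: PipelineConfig, seed: int) -> Trial:
    from .render import DEFAULT_CAMERA, render_frames
    from .tracking import Calibration, to_arena_coords, track_markers, \
        project_to_image

    stack, gantry = render_frames(trial, DEFAULT_CAMERA, seed=seed)
    init = {lab: tuple(project_to_image(trial.markers[lab][0], gantry[0],
                                        DEFAULT_CAMERA))
            for lab in trial.markers}
    tracks = track_markers(stack, init, cfg.max_jump_px,
                           intensity_threshold=cfg.intensity_threshold,
                           min_pixels=cfg.min_pixels)
    cal = Calibration(mm_per_px=DEFAULT_CAMERA.mm_per_px,
                      image_centre_px=DEFAULT_CAMERA.image_centre_px)
    out = to_arena_coords(tracks, gantry, cal,
                          frame_rate_hz=trial.frame_rate_hz,
                          animal_id=trial.animal_id, cohort=trial.cohort)
    return out


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order and write all outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    row_counts: dict[str, int] = {}
    template = cfg.walker if cfg.walker is not None else \
        default_walker_config()

    if "simulate" not in cfg.stages:
        raise ValueError("pre-flight: this pipeline driver requires the "
                         "'simulate' stage (no external trial inputs given)")
    if cfg.render_and_track and "track" not in cfg.stages:
        log.info("render_and_track set; implicit 'track' stage enabled")

    cohorts: dict[str, list] = {}
    seeds = {"root": cfg.seed}
    for name, site, sub in (("control", "none", 1),
                            ("lesion", cfg.lesion_site, 2)):
        wcfg = replace(template, lesion=dataclasses.replace(
            template.lesion, site=site, severed_edges=None))
        cohort_seed = cfg.seed * 10007 + sub
        seeds[name] = cohort_seed
        log.info("[simulate] cohort %s (site=%s)", name, site)
        cohorts[name] = generate_cohort(
            wcfg, cfg.n_animals, cfg.trials_per_animal,
            cfg.between_animal_sd, seed=cohort_seed,
            duration_s=cfg.duration_s, cohort=name)
    row_counts["trials"] = sum(len(v) for v in cohorts.values())

    if cfg.render_and_track:
        log.info("[track] rendering and re-tracking every trial")
        for name in cohorts:
            cohorts[name] = [
                (_rendered_roundtrip(tr, cfg, seeds[name] + i), gt)
                for i, (tr, gt) in enumerate(cohorts[name])]

    # kinematics + step segmentation
    cycle_rows, velocity_rows, phase_samples = [], [], {}
    for name, trials in cohorts.items():
        for tr, _gt in trials:
            body, angles = _trial_angles(tr, cfg)
            if "kinematics" in cfg.stages:
                vel = body_velocities(body, cfg.window_ms)
                velocity_rows.append(pd.DataFrame({
                    "cohort": name, "animal_id": tr.animal_id,
                    "time_s": vel.times_s, "tx_mm_s": vel.tx_mm_s,
                    "ty_mm_s": vel.ty_mm_s, "rot_deg_s": vel.rot_deg_s}))
            if "steps" not in cfg.stages:
                continue
            events = {leg: detect_events(angles[leg],
                                         cfg.min_prominence_deg,
                                         cfg.min_separation_s)
                      for leg in LEG_IDS}
            for leg in LEG_IDS:
                tab = cycles_table(step_cycles(events[leg]))
                if len(tab):
                    tab.insert(0, "cohort", name)
                    tab.insert(1, "animal_id", tr.animal_id)
                    cycle_rows.append(tab)
            if "phases" in cfg.stages:
                for recv, send in cfg.pairs:
                    refs = [e.time_s for e in events[send] if e.kind == "AEP"]
                    los = [e.time_s for e in events[recv] if e.kind == "PEP"]
                    if len(refs) < 2:
                        continue
                    res = phase_in_reference(los, refs)
                    phase_samples.setdefault((name, recv, send), []).extend(
                        PhaseSample(pair_id=(recv, send),
                                    animal_id=tr.animal_id, phase_deg=p)
                        for p in res.phases_deg % 360.0)

    if velocity_rows:
        vel_df = pd.concat(velocity_rows, ignore_index=True)
        vel_df.to_csv(outdir / "velocities.csv", index=False,
                      float_format="%.6g")
        row_counts["velocities"] = len(vel_df)
    cycles_df = (pd.concat(cycle_rows, ignore_index=True) if cycle_rows
                 else pd.DataFrame())
    if len(cycles_df):
        cycles_df.to_csv(outdir / "step_cycles.csv", index=False,
                         float_format="%.6g")
        row_counts["step_cycles"] = len(cycles_df)

    # per-animal circular statistics and cohort tests per leg pair
    if "phases" in cfg.stages and phase_samples:
        stat_rows, hist_rows, test_rows = [], [], []
        for (name, recv, send), samples in sorted(phase_samples.items()):
            stats, counts = per_animal_phase_stats(samples)
            for st in stats:
                stat_rows.append({"cohort": name, "receiver": recv,
                                  "sender": send, "animal_id": st.animal_id,
                                  "phi_deg": st.phi_deg, "r": st.r,
                                  "n": st.n})
            for b, cnt in enumerate(counts):
                hist_rows.append({"cohort": name, "receiver": recv,
                                  "sender": send,
                                  "bin_start_deg": b * HIST_BIN_DEG,
                                  "count": int(cnt)})
        stats_df = pd.DataFrame(stat_rows)
        stats_df.to_csv(outdir / "phase_stats.csv", index=False,
                        float_format="%.6g")
        pd.DataFrame(hist_rows).to_csv(outdir / "phase_histograms.csv",
                                       index=False)
        row_counts["phase_stats"] = len(stats_df)
        if "compare" in cfg.stages:
            for recv, send in cfg.pairs:
                key_a, key_b = ("control", recv, send), ("lesion", recv, send)
                if key_a not in phase_samples or key_b not in phase_samples:
                    continue
                ph_a = [s for s in phase_samples[key_a]]
                ph_b = [s for s in phase_samples[key_b]]
                stats_a, _ = per_animal_phase_stats(ph_a)
                stats_b, _ = per_animal_phase_stats(ph_b)
                phis_a = [s.phi_deg for s in stats_a if np.isfinite(s.phi_deg)]
                phis_b = [s.phi_deg for s in stats_b if np.isfinite(s.phi_deg)]
                row = {"receiver": recv, "sender": send,
                       "phi_control_deg": mean_vector(phis_a).phi_deg
                       if phis_a else np.nan,
                       "phi_lesion_deg": mean_vector(phis_b).phi_deg
                       if phis_b else np.nan,
                       "r_control": float(np.mean([s.r for s in stats_a])),
                       "r_lesion": float(np.mean([s.r for s in stats_b]))}
                try:
                    import warnings as _w
                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        row["ww_F"], row["ww_p"] = watson_williams(phis_a,
                                                                   phis_b)
                except ValueError as exc:
                    warnings_log.append(f"watson_williams {recv}-in-{send}: "
                                        f"{exc}")
                    row["ww_F"] = row["ww_p"] = np.nan
                try:
                    row["kuiper_V"], row["kuiper_p"] = kuiper_two_sample(
                        [s.phase_deg for s in ph_a],
                        [s.phase_deg for s in ph_b])
                except ValueError as exc:
                    warnings_log.append(f"kuiper {recv}-in-{send}: {exc}")
                    row["kuiper_V"] = row["kuiper_p"] = np.nan
                test_rows.append(row)
            pd.DataFrame(test_rows).to_csv(outdir / "phase_tests.csv",
                                           index=False, float_format="%.6g")

    # balanced-bootstrap cohort comparison of step parameters
    if "compare" in cfg.stages and len(cycles_df):
        est_rows, comparisons = [], {}
        for pi, (param, units) in enumerate(STEP_PARAMETERS):
            for li, leg in enumerate(LEG_IDS):
                ests = {}
                for ci, name in enumerate(("control", "lesion")):
                    sub = cycles_df[(cycles_df.cohort == name) &
                                    (cycles_df.leg_id == leg)]
                    groups = [AnimalSamples(a, g[param].to_numpy())
                              for a, g in sub.groupby("animal_id")]
                    if not groups:
                        continue
                    boot_seed = (cfg.seed * 1009 + pi * 101 + li * 11
                                 + ci) % (2**31)
                    ests[name] = bootstrap_median_ci(
                        groups, cfg.n_boot, seed=boot_seed,
                        parameter=param, units=units)
                    e = ests[name]
                    est_rows.append({
                        "cohort": name, "leg_id": leg, "parameter": param,
                        "units": units, "median": e.median,
                        "ci95_lo": e.ci95[0], "ci95_hi": e.ci95[1],
                        "ci99_lo": e.ci99[0], "ci99_hi": e.ci99[1],
                        "n_total": e.n_total})
                if len(ests) == 2:
                    comparisons[(param, leg)] = compare_cohorts(
                        ests["control"], ests["lesion"])
        pd.DataFrame(est_rows).to_csv(outdir / "cohort_estimates.csv",
                                      index=False, float_format="%.6g")
        table = summarize_lesion_effects(comparisons)
        table.to_csv(outdir / "effect_table.csv")
        row_counts["comparisons"] = len(comparisons)

    cfg_dict = dataclasses.asdict(replace(cfg, walker=None))
    cfg_dict["walker"] = "default" if cfg.walker is None else "custom"
    manifest = RunManifest(config=cfg_dict, version=__version__, seeds=seeds,
                           row_counts=row_counts, warnings=warnings_log)
    (outdir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True))
    return manifest
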