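"""End-to-end pipeline: simulate → link → analyze → anisotropy → FPT → report.

The pipeline is driven by a flat YAML configuration covering every tunable
parameter. It either generates a synthetic dataset (the default) or starts
from user-supplied trajectory + synapse CSVs, then runs every analysis
stage and writes per-stage CSV tables, a JSON run summary and a plain-text
log into the output directory. Fixed seed ⇒ byte-identical outputs.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import dendrospt
from dendrospt import anisotropy as aniso
from dendrospt import fpt as fpt_mod
from dendrospt import metrics, reporting
from dendrospt.geometry import DendriteGeometry, SynapseMap, make_synapse_map
from dendrospt.linking import LinkerParams, link
from dendrospt.simulate import SimulationParams, simulate_many

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "inputs": {  # set both to use pre-existing data instead of simulating
        "trajectories_csv": None,
        "synapses_csv": None,
    },
    "geometry": {"length": 12.0, "half_width": 1.0},
    "synapses": {
        "n_inhibitory": 3,
        "n_excitatory": 0,
        "spacing": [2.0, 4.0],
        "punctum_radius": 0.2,
    },
    "simulation": {
        "n_receptors": 20,
        "D_long": 0.08,
        "D_trans": 0.02,
        "drift_long": 0.0,
        "drift_trans": 0.0,
        "dt": 0.05,
        "n_frames": 1200,
        "loc_noise_sd": 0.040,
        "trap_D_factor": 0.25,
        "trap_escape_prob": 0.02,
        "blink_on_prob": 0.4,
        "blink_off_prob": 0.1,
    },
    "linking": {"max_disp_px": 4.0, "max_gap": 25},
    "analysis": {
        "msd_fit_points": 4,
        "mobile_threshold": metrics.MOBILE_D_THRESHOLD,
        "paper_convention": False,
    },
    "anisotropy": {
        "convention": "standard",
        "linearity_threshold": aniso.LINEARITY_THRESHOLD,
        "use_geometry": True,
        "min_steps": 30,
    },
    "fpt": {"n_sim": 2000, "enabled": True},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Read a YAML config, filling unset keys with defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stats_dict(s: reporting.SummaryStats) -> dict:
    return {"median": s.median, "q25": s.q25, "q75": s.q75, "n": s.n, "unit": s.unit}


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage and write results under ``out_dir``.

    Returns the run summary (also written as ``summary.json``). Any stage
    failure raises :class:`StageError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    seed = int(config.get("seed", 0))
    log(f"dendrospt {dendrospt.__version__} on python {platform.python_version()}")
    log(f"seed = {seed}")

    # --- stage: simulate (or load) -------------------------------------
    try:
        inputs = config.get("inputs") or {}
        if inputs.get("trajectories_csv"):
            traj = pd.read_csv(inputs["trajectories_csv"])
            synapse_map = (
                SynapseMap.read_csv(inputs["synapses_csv"])
                if inputs.get("synapses_csv")
                else SynapseMap()
            )
            geometry = None
            truth = None
            log(f"loaded {len(traj)} localizations from {inputs['trajectories_csv']}")
        else:
            g = config["geometry"]
            geometry = DendriteGeometry(
                length=float(g["length"]), half_width=float(g["half_width"])
            )
            s = config["synapses"]
            synapse_map = make_synapse_map(
                geometry,
                n_inhibitory=int(s["n_inhibitory"]),
                n_excitatory=int(s.get("n_excitatory", 0)),
                spacing=tuple(s["spacing"]),
                punctum_radius=float(s["punctum_radius"]),
                seed=seed,
            )
            sim_cfg = dict(config["simulation"])
            n_receptors = int(sim_cfg.pop("n_receptors"))
            params = SimulationParams(seed=seed + 1, **sim_cfg)
            traj, truth = simulate_many(n_receptors, geometry, synapse_map, params)
            log(
                f"simulated {n_receptors} receptors, {len(traj)} localizations, "
                f"{len(synapse_map)} synapses"
            )
        synapse_map.write_csv(out / "synapses.csv")
        traj.to_csv(out / "localizations.csv", index=False, float_format="%.6f")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", exc) from exc

    dt = float(config["simulation"]["dt"])

    # --- stage: link ----------------------------------------------------
    try:
        lk = config["linking"]
        lparams = LinkerParams(max_disp=float(lk["max_disp_px"]), max_gap=int(lk["max_gap"]))
        loc_table = traj.rename(columns={"track_id": "source_id"})
        linked = link(loc_table, lparams)
        linked.to_csv(out / "trajectories.csv", index=False, float_format="%.6f")
        log(f"linked into {linked['track_id'].nunique()} trajectories")
        if truth is not None:
            from dendrospt.linking import link_quality

            quality = link_quality(linked, truth)
            quality.to_csv(out / "link_quality.csv", index=False, float_format="%.6f")
            if not quality.empty:
                log(f"link quality: mean purity {quality['purity'].mean():.4f}")
    except Exception as exc:  # noqa: BLE001
        raise StageError("link", exc) from exc

    # --- stage: analyze -------------------------------------------------
    try:
        an = config["analysis"]
        tables = metrics.analyze_tracks(
            linked,
            synapse_map,
            dt=dt,
            msd_fit_points=int(an["msd_fit_points"]),
            mobile_threshold=float(an["mobile_threshold"]),
            paper_convention=bool(an["paper_convention"]),
        )
        for name in ("tracks", "transitions", "dwells"):
            tables[name].to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
        log(
            f"analyzed {len(tables['tracks'])} tracks: "
            f"{len(tables['transitions'])} transitions, {len(tables['dwells'])} dwell episodes"
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("analyze", exc) from exc

    # --- stage: anisotropy ----------------------------------------------
    aniso_table = pd.DataFrame()
    aniso_test = None
    try:
        ac = config["anisotropy"]
        geom_for_axis = geometry if ac.get("use_geometry", True) else None
        try:
            aniso_table, aniso_test = aniso.compare_axes(
                linked,
                geometry=geom_for_axis,
                dt=dt,
                convention=str(ac["convention"]),
                linearity_threshold=float(ac["linearity_threshold"]),
                min_steps=int(ac["min_steps"]),
            )
        except metrics.InsufficientDataError:
            log("anisotropy: no eligible trajectories")
        aniso_table.to_csv(out / "anisotropy.csv", index=False, float_format="%.6f")
    except Exception as exc:  # noqa: BLE001
        raise StageError("anisotropy", exc) from exc

    # --- stage: fpt-match -----------------------------------------------
    intercepts = pd.DataFrame()
    try:
        fc = config["fpt"]
        if fc.get("enabled", True) and not tables["transitions"].empty:
            ev = tables["transitions"].copy()
            d_by_track = tables["tracks"].set_index("track_id")["D_msd_um2s"]
            centers = {s.synapse_id: np.array(s.center) for s in synapse_map}
            n_frames = int(config["simulation"]["n_frames"])
            rows = []
            for i, e in enumerate(ev.itertuples(index=False)):
                L = float(
                    np.hypot(*(centers[e.source_id] - centers[e.target_id]))
                )
                chance = (n_frames - 1 - e.exit_frame) * dt
                rows.append(
                    {
                        "event_id": i,
                        "D_um2s": float(d_by_track.get(e.track_id, np.nan)),
                        "L_um": L,
                        "chance_time_s": chance,
                        "observed_s": float(e.transition_s),
                    }
                )
            events = pd.DataFrame(rows)
            intercepts = fpt_mod.match_experiment(
                events, dt=dt, n_sim=int(fc["n_sim"]), seed=seed + 2
            )
            log(
                f"fpt-match: {len(intercepts)} events matched, "
                f"{len(intercepts.attrs.get('skipped', []))} skipped"
            )
        intercepts.to_csv(out / "fpt_intercepts.csv", index=False, float_format="%.6f")
    except Exception as exc:  # noqa: BLE001
        raise StageError("fpt", exc) from exc

    # --- stage: report ---------------------------------------------------
    try:
        summary: dict = {
            "config": _round_floats(config),
            "n_localizations": int(len(traj)),
            "n_tracks": int(linked["track_id"].nunique()),
            "n_analyzed_tracks": int(len(tables["tracks"])),
            "n_transitions": int(len(tables["transitions"])),
            "n_dwell_episodes": int(len(tables["dwells"])),
        }
        tr = tables["tracks"]
        if not tr.empty:
            summary["D_msd_um2s"] = _stats_dict(
                reporting.summarize(tr["D_msd_um2s"], "um2/s")
            )
            summary["mobile_fraction"] = float(tr["mobile"].mean())
            syn_tracks = tr[tr["synaptic_fraction"] > 0]
            summary["n_synaptic_tracks"] = int(len(syn_tracks))
            if len(syn_tracks):
                summary["intersynaptic_fraction_of_synaptic"] = float(
                    (syn_tracks["n_transitions"] > 0).mean()
                )
        if not tables["transitions"].empty:
            summary["transition_time_s"] = _stats_dict(
                reporting.summarize(tables["transitions"]["transition_s"], "s")
            )
        if not tables["dwells"].empty:
            summary["dwell_time_s"] = _stats_dict(
                reporting.summarize(tables["dwells"]["duration_s"], "s")
            )
        if not aniso_table.empty:
            summary["D_long_um2s"] = _stats_dict(
                reporting.summarize(aniso_table["D_long"], "um2/s")
            )
            summary["D_trans_um2s"] = _stats_dict(
                reporting.summarize(aniso_table["D_trans"], "um2/s")
            )
            if aniso_test is not None:
                summary["D_long_vs_trans"] = _round_floats(aniso_test)
        if not intercepts.empty:
            summary["fpt_intercept_pct"] = _stats_dict(
                reporting.summarize(intercepts["intercept_pct"], "%")
            )
        summary = _round_floats(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log("report written")
    except Exception as exc:  # noqa: BLE001
        raise StageError("report", exc) from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
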