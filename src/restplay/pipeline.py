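"""End-to-end session analysis and reproducible pipeline orchestration.

``analyze_session`` runs every stage on an in-memory session bundle and
returns a nested results dictionary; ``run_all`` drives the same flow
from a config mapping, writing per-stage files and a run manifest with
config hash and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cp
from . import hopfield as hf
from .ensembles import EnsembleDetector, label_ensembles
from .io import load_session, save_session, save_truth
from .reactivation import ReactivationModel
from .ripples import RippleDetector
from .spatial import SpatialCellDetector, compute_tuning_curve
from .synthetic import SimConfig, simulate_full_experiment

__all__ = ["analyze_session", "run_all", "validate_session",
           "DEFAULT_STAGE_PARAMS"]

DEFAULT_STAGE_PARAMS = {
    "n_bins": 50,
    "n_shuffles": 1000,
    "cutoff": 0.75,
    "min_size": 5,
    "sigma_ms": 200.0,
    "penalty_weight": 1.0,
    "swr_window_s": 0.5,
    "pair_window_s": 1.0,
    "pair_alpha": 0.05,
    "pair_n_null": 500,
    "peri_window_s": 2.0,
    "persistence_alpha": 0.001,
}


def _events_by_class(events, labels):
    out = {"cue": [], "trajectory": [], "none": []}
    for ev in events:
        out[labels[ev.ensemble_id]].append(ev)
    return out


def analyze_session(bundle, seed: int = 0, params: dict | None = None,
                    stages: dict | None = None) -> dict:
    """Run the full analysis on a session bundle.

    ``stages`` maps stage names (spatial, ensembles, reactivation,
    ripples, coupling, hopfield) to booleans; omitted stages default to
    enabled.  Stages with unmet dependencies (e.g. coupling without
    LFP) are skipped with a recorded reason.
    """
    p = dict(DEFAULT_STAGE_PARAMS)
    if params:
        p.update(params)
    on = {s: True for s in ("spatial", "ensembles", "reactivation",
                            "ripples", "coupling", "hopfield")}
    if stages:
        on.update(stages)
    meta = bundle.meta or SimConfig()
    fr = meta.frame_rate_hz
    results: dict = {"skipped": {}}

    # --- spatial ---
    spatial_results = None
    tuning = None
    if on["spatial"]:
        det = SpatialCellDetector(
            n_bins=p["n_bins"], belt_length_cm=meta.belt_length_cm,
            n_shuffles=p["n_shuffles"], frame_rate_hz=fr, seed=seed)
        det.fit(bundle.run, position_cm=bundle.position_cm)
        spatial_results = det.results_
        tuning = [compute_tuning_curve(bundle.run[:, i], bundle.position_cm,
                                       p["n_bins"], meta.belt_length_cm)
                  for i in range(bundle.run.shape[1])]
        results["spatial"] = {
            "results": spatial_results,
            "n_spatial": int(det.is_spatial_.sum()),
            "is_spatial": det.is_spatial_,
        }

    # --- ensembles ---
    ensembles = {}
    if on["ensembles"]:
        for block in ("rest1", "rest2"):
            edet = EnsembleDetector(cutoff=p["cutoff"], min_size=p["min_size"],
                                    sigma_ms=p["sigma_ms"], frame_rate_hz=fr)
            edet.fit(getattr(bundle, block),
                     movement_mask=getattr(bundle, f"{block}_movement_mask"),
                     block=block)
            ens = edet.ensembles_
            if spatial_results is not None:
                label_ensembles(ens, spatial_results, tuning,
                                meta.cue_centers_cm, meta.belt_length_cm)
            ensembles[block] = ens
        results["ensembles"] = ensembles

    # --- reactivation (per block with detected ensembles) ---
    models = {}
    if on["reactivation"] and ensembles:
        results["reactivation"] = {}
        for block, ens in ensembles.items():
            if not ens:
                continue
            model = ReactivationModel(penalty_weight=p["penalty_weight"],
                                      frame_rate_hz=fr)
            model.fit(getattr(bundle, block),
                      member_sets=[e.members for e in ens],
                      movement_mask=getattr(bundle,
                                            f"{block}_movement_mask"))
            strengths = model.transform(getattr(bundle, block))
            events = model.detect_events(getattr(bundle, block))
            features = model.run_features(
                bundle.run, bundle.position_cm, p["n_bins"],
                meta.belt_length_cm)
            models[block] = model
            results["reactivation"][block] = {
                "model": model, "strengths": strengths,
                "events": events, "features": features,
            }
    elif on["reactivation"]:
        results["skipped"]["reactivation"] = "no ensembles detected"

    # --- ripples ---
    swr = {}
    if on["ripples"]:
        any_lfp = False
        for block in ("rest1", "rest2"):
            lfp = getattr(bundle, f"lfp_{block}")
            if lfp is None:
                continue
            any_lfp = True
            rdet = RippleDetector(rate_hz=meta.lfp_rate_hz)
            rdet.fit(lfp)
            swr[block] = rdet.events_
        if not any_lfp:
            results["skipped"]["ripples"] = "no LFP in session"
        else:
            results["ripples"] = swr

    # --- coupling ---
    if on["coupling"] and "rest2" in models and "rest2" in swr:
        results["coupling"] = _coupling_stage(
            bundle, results, models, swr, ensembles, p, fr, seed)
    elif on["coupling"]:
        results["skipped"]["coupling"] = "needs rest2 reactivation and SWRs"

    # --- hopfield ---
    if on["hopfield"] and results.get("coupling", {}).get("pairs"):
        block = "rest2"
        ens = ensembles[block]
        feats = results["reactivation"][block]["features"]
        cue_ids = [m for m, e in enumerate(ens) if e.label == "cue"]
        traj_ids = [m for m, e in enumerate(ens) if e.label == "trajectory"]
        cue_feats = {m: feats[m] for m in cue_ids}
        traj_feats = {m: feats[m] for m in traj_ids}
        coupled = [(cue_ids[pr.cue_id], traj_ids[pr.traj_id])
                   for pr in results["coupling"]["pairs"] if pr.coupled]
        results["hopfield"] = hf.coupled_retrieval_experiment(
            cue_feats, traj_feats, coupled)
    elif on["hopfield"]:
        results["skipped"]["hopfield"] = "no coupled pairs available"

    return results


def _coupling_stage(bundle, results, models, swr, ensembles, p, fr, seed):
    block = "rest2"
    ens = ensembles[block]
    labels = [e.label for e in ens]
    strengths = results["reactivation"][block]["strengths"]
    feats = results["reactivation"][block]["features"]
    events = results["reactivation"][block]["events"]
    swr_onsets = [e.onset_s for e in swr[block]]
    out: dict = {}

    # peri-SWR averages per class and the cue-vs-trajectory lag
    peri = {}
    for label in ("cue", "trajectory"):
        ids = [m for m, lab in enumerate(labels) if lab == label]
        if not ids or not swr_onsets:
            continue
        mean_s = strengths[:, ids].mean(axis=1)
        try:
            peri[label] = cp.peri_event_average(
                mean_s, swr_onsets, fr, p["peri_window_s"])
        except ValueError:
            pass
    out["peri_swr"] = peri
    if "cue" in peri and "trajectory" in peri:
        lag = cp.xcorr_gaussian_lag(peri["cue"].mean_z,
                                    peri["trajectory"].mean_z, fr,
                                    max_lag_s=p["pair_window_s"])
        out["cue_traj_lag"] = lag

    # SWR-association fraction per class
    by_class = _events_by_class(events, labels)
    out["swr_association_pct"] = {
        lab: cp.swr_association_fraction(
            [e.onset_s for e in evs], swr_onsets, p["swr_window_s"])
        for lab, evs in by_class.items() if evs}

    # coupled cue-trajectory pairs and feature similarity
    cue_ids = [m for m, lab in enumerate(labels) if lab == "cue"]
    traj_ids = [m for m, lab in enumerate(labels) if lab == "trajectory"]
    pairs = []
    if cue_ids and traj_ids:
        pairs = cp.find_coupled_pairs(
            strengths[:, cue_ids], strengths[:, traj_ids], fr,
            window_s=p["pair_window_s"], alpha=p["pair_alpha"],
            n_null=p["pair_n_null"], seed=seed)
        for pr in pairs:
            try:
                r, z = cp.feature_similarity(feats[cue_ids[pr.cue_id]],
                                             feats[traj_ids[pr.traj_id]])
                pr.feature_r, pr.feature_z = r, z
            except ValueError:
                pass
    out["pairs"] = pairs

    # explained variance and ensemble persistence
    try:
        ev, rev = cp.explained_variance(bundle.rest1, bundle.run,
                                        bundle.rest2)
        out["explained_variance"] = {"ev": ev, "rev": rev}
    except ValueError:
        pass
    r1_members = [e.members for e in ensembles.get("rest1", [])]
    persistence = []
    n_total = bundle.rest2.shape[1]
    for e in ens:
        J = cp.max_jaccard(e.members, r1_members)
        sig = False
        if r1_members:
            best = max(r1_members,
                       key=lambda m: cp.jaccard_persistence(e.members, m))
            O = len(set(e.members) & set(best))
            _, sig = cp.persistence_significance(
                O, len(best), len(e.members), n_total,
                p["persistence_alpha"])
        persistence.append({"label": e.label, "max_jaccard": J,
                            "persistent": sig})
    out["persistence"] = persistence
    return out


# ---------------------------------------------------------------------------
# file-level pipeline
# ---------------------------------------------------------------------------

def validate_session(path) -> list[str]:
    """Schema and invariant checks on a stored session; returns a list
    of violations (empty when the session is valid)."""
    try:
        bundle = load_session(path)
    except Exception as exc:  # unreadable file is one big violation
        return [f"cannot read session: {exc}"]
    return bundle.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_outputs(out_dir: Path, results: dict, fr: float) -> list[Path]:
    written = []

    def record(path):
        written.append(path)
        return path

    if "spatial" in results:
        rows = []
        for r in results["spatial"]["results"]:
            rows.append({
                "neuron": r.neuron, "si_bits": r.si_bits, "si_p": r.si_p,
                "n_fields": len(r.fields), "is_spatial": r.is_spatial,
                "field_centers": ";".join(str(f.center_bin)
                                          for f in r.fields),
                "field_widths": ";".join(f"{f.width_bins:g}"
                                         for f in r.fields)})
        pd.DataFrame(rows).to_csv(record(out_dir / "spatial.csv"),
                                  index=False)
    if "ensembles" in results:
        payload = {block: [{"members": e.members, "label": e.label,
                            "segments": [list(s) for s in e.segments]}
                           for e in ens]
                   for block, ens in results["ensembles"].items()}
        record(out_dir / "ensembles.json").write_text(
            json.dumps(payload, indent=1))
    if "reactivation" in results:
        for block, r in results["reactivation"].items():
            rows = [{"ensemble_id": e.ensemble_id, "onset_s": e.onset_s,
                     "offset_s": e.offset_s, "peak_s": e.peak_s,
                     "peak_z": e.peak_strength} for e in r["events"]]
            pd.DataFrame(rows).to_csv(
                record(out_dir / f"react_events_{block}.csv"), index=False)
            pd.DataFrame(r["features"]).to_csv(
                record(out_dir / f"react_features_{block}.csv"), index=False)
    if "ripples" in results:
        for block, evs in results["ripples"].items():
            rows = [{"onset_s": e.onset_s, "offset_s": e.offset_s,
                     "peak_s": e.peak_s, "peak_power_sd": e.peak_power_sd}
                    for e in evs]
            pd.DataFrame(rows).to_csv(
                record(out_dir / f"swr_{block}.csv"), index=False)
    if "coupling" in results:
        c = results["coupling"]
        payload = {
            "swr_association_pct": c.get("swr_association_pct", {}),
            "explained_variance": c.get("explained_variance", {}),
            "cue_traj_lag_s": (c["cue_traj_lag"].lag_s
                               if "cue_traj_lag" in c else None),
            "pairs": [dataclasses.asdict(pr) for pr in c.get("pairs", [])],
            "persistence": c.get("persistence", []),
        }
        record(out_dir / "coupling.json").write_text(
            json.dumps(payload, indent=1))
    if "hopfield" in results:
        record(out_dir / "hopfield.json").write_text(
            json.dumps(results["hopfield"], indent=1))
    return written


def run_all(config: dict) -> dict:
    """Execute the pipeline from a config mapping; returns the manifest.

    Config keys: ``out_dir`` (required), ``seed``, ``session`` (path to
    an existing HDF5 session; omit to simulate), ``simulate`` (SimConfig
    overrides), ``params`` (stage parameters), ``stages`` (enable
    flags).
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    t0 = time.time()

    if config.get("session"):
        bundle = load_session(config["session"])
        truth = None
    else:
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs.pop("enabled", None)
        sim_kwargs.setdefault("seed", seed)
        sim = SimConfig(**sim_kwargs)
        bundle, truth = simulate_full_experiment(sim)
        save_session(out_dir / "session.h5", bundle)
        save_truth(out_dir / "truth.json", truth)

    violations = bundle.validate()
    if violations:
        raise ValueError("invalid session: " + "; ".join(violations))

    results = analyze_session(bundle, seed=seed,
                              params=config.get("params"),
                              stages=config.get("stages"))
    fr = (bundle.meta or SimConfig()).frame_rate_hz
    written = _write_outputs(out_dir, results, fr)

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "outputs": {p.name: _sha256(p) for p in written},
        "skipped": results.get("skipped", {}),
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
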