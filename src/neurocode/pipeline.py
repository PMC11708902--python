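"""End-to-end orchestration on synthetic ensembles.

``run_all`` takes one configuration (dict or YAML file) and one master
seed, generates a synthetic ensemble, runs the preprocessing screen,
builds raw and noise-corrected RSA matrices in both featurizations,
computes decoding curves per timescale, validates the corrected
estimator against the ensemble's ground truth, and trains the RL model
on an artificial pattern pair — writing every result as CSV/JSON into
the output directory together with the config hash and per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decode, periphery, popcode, rlmodel, synthio
from .preprocess import reproducibility

log = logging.getLogger(__name__)

__all__ = ["default_config", "run_all"]


def default_config() -> dict:
    return {
        "seed": 0,
        "ensemble": {
            "n_neurons": 300, "n_bins": 12, "n_stimuli": 8,
            "true_corr": 0.5, "noise_sd": 1.0, "n_trials": 12,
            "n_sessions": 4,
        },
        "preprocess": {"repro_threshold": 0.12},
        "decode": {"n_split_seeds": 5, "fourier": "cumulative"},
        "rlmodel": {
            "n_neurons": 300, "n_bins": 25, "frac_resampled": 0.8,
            "activity_offset": 0.0, "max_trials": 3000, "n_repeats": 3,
        },
    }


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _seed_for(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_all(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the full synthetic analysis flow; returns the report dict."""
    if not isinstance(config, dict):
        with open(config) as f:
            config = yaml.safe_load(f)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config["seed"])
    chash = _config_hash(config)
    report: dict = {"config_hash": chash, "seed": master, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        return t0

    def done(name, t0):
        dt = time.perf_counter() - t0
        report["stages"][name] = round(dt, 3)
        log.info("stage %s: %.2fs", name, dt)

    # ---- generate ----------------------------------------------------
    t0 = stage("generate")
    ens_cfg = config["ensemble"]
    ensemble = synthio.make_noisy_ensemble(
        seed=_seed_for(master, "ensemble"), **ens_cfg)
    done("generate", t0)

    # ---- preprocess screen -------------------------------------------
    t0 = stage("preprocess")
    report_pre = reproducibility(
        ensemble, config["preprocess"]["repro_threshold"])
    report_pre.to_frame().to_csv(out / "reproducibility.csv", index=False)
    report["n_kept_neurons"] = int(report_pre.kept_mask.sum())
    done("preprocess", t0)

    # ---- RSA ---------------------------------------------------------
    t0 = stage("rsa")
    rsa_summary = {}
    for mode in ("spatial", "spatiotemporal"):
        for corrected in (True, False):
            m = popcode.rsa(ensemble, mode, corrected=corrected)
            tag = f"{mode}_{'corrected' if corrected else 'raw'}"
            m.to_frame().to_csv(out / f"rsa_{tag}.csv")
            rsa_summary[tag] = m.mean_offdiagonal()
    rsa_summary["rho_diff"] = popcode.rho_diff(
        rsa_summary["spatial_corrected"],
        rsa_summary["spatiotemporal_corrected"])
    report["rsa"] = rsa_summary
    done("rsa", t0)

    # ---- estimator validation against ground truth -------------------
    t0 = stage("estimator")
    true_corr = float(ensemble.truth["correlations"][0, 1])
    report["estimator"] = {
        "true_corr": true_corr,
        "corrected": rsa_summary["spatiotemporal_corrected"],
        "raw": rsa_summary["spatiotemporal_raw"],
    }
    done("estimator", t0)

    # ---- decoding ----------------------------------------------------
    t0 = stage("decode")
    seeds = [_seed_for(master, f"split{i}")
             for i in range(config["decode"]["n_split_seeds"])]
    curves = {}
    for fmode in ("per_band", "cumulative"):
        res = decode.decode_by_timescale(ensemble, fmode, seeds=seeds)
        pd.DataFrame({"band": res["bands"],
                      "accuracy": res["accuracy"]}).to_csv(
            out / f"decode_{fmode}.csv", index=False)
        curves[fmode] = res["accuracy"].tolist()
    accs = {m: float(np.mean([
        decode.decode_ensemble(ensemble, m, s).accuracy for s in seeds]))
        for m in ("spatial", "spatiotemporal")}
    report["decode"] = {"time_domain": accs, **curves}
    done("decode", t0)

    # ---- RL learning -------------------------------------------------
    t0 = stage("rlmodel")
    rl_cfg = dict(config["rlmodel"])
    pair = synthio.make_pattern_pair(
        rl_cfg.pop("n_neurons"), rl_cfg.pop("n_bins"),
        frac_resampled=rl_cfg.pop("frac_resampled"),
        activity_offset=rl_cfg.pop("activity_offset"),
        seed=_seed_for(master, "pair"))
    outcome = rlmodel.train(pair.X_go, pair.X_nogo,
                            seed=_seed_for(master, "train"), **rl_cfg)
    pd.DataFrame({"block": np.arange(len(outcome.curve)),
                  "accuracy": outcome.curve}).to_csv(
        out / "learning_curve.csv", index=False)
    report["rlmodel"] = {
        "trials_to_criterion": outcome.trials_to_criterion,
        "learned": bool(outcome.learned),
        "realized": pair.meta["realized"],
    }
    done("rlmodel", t0)

    # ---- periphery layout (deterministic constants) -------------------
    t0 = stage("periphery")
    layout = periphery.build_layout(seed=_seed_for(master, "periphery"))
    layout.ihc_table().to_csv(out / "anf_layout_ihc.csv", index=False)
    report["periphery"] = {
        "n_ihcs": layout.n_ihcs, "n_fibers": layout.n_fibers,
        "apex_percent": float(layout.ihc_positions[0]),
        "increment_percent": float(np.diff(layout.ihc_positions).mean()),
    }
    done("periphery", t0)

    report["versions"] = {"neurocode": "0.1.0"}
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    return report
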