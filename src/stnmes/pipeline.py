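"""End-to-end orchestration: simulate -> metrics -> MES -> featurize ->
decode -> weight statistics, with a machine-readable run report.

The report records per-stage provenance (config hash, seeds, epoch
counts) and the headline numbers: MES classification AUC, decoding
accuracy per timescale, and flagged weight clusters.  Identical config
and seed reproduce the report exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import click
import numpy as np
import yaml

from stnmes import behavior as bhv
from stnmes import decoding as dec
from stnmes import io as sio
from stnmes import mes as mes_mod
from stnmes import weight_stats as ws
from stnmes.spectral import build_band_scheme, epoch_spectral_features, preprocess_lfp
from stnmes.synth import GeneratorConfig, simulate_session

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "epoch_len": 7.0,
    "epoch_lens": [],  # optional timescale sweep, e.g. [1, ..., 10]
    "generator": {},  # overrides for GeneratorConfig fields
    "decode": {"kernel": "linear", "n_folds": 100},
    "mes": {"n_folds": 100},
    "stages": {"decode": True, "weights": True},
    "out": None,
}


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merged(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config: dict | None = None) -> dict:
    """Run the full synthetic-session analysis and return the run report."""
    cfg = _merged(config)
    seed = int(cfg["seed"])
    gen = GeneratorConfig(**cfg["generator"])
    report: dict = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "generator": dataclasses.asdict(gen),
        "warnings": [],
    }

    ss = np.random.SeedSequence(seed).generate_state(2)
    pd_session = simulate_session(gen, group="PD", seed=int(ss[0]), subject_id="PD00")
    ct_session = simulate_session(
        gen, group="control", seed=int(ss[1]), subject_id="CTRL", with_lfp=False
    )

    el = float(cfg["epoch_len"])
    pd_mm = bhv.metrics_from_traces(pd_session.cursor, pd_session.target, el, group="PD")
    ct_mm = bhv.metrics_from_traces(ct_session.cursor, ct_session.target, el, group="control")
    model = mes_mod.fit_mes_model(pd_mm, ct_mm, n_folds=int(cfg["mes"]["n_folds"]), seed=seed)
    pd_mes = mes_mod.score_mes(model, pd_mm)
    ct_mes = mes_mod.score_mes(model, ct_mm)
    report["mes"] = {
        "epoch_len": el,
        "cv_auc": model.cv_auc,
        "auc": mes_mod.mes_discriminability(pd_mes, ct_mes),
        "n_pd_epochs": int(pd_mm.complete.sum()),
        "weights": dict(zip(bhv.METRICS, model.w.tolist())),
    }

    outdir = Path(cfg["out"]) if cfg["out"] else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_behavior_h5(pd_session.cursor, pd_session.target, outdir / "pd_behavior.h5")
        sio.write_lfp_h5(pd_session.lfp, outdir / "pd_lfp.h5")
        pd_mm.to_csv(outdir / "pd_metrics.csv")
        sio.write_mes_csv(pd_mes, outdir / "pd_mes.csv")
        sio.write_mes_model(model, outdir / "mes_model.json")

    if cfg["stages"].get("decode", True):
        scheme = build_band_scheme()
        clean = preprocess_lfp(pd_session.lfp)
        feats = epoch_spectral_features(clean, el, scheme=scheme)
        decode_cfg = cfg["decode"]
        broadband, per_band = dec.broadband_vs_band(
            feats,
            pd_mes,
            seed=seed,
            kernel=decode_cfg.get("kernel", "linear"),
            n_folds=int(decode_cfg.get("n_folds", 100)),
        )
        report["decode"] = {
            "epoch_len": el,
            "mean_r": broadband.mean_r,
            "per_band_mean_r": {b: c.result.mean_r for b, c in per_band.items()},
            "broadband_vs_band_p": {b: c.p_wilcoxon for b, c in per_band.items()},
        }
        if cfg["epoch_lens"]:
            sweep = dec.timescale_sweep(
                pd_session.cursor,
                pd_session.target,
                ct_session.cursor,
                ct_session.target,
                clean,
                epoch_lens=[float(x) for x in cfg["epoch_lens"]],
                preprocessed=True,
                n_folds=int(decode_cfg.get("n_folds", 100)),
                mes_folds=int(cfg["mes"]["n_folds"]),
                seed=seed,
            )
            report["decode"]["timescale_mean_r"] = dict(
                zip(sweep["epoch_len"].tolist(), sweep["mean_r"].tolist())
            )
            if outdir:
                sweep.to_csv(outdir / "timescale_sweep.csv", index=False)
        if outdir:
            sio.write_features_csv(feats, outdir / "pd_features.csv")

        if cfg["stages"].get("weights", True) and broadband.coefs is not None:
            profile = ws.performance_weighted_mean(
                broadband.coefs[np.isfinite(broadband.fold_r)],
                broadband.fold_r[np.isfinite(broadband.fold_r)],
            )
            clusters = ws.contiguity_permutation_test(profile, seed=seed)
            report["weights"] = {
                "profile": profile.mean.tolist(),
                "n_high_clusters": len(clusters.high),
                "n_low_clusters": len(clusters.low),
            }

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


@click.group()
@click.option("--verbose", is_flag=True, default=False)
def cli(verbose: bool) -> None:
    """Motor-impairment scoring and STN LFP decoding pipeline."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def run(config_path, seed, out) -> None:
    """Run the full synthetic pipeline and print the report."""
    cfg = yaml.safe_load(Path(config_path).read_text()) if config_path else {}
    if seed is not None:
        cfg["seed"] = seed
    if out is not None:
        cfg["out"] = out
    report = run_pipeline(cfg)
    click.echo(json.dumps(report, indent=2))


@cli.command()
@click.option("--seed", type=int, default=0)
@click.option("--duration", type=float, default=600.0)
@click.option("--group", type=click.Choice(["PD", "control"]), default="PD")
@click.option("--out", type=click.Path(), required=True)
def simulate(seed, duration, group, out) -> None:
    """Write one synthetic session (behavior HDF5 + LFP HDF5)."""
    gen = GeneratorConfig(duration=duration)
    session = simulate_session(gen, group=group, seed=seed, with_lfp=group == "PD")
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_behavior_h5(session.cursor, session.target, outdir / "behavior.h5")
    if session.lfp is not None:
        sio.write_lfp_h5(session.lfp, outdir / "lfp.h5")
    click.echo(f"wrote session ({group}, {duration:g} s) to {outdir}")
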