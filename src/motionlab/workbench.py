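"""Experiment orchestration: config, ensembles, tables, reports.

A single YAML/JSON config describes the corpus, training, battery and
analysis parameters for a multi-seed ensemble run (10 seeds mirrors the
convention of training 10 networks; the smoke profile uses 2).  Every
output table carries the config hash so tables from different runs
cannot be silently mixed, and the whole pipeline is a pure function of
(config, seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuits, psychophys, tuning
from .corpus import build_corpus, save_corpus
from .model import TrainConfig, evaluate, init_model, persist_model, train

__all__ = [
    "ExperimentConfig",
    "ResultsBundle",
    "PROFILES",
    "run_experiment",
    "write_report",
    "write_table",
    "read_table",
]

ANALYSES = ("tuning", "classify", "circuits", "psychophys")


@dataclass(frozen=True)
class ExperimentConfig:
    name: str = "experiment"
    # corpus
    n_sequences: int = 32000
    speed_range: tuple[float, float] = (0.8, 3.8)
    n_frames: int = 6
    n_textures: int = 200
    texture_size: int = 128
    corpus_seed: int = 0
    # training
    learning_rate: float = 1.0e-4
    batch_size: int = 32
    epochs: int = 25
    seeds: tuple[int, ...] = tuple(range(10))
    # batteries
    n_directions: int = 16
    n_sf: int = 10
    n_tf: int = 10
    spectral_n_sf: int = 6
    spectral_n_tf: int = 6
    n_phases: int = 32
    # psychophysics
    trials: int = 100
    stim_seeds: int = 20
    # which analyses to run
    analyses: tuple[str, ...] = ANALYSES
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.n_sequences < 4:
            raise ValueError("n_sequences must be >= 4")
        if not self.seeds:
            raise ValueError("need at least one ensemble seed")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; valid: {ANALYSES}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speed_range"] = list(d["speed_range"])
        d["seeds"] = list(d["seeds"])
        d["analyses"] = list(d["analyses"])
        return d

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("speed_range", "seeds", "analyses"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


PROFILES = {
    "full": ExperimentConfig(name="full"),
    "smoke": ExperimentConfig(
        name="smoke",
        n_sequences=500,
        n_textures=20,
        epochs=2,
        seeds=(0, 1),
        n_sf=3,
        n_tf=3,
        spectral_n_sf=3,
        spectral_n_tf=3,
        n_phases=4,
        trials=10,
        stim_seeds=3,
    ),
    "desk": ExperimentConfig(
        name="desk",
        n_sequences=8000,
        epochs=25,
        seeds=tuple(range(10)),
    ),
}


@dataclass
class ResultsBundle:
    config: ExperimentConfig
    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    models: dict[int, Path] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    """CSV with a leading config-hash comment line."""
    with open(path, "w") as f:
        f.write(f"# config_hash={config_hash}\n")
        df.to_csv(f, index=False)


def read_table(path: str | Path, expect_hash: str | None = None) -> pd.DataFrame:
    with open(path) as f:
        header = f.readline().strip()
        if not header.startswith("# config_hash="):
            raise ValueError(f"{path}: missing config-hash header")
        got = header.split("=", 1)[1]
        if expect_hash is not None and got != expect_hash:
            raise ValueError(
                f"{path}: config hash {got} does not match expected {expect_hash}; "
                "refusing to mix tables from different runs"
            )
        return pd.read_csv(f)


def _log_grid_counts(cfg: ExperimentConfig):
    sf = (8.0, 25.0, cfg.n_sf)
    tf = (4.0, 25.0, cfg.n_tf)
    ssf = (8.0, 33.0, cfg.spectral_n_sf)
    stf = (4.0, 500.0, cfg.spectral_n_tf)
    return sf, tf, ssf, stf


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> ResultsBundle:
    """Corpus -> per-seed training -> requested analyses.

    Writes models, CSV tables and a manifest under ``out_dir``;
    idempotent and deterministic per (config, seeds).
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    bundle = ResultsBundle(config=cfg, out_dir=out)
    chash = cfg.hash

    corpus = build_corpus(
        cfg.n_sequences,
        speed_range=cfg.speed_range,
        n_frames=cfg.n_frames,
        seed=cfg.corpus_seed,
        n_textures=cfg.n_textures,
        texture_size=cfg.texture_size,
    )
    save_corpus(corpus, out / "corpus.h5")

    models = {}
    eval_rows = []
    for seed in cfg.seeds:
        params = init_model(seed=seed)
        params, history = train(
            params, corpus,
            TrainConfig(learning_rate=cfg.learning_rate,
                        batch_size=cfg.batch_size, epochs=cfg.epochs, seed=seed),
        )
        mpath = out / "models" / f"model_seed{seed}.h5"
        persist_model(params, mpath)
        bundle.models[seed] = mpath
        models[seed] = params
        r_vx, r_vy = evaluate(params, corpus.test)
        eval_rows.append({
            "seed": seed, "r_vx": r_vx, "r_vy": r_vy,
            "final_train_loss": history.train_loss[-1],
            "final_test_loss": history.test_loss[-1] if history.test_loss else np.nan,
        })
    df_eval = pd.DataFrame(eval_rows)
    write_table(df_eval, out / "velocity_correlations.csv", chash)
    bundle.tables["velocity_correlations"] = out / "velocity_correlations.csv"

    sf, tf, ssf, stf = _log_grid_counts(cfg)
    need_tuning = bool(set(cfg.analyses) & {"tuning", "classify", "circuits"})
    batteries = {}
    if need_tuning:
        tuning_rows = []
        for seed, params in models.items():
            v1_t, mt_t = tuning.grating_battery(
                params, cfg.n_directions, sf, tf, cfg.n_phases)
            v1_sum = [tuning.preferred_tuning(v1_t, u) for u in range(v1_t.n_units)]
            mt_sum = [tuning.preferred_tuning(mt_t, u) for u in range(mt_t.n_units)]
            batteries[seed] = (v1_t, mt_t, v1_sum, mt_sum)
            for layer, summaries in (("v1", v1_sum), ("mt", mt_sum)):
                for s in summaries:
                    tuning_rows.append({
                        "seed": seed, "layer": layer, "unit": s.unit,
                        "preferred_direction": s.preferred_direction,
                        "preferred_sf": s.preferred_sf,
                        "preferred_tf": s.preferred_tf,
                        "preferred_speed": s.preferred_speed,
                        "defined": s.defined, "tied": s.tied,
                    })
        if "tuning" in cfg.analyses:
            write_table(pd.DataFrame(tuning_rows), out / "tuning_summaries.csv", chash)
            bundle.tables["tuning_summaries"] = out / "tuning_summaries.csv"

    if "classify" in cfg.analyses:
        class_rows = []
        for seed, params in models.items():
            v1_t, mt_t, v1_sum, mt_sum = batteries[seed]
            spectral = tuning.spectral_battery(
                params, cfg.n_directions, ssf, stf, cfg.n_phases)
            classes = tuning.classify_network(
                params, battery=(v1_t, mt_t), spectral=spectral,
                n_phases=cfg.n_phases)
            for layer in ("v1", "mt"):
                for dcls, scls in zip(classes[layer]["direction"],
                                      classes[layer]["spectral"]):
                    for cls in (dcls, scls):
                        if cls is None:
                            continue
                        class_rows.append({
                            "seed": seed, "layer": layer, "unit": cls.unit,
                            "axis": cls.axis, "r_p": cls.r_p, "r_c": cls.r_c,
                            "r_cp": cls.r_cp, "R_p": cls.R_p, "R_c": cls.R_c,
                            "Z_p": cls.Z_p, "Z_c": cls.Z_c,
                            "label": cls.label, "index": cls.index,
                            "flags": ";".join(cls.flags),
                        })
        write_table(pd.DataFrame(class_rows), out / "selectivity_classes.csv", chash)
        bundle.tables["selectivity_classes"] = out / "selectivity_classes.csv"

    if "circuits" in cfg.analyses:
        prof_rows, split_rows = [], []
        for seed, params in models.items():
            _, _, v1_sum, mt_sum = batteries[seed]
            for mode in ("preferred-direction", "max-excitation", "max-inhibition"):
                prof = circuits.aligned_weight_profile(params, v1_sum, mt_sum, mode,
                                                       n_bins=cfg.n_directions)
                for off, m, sd in zip(prof.offsets, prof.mean, prof.sd):
                    prof_rows.append({"seed": seed, "mode": mode, "offset": off,
                                      "mean_weight": m, "sd": sd})
            split = circuits.speed_split_connectivity(params, v1_sum, mt_sum)
            for _, row in split.summary().iterrows():
                split_rows.append({"seed": seed, **row.to_dict()})
        write_table(pd.DataFrame(prof_rows), out / "weight_profiles.csv", chash)
        write_table(pd.DataFrame(split_rows), out / "connectivity_split.csv", chash)
        bundle.tables["weight_profiles"] = out / "weight_profiles.csv"
        bundle.tables["connectivity_split"] = out / "connectivity_split.csv"
        rp = circuits.reverse_phi_experiment(
            list(models.values()), n_stim_seeds=cfg.stim_seeds, seed=cfg.corpus_seed)
        write_table(rp, out / "reverse_phi.csv", chash)
        bundle.tables["reverse_phi"] = out / "reverse_phi.csv"
        cc = circuits.edge_crosscorr_sim()
        write_table(cc, out / "edge_crosscorr.csv", chash)
        bundle.tables["edge_crosscorr"] = out / "edge_crosscorr.csv"

    if "psychophys" in cfg.analyses:
        psych_rows = []
        for seed, params in models.items():
            dcurve = psychophys.coherence_direction_task(
                params, trials=cfg.trials, seed=cfg.corpus_seed)
            for c, v in zip(dcurve.coherences, dcurve.values):
                psych_rows.append({"seed": seed, "task": "direction", "coherence": c,
                                   "value": v, "n_trials": dcurve.n_trials,
                                   "weibull_alpha": dcurve.weibull.alpha if dcurve.weibull else np.nan,
                                   "weibull_beta": dcurve.weibull.beta if dcurve.weibull else np.nan,
                                   "flagged": len(dcurve.flags) > 0})
            scurve = psychophys.coherence_speed_task(
                params, trials=cfg.trials, seed=cfg.corpus_seed)
            for c, v, raw in zip(scurve.coherences, scurve.values, scurve.raw_speeds):
                psych_rows.append({"seed": seed, "task": "speed", "coherence": c,
                                   "value": v, "n_trials": scurve.n_trials,
                                   "weibull_alpha": np.nan, "weibull_beta": np.nan,
                                   "flagged": len(scurve.flags) > 0})
        write_table(pd.DataFrame(psych_rows), out / "psychophysics.csv", chash)
        bundle.tables["psychophysics"] = out / "psychophysics.csv"
        pool = psychophys.pooling_prediction(list(models.values()),
                                             trials=cfg.trials, seed=cfg.corpus_seed)
        pool_df = pd.DataFrame({
            "unit": np.arange(pool.n),
            "activity_0": pool.activity_0,
            "activity_50": pool.activity_50,
            "activity_100": pool.activity_100,
            "predicted_50": pool.predicted_50,
        })
        pool_df["pearson_r"] = pool.r
        pool_df["p_value"] = pool.p
        write_table(pool_df, out / "pooling_prediction.csv", chash)
        bundle.tables["pooling_prediction"] = out / "pooling_prediction.csv"

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": chash,
        "tables": {k: str(v.name) for k, v in bundle.tables.items()},
        "models": {str(k): str(v.name) for k, v in bundle.models.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def write_report(bundle: ResultsBundle, path: str | Path | None = None) -> str:
    """Render a plain-text/markdown summary from the bundle's tables."""
    if not bundle.tables:
        raise ValueError("empty bundle: nothing to report")
    chash = bundle.config.hash
    lines = [f"# {bundle.config.name} — run report", "",
             f"config hash: `{chash}`", ""]
    ev = read_table(bundle.tables["velocity_correlations"], chash)
    lines.append("## Velocity decoding")
    for _, row in ev.iterrows():
        lines.append(f"- seed {int(row.seed)}: r_vx={row.r_vx:.3f}, r_vy={row.r_vy:.3f}")
    lines.append("")
    if "selectivity_classes" in bundle.tables:
        sc = read_table(bundle.tables["selectivity_classes"], chash)
        lines.append("## Selectivity classification (units per label)")
        counts = sc.groupby(["layer", "axis", "label"]).size()
        for (layer, axis, label), n in counts.items():
            lines.append(f"- {layer}/{axis}/{label}: {n}")
        n_flagged = int((sc["flags"].fillna("") != "").sum())
        if n_flagged:
            lines.append(f"- WARNING: {n_flagged} unit classifications carried flags")
        lines.append("")
    if "psychophysics" in bundle.tables:
        ps = read_table(bundle.tables["psychophysics"], chash)
        lines.append("## Psychophysics")
        for task, grp in ps.groupby("task"):
            mean_curve = grp.groupby("coherence")["value"].mean()
            pts = ", ".join(f"{c:g}:{v:.2f}" for c, v in mean_curve.items())
            lines.append(f"- {task}: {pts}")
        if bool(ps["flagged"].any()):
            lines.append("- WARNING: some psychophysics runs carried flags")
        lines.append("")
    report = "\n".join(lines)
    if path is not None:
        Path(path).write_text(report)
    return report
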