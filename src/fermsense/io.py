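"""CSV/YAML interfaces for cultivation records, latent states and results.

Record time series travel as a CSV (``time_h, our, cpr, broth_kg,
feed_glucose[, feed_isoleucine]``) with a YAML metadata sidecar carrying the
scalars (``x0, s0, induction_time_h, units, seed``).  Latent states, offline
assays, evaluation tables and committee manifests all use plain CSV/YAML so
every artifact is inspectable and diffable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ensemble import Committee, ModelEvaluation
from .physiology import CultivationRecord, LatentStates
from .simulate import GroundTruth, SimulationConfig, SoluteLaw

__all__ = [
    "write_record", "read_record", "write_latent_states", "read_latent_states",
    "write_ground_truth", "write_assays", "read_assays",
    "write_scenario", "read_scenario",
    "write_eval_table", "write_committee_manifest",
]


def write_record(record: CultivationRecord, directory,
                 seed: Optional[int] = None) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cols = {
        "time_h": record.times, "our": record.our, "cpr": record.cpr,
        "broth_kg": record.broth_weight, "feed_glucose": record.feed_glucose,
    }
    if record.feed_isoleucine is not None:
        cols["feed_isoleucine"] = record.feed_isoleucine
    pd.DataFrame(cols).to_csv(d / "record.csv", index=False)
    meta = {
        "experiment_id": record.experiment_id,
        "x0": float(record.x0), "s0": float(record.s0),
        "induction_time_h": None if record.induction_time is None
        else float(record.induction_time),
        "units": {"our": "g/L/h", "cpr": "g/L/h", "broth": "kg",
                  "feed": "g/h", "concentration": "g/L"},
    }
    if seed is not None:
        meta["seed"] = int(seed)
    (d / "meta.yaml").write_text(yaml.safe_dump(meta))
    return d / "record.csv"


def read_record(directory) -> CultivationRecord:
    d = Path(directory)
    df = pd.read_csv(d / "record.csv")
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    return CultivationRecord(
        experiment_id=meta["experiment_id"],
        times=df["time_h"].to_numpy(), our=df["our"].to_numpy(),
        cpr=df["cpr"].to_numpy(), broth_weight=df["broth_kg"].to_numpy(),
        feed_glucose=df["feed_glucose"].to_numpy(),
        feed_isoleucine=df["feed_isoleucine"].to_numpy()
        if "feed_isoleucine" in df else None,
        induction_time=meta.get("induction_time_h"),
        x0=meta["x0"], s0=meta["s0"])


def write_latent_states(latent: LatentStates, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "time_h": latent.times, "biomass": latent.biomass, "mu": latent.mu,
        "age": latent.age, "cage": latent.cage,
        "cum_biomass_time": latent.cum_biomass_time,
    }).to_csv(path, index=False)
    return path


def read_latent_states(path) -> LatentStates:
    df = pd.read_csv(path)
    return LatentStates(times=df["time_h"].to_numpy(),
                        biomass=df["biomass"].to_numpy(), mu=df["mu"].to_numpy(),
                        age=df["age"].to_numpy(), cage=df["cage"].to_numpy(),
                        cum_biomass_time=df["cum_biomass_time"].to_numpy())


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time_h": truth.times, "biomass": truth.biomass,
            "glucose": truth.glucose, "our_true": truth.our_true,
            "cpr_true": truth.cpr_true,
            "overflow": truth.overflow_active.astype(int)}
    for name, series in truth.solutes.items():
        cols[name] = series
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def write_assays(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time_h": truth.assay_times}
    for name, vals in truth.assays.items():
        cols[name] = vals
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def read_assays(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scenario(config: SimulationConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = dataclasses.asdict(config)
    d["solutes"] = {k: dataclasses.asdict(v) if isinstance(v, SoluteLaw) else v
                    for k, v in config.solutes.items()}
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def read_scenario(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["solutes"] = {k: SoluteLaw(**v) for k, v in (d.get("solutes") or {}).items()}
    return SimulationConfig(**d)


def write_eval_table(evals: Sequence[ModelEvaluation], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, e in enumerate(evals):
        rows.append({"group_id": i, "variables": "|".join(e.group),
                     "mae": e.mae, "rss": e.rss, "r2": e.r2, "rmse": e.rmse,
                     "n_trials": e.n_trials})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_committee_manifest(committee: Committee, path,
                             extra: Optional[dict] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "size": len(committee),
        "prob_source": committee.prob_source,
        "entropy_bits": float(committee.entropy),
        "members": [{"variables": list(m.group), "mae": float(m.mae),
                     "rmse": float(m.rmse),
                     "weight": float(w)}
                    for m, w in zip(committee.members, committee.weights)],
        "occurrence_probs": {k: float(v)
                             for k, v in committee.occurrence_probs.items()},
    }
    if extra:
        doc.update(extra)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
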