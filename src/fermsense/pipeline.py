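"""End-to-end campaign orchestration.

Runs the whole soft-sensor experiment on synthetic cultivations: simulate a
campaign, derive the latent physiological variables from the (noisy) OUR,
window the features at the offline assay instants, train one sensor per
enumerated input group (several trials each), filter and rank the groups,
and form the entropy-selected weighted committee.  The desk-scale profile
keeps the same structure at a size a single CPU handles in minutes: a pool
of 8 variables, group sizes 3-5, 3 trials and a 30-epoch training cap.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import ensemble as ens
from .ensemble import Committee, InputGroup, ModelEvaluation
from .errors import InvalidInputError
from .physiology import CultivationRecord, LatentStates, StrainParams, derive_all
from .sensor import (SensorConfig, TrainedSensor, WindowedDataset,
                     concat_windows, make_windows, predict, train_sensors)
from .simulate import GroundTruth, generate_campaign, make_site_scenario

logger = logging.getLogger(__name__)

__all__ = ["CampaignConfig", "CampaignResult", "feature_matrix",
           "build_campaign_windows", "run_campaign", "run_pipeline",
           "DESK_POOL"]

#: desk-scale variable pool (8 of the 12 available variables)
DESK_POOL = ("time", "our", "cpr", "broth_weight", "feed_glucose",
             "biomass", "mu", "age")


def feature_matrix(record: CultivationRecord, latent: LatentStates,
                   pool: Sequence[str]) -> np.ndarray:
    """Assemble the per-instant feature columns named in ``pool``."""
    n = len(record)
    cols = {
        "time": record.times,
        "our": record.our,
        "cpr": record.cpr,
        "broth_weight": record.broth_weight,
        "feed_glucose": record.feed_glucose,
        "feed_isoleucine": record.feed_isoleucine
        if record.feed_isoleucine is not None else np.zeros(n),
        "initial_glucose": np.full(n, record.s0),
        "induction_time": np.full(n, record.induction_time
                                  if record.induction_time is not None else -1.0),
        "biomass": latent.biomass,
        "mu": latent.mu,
        "age": latent.age,
        "cage": latent.cage,
    }
    missing = [v for v in pool if v not in cols]
    if missing:
        raise InvalidInputError(f"unknown feature(s) {missing}")
    return np.column_stack([cols[v] for v in pool])


@dataclass
class CampaignConfig:
    """Study conditions for one synthetic campaign experiment."""

    site: int = 1
    n_train_runs: int = 12
    n_val_runs: int = 5
    base_seed: int = 1
    pool: Tuple[str, ...] = DESK_POOL
    min_size: int = 3
    max_size: int = 5
    trials: int = 3
    solute: str = "acetate"
    mae_threshold: float = 0.5          # [g/L]
    max_committee: int = 14
    prob_source: str = "occurrence"
    noiseless: bool = False
    sensor: SensorConfig = field(default_factory=lambda: SensorConfig(
        max_epochs=30, batch_size=32))


@dataclass
class CampaignResult:
    evals: List[ModelEvaluation]                # every trained group
    survivors: List[ModelEvaluation]            # after both filters, ranked
    committee: Committee
    committee_mae_by_size: List[float]
    entropy_by_size: List[float]
    committee_mae: float
    committee_r2: float
    committee_nmae: float
    best_single_mae: float
    train_mean_mae: float                       # train-mean predictor baseline
    observations: np.ndarray                    # validation assay values
    committee_estimates: np.ndarray
    runtime_s: float
    # internal handles for artifact export
    _runs: list = field(default_factory=list, repr=False)
    _params: Optional[StrainParams] = field(default=None, repr=False)
    _ds_val: Optional[WindowedDataset] = field(default=None, repr=False)


def _subset(ds: WindowedDataset, variables: Sequence[str]) -> WindowedDataset:
    idx = [ds.feature_names.index(v) for v in variables]
    return WindowedDataset(X=ds.X[:, :, idx], y=ds.y,
                           feature_names=list(variables),
                           exp_ids=ds.exp_ids, end_times=ds.end_times)


def build_campaign_windows(runs: Sequence[Tuple[CultivationRecord, GroundTruth]],
                           pool: Sequence[str], solute: str,
                           window_steps: int, params: StrainParams,
                           padding: str = "edge") -> WindowedDataset:
    """Derive latents and window every run at its assay instants."""
    parts = []
    for rec, truth in runs:
        latent = derive_all(rec, params)
        feats = feature_matrix(rec, latent, pool)
        assay_idx = np.searchsorted(rec.times, truth.assay_times)
        target = np.zeros(len(rec))
        target[assay_idx] = truth.assays[solute]
        parts.append(make_windows(feats, target, window_steps,
                                  experiment_id=rec.experiment_id,
                                  times=rec.times, at_indices=assay_idx,
                                  feature_names=list(pool), padding=padding))
    return concat_windows(parts)


def run_campaign(config: CampaignConfig) -> CampaignResult:
    """Execute the full study on one synthetic campaign."""
    t_start = time.time()
    c = config
    scenario = make_site_scenario(c.site)
    params = StrainParams(alpha=scenario.alpha, beta=scenario.beta,
                          k_cX=scenario.k_cX, X_cX=scenario.X_cX)
    runs = generate_campaign(c.n_train_runs + c.n_val_runs, c.site,
                             c.base_seed, noiseless=c.noiseless)
    train_runs = runs[:c.n_train_runs]
    val_runs = runs[c.n_train_runs:]

    ws = c.sensor.window_steps
    ds_train = build_campaign_windows(train_runs, c.pool, c.solute, ws, params,
                                      c.sensor.padding)
    ds_val = build_campaign_windows(val_runs, c.pool, c.solute, ws, params,
                                    c.sensor.padding)
    obs = ds_val.y

    groups = ens.enumerate_input_groups(c.pool, c.min_size, c.max_size)
    seed_rng = np.random.default_rng(c.base_seed + 7)
    trial_seeds = seed_rng.integers(0, 2**31 - 1,
                                    size=(len(groups), c.trials))

    # train whole same-size group families (x trials) in stacked passes
    name_to_idx = {v: i for i, v in enumerate(c.pool)}
    by_size: Dict[int, List[Tuple[int, InputGroup]]] = {}
    for gi, group in enumerate(groups):
        by_size.setdefault(len(group), []).append((gi, group))
    trained_by_group: Dict[int, List[TrainedSensor]] = {}
    for size, glist in sorted(by_size.items()):
        configs, columns = [], []
        for gi, group in glist:
            cols = [name_to_idx[v] for v in group.variables]
            for tr in range(c.trials):
                configs.append(replace(c.sensor, seed=int(trial_seeds[gi, tr])))
                columns.append(cols)
        stack = train_sensors(ds_train, configs, columns=columns)
        for j, (gi, group) in enumerate(glist):
            trained_by_group[gi] = stack[j * c.trials:(j + 1) * c.trials]
        logger.info("trained %d groups of size %d", len(glist), size)

    evals: List[ModelEvaluation] = []
    for gi, group in enumerate(groups):
        sub_va = _subset(ds_val, group.variables)
        trial_maes, best = [], None
        for trained in trained_by_group[gi]:
            est = predict(trained, sub_va)
            m = ens.mae(est, obs)
            trial_maes.append(m)
            if best is None or m < best[0]:
                best = (m, trained, est)
        _, best_model, best_est = best
        rss_v = ens.rss(best_est, obs)
        evals.append(ModelEvaluation(
            group=group, mae=float(np.mean(trial_maes)), rss=rss_v,
            r2=ens.r2(best_est, obs),
            rmse=ens.rmse_from_rss(rss_v, obs.size),
            n_trials=c.trials, per_trial_mae=trial_maes, model=best_model))

    kept = ens.filter_by_mae(evals, c.mae_threshold)
    if not kept:          # keep the pipeline alive on a bad campaign
        kept = sorted(evals, key=lambda e: e.mae)[:c.max_committee]
    survivors = ens.subset_dominance_filter(kept)

    member_preds = {id(e): predict(e.model, _subset(ds_val, e.group.variables))
                    for e in survivors}
    max_size = min(c.max_committee, len(survivors))
    committee_mae_by_size, entropy_by_size = [], []
    for size in range(1, max_size + 1):
        head = survivors[:size]
        w = ens.ensemble_weights([m.rmse for m in head])
        est = ens.committee_predict([member_preds[id(m)] for m in head], w)
        committee_mae_by_size.append(ens.mae(est, obs))
        entropy_by_size.append(
            ens.shannon_entropy(ens.occurrence_probabilities(head).values()))

    explanation_kwargs = None
    if c.prob_source == "explanation":
        explanation_kwargs = {
            "datasets": [_subset(ds_val, e.group.variables) for e in survivors],
            "seed": c.base_seed}
    committee = ens.select_committee(survivors, max_size=max_size,
                                    prob_source=c.prob_source,
                                    explanation_kwargs=explanation_kwargs)
    est = ens.committee_predict(
        [member_preds[id(m)] for m in committee.members], committee.weights)

    train_mean = float(np.mean(ds_train.y))
    return CampaignResult(
        evals=evals, survivors=survivors, committee=committee,
        committee_mae_by_size=committee_mae_by_size,
        entropy_by_size=entropy_by_size,
        committee_mae=ens.mae(est, obs),
        committee_r2=ens.r2(est, obs),
        committee_nmae=ens.nmae(ens.mae(est, obs), obs),
        best_single_mae=committee_mae_by_size[0],
        train_mean_mae=ens.mae(np.full_like(obs, train_mean), obs),
        observations=obs, committee_estimates=est,
        runtime_s=time.time() - t_start,
        _runs=runs, _params=params, _ds_val=ds_val)


def run_pipeline(config: CampaignConfig, out_dir) -> dict:
    """Execute a campaign and write every artifact to ``out_dir``.

    Layout: ``runs/runNN/`` (record + ground truth + assays), ``latents/``,
    ``evals.csv`` (every trained group), ``survivors.csv``,
    ``committee.yaml``, ``sizes.csv`` (MAE and entropy per committee size),
    ``predictions.csv`` (validation observations vs committee estimates) and
    ``metrics.yaml`` / ``manifest.yaml``.  Returns the manifest dict.
    """
    import dataclasses
    from pathlib import Path

    import pandas as pd
    import yaml

    from . import io as fio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_campaign(config)

    for i, (rec, truth) in enumerate(result._runs):
        d = out / "runs" / f"run{i:02d}"
        fio.write_record(rec, d)
        fio.write_ground_truth(truth, d / "truth.csv")
        fio.write_assays(truth, d / "assays.csv")
        latent = derive_all(rec, result._params)
        fio.write_latent_states(latent, out / "latents" / f"run{i:02d}.csv")

    fio.write_eval_table(sorted(result.evals, key=lambda e: e.mae),
                         out / "evals.csv")
    fio.write_eval_table(result.survivors, out / "survivors.csv")
    fio.write_committee_manifest(result.committee, out / "committee.yaml")
    pd.DataFrame({"size": np.arange(1, len(result.committee_mae_by_size) + 1),
                  "mae": result.committee_mae_by_size,
                  "entropy_bits": result.entropy_by_size}
                 ).to_csv(out / "sizes.csv", index=False)
    pd.DataFrame({"experiment_id": result._ds_val.exp_ids,
                  "time_h": result._ds_val.end_times,
                  "observed": result.observations,
                  "committee_estimate": result.committee_estimates}
                 ).to_csv(out / "predictions.csv", index=False)
    metrics = {
        "solute": config.solute,
        "committee_mae_g_per_L": float(result.committee_mae),
        "committee_r2": float(result.committee_r2),
        "committee_nmae": float(result.committee_nmae),
        "committee_size": len(result.committee),
        "entropy_bits": float(result.committee.entropy),
        "best_single_mae_g_per_L": float(result.best_single_mae),
        "train_mean_mae_g_per_L": float(result.train_mean_mae),
        "improvement_vs_best_single_pct": float(
            100 * (1 - result.committee_mae / result.best_single_mae)),
        "n_groups_trained": len(result.evals),
        "n_groups_surviving": len(result.survivors),
    }
    (out / "metrics.yaml").write_text(yaml.safe_dump(metrics, sort_keys=False))
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["pool"] = list(config.pool)
    manifest = {
        "config": cfg_dict,
        "seed": config.base_seed,
        "runtime_s": float(result.runtime_s),
        "metrics": metrics,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
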