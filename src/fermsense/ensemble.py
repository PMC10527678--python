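"""Input-group enumeration, model evaluation, and committee formation.

The soft-sensor pipeline trains one recurrent estimator per *input group* —
a subset (size 3..11) of the available measured and derived variables —
then combines the best of them into a weighted committee:

* models are scored with MAE / RSS / R^2, and RMSE derived from the RSS;
* groups with MAE above a threshold (0.5 g/L by default) are excluded, and a
  group is also dropped when a proper subset of it achieved a lower MAE
  (the extra variables bought nothing);
* committee weights follow the RMSE-complement rule
  w_i = (sum_j RMSE_j - RMSE_i) / (sum_j RMSE_j * (n - 1)), which sums to 1
  and gives low-RMSE members larger weights;
* the committee size is chosen by Shannon entropy over per-variable
  occurrence probabilities p(x) = (members whose group contains x) / n —
  applied literally, without renormalizing across variables — the size with
  maximal H = -sum p log2 p wins, ties going to the smallest committee.

Occurrence probabilities can alternatively come from local surrogate
explanations: for each validation point a ridge regression is fitted to the
sensor's response to Gaussian perturbations of the window, the top-k
features by |coefficient| are collected, and counts are normalized by the
total number collected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import Ridge

from .errors import ContractError, InvalidInputError
from .sensor import TrainedSensor, WindowedDataset, _scale_windows, invert_scaler

logger = logging.getLogger(__name__)

__all__ = [
    "InputGroup", "ModelEvaluation", "Committee",
    "enumerate_input_groups", "mae", "rss", "r2", "rmse_from_rss", "nmae",
    "filter_by_mae", "subset_dominance_filter", "ensemble_weights",
    "committee_predict", "occurrence_probabilities", "shannon_entropy",
    "explanation_probabilities", "select_committee",
]

#: the full variable pool of measured and derived inputs
FULL_POOL = ("time", "our", "cpr", "broth_weight", "feed_glucose",
             "feed_isoleucine", "initial_glucose", "induction_time",
             "biomass", "mu", "age", "cage")


@dataclass(frozen=True)
class InputGroup:
    """An ordered, duplicate-free subset of the variable pool."""

    variables: Tuple[str, ...]

    def __post_init__(self):
        if len(set(self.variables)) != len(self.variables):
            raise InvalidInputError("duplicate variables in input group")

    def __len__(self):
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def is_proper_subset_of(self, other: "InputGroup") -> bool:
        return set(self.variables) < set(other.variables)


@dataclass
class ModelEvaluation:
    """Evaluation-set metrics for the sensors trained on one input group."""

    group: InputGroup
    mae: float
    rss: float
    r2: float
    rmse: float
    n_trials: int = 1
    per_trial_mae: List[float] = field(default_factory=list)
    model: Optional[TrainedSensor] = None   # best trial, retained for committees


@dataclass
class Committee:
    """Ranked member models with their weights and entropy diagnostics."""

    members: List[ModelEvaluation]
    weights: np.ndarray
    occurrence_probs: Dict[str, float]
    entropy: float
    prob_source: str = "occurrence"

    def __len__(self):
        return len(self.members)


# -------------------------------------------------------------- enumeration
def enumerate_input_groups(pool: Sequence[str], min_size: int = 3,
                           max_size: int = 11) -> List[InputGroup]:
    """All variable subsets with sizes in [min_size, max_size].

    Deterministic order: by size, then lexicographic in pool order.  The
    count is sum_k C(|pool|, k) over the admissible k.
    """
    if max_size < min_size:
        raise InvalidInputError("max_size must be >= min_size")
    if len(pool) < min_size:
        raise InvalidInputError("pool smaller than min_size")
    out = []
    for k in range(min_size, min(max_size, len(pool)) + 1):
        out.extend(InputGroup(c) for c in itertools.combinations(pool, k))
    return out


# ------------------------------------------------------------------ metrics
def _pair(est, obs):
    e = np.asarray(est, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if e.size == 0 or e.size != o.size:
        raise InvalidInputError("estimates/observations must be equal-length, non-empty")
    return e, o


def mae(est, obs) -> float:
    e, o = _pair(est, obs)
    return float(np.mean(np.abs(e - o)))


def rss(est, obs) -> float:
    e, o = _pair(est, obs)
    return float(np.sum((e - o) ** 2))


def r2(est, obs) -> float:
    e, o = _pair(est, obs)
    tss = float(np.sum((o - o.mean()) ** 2))
    if tss == 0:
        raise InvalidInputError("R^2 undefined: observations are constant (TSS = 0)")
    return 1.0 - rss(e, o) / tss


def rmse_from_rss(rss_value: float, n: int) -> float:
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    return float(np.sqrt(rss_value / n))


def nmae(mae_value: float, observations) -> float:
    """MAE normalized by the observed range of the target."""
    o = np.asarray(observations, dtype=float).ravel()
    rng = o.max() - o.min()
    if rng <= 0:
        raise InvalidInputError("nMAE undefined: constant observations")
    return float(mae_value / rng)


# ---------------------------------------------------------------- filtering
def filter_by_mae(evals: Sequence[ModelEvaluation],
                  threshold: float = 0.5) -> List[ModelEvaluation]:
    """Keep groups whose MAE does not exceed the threshold (boundary kept)."""
    if not evals:
        raise InvalidInputError("no evaluations to filter")
    out = [e for e in evals if e.mae <= threshold]
    if not out:
        logger.warning("filter_by_mae: no group at or below %.3g g/L", threshold)
    return out


def subset_dominance_filter(evals: Sequence[ModelEvaluation]) -> List[ModelEvaluation]:
    """Drop a group when a proper subset of it achieved a strictly lower MAE.

    Equal-MAE pairs are both kept.  The survivors are returned ordered by
    MAE ascending.
    """
    survivors = []
    for e in evals:
        dominated = any(
            other is not e
            and other.group.is_proper_subset_of(e.group)
            and other.mae < e.mae
            for other in evals)
        if not dominated:
            survivors.append(e)
    return sorted(survivors, key=lambda e: e.mae)


# ---------------------------------------------------------------- weighting
def ensemble_weights(rmses: Sequence[float]) -> np.ndarray:
    """RMSE-complement committee weights (sum to 1, anti-monotone in RMSE)."""
    r = np.asarray(rmses, dtype=float).ravel()
    if r.size == 0:
        raise InvalidInputError("no RMSE values")
    if r.size == 1:
        return np.ones(1)
    if np.any(r <= 0):
        raise InvalidInputError("RMSE values must be positive")
    total = r.sum()
    return (total - r) / (total * (r.size - 1))


def committee_predict(predictions: Sequence[np.ndarray],
                      weights: Sequence[float]) -> np.ndarray:
    """Pointwise weighted average of member predictions (weights pre-normalized)."""
    preds = [np.asarray(p, dtype=float).ravel() for p in predictions]
    w = np.asarray(weights, dtype=float).ravel()
    if len(preds) != w.size:
        raise ContractError("weights do not match member count")
    n = preds[0].size
    if any(p.size != n for p in preds):
        raise ContractError("member predictions are on different grids")
    return np.einsum("mn,m->n", np.vstack(preds), w)


# ------------------------------------------------------------------ entropy
def occurrence_probabilities(members: Sequence[ModelEvaluation],
                             normalized: bool = False) -> Dict[str, float]:
    """p(x) = fraction of committee members whose input group contains x.

    Computed literally per member count; the values do not form a normalized
    distribution across variables.  ``normalized=True`` rescales them to sum
    to one (a sensitivity-analysis variant, not the default behavior).
    """
    if not members:
        raise InvalidInputError("empty committee")
    counts: Dict[str, int] = {}
    for m in members:
        for v in m.group:
            counts[v] = counts.get(v, 0) + 1
    denom = sum(counts.values()) if normalized else len(members)
    return {v: c / denom for v, c in counts.items()}


def shannon_entropy(probs: Iterable[float]) -> float:
    """H = -sum p log2 p [bits], with 0 log 0 := 0."""
    p = np.asarray(list(probs), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def explanation_probabilities(members: Sequence[ModelEvaluation],
                              datasets: Sequence[WindowedDataset],
                              top_k: int = 20, n_samples: int = 200,
                              perturb_sd: float = 0.1,
                              seed: int = 0,
                              backend: str = "surrogate") -> Dict[str, float]:
    """Per-variable probabilities from local surrogate explanations.

    For every data point of every member, the member's response to Gaussian
    perturbations of the (scaled) window is fitted with a ridge surrogate;
    the ``top_k`` window-features by absolute coefficient are collected, each
    mapped to its source variable regardless of time lag, and counts are
    divided by the total number of collected features.  With
    ``backend="none"`` (explanations disabled) falls back to occurrence
    probabilities with a warning.
    """
    if backend == "none":
        logger.warning("explanation backend disabled; falling back to "
                       "occurrence probabilities")
        return occurrence_probabilities(members)
    rng = np.random.default_rng(seed)
    counts: Dict[str, int] = {}
    total = 0
    for m, ds in zip(members, datasets):
        trained = m.model
        if trained is None:
            raise ContractError("committee member carries no trained model")
        Xs = _scale_windows(ds.X, trained.x_scaler)
        n_w, T, F = Xs.shape
        k = min(top_k, T * F)
        for i in range(n_w):
            base = Xs[i].ravel()
            pert = base + perturb_sd * rng.standard_normal((n_samples, base.size))
            yh = trained.net.forward(pert.reshape(n_samples, T, F))
            coefs = Ridge(alpha=1.0).fit(pert, yh).coef_
            top = np.argsort(-np.abs(coefs))[:k]
            for slot in top:
                var = ds.feature_names[slot % F]
                counts[var] = counts.get(var, 0) + 1
            total += k
    return {v: c / total for v, c in counts.items()}


# ---------------------------------------------------------------- selection
def select_committee(ranked_evals: Sequence[ModelEvaluation],
                     max_size: int = 14,
                     prob_source: str = "occurrence",
                     explanation_kwargs: Optional[dict] = None
                     ) -> Committee:
    """Pick the committee size with maximal Shannon entropy.

    ``ranked_evals`` must be sorted by MAE ascending; nested committees of
    sizes 1..max_size are formed from the head of the ranking, the entropy of
    each is computed from its per-variable probabilities, and the maximal-
    entropy size wins (ties: smallest size).  Weights follow the RMSE rule.
    """
    if not ranked_evals:
        raise InvalidInputError("empty ranking")
    if any(a.mae > b.mae for a, b in zip(ranked_evals, ranked_evals[1:])):
        raise InvalidInputError("ranked_evals must be sorted by MAE ascending")
    max_size = min(max_size, len(ranked_evals))
    best_size, best_H = 1, -np.inf
    for size in range(1, max_size + 1):
        head = list(ranked_evals[:size])
        if prob_source == "occurrence":
            probs = occurrence_probabilities(head)
        elif prob_source == "explanation":
            kw = dict(explanation_kwargs or {})
            datasets = kw.pop("datasets")
            probs = explanation_probabilities(head, datasets[:size], **kw)
        else:
            raise InvalidInputError(f"unknown prob_source {prob_source!r}")
        H = shannon_entropy(probs.values())
        if H > best_H + 1e-12:
            best_size, best_H = size, H
            best_probs = probs
    members = list(ranked_evals[:best_size])
    weights = ensemble_weights([m.rmse for m in members])
    return Committee(members=members, weights=weights,
                     occurrence_probs=best_probs, entropy=best_H,
                     prob_source=prob_source)
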