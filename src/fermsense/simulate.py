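"""Synthetic fed-batch cultivation generator.

Stands in for proprietary cultivation data: a minimal mechanistic model that
produces the couplings a soft sensor exploits — Monod growth on glucose,
overflow metabolism (acetate is excreted while the specific glucose uptake
exceeds the culture's oxidative capacity and re-consumed once glucose becomes
limiting), an exponential feed after a batch phase, and off-gas signals tied
to biomass formation.

The oxygen uptake rate is emitted from the same strain model the physiology
module inverts, ``OUR = alpha * dx/dt + beta * (x - X_cX)`` (maintenance term
active once the cumulative biomass-time passes ``k_cX``), with dx/dt taken
from the ODE right-hand side.  Applying :func:`fermsense.physiology.
latent_biomass` with the simulator's own alpha/beta to a noiseless simulated
OUR therefore recovers the true biomass up to discretization error — the
self-consistency contract the whole pipeline rests on.

Two scenario families mirror the regimes of the two production sites the
sensor is meant for: short, densely sampled 20 h runs with feeding from
5–7 h (site 1), and long 66 h runs with feeding from 21 h, an isoleucine
co-feed and sparser offline assays (site 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidInputError, SimulationError
from .physiology import CultivationRecord

__all__ = [
    "SoluteLaw",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cultivation",
    "make_site_scenario",
    "generate_campaign",
]


@dataclass
class SoluteLaw:
    """First-order production/consumption law for a secondary solute.

    dP/dt = (k_mu * mu + k_ind * [t >= induction]) * X  - k_cons * p * X + feed
    (all per-volume; ``p`` is the solute concentration, X the biomass).
    """

    k_mu: float = 0.0     # growth-coupled production [g solute / g X]
    k_ind: float = 0.0    # induction-coupled production [g / g X / h]
    k_cons: float = 0.0   # biomass-specific consumption [L / g X / h]
    fed: bool = False     # receives the secondary feed stream


@dataclass
class SimulationConfig:
    """Scenario definition for one synthetic cultivation."""

    # horizon & grids [h]
    duration: float = 20.0
    sampling_interval: float = 0.05
    n_assay: int = 17                 # offline solute samples per run
    assay_start: float = 1.0

    # feed
    feed_start: float = 6.0
    feed_rate0: float = 2.5           # glucose feed at feed_start [g/h]
    feed_mu: float = 0.20             # exponential feed rate constant [1/h]
    feed_conc: float = 500.0          # feed solution strength [g glucose/kg]
    feed_iso_rate0: float = 0.0       # optional secondary feed [g/h]
    feed_iso_mu: float = 0.0

    # initial state
    x0: float = 0.2                   # inoculation biomass [g/L]
    s0: float = 15.0                  # initial glucose [g/L]
    broth0: float = 3.7               # initial broth weight [kg]

    # growth & overflow kinetics
    mu_max: float = 0.65              # [1/h]
    K_S: float = 0.05                 # Monod constant [g/L]
    Y_XS: float = 0.5                 # biomass yield on oxidized glucose [g/g]
    qS_crit: float = 0.75             # critical specific uptake [g/gX/h]
    Y_AS: float = 0.60                # acetate yield on overflow flux [g/g]
    qA_max: float = 0.25              # max specific acetate uptake [g/gX/h]
    K_A: float = 0.1                  # acetate uptake affinity [g/L]
    Y_XA: float = 0.35                # biomass yield on acetate [g/g]

    # off-gas model (shared with the physiology module)
    alpha: float = 1.0                # [g O2 / g X]
    beta: float = 0.03                # [g O2 / g X / h]
    k_cX: float = 5.0                 # maintenance onset threshold [g h/L]
    X_cX: float = 0.0
    rq0: float = 1.0                  # respiratory quotient at t=0 [mol/mol]
    rq_drift: float = 0.002           # RQ drift [1/h]

    # secondary solutes (acetate is built in)
    solutes: Dict[str, SoluteLaw] = field(default_factory=dict)

    # noise model: relative Gaussian sd per signal
    noise_our: float = 0.02
    noise_cpr: float = 0.02
    noise_broth: float = 0.002
    noise_assay: float = 0.02
    assay_floor: float = 0.01         # additive assay sd [g/L]

    induction_time: Optional[float] = 8.0
    temperature_profile: str = "37C"
    seed: int = 0

    # integrator
    rtol: float = 1e-8
    atol: float = 1e-10

    def validate(self) -> None:
        if not (self.duration > self.feed_start >= 0):
            raise InvalidInputError("require duration > feed_start >= 0")
        if self.sampling_interval <= 0:
            raise InvalidInputError("sampling_interval must be positive")
        for name in ("Y_XS", "Y_AS", "Y_XA", "qS_crit", "qA_max", "mu_max",
                     "K_S", "K_A", "alpha"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Noise-free state trajectories plus the (noisy) offline assay samples."""

    times: np.ndarray
    biomass: np.ndarray                    # [g/L]
    glucose: np.ndarray                    # [g/L]
    solutes: Dict[str, np.ndarray]         # concentration [g/L], incl. acetate
    our_true: np.ndarray                   # [g O2/L/h]
    cpr_true: np.ndarray                   # [g CO2/L/h]
    overflow_active: np.ndarray            # bool per instant
    assay_times: np.ndarray
    assays: Dict[str, np.ndarray]          # measured (noisy) assay values
    assays_true: Dict[str, np.ndarray]     # noise-free values at assay times
    fed_glucose_total: float               # [g]
    consumed_glucose_total: float = 0.0    # integrated uptake [g]
    residual_glucose_mass: float = 0.0     # S at the final instant [g]


def _feed_rate(t, start, rate0, k):
    t = np.asarray(t, dtype=float)
    r = np.where(t >= start, rate0 * np.exp(k * np.clip(t - start, 0, None)), 0.0)
    return r


def simulate_cultivation(config: SimulationConfig) -> Tuple[CultivationRecord, GroundTruth]:
    """Integrate the fed-batch model and package measured + true signals.

    Identical configs (including ``seed``) give bit-identical output; the
    seed only affects the observation-noise draws.
    """
    config.validate()
    c = config
    solute_names = list(c.solutes.keys())
    n_extra = len(solute_names)

    # state vector: [X, S, A, W, P_1..P_k, C_S] (masses in g, broth weight in
    # kg; C_S tracks cumulative glucose uptake for the mass-balance audit)
    def rates(t, y):
        X, S, A, W = y[0], y[1], y[2], y[3]
        V = max(W, 1e-9)               # broth density ~1 kg/L
        s = max(S, 0.0) / V
        a = max(A, 0.0) / V
        qS = c.mu_max / c.Y_XS * s / (c.K_S + s)
        qS_ox = min(qS, c.qS_crit)
        qS_over = qS - qS_ox
        qA_up = c.qA_max * a / (c.K_A + a) * max(0.0, 1.0 - qS / c.qS_crit) \
            if c.qS_crit > 0 else 0.0
        mu = c.Y_XS * qS_ox + c.Y_XA * qA_up
        F = float(_feed_rate(t, c.feed_start, c.feed_rate0, c.feed_mu))
        F_iso = float(_feed_rate(t, c.feed_start, c.feed_iso_rate0, c.feed_iso_mu))
        dX = mu * X
        dS = -qS * X + F
        dA = (c.Y_AS * qS_over - qA_up) * X
        dW = F / c.feed_conc + (F_iso / c.feed_conc if F_iso else 0.0)
        dP = []
        ind = 1.0 if (c.induction_time is not None and t >= c.induction_time) else 0.0
        for name in solute_names:
            law = c.solutes[name]
            p = max(y[4 + solute_names.index(name)], 0.0) / V
            prod = (law.k_mu * mu + law.k_ind * ind) * X
            cons = law.k_cons * p * X
            feed_in = F_iso if law.fed else 0.0
            dP.append(prod - cons + feed_in)
        return [dX, dS, dA, dW] + dP + [qS * X]

    y0 = [c.x0 * c.broth0, c.s0 * c.broth0, 0.0, c.broth0] + [0.0] * (n_extra + 1)
    grid = np.arange(0.0, c.duration + 1e-9, c.sampling_interval)
    if grid[-1] < c.duration - 1e-9:
        grid = np.append(grid, c.duration)

    # integrate in segments split at the feed discontinuity
    breakpoints = [0.0, c.duration]
    if 0.0 < c.feed_start < c.duration:
        breakpoints.insert(1, c.feed_start)
    ys = []
    ts = []
    y_start = y0
    for a0, b0 in zip(breakpoints[:-1], breakpoints[1:]):
        seg = grid[(grid >= a0 - 1e-12) & (grid <= b0 + 1e-12)]
        t_eval = np.unique(np.concatenate(([a0], seg, [b0])))
        sol = solve_ivp(rates, (a0, b0), y_start, method="RK45",
                        t_eval=t_eval, rtol=c.rtol, atol=c.atol)
        if not sol.success:
            raise SimulationError(f"ODE integration failed on [{a0}, {b0}]: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y)
        y_start = sol.y[:, -1]
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # restrict to the sampling grid (drop duplicated breakpoints)
    idx = np.searchsorted(t_all, grid)
    idx = np.clip(idx, 0, t_all.size - 1)
    Y = y_all[:, idx]
    t = grid

    W = Y[3]
    V = W                                  # 1 kg/L broth density
    x = np.clip(Y[0], 0, None) / V
    s_conc = np.clip(Y[1], 0, None) / V
    a_conc = np.clip(Y[2], 0, None) / V
    sol_conc = {"acetate": a_conc}
    for k, name in enumerate(solute_names):
        sol_conc[name] = np.clip(Y[4 + k], 0, None) / V

    # biomass-concentration derivative from the RHS (not finite differences)
    dxdt = np.empty_like(x)
    for i, ti in enumerate(t):
        d = rates(ti, Y[:, i])
        dxdt[i] = (d[0] - x[i] * d[3]) / V[i]

    # overflow indicator
    qS = c.mu_max / c.Y_XS * s_conc / (c.K_S + s_conc)
    overflow = qS > c.qS_crit

    # off-gas signals from the strain model shared with the physiology module
    dt = np.diff(t)
    cum_xt = np.concatenate(([0.0], np.cumsum(x[1:] * dt)))
    maint = cum_xt > c.k_cX
    # the switch rule evaluates history up to the previous instant
    maint = np.concatenate(([False], maint[:-1])) | maint
    our_true = np.clip(c.alpha * dxdt + np.where(maint, c.beta * (x - c.X_cX), 0.0), 0, None)
    rq = c.rq0 + c.rq_drift * t
    cpr_true = our_true * rq * (44.01 / 32.0)

    rng = np.random.default_rng(c.seed)
    our_meas = our_true * (1 + c.noise_our * rng.standard_normal(t.size))
    cpr_meas = cpr_true * (1 + c.noise_cpr * rng.standard_normal(t.size))
    broth_meas = W * (1 + c.noise_broth * rng.standard_normal(t.size))
    our_meas = np.clip(our_meas, 0, None)
    cpr_meas = np.clip(cpr_meas, 0, None)

    assay_times = np.linspace(c.assay_start, c.duration - 0.25 * c.sampling_interval,
                              c.n_assay)
    assay_idx = np.searchsorted(t, assay_times)
    assay_idx = np.clip(assay_idx, 0, t.size - 1)
    assay_times = t[assay_idx]
    assays_true = {name: conc[assay_idx] for name, conc in sol_conc.items()}
    assays = {}
    for name, vals in assays_true.items():
        noise = (c.noise_assay * vals + c.assay_floor) * rng.standard_normal(vals.size)
        assays[name] = np.clip(vals + noise, 0, None)

    feed_series = _feed_rate(t, c.feed_start, c.feed_rate0, c.feed_mu)
    iso_series = (_feed_rate(t, c.feed_start, c.feed_iso_rate0, c.feed_iso_mu)
                  if c.feed_iso_rate0 > 0 else None)
    fed_total = (c.feed_rate0 / c.feed_mu *
                 (np.exp(c.feed_mu * (c.duration - c.feed_start)) - 1.0)
                 if c.feed_rate0 > 0 and c.feed_mu > 0
                 else c.feed_rate0 * (c.duration - c.feed_start))

    record = CultivationRecord(
        experiment_id=f"sim-{c.temperature_profile}-{c.seed}",
        times=t, our=our_meas, cpr=cpr_meas, broth_weight=broth_meas,
        feed_glucose=feed_series, feed_isoleucine=iso_series,
        induction_time=c.induction_time, x0=c.x0, s0=c.s0)
    truth = GroundTruth(
        times=t, biomass=x, glucose=s_conc, solutes=sol_conc,
        our_true=our_true, cpr_true=cpr_true, overflow_active=overflow,
        assay_times=assay_times, assays=assays, assays_true=assays_true,
        fed_glucose_total=fed_total,
        consumed_glucose_total=float(Y[-1, -1]),
        residual_glucose_mass=float(Y[1, -1]))
    return record, truth


def make_site_scenario(site: int, seed: int = 0) -> SimulationConfig:
    """Default scenario for one of the two emulated production regimes.

    Site 1: <= 20 h runs, glucose-only feed from ~6 h, dense off-gas sampling,
    17 offline acetate assays per run.  Site 2: 66 h runs, feed from 21 h with
    an isoleucine co-feed, sparser assays (~18 per run) and a wider solute
    panel (lactate, glutamate, glutamine, isoleucine).
    """
    if site == 1:
        return SimulationConfig(seed=seed)
    if site == 2:
        return SimulationConfig(
            duration=66.0, sampling_interval=0.1, n_assay=18, assay_start=2.0,
            feed_start=21.0, feed_rate0=1.2, feed_mu=0.06,
            feed_iso_rate0=0.05, feed_iso_mu=0.02,
            x0=0.15, s0=18.0, broth0=9.0,
            mu_max=0.35, qS_crit=0.55, induction_time=24.0,
            temperature_profile="28C",
            solutes={
                "lactate": SoluteLaw(k_mu=0.004, k_cons=0.002),
                "glutamate": SoluteLaw(k_mu=0.01, k_ind=0.001, k_cons=0.004),
                "glutamine": SoluteLaw(k_ind=0.002, k_cons=0.006),
                "isoleucine": SoluteLaw(k_cons=0.01, fed=True),
            },
            seed=seed)
    raise InvalidInputError(f"unknown site id {site!r} (expected 1 or 2)")


def generate_campaign(n_runs: int, site: int, base_seed: int,
                      perturb_scale: float = 0.05,
                      noiseless: bool = False
                      ) -> list[Tuple[CultivationRecord, GroundTruth]]:
    """Simulate a campaign of runs with seeded run-to-run variability.

    Kinetic parameters, inoculum, feed magnitude and (site 1) feeding start
    are jittered per run; ``perturb_scale`` is the relative sd of the
    log-normal jitters (0 makes runs identical up to observation noise).
    Deterministic given ``base_seed``.
    """
    if n_runs < 1:
        raise InvalidInputError("n_runs must be >= 1")
    master = np.random.default_rng(base_seed)
    out = []
    for r in range(n_runs):
        cfg = make_site_scenario(site)
        jitter = lambda v: float(v * np.exp(perturb_scale * master.standard_normal()))
        cfg = replace(
            cfg,
            mu_max=jitter(cfg.mu_max), qS_crit=jitter(cfg.qS_crit),
            Y_XS=jitter(cfg.Y_XS), feed_rate0=jitter(cfg.feed_rate0),
            x0=jitter(cfg.x0), s0=jitter(cfg.s0),
            seed=int(master.integers(0, 2**31 - 1)))
        if site == 1 and perturb_scale > 0:
            cfg = replace(cfg, feed_start=float(master.uniform(5.0, 7.0)))
        if noiseless:
            cfg = replace(cfg, noise_our=0.0, noise_cpr=0.0, noise_broth=0.0,
                          noise_assay=0.0, assay_floor=0.0)
        rec, truth = simulate_cultivation(cfg)
        rec.experiment_id = f"site{site}-run{r:02d}"
        out.append((rec, truth))
    return out
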