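"""Particle-filter parameter estimation (data assimilation).

Parameters are estimated by sequential Monte Carlo over *static*
parameters: at every step the particle cloud is weighted by the data
likelihood, systematically resampled, and perturbed with a log-normal
multiplicative kernel whose width anneals geometrically from
``kernel_width_start`` (20% of a log-unit) to ``kernel_width_end`` (2%)
across the steps.  Priors are log-uniform within per-parameter bounds.

The observation density is Gaussian on the fitting scale (the data
normalization chain of :func:`egfrda.scoring.prepare_for_fitting`),
with a global standard deviation ``sigma`` (default 0.1).  The overall
likelihood of a parameter set is the geometric mean of the per-protein
likelihoods, each of which is the product over time points of the
Gaussian residual densities.  A failed simulation scores likelihood 0.

The two-stage scheme mirrors the global/local optimization split: stage
one varies all free parameters jointly within a narrow range (x3 around
the initial values); stage two re-estimates each parameter separately
within a broad range (x100) while co-sampling the other parameters from
the stage-one ensemble.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .egfr_model import OBSERVED_PROTEINS, PROTEIN_OBSERVABLE, ConfigurationError
from .network import ParameterSet, ReactionNetwork
from .scoring import WT, ScoreError, TimeCourseTable, rmse
from .simulate import IntegrationError, StimulusSpec, observable_timecourse, simulate

log = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class EstimationError(RuntimeError):
    pass


@dataclass
class ObservationModel:
    """Maps data proteins to network observables and defines the Gaussian
    observation noise.

    ``wt_reference`` maps protein -> WT-model fitting denominator
    (value at 5 min minus value at 0 after stimulation).  When None the
    simulated series is self-referenced (appropriate when fitting WT
    data, where the data normalization makes the WT 5-min value 1 by
    construction); a fixed reference is required when fitting mutant
    data, which shares the WT anchor.
    """

    protein_observables: dict = field(
        default_factory=lambda: dict(PROTEIN_OBSERVABLE))
    sigma: float = 0.1
    sigma_per_protein: dict = field(default_factory=dict)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    wt_reference: dict = None
    anchor_time: float = 5.0
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self):
        if self.sigma <= 0 or any(s <= 0 for s in self.sigma_per_protein.values()):
            raise ValueError("observation sigma must be > 0")

    def protein_sigma(self, protein):
        return self.sigma_per_protein.get(protein, self.sigma)


@dataclass
class EstimationConfig:
    n_particles: int = 1000
    n_steps: int = 60
    free_parameters: list = None  # None -> all WT-optimized parameters
    bounds: dict = None  # parameter id -> (low, high); None -> factor around init
    init: ParameterSet = None  # None -> network defaults
    narrow_factor: float = 3.0
    broad_factor: float = 100.0
    kernel_width_start: float = 0.20
    kernel_width_end: float = 0.02
    n_processes: int = 10
    n_sweeps: int = 2  # per-parameter refinement sweeps in derive_mutant_ensemble
    mutant_prior_sd: float = 1.5  # log-units; WT-centered prior in the derivation
    seed: int = 0

    def validated(self, network: ReactionNetwork):
        cfg = replace(self)
        if cfg.init is None:
            cfg.init = network.default_parameters()
        if cfg.free_parameters is None:
            cfg.free_parameters = network.parameter_subset(wt_optimized=True)
        unknown = set(cfg.free_parameters) - set(network.parameters)
        if unknown:
            raise ConfigurationError(f"free parameters not in network: {sorted(unknown)}")
        if cfg.bounds:
            for pid, (lo, hi) in cfg.bounds.items():
                if not (0 < lo < hi):
                    raise ConfigurationError(f"bad bounds for {pid}: ({lo}, {hi})")
        return cfg

    def bounds_for(self, pid, factor=None):
        if self.bounds and pid in self.bounds:
            return self.bounds[pid]
        f = factor if factor is not None else self.narrow_factor
        c = self.init[pid]
        c = c if c > 0 else 1e-6  # zero-abundance center: nominal floor
        return (c / f, c * f)


@dataclass
class ParticleEnsemble:
    """A weighted collection of full parameter vectors."""

    parameter_ids: list
    particles: np.ndarray  # n x d, natural scale
    weights: np.ndarray
    seed: int = 0
    n_steps: int = 0
    free_parameters: list = field(default_factory=list)
    best_particle: ParameterSet = None
    best_loglik: float = -math.inf
    best_loglik_history: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("ensemble weights must sum to 1")
        if (self.weights < 0).any():
            raise ValueError("negative ensemble weight")

    @property
    def n_particles(self):
        return self.particles.shape[0]

    def parameter_set(self, i) -> ParameterSet:
        return ParameterSet(zip(self.parameter_ids, self.particles[i]))

    def column(self, pid) -> np.ndarray:
        return self.particles[:, self.parameter_ids.index(pid)]

    def mean(self) -> ParameterSet:
        m = self.weights @ self.particles
        return ParameterSet(zip(self.parameter_ids, m))

    def equal_weight_resample(self, n=None, seed=0) -> "ParticleEnsemble":
        n = n or self.n_particles
        rng = np.random.default_rng(seed)
        idx = _systematic_resample(self.weights, n, rng)
        return ParticleEnsemble(
            list(self.parameter_ids), self.particles[idx].copy(),
            np.full(n, 1.0 / n), self.seed, self.n_steps,
            list(self.free_parameters), self.best_particle, self.best_loglik,
            list(self.best_loglik_history),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.particles, columns=self.parameter_ids)
        df.insert(0, "weight", self.weights)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "ParticleEnsemble":
        w = df["weight"].to_numpy(dtype=float)
        p = df.drop(columns=["weight"])
        return cls(list(p.columns), p.to_numpy(dtype=float), w / w.sum(), **meta)


# ---------------------------------------------------------------- likelihood


def _sim_observables(network, params, times, obs: ObservationModel, proteins):
    res = simulate(network, params, times, obs.stimulus,
                   rtol=obs.rtol, atol=obs.atol, with_observables=False)
    out = {}
    for p in proteins:
        out[p] = observable_timecourse(res, network.observables[obs.protein_observables[p]])
    return out


def fitting_reference(network, wt_params, obs: ObservationModel,
                      proteins=None) -> dict:
    """Per-protein fitting denominator (5-min minus 0-min observable value)
    of the WT-parameterized model; used to put mutant simulations on the
    WT-anchored data scale."""
    proteins = proteins or list(obs.protein_observables)
    times = np.array([0.0, obs.anchor_time])
    sims = _sim_observables(network, wt_params, times, obs, proteins)
    return {p: s[-1] - s[0] for p, s in sims.items()}


def _fitting_transform(series, reference):
    shifted = series - series[0]
    if reference is None:  # self-referenced (WT fit)
        return shifted, shifted
    return shifted / reference, None


@dataclass
class LikelihoodResult:
    overall: float
    log_overall: float
    per_protein: dict  # protein -> likelihood
    log_per_protein: dict
    #: unpenalized data log-likelihood when ``log_overall`` carries a prior
    log_data: float = None


def make_loglik(network, data: TimeCourseTable, obs: ObservationModel,
                condition=WT):
    """Build a fast callable ParameterSet -> LikelihoodResult for repeated
    evaluation inside the particle filter."""
    times = data.times
    if times[0] != 0:
        raise ScoreError("fitting data grid must start at 0")
    anchor_ix = int(np.where(times == obs.anchor_time)[0][0])
    proteins, observed, masks = [], {}, {}
    for p in obs.protein_observables:
        if data.has(p, condition):
            v = data.series(p, condition)
            m = ~np.isnan(v)
            if m.any():
                proteins.append(p)
                observed[p] = v
                masks[p] = m
    if not proteins:
        raise ScoreError("no data points overlap the observation model")

    def loglik(params: ParameterSet) -> LikelihoodResult:
        try:
            sims = _sim_observables(network, params, times, obs, proteins)
        except (IntegrationError, FloatingPointError, ValueError) as e:
            log.debug("simulation failure scored as likelihood 0: %s", e)
            return LikelihoodResult(0.0, -math.inf, {}, {})
        logs = {}
        for p in proteins:
            ref = None if obs.wt_reference is None else obs.wt_reference.get(p)
            if ref is not None and ref <= 0:
                return LikelihoodResult(0.0, -math.inf, {}, {})
            series, self_ref = _fitting_transform(sims[p], ref)
            if self_ref is not None:
                denom = self_ref[anchor_ix]
                if denom <= 0 or not np.isfinite(denom):
                    return LikelihoodResult(0.0, -math.inf, {}, {})
                series = self_ref / denom
            if not np.all(np.isfinite(series)):
                return LikelihoodResult(0.0, -math.inf, {}, {})
            r = series[masks[p]] - observed[p][masks[p]]
            s = obs.protein_sigma(p)
            logs[p] = float(-0.5 * np.sum((r / s) ** 2)
                            - r.size * (_LOG_SQRT_2PI + math.log(s)))
        log_overall = sum(logs.values()) / len(logs)
        return LikelihoodResult(math.exp(log_overall), log_overall,
                                {p: math.exp(v) for p, v in logs.items()}, logs)

    return loglik


def likelihood(params: ParameterSet, network, data: TimeCourseTable,
               obs: ObservationModel, condition=WT) -> LikelihoodResult:
    """Data likelihood of one parameter set: geometric mean over proteins of
    the per-protein products of Gaussian residual densities."""
    return make_loglik(network, data, obs, condition)(params)


def simulated_fitting_series(network, params, data, obs: ObservationModel) -> dict:
    """Simulated observables on the fitting scale, aligned to the data grid
    (for RMSE reporting)."""
    times = data.times
    anchor_ix = int(np.where(times == obs.anchor_time)[0][0])
    sims = _sim_observables(network, params, times, obs,
                            list(obs.protein_observables))
    out = {}
    for p, s in sims.items():
        ref = None if obs.wt_reference is None else obs.wt_reference.get(p)
        series, self_ref = _fitting_transform(s, ref)
        if self_ref is not None:
            series = self_ref / self_ref[anchor_ix]
        out[p] = series
    return out


# ------------------------------------------------------------ filter internals


def _systematic_resample(weights, n, rng):
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, len(weights) - 1)


def _kernel_widths(cfg):
    if cfg.n_steps == 1:
        return np.array([cfg.kernel_width_start])
    return np.geomspace(cfg.kernel_width_start, cfg.kernel_width_end, cfg.n_steps)


def _pf_core(loglik_fn, ids, init_particles, free_ix, lo, hi, cfg, rng,
             perturb_first=True):
    """Weight/resample/perturb iteration in log-parameter space.

    ``init_particles``: n x d natural-scale matrix; only columns ``free_ix``
    are perturbed (clipped to [lo, hi] log-bounds).
    """
    n = init_particles.shape[0]
    x = np.log(np.maximum(init_particles, 1e-300))
    widths = _kernel_widths(cfg)
    best_ll, best_x = -math.inf, None
    history = []
    weights = np.full(n, 1.0 / n)
    for step in range(cfg.n_steps):
        if perturb_first or step > 0:
            x[:, free_ix] += rng.normal(0.0, widths[step], (n, len(free_ix)))
            x[:, free_ix] = np.clip(x[:, free_ix], lo, hi)
        ll = np.empty(n)
        score = np.empty(n)  # best-particle metric: data likelihood if distinct
        for i in range(n):
            res = loglik_fn(ParameterSet(zip(ids, np.exp(x[i]))))
            ll[i] = res.log_overall
            score[i] = res.log_data if res.log_data is not None else res.log_overall
        i_best = int(np.argmax(score))
        if score[i_best] > best_ll:
            best_ll, best_x = score[i_best], x[i_best].copy()
        history.append(best_ll)
        finite = np.isfinite(ll)
        if not finite.any():
            raise EstimationError(
                "all particle weights are zero; widen sigma or the parameter bounds")
        w = np.where(finite, np.exp(ll - ll[finite].max()), 0.0)
        weights = w / w.sum()
        idx = _systematic_resample(weights, n, rng)
        x_weighted, w_final = x.copy(), weights.copy()
        x = x[idx]
    return (np.exp(x_weighted), w_final, np.exp(best_x), best_ll, history)


def _init_particles(cfg, ids, free, factor, rng):
    """Prior draw: log-uniform within bounds for free parameters, init values
    elsewhere."""
    init_vec = np.array([cfg.init[p] for p in ids])
    particles = np.tile(init_vec, (cfg.n_particles, 1))
    free_ix = [ids.index(p) for p in free]
    lo = np.empty(len(free_ix))
    hi = np.empty(len(free_ix))
    for j, p in enumerate(free):
        b = cfg.bounds_for(p, factor)
        lo[j], hi[j] = math.log(b[0]), math.log(b[1])
        particles[:, free_ix[j]] = np.exp(rng.uniform(lo[j], hi[j], cfg.n_particles))
    return particles, free_ix, lo, hi


def run_particle_filter(network, data, obs: ObservationModel,
                        config: EstimationConfig, condition=WT,
                        loglik_fn=None, init_particles=None,
                        range_factor=None, perturb_first=False) -> ParticleEnsemble:
    """Estimate the free parameters by iterated weighting / systematic
    resampling / annealed log-normal perturbation; reproducible from
    ``config.seed``."""
    cfg = config.validated(network)
    rng = np.random.default_rng(cfg.seed)
    ids = list(network.parameters)
    if loglik_fn is None:
        loglik_fn = make_loglik(network, data, obs, condition)
    prior, free_ix, lo, hi = _init_particles(cfg, ids, cfg.free_parameters,
                                             range_factor, rng)
    if init_particles is not None:
        prior = init_particles
    particles, weights, best, best_ll, hist = _pf_core(
        loglik_fn, ids, prior, free_ix, lo, hi, cfg, rng,
        perturb_first=perturb_first)
    return ParticleEnsemble(
        ids, particles, weights, seed=cfg.seed, n_steps=cfg.n_steps,
        free_parameters=list(cfg.free_parameters),
        best_particle=ParameterSet(zip(ids, best)),
        best_loglik=best_ll, best_loglik_history=hist,
    )


def _local_refinement(loglik_fn, ids, cfg, base: ParticleEnsemble, centers,
                      start_best, start_best_ll, start_history):
    """Stage two: re-estimate each free parameter separately within the
    broad range around ``centers``, co-sampling the remaining parameters
    from the stage-one ensemble; merge the per-parameter marginals."""
    merged = base.particles.copy()
    best, best_ll = start_best, start_best_ll
    history = list(start_history)
    for j, pid in enumerate(cfg.free_parameters):
        sub_rng = np.random.default_rng(cfg.seed + 1000 + j)
        # sequential sweep: co-sample from the progressively refined ensemble
        init = merged.copy()
        if cfg.bounds and pid in cfg.bounds:
            b = cfg.bounds[pid]
        else:
            c = max(centers[pid], 1e-6)
            b = (c / cfg.broad_factor, c * cfg.broad_factor)
        lo = np.array([math.log(b[0])])
        hi = np.array([math.log(b[1])])
        col = ids.index(pid)
        init[:, col] = np.exp(sub_rng.uniform(lo[0], hi[0], cfg.n_particles))
        particles, weights, b_x, b_ll, hist = _pf_core(
            loglik_fn, ids, init, [col], lo, hi, cfg, sub_rng)
        # the history tracks the running best across the whole scheme
        running = best_ll
        for h in hist:
            running = max(running, h)
            history.append(running)
        idx = _systematic_resample(weights, cfg.n_particles, sub_rng)
        merged[:, col] = particles[idx, col]
        if b_ll > best_ll:
            best_ll = b_ll
            best = ParameterSet(zip(ids, b_x))
    return ParticleEnsemble(
        ids, merged, np.full(cfg.n_particles, 1.0 / cfg.n_particles),
        seed=cfg.seed, n_steps=cfg.n_steps,
        free_parameters=list(cfg.free_parameters),
        best_particle=best, best_loglik=best_ll, best_loglik_history=history,
    )


def two_stage_estimate(network, data, obs: ObservationModel,
                       config: EstimationConfig, condition=WT) -> ParticleEnsemble:
    """Global (narrow-range, all free parameters) then local (broad-range,
    one parameter at a time, others co-sampled from the global ensemble)
    estimation; returns the merged ensemble."""
    cfg = config.validated(network)
    stage1 = run_particle_filter(network, data, obs, cfg, condition,
                                 range_factor=cfg.narrow_factor)
    ids = list(network.parameters)
    loglik_fn = make_loglik(network, data, obs, condition)
    base = stage1.equal_weight_resample(cfg.n_particles, seed=cfg.seed + 1)
    return _local_refinement(loglik_fn, ids, cfg, base, cfg.init,
                             stage1.best_particle, stage1.best_loglik,
                             stage1.best_loglik_history)


def derive_mutant_ensemble(wt_ensemble: ParticleEnsemble, network,
                           mutant_data, obs: ObservationModel,
                           config: EstimationConfig,
                           condition="Y992F") -> ParticleEnsemble:
    """Estimate the mutant ensemble on the basis of the WT ensemble: the
    free parameters (default: the mutant-variable subset) are re-estimated
    against the mutant data with the same global(narrow)/local(broad)
    two-stage scheme, while every other parameter stays pinned, per
    particle, to values sampled from the WT ensemble.  Simulated mutant
    observables are put on the data scale with a fixed WT-model reference
    (the WT best particle)."""
    cfg = replace(config)
    if cfg.free_parameters is None:
        cfg.free_parameters = network.parameter_subset(mutant_variable=True)
    cfg = cfg.validated(network)
    ids = list(network.parameters)
    base = wt_ensemble.equal_weight_resample(cfg.n_particles, seed=cfg.seed + 7)
    if list(base.parameter_ids) != ids:
        raise ConfigurationError("WT ensemble does not match the network parameters")
    if obs.wt_reference is None:
        obs = replace(obs, wt_reference=fitting_reference(
            network, wt_ensemble.best_particle or wt_ensemble.mean(), obs))
    loglik_fn = make_loglik(network, mutant_data, obs, condition)
    if not cfg.free_parameters:
        ll = np.array([loglik_fn(base.parameter_set(i)).log_overall
                       for i in range(base.n_particles)])
        w = np.exp(ll - ll[np.isfinite(ll)].max())
        w = np.where(np.isfinite(ll), w, 0.0)
        i_best = int(np.argmax(ll))
        return ParticleEnsemble(ids, base.particles, w / w.sum(),
                                seed=cfg.seed, n_steps=0,
                                free_parameters=[],
                                best_particle=base.parameter_set(i_best),
                                best_loglik=float(ll[i_best]),
                                best_loglik_history=[float(ll[i_best])])
    wt_mean = wt_ensemble.mean()
    # a log-normal prior centered on the WT values regularizes the free
    # parameters: weakly identified ones shrink to WT instead of wandering
    # the broad range, while the data easily pays the prior cost of the
    # large genuine shifts
    if cfg.mutant_prior_sd and cfg.mutant_prior_sd > 0:
        free_set = list(cfg.free_parameters)
        wt_log = {p: math.log(max(wt_mean[p], 1e-12)) for p in free_set}
        inv2v = 1.0 / (2.0 * cfg.mutant_prior_sd ** 2)
        data_loglik = loglik_fn

        def loglik_fn(params, _fn=data_loglik):
            res = _fn(params)
            if not math.isfinite(res.log_overall):
                return res
            pen = sum((math.log(max(params[p], 1e-300)) - wt_log[p]) ** 2
                      for p in free_set) * inv2v
            # posterior score weights the particles; the unpenalized data
            # likelihood still selects the reported best particle
            return LikelihoodResult(math.exp(res.log_overall - pen),
                                    res.log_overall - pen,
                                    res.per_protein, res.log_per_protein,
                                    log_data=res.log_overall)

    # free columns start at their WT draws; each sweep refines one free
    # parameter at a time within the broad range (conditional 1-D fits),
    # which avoids the compensated modes a joint narrow search falls into
    ens = base
    best, best_ll, history = None, -math.inf, []
    for sweep in range(max(1, cfg.n_sweeps)):
        sweep_cfg = replace(cfg, seed=cfg.seed + 5000 * sweep)
        ens = _local_refinement(loglik_fn, ids, sweep_cfg, ens, wt_mean,
                                best, best_ll, history)
        best, best_ll = ens.best_particle, ens.best_loglik
        history = ens.best_loglik_history
    return ens


# --------------------------------------------------------- constrained presets

PRESET_EXPECTED_SIZE = {"type1": 54, "type2": 40, "type3": 49, "type4": 35,
                        "abundance_only": 12}


def preset_free_parameters(network, preset: str) -> list:
    """Free-parameter subsets of the constrained re-estimation experiments,
    drawn from the mutant-variable partition by group tag."""
    mut = network.parameter_subset(mutant_variable=True)
    if preset == "type1":
        out = mut
    elif preset == "type2":
        out = [p for p in mut if network.parameters[p].group != "dephosphorylation"]
    elif preset == "type3":
        out = [p for p in mut if network.parameters[p].group != "phosphorylation"]
    elif preset == "type4":
        out = [p for p in mut if network.parameters[p].group not in
               ("phosphorylation", "dephosphorylation")]
    elif preset == "abundance_only":
        out = [p for p in mut if network.parameters[p].group == "abundance"]
    else:
        raise ConfigurationError(f"unknown preset {preset!r}")
    if len(mut) == 54 and len(out) != PRESET_EXPECTED_SIZE[preset]:
        raise ConfigurationError(
            f"preset {preset}: {len(out)} parameters, expected "
            f"{PRESET_EXPECTED_SIZE[preset]} on the default network")
    return out


@dataclass
class ConstrainedResult:
    preset: str
    best_particle: ParameterSet
    best_loglik: float
    best_rmse: float
    ensemble: ParticleEnsemble
    process_logliks: list = field(default_factory=list)
    process_rmses: list = field(default_factory=list)


def constrained_estimation(preset: str, network, wt_reference: ParameterSet,
                           mutant_data, obs: ObservationModel,
                           config: EstimationConfig,
                           condition="Y992F") -> ConstrainedResult:
    """Re-estimate the mutant model with a constrained free subset, all
    other parameters pinned at WT values, over ``config.n_processes``
    independent seeded processes; reports the best particle found."""
    free = preset_free_parameters(network, preset)
    cfg = replace(config, free_parameters=free, init=wt_reference.copy())
    if preset == "abundance_only":
        cfg.bounds = {p: (0.1 * wt_reference[p], 10.0 * wt_reference[p])
                      for p in free}
    cfg = cfg.validated(network)
    if obs.wt_reference is None:
        obs = replace(obs, wt_reference=fitting_reference(network, wt_reference, obs))
    best = None
    process_ll, process_rmse = [], []
    ids = list(network.parameters)
    # every process starts from the WT model (free parameters at their WT
    # values) and lets the annealed kernel walk them within the bounds
    start = np.tile(np.array([cfg.init[p] for p in ids]), (cfg.n_particles, 1))
    for k in range(cfg.n_processes):
        run_cfg = replace(cfg, seed=cfg.seed + k)
        ens = run_particle_filter(network, mutant_data, obs, run_cfg, condition,
                                  init_particles=start.copy(),
                                  range_factor=cfg.broad_factor,
                                  perturb_first=True)
        sim = simulated_fitting_series(network, ens.best_particle, mutant_data, obs)
        r = rmse(sim, mutant_data, condition)
        process_ll.append(ens.best_loglik)
        process_rmse.append(r)
        if best is None or ens.best_loglik > best.best_loglik:
            best = ens
            best_rmse = r
    return ConstrainedResult(preset, best.best_particle, best.best_loglik,
                             best_rmse, best, process_ll, process_rmse)
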