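"""Multistart Nelder-Mead estimation and the four-stage hierarchical scheme.

Estimation is simulation-based: a candidate parameter vector is scored by
simulating trials, classifying them into the observed CDF/CAF cells of each
observation it must explain, and summing the -2 log binomial deviances. The
simulation seed is fixed for the duration of one optimization run (common
random numbers), so the simplex sees a deterministic objective surface.

The hierarchy has four stages, each a multistart Nelder-Mead fit:

1. population — one vector fit against every observation's cells at once
   (per-observation deviances summed, not pooled);
2. condition deltas — zero-centered deviations around the population vector,
   one per condition, fit to that condition's observations;
3. participant deltas — likewise per participant, across conditions;
4. observation noise deltas — around population + condition + participant,
   one per participant-by-condition observation.

Sums population + deltas are kept inside [0, STAGE_UPPER] by clipping the
simulated candidate and adding a quadratic penalty on the excursion
(Nelder-Mead itself is unconstrained).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from . import ssp_core
from .params import (
    CONDITIONS,
    DELTA_SDS,
    N_PARAMS,
    SIMULATION_FLOOR,
    STAGE_LOWER,
    STAGE_UPPER,
    START_LOWER,
    START_MEANS,
    START_SDS,
    START_UPPER,
    SimulationConfig,
    SSPParameters,
)
from .summaries import goodness_of_fit, summarize_by_type

__all__ = [
    "StartDistribution",
    "FitProfile",
    "PROFILES",
    "FitResult",
    "HierarchicalEstimates",
    "draw_starts",
    "population_start_distribution",
    "delta_start_distribution",
    "fit_dataset",
    "fit_population",
    "fit_condition_deltas",
    "fit_participant_deltas",
    "fit_observation_noise",
    "fit_hierarchical",
    "compose_within_transformed",
    "observation_fit_statistics",
]


@dataclass(frozen=True)
class StartDistribution:
    """Truncated-normal start-value distribution, one marginal per parameter."""

    means: np.ndarray
    sds: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_starts: int = 100

    def __post_init__(self):
        for name in ("means", "sds", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lower > self.upper):
            raise ValueError("lower bounds must not exceed upper bounds")
        if np.any(self.sds <= 0):
            raise ValueError("start SDs must be strictly positive")


def population_start_distribution(n_starts: int = 100) -> StartDistribution:
    return StartDistribution(START_MEANS, START_SDS, START_LOWER, START_UPPER, n_starts)


def delta_start_distribution(base: np.ndarray, n_starts: int = 100) -> StartDistribution:
    """Zero-mean deviation starts with bounds keeping base + delta in stage bounds."""
    base = np.asarray(base, dtype=float)
    return StartDistribution(
        np.zeros(N_PARAMS), DELTA_SDS, STAGE_LOWER - base, STAGE_UPPER - base, n_starts
    )


def draw_starts(dist: StartDistribution, rng: np.random.Generator) -> np.ndarray:
    """``(n_starts, 6)`` start vectors, marginally truncated-normal in bounds.

    Rejection sampling (bounds sit within a few SD, so acceptance is high);
    falls back to inverse-CDF truncated-normal draws for extreme intervals.
    Collapsed bounds yield that point.
    """
    n = dist.n_starts
    out = np.empty((n, N_PARAMS))
    for j in range(N_PARAMS):
        lo, hi, mu, sd = dist.lower[j], dist.upper[j], dist.means[j], dist.sds[j]
        if hi == lo:
            out[:, j] = lo
            continue
        col = np.empty(n)
        filled = 0
        for _ in range(1000):
            need = n - filled
            draw = mu + sd * rng.standard_normal(need * 2 + 8)
            ok = draw[(draw >= lo) & (draw <= hi)]
            take = min(ok.size, need)
            col[filled : filled + take] = ok[:take]
            filled += take
            if filled == n:
                break
        if filled < n:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            col[filled:] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n - filled, random_state=rng)
        out[:, j] = col
    return out


@dataclass(frozen=True)
class FitProfile:
    """Compute scale of one optimization run.

    ``n_sim`` is the simulated trial count per trial type per objective
    evaluation; the original procedure used 12,500 per type with 100 starts.

    The binned objective is piecewise constant, so a single Nelder-Mead run
    stalls: each start is instead optimized by a chain of NM runs, every run
    re-seeded with a fresh simplex whose edge lengths (in start-SD units)
    follow ``explore_sizes`` / ``polish_sizes``, keeping the best point found.

    When ``n_polish > 0`` the multistart runs in two phases: every start is
    explored with a cheaper objective (``explore_n_sim`` simulated trials,
    ``explore_maxiter`` iterations per NM run), the explore optima are
    re-ranked under the full-size objective, and the ``n_polish`` best are
    re-optimized at full ``n_sim``/``maxiter``. Exploration and polish each
    use one fixed simulation seed (common random numbers), so the whole run
    is deterministic given the input generator.
    """

    n_starts: int = 100
    n_sim: int = 12500
    maxiter: int = 500
    explore_n_sim: int | None = None  # defaults to n_sim (single phase)
    explore_maxiter: int | None = None  # defaults to maxiter
    n_polish: int = 0
    explore_sizes: tuple = (1.0, 0.3)
    polish_sizes: tuple = (0.5, 0.2, 0.1)
    select_n_sim: int | None = None  # high-precision candidate selection; defaults to 4 * n_sim
    final_sizes: tuple = (0.15, 0.08)  # last descent at select_n_sim precision
    final_maxiter: int = 0  # 0 disables the final descent
    xatol: float = 1e-3  # simplex tolerance in start-SD units
    fatol: float = 1.0  # deviance units
    penalty_weight: float = 1e4

    def with_(self, **kwargs) -> "FitProfile":
        return replace(self, **kwargs)

    @property
    def explore_sim(self) -> int:
        return self.n_sim if self.explore_n_sim is None else self.explore_n_sim

    @property
    def explore_iters(self) -> int:
        return self.maxiter if self.explore_maxiter is None else self.explore_maxiter


PROFILES = {
    "paper": FitProfile(n_starts=100, n_sim=12500, maxiter=500, explore_sizes=(1.0, 0.3, 0.1)),
    "desk": FitProfile(
        n_starts=10,
        n_sim=12500,
        maxiter=200,
        explore_n_sim=4000,
        explore_maxiter=120,
        n_polish=1,
        polish_sizes=(0.4, 0.15),
        final_sizes=(0.1,),
        final_maxiter=80,
    ),
}


@dataclass
class FitResult:
    """Outcome of one multistart run (absolute vector or deviation vector)."""

    parameters: np.ndarray  # composed absolute vector, clipped to stage bounds
    delta: np.ndarray  # the optimized candidate itself (0-based for delta stages)
    objective: float
    n_starts_run: int
    best_start_index: int
    converged: bool
    start_objectives: np.ndarray
    fit_stats: object = None

    def as_parameters(self) -> SSPParameters:
        return SSPParameters.from_array(np.maximum(self.parameters, SIMULATION_FLOOR))


# Internal optimizer coordinates. The deviance surface forms a narrow valley
# curved along near-constant sd_a0 / r_d (the spotlight convergence time);
# log coordinates u0 = log sd_a0, u1 = log(sd_a0 / r_d) straighten it so the
# simplex can track the valley floor. Remaining parameters are linearly
# scaled by the start SDs.
_U_SCALE_SD = 0.5  # log-units per u0 step
_U_SCALE_RATIO = 0.3  # log-units per u1 step
_SD_FLOOR = 1e-4
_RD_FLOOR = 1e-6


def _to_internal(v: np.ndarray, scale: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    u = v / scale
    sd = max(v[0], _SD_FLOOR)
    rd = max(v[1], _RD_FLOOR)
    u[0] = np.log(sd) / _U_SCALE_SD
    u[1] = np.log(sd / rd) / _U_SCALE_RATIO
    return u


def _from_internal(u: np.ndarray, scale: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    v = u * scale
    sd = np.exp(_U_SCALE_SD * u[0])
    v[0] = sd
    v[1] = sd / np.exp(_U_SCALE_RATIO * u[1])
    return v


class _GroupObjective:
    """Summed deviance of one candidate against several observed summaries.

    Operates in the internal log coordinates above; the candidate is the
    COMPOSED (absolute) parameter vector. One simulated dataset per candidate
    (common random numbers via a fixed seed) is classified into every group's
    cells; out-of-bound candidates are simulated at the clipped point and
    penalized quadratically.
    """

    def __init__(self, group_summaries, sim_config, profile, sim_seed, scale):
        self.groups = list(group_summaries)
        self.sim_config = sim_config
        self.profile = profile
        self.sim_seed = int(sim_seed)
        self.scale = np.asarray(scale, dtype=float)
        # Candidate-independent pieces: binomial coefficients and bin edges.
        self._cells = []  # (trial_type, cdf_inner_edges, caf_inner_edges, counts, n_trials, log_coef)
        for summaries in self.groups:
            for tt, s in summaries.items():
                k, n_tr = s.cell_counts, s.n_trials
                coef = float((gammaln(n_tr + 1) - gammaln(k + 1) - gammaln(n_tr - k + 1)).sum())
                self._cells.append((tt, s.cdf_edges[:-1], s.caf_edges[:-1], k, n_tr, coef))

    def __call__(self, u: np.ndarray) -> float:
        comp = _from_internal(u, self.scale)
        clipped = np.clip(comp, STAGE_LOWER, STAGE_UPPER)
        penalty = self.profile.penalty_weight * float(
            (((comp - clipped) / self.scale) ** 2).sum()
        )
        params = SSPParameters.from_array(np.maximum(clipped, SIMULATION_FLOOR))
        rng = np.random.default_rng(self.sim_seed)
        sim = {}
        for tt in ("congruent", "incongruent"):
            rt, acc, responded = ssp_core._simulate_type_arrays(
                params, tt, self.profile.n_sim, self.sim_config, rng
            )
            rt, acc = rt[responded], acc[responded]
            if rt.size == 0:
                return 1e12 + penalty
            # Sorted correct/error RTs: every group's cell counts then come
            # from binary searches on the shared simulated sample.
            sim[tt] = (np.sort(rt[acc == 1]), np.sort(rt[acc == 0]), rt.size)
        total = penalty
        for tt, cdf_edges, caf_edges, k, n_tr, coef in self._cells:
            corr, err, n_sim = sim[tt]
            cdf_cum = np.searchsorted(corr, cdf_edges, side="right")
            caf_cum = np.searchsorted(err, caf_edges, side="right")
            counts = np.concatenate(
                [np.diff(cdf_cum, prepend=0), [corr.size - cdf_cum[-1]],
                 np.diff(caf_cum, prepend=0), [err.size - caf_cum[-1]]]
            )
            pi = np.maximum(counts / n_sim, 1.0 / (10.0 * n_sim))
            pi = pi / pi.sum()
            total += -2.0 * (
                coef + float((k * np.log(pi) + (n_tr - k) * np.log1p(-pi)).sum())
            )
        return total


def _chained_nelder_mead(objective, z0, sizes, maxiter, xatol, fatol):
    """Chain of NM runs with fresh, shrinking initial simplexes.

    Keeps the best point seen; each run restarts from it with simplex edge
    length ``sizes[k]`` (scaled units). Returns (fun, z, converged)."""
    z = np.asarray(z0, dtype=float)
    fun = float(objective(z))
    conv = False
    if maxiter == 0:
        return fun, z, conv
    n = z.size
    for size in sizes:
        simplex = np.vstack([z, z + size * np.eye(n)])
        res = optimize.minimize(
            objective,
            z,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol, "initial_simplex": simplex},
        )
        if float(res.fun) < fun:
            fun, z, conv = float(res.fun), res.x, bool(res.success)
    return fun, z, conv


def _fit_multistart(
    group_summaries,
    base,
    start_dist: StartDistribution,
    sim_config: SimulationConfig,
    profile: FitProfile,
    rng: np.random.Generator,
    starts: np.ndarray | None = None,
) -> FitResult:
    base = np.asarray(base, dtype=float)
    if starts is None:
        # The start-distribution mean always joins the drawn starts: for
        # deviation stages it is the zero deviation (the natural null), so
        # the selected optimum can never lose to the stage's own base.
        starts = np.vstack([start_dist.means, draw_starts(start_dist, rng)])
    else:
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
    explore_seed = int(rng.integers(2**31 - 1))
    polish_seed = int(rng.integers(2**31 - 1))
    scale = np.asarray(start_dist.sds, dtype=float)

    explore_profile = profile.with_(n_sim=profile.explore_sim)
    explore_obj = _GroupObjective(group_summaries, sim_config, explore_profile, explore_seed, scale)

    results = []  # (fun, u, start_index, converged)
    for i, start in enumerate(starts):
        fun, u, conv = _chained_nelder_mead(
            explore_obj,
            _to_internal(base + start, scale),
            profile.explore_sizes,
            profile.explore_iters,
            profile.xatol,
            profile.fatol,
        )
        results.append((fun, u, i, conv))
    start_objs = np.array([r[0] for r in results])
    results.sort(key=lambda r: r[0])

    if profile.n_polish > 0 and profile.maxiter > 0:
        polish_obj = _GroupObjective(group_summaries, sim_config, profile, polish_seed, scale)
        select_profile = profile.with_(
            n_sim=profile.select_n_sim if profile.select_n_sim is not None else 4 * profile.n_sim
        )
        select_obj = _GroupObjective(group_summaries, sim_config, select_profile, polish_seed, scale)
        # Re-rank the explore optima under a high-precision objective: the
        # cheap explore surface is too noisy to pick polish candidates (or,
        # later, the winner) reliably.
        reranked = sorted(
            ((select_obj(u), u, i, conv) for _, u, i, conv in results), key=lambda r: r[0]
        )
        candidates = reranked[: profile.n_polish]
        # Width scan: the surface is shallow along log-width (narrow-vs-wide
        # spotlight regimes can nearly mimic each other), so explore chains
        # stall at regime-dependent points. Scanning spotlight width on the
        # low-noise surface — holding the best candidate's ratio and
        # nuisance parameters — anchors the true regime in the candidate set.
        u_best = candidates[0][1]
        w_best = None
        for w in np.geomspace(0.15, 5.0, 8):
            u_w = u_best.copy()
            u_w[0] = np.log(w) / _U_SCALE_SD
            f_w = select_obj(u_w)
            if w_best is None or f_w < w_best[0]:
                w_best = (f_w, u_w)
        candidates.append((w_best[0], w_best[1], -1, False))
        polished = []
        for fun, u, i, _ in candidates:
            pfun, pu, pconv = _chained_nelder_mead(
                polish_obj, u, profile.polish_sizes, profile.maxiter, profile.xatol, profile.fatol
            )
            polished.append((select_obj(pu), pu, i, pconv))
        polished.sort(key=lambda r: r[0])
        fun, u, idx, conv = polished[0]
        if profile.final_maxiter > 0:
            # Short descent at high precision: near the optimum the deviance
            # differences sink below the polish objective's noise floor, so
            # the last leg runs on the low-noise surface.
            ffun, fu, fconv = _chained_nelder_mead(
                select_obj, u, profile.final_sizes, profile.final_maxiter, profile.xatol, profile.fatol
            )
            if ffun < fun:
                fun, u, conv = ffun, fu, fconv
    else:
        fun, u, idx, conv = results[0]

    cand = _from_internal(u, scale) - base
    composed = np.clip(base + cand, STAGE_LOWER, STAGE_UPPER)
    return FitResult(
        parameters=composed,
        delta=cand,
        objective=fun,
        n_starts_run=len(starts),
        best_start_index=idx,
        converged=conv,
        start_objectives=start_objs,
    )


def _observation_groups(trials: pd.DataFrame):
    """Per participant-by-condition observed summaries, with keys."""
    keys, groups = [], []
    for (participant, condition), sub in trials.groupby(["participant", "condition"], sort=True):
        keys.append((participant, condition))
        groups.append(summarize_by_type(sub))
    return keys, groups


def fit_dataset(
    trials: pd.DataFrame,
    start_dist: StartDistribution | None = None,
    base: np.ndarray | None = None,
    sim_config: SimulationConfig | None = None,
    profile: FitProfile = PROFILES["desk"],
    rng: np.random.Generator | None = None,
    starts: np.ndarray | None = None,
) -> FitResult:
    """Fit one trial set (both trial types) with multistart Nelder-Mead.

    With ``base`` given, the optimized vector is a deviation around it;
    otherwise an absolute parameter vector starting from the published
    population start distribution. Explicit ``starts`` override the drawn
    start set (useful for reproducible superset comparisons).
    """
    rng = np.random.default_rng() if rng is None else rng
    sim_config = sim_config or SimulationConfig()
    if base is None:
        base = np.zeros(N_PARAMS)
        start_dist = start_dist or population_start_distribution(profile.n_starts)
    else:
        start_dist = start_dist or delta_start_distribution(base, profile.n_starts)
    summaries = summarize_by_type(trials)
    return _fit_multistart([summaries], base, start_dist, sim_config, profile, rng, starts=starts)


def fit_population(
    trials: pd.DataFrame,
    sim_config: SimulationConfig | None = None,
    profile: FitProfile = PROFILES["desk"],
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Stage 1: one absolute vector against all observations' cells."""
    rng = np.random.default_rng() if rng is None else rng
    sim_config = sim_config or SimulationConfig()
    _, groups = _observation_groups(trials)
    start_dist = population_start_distribution(profile.n_starts)
    return _fit_multistart(groups, np.zeros(N_PARAMS), start_dist, sim_config, profile, rng)


def _fit_delta_stage(trials_by_key, population, sim_config, profile, rng):
    # Deviation stages score candidates against each observation's own cells
    # (deviances summed). Pooling the entity's trials into one summary would
    # mix participants' RT distributions and inflate the apparent nondecision
    # variability, which in turn blurs the spotlight-width information.
    out = {}
    for key, sub in trials_by_key:
        _, groups = _observation_groups(sub)
        start_dist = delta_start_distribution(population, profile.n_starts)
        out[key] = _fit_multistart(groups, population, start_dist, sim_config, profile, rng)
    return out


def fit_condition_deltas(
    trials: pd.DataFrame,
    population: np.ndarray,
    sim_config: SimulationConfig | None = None,
    profile: FitProfile = PROFILES["desk"],
    rng: np.random.Generator | None = None,
) -> dict:
    """Stage 2: zero-centered deviations around the population per condition."""
    rng = np.random.default_rng() if rng is None else rng
    sim_config = sim_config or SimulationConfig()
    items = [(c, trials[trials["condition"] == c]) for c in _ordered_levels(trials, "condition")]
    return _fit_delta_stage(items, population, sim_config, profile, rng)


def fit_participant_deltas(
    trials: pd.DataFrame,
    population: np.ndarray,
    sim_config: SimulationConfig | None = None,
    profile: FitProfile = PROFILES["desk"],
    rng: np.random.Generator | None = None,
) -> dict:
    """Stage 3: deviations around the population per participant (all conditions)."""
    rng = np.random.default_rng() if rng is None else rng
    sim_config = sim_config or SimulationConfig()
    items = [(p, trials[trials["participant"] == p]) for p in _ordered_levels(trials, "participant")]
    return _fit_delta_stage(items, population, sim_config, profile, rng)


def fit_observation_noise(
    trials: pd.DataFrame,
    population: np.ndarray,
    condition_deltas: dict,
    participant_deltas: dict,
    sim_config: SimulationConfig | None = None,
    profile: FitProfile = PROFILES["desk"],
    rng: np.random.Generator | None = None,
) -> dict:
    """Stage 4: per-observation noise deltas around pop + cond + participant."""
    rng = np.random.default_rng() if rng is None else rng
    sim_config = sim_config or SimulationConfig()
    out = {}

    def _delta(x):
        return x.delta if hasattr(x, "delta") else np.asarray(x, dtype=float)

    for (participant, condition), sub in trials.groupby(["participant", "condition"], sort=True):
        base = population + _delta(condition_deltas[condition]) + _delta(participant_deltas[participant])
        summaries = summarize_by_type(sub)
        start_dist = delta_start_distribution(base, profile.n_starts)
        out[(participant, condition)] = _fit_multistart(
            [summaries], base, start_dist, sim_config, profile, rng
        )
    return out


def _ordered_levels(trials: pd.DataFrame, column: str):
    levels = list(pd.unique(trials[column]))
    if column == "condition":
        return [c for c in CONDITIONS if c in levels] + [c for c in levels if c not in CONDITIONS]
    return sorted(levels)


@dataclass
class HierarchicalEstimates:
    """Population vector plus condition/participant/noise deviations."""

    population: np.ndarray
    condition_deltas: dict  # condition -> delta vector
    participant_deltas: dict  # participant -> delta vector
    noise_deltas: dict | None = None  # (participant, condition) -> delta vector

    def within_transformed(self) -> pd.DataFrame:
        """Population + condition + participant sums per observation (untruncated)."""
        return compose_within_transformed(
            self.population, self.condition_deltas, self.participant_deltas
        )

    def observation_values(self) -> pd.DataFrame:
        """Full sums incl. noise deltas, clipped to the stage bounds."""
        if self.noise_deltas is None:
            raise ValueError("noise deltas have not been fit")
        rows = []
        for (participant, condition), dn in self.noise_deltas.items():
            vec = (
                self.population
                + self.condition_deltas[condition]
                + self.participant_deltas[participant]
                + dn
            )
            vec = np.clip(vec, STAGE_LOWER, STAGE_UPPER)
            rows.append({"participant": participant, "condition": condition, **_param_dict(vec)})
        return pd.DataFrame(rows)


def _param_dict(vec: np.ndarray) -> dict:
    from .params import PARAM_NAMES

    return dict(zip(PARAM_NAMES, np.asarray(vec, dtype=float)))


def compose_within_transformed(
    population: np.ndarray, condition_deltas: dict, participant_deltas: dict
) -> pd.DataFrame:
    """Per participant-by-condition sums population + dcond + dparticipant.

    These sums are deliberately not truncated: they can stray outside the
    parameter bounds, which suits linear-model analyses assuming unbounded
    normal variation.
    """
    rows = []
    for participant in sorted(participant_deltas):
        for condition in condition_deltas:
            vec = population + condition_deltas[condition] + participant_deltas[participant]
            rows.append({"participant": participant, "condition": condition, **_param_dict(vec)})
    return pd.DataFrame(rows)


def fit_hierarchical(
    trials: pd.DataFrame,
    sim_config: SimulationConfig | None = None,
    profile: FitProfile = PROFILES["desk"],
    rng: np.random.Generator | None = None,
    include_noise_stage: bool = True,
    noise_profile: FitProfile | None = None,
) -> tuple[HierarchicalEstimates, dict]:
    """Run stages 1-4 and return estimates plus per-stage fit results.

    The observation-noise stage refines an already composed base, so by
    default it runs with a reduced start count (at most 4) and one polish.
    """
    rng = np.random.default_rng() if rng is None else rng
    sim_config = sim_config or SimulationConfig()
    pop_fit = fit_population(trials, sim_config, profile, rng)
    pop = pop_fit.parameters
    cond_fits = fit_condition_deltas(trials, pop, sim_config, profile, rng)
    part_fits = fit_participant_deltas(trials, pop, sim_config, profile, rng)
    noise_fits = None
    noise_deltas = None
    if include_noise_stage:
        if noise_profile is None:
            # The noise stage refines an already composed base, so it runs
            # with few starts and no final descent.
            noise_profile = profile.with_(
                n_starts=min(4, profile.n_starts),
                n_polish=min(profile.n_polish, 1),
                final_maxiter=0,
            )
        noise_fits = fit_observation_noise(trials, pop, cond_fits, part_fits, sim_config, noise_profile, rng)
        noise_deltas = {k: v.delta for k, v in noise_fits.items()}
    estimates = HierarchicalEstimates(
        population=pop,
        condition_deltas={k: v.delta for k, v in cond_fits.items()},
        participant_deltas={k: v.delta for k, v in part_fits.items()},
        noise_deltas=noise_deltas,
    )
    results = {"population": pop_fit, "condition": cond_fits, "participant": part_fits}
    if noise_fits is not None:
        results["noise"] = noise_fits
    return estimates, results


def observation_fit_statistics(
    trials: pd.DataFrame,
    observation_values: pd.DataFrame,
    sim_config: SimulationConfig | None = None,
    n_sim: int = 2500,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Goodness of fit per observation at its estimated parameter vector.

    Simulates ``n_sim`` trials per trial type at each observation's estimate
    and scores chi-square, acceptability and RMSEA against that observation's
    observed cells. Aggregate RMSEA pools chi-square and df across rows.
    """
    from .params import PARAM_NAMES

    rng = np.random.default_rng() if rng is None else rng
    sim_config = sim_config or SimulationConfig()
    rows = []
    for _, est in observation_values.iterrows():
        sub = trials[
            (trials["participant"] == est["participant"])
            & (trials["condition"] == est["condition"])
        ]
        vec = np.array([est[p] for p in PARAM_NAMES], dtype=float)
        params = SSPParameters.from_array(np.maximum(vec, SIMULATION_FLOOR))
        sim = ssp_core.simulate_dataset(params, n_sim, n_sim, sim_config, rng)
        summaries = summarize_by_type(sub)
        fs = goodness_of_fit(summaries, sim)
        rows.append(
            {
                "participant": est["participant"],
                "condition": est["condition"],
                "neg2_loglik": fs.neg2_loglik,
                "chi_square": fs.chi_square,
                "df": fs.df,
                "acceptable": fs.acceptable,
                "rmsea": fs.rmsea,
                "n_trials": int(sub["rt_ms"].notna().sum() if "rt_ms" in sub else len(sub)),
            }
        )
    return pd.DataFrame(rows)
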