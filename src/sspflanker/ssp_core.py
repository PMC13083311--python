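"""Shrinking-spotlight generative model and trial-level flanker simulation.

The spotlight is a zero-mean Gaussian over the five-arrow array whose SD
narrows linearly in time. Item activations are the Gaussian mass over each
item's unit-width window; they always sum to one. On congruent trials every
item pushes toward the correct response, so drift equals the perceptual gain
``P`` at all times; on incongruent trials the four flankers push the other
way, so drift is ``P * (2 * a_target - 1)``, negative early when the
spotlight is wide and converging to ``+P`` as it narrows.

Evidence follows ``X_t = X_{t-1} + v(t) dt + sigma sqrt(dt) Z``, absorbed at
``+boundary`` (correct) or ``-boundary`` (error). Response time adds a
truncated-normal nondecision component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import ndtr

from .params import SimulationConfig, SSPParameters, WIDTH_FLOOR

__all__ = [
    "spotlight_width",
    "activations",
    "drift",
    "drift_timecourse",
    "draw_nondecision",
    "simulate_trial",
    "simulate_dataset",
]


def spotlight_width(t, sd_a0: float, r_d: float, floor: float = WIDTH_FLOOR):
    """Spotlight SD at time ``t`` (ms): ``max(sd_a0 - r_d * t, floor)``.

    Non-increasing in ``t`` and equal to ``sd_a0`` at ``t = 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if sd_a0 <= 0:
        raise ValueError("sd_a0 must be strictly positive")
    if r_d < 0:
        raise ValueError("r_d must be non-negative")
    width = np.maximum(sd_a0 - r_d * t, floor)
    return width if width.ndim else float(width)


def activations(sd):
    """Five item activations at spotlight width ``sd``.

    Returns ``[outer_left, inner_left, target, inner_right, outer_right]``:
    the normal(0, sd) mass over (-inf,-1.5], (-1.5,-0.5], (-0.5,0.5],
    (0.5,1.5], (1.5,inf). The five values sum to 1 and are mirror-symmetric.
    """
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be strictly positive")
    phi_half = ndtr(0.5 / sd)
    phi_three_half = ndtr(1.5 / sd)
    target = 2.0 * phi_half - 1.0
    inner = phi_three_half - phi_half
    outer = 1.0 - phi_three_half
    return np.stack([outer, inner, target, inner, outer], axis=-1)


def _target_activation(sd):
    sd = np.asarray(sd, dtype=float)
    return 2.0 * ndtr(0.5 / sd) - 1.0


def drift(sd, congruency: str, p_input: float):
    """Mean drift (evidence/ms) at spotlight width ``sd``.

    Congruent: all five activations share the target's sign, so
    ``v = P * sum(a) = P`` exactly. Incongruent: the flankers' sign flips,
    ``v = P * (2 * a_target - 1)``.
    """
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be strictly positive")
    if p_input <= 0:
        raise ValueError("p_input must be strictly positive")
    if congruency == "congruent":
        v = np.broadcast_to(np.asarray(p_input, dtype=float), sd.shape).copy()
    elif congruency == "incongruent":
        v = p_input * (2.0 * _target_activation(sd) - 1.0)
    else:
        raise ValueError(f"unknown congruency label: {congruency!r}")
    return v if v.ndim else float(v)


def drift_timecourse(params: SSPParameters, congruency: str, config: SimulationConfig) -> np.ndarray:
    """Per-step mean evidence increments ``v(t_k) * dt`` for the simulator.

    Step ``k`` (producing X at time ``(k+1) dt``) uses the spotlight width at
    the end of the step, matching the discrete recursion
    ``sd_a(t) = sd_a(t-1) - r_d``.
    """
    n = config.n_steps
    t = (np.arange(1, n + 1)) * config.dt
    sd = np.maximum(params.sd_a0 - params.r_d * t, config.width_floor)
    return drift(sd, congruency, params.p_input) * config.dt


@njit(cache=True)
def _simulate_decisions(increments, sigma_step, boundary, n_trials, rng):
    """First-passage of the stepwise diffusion; 0 decision step = censored."""
    n_steps = increments.shape[0]
    steps = np.zeros(n_trials, np.int64)
    acc = np.zeros(n_trials, np.int8)
    for i in range(n_trials):
        x = 0.0
        for t in range(n_steps):
            x += increments[t] + sigma_step * rng.standard_normal()
            if x >= boundary:
                steps[i] = t + 1
                acc[i] = 1
                break
            elif x <= -boundary:
                steps[i] = t + 1
                break
    return steps, acc


def draw_nondecision(n: int, ndt_mean: float, ndt_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Nondecision times (ms): normal(ndt_mean, ndt_sd) truncated at 0.

    Drawn as ``mean + sd * z`` with rejection of non-positive values, so the
    distributional family is swappable behind this one function.
    """
    if ndt_sd == 0.0:
        return np.full(n, float(ndt_mean))
    out = ndt_mean + ndt_sd * rng.standard_normal(n)
    bad = out <= 0.0
    # Truncation essentially never binds at realistic parameters.
    while np.any(bad):
        out[bad] = ndt_mean + ndt_sd * rng.standard_normal(int(bad.sum()))
        bad = out <= 0.0
    return out


def _simulate_type_arrays(
    params: SSPParameters,
    congruency: str,
    n_trials: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (rt_ms, accuracy, responded) arrays; the fast path for fitting."""
    increments = drift_timecourse(params, congruency, config)
    sigma_step = config.sigma * np.sqrt(config.dt)
    steps, acc = _simulate_decisions(increments, sigma_step, params.boundary, n_trials, rng)
    responded = steps > 0
    decision_ms = steps.astype(float) * config.dt
    ndt = draw_nondecision(n_trials, params.ndt_mean, params.ndt_sd, rng)
    rt = np.where(responded, decision_ms + ndt, np.nan)
    return rt, acc.astype(int), responded


def _simulate_type(
    params: SSPParameters,
    congruency: str,
    n_trials: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rt, acc, responded = _simulate_type_arrays(params, congruency, n_trials, config, rng)
    return pd.DataFrame(
        {
            "congruency": congruency,
            "rt_ms": rt,
            "accuracy": np.where(responded, acc, -1),
            "responded": responded,
        }
    )


def simulate_trial(
    params: SSPParameters,
    congruency: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[float, int, bool]:
    """One trial; returns ``(rt_ms, accuracy, responded)``.

    ``rt_ms`` is NaN and ``accuracy`` -1 when no boundary is crossed before
    the censoring horizon.
    """
    row = _simulate_type(params, congruency, 1, config, rng).iloc[0]
    return float(row.rt_ms), int(row.accuracy), bool(row.responded)


def simulate_dataset(
    params: SSPParameters,
    n_congruent: int,
    n_incongruent: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a trial set; columns congruency, rt_ms, accuracy, responded.

    Exactly ``n_congruent + n_incongruent`` rows (censored trials included,
    flagged ``responded=False``). Reproducible given the generator state.
    """
    if n_congruent < 0 or n_incongruent < 0:
        raise ValueError("trial counts must be non-negative")
    parts = []
    if n_congruent:
        parts.append(_simulate_type(params, "congruent", n_congruent, config, rng))
    if n_incongruent:
        parts.append(_simulate_type(params, "incongruent", n_incongruent, config, rng))
    if not parts:
        return pd.DataFrame(
            {
                "congruency": pd.Series(dtype=str),
                "rt_ms": pd.Series(dtype=float),
                "accuracy": pd.Series(dtype=int),
                "responded": pd.Series(dtype=bool),
            }
        )
    return pd.concat(parts, ignore_index=True)
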