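"""Synthetic flanker study generator.

Emulates the study design the analysis assumes: a within-subject crossover
with three state inductions — focused attention (FA), open monitoring (OM)
and an active control (C) — each session contributing 512 flanker trials
split evenly between congruent and incongruent arrays, RTs bounded by the
task's 950 ms response window.

Condition profiles default to the estimated condition means of the real
study: FA narrows the initial spotlight (sd_a0 = 0.42) but barely shrinks it
further (r_d = 0.001); OM starts wide (4.63) and shrinks fastest (0.105) with
the longest and most variable nondecision component; control sits between.
Perceptual gain and boundary are common across conditions (0.6, 60), where no
condition differences were found. Participants deviate from the profiles by
a zero-mean truncated-normal baseline shared across their three sessions,
mirroring the additive population + condition + participant structure the
hierarchical fit estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ssp_core
from .params import (
    CONDITIONS,
    N_PARAMS,
    PARAM_NAMES,
    SIMULATION_FLOOR,
    STAGE_UPPER,
    SimulationConfig,
    SSPParameters,
)

__all__ = ["StudyDesign", "default_condition_profiles", "generate_study"]

#: Default between-participant SDs, half the start-distribution SDs
#: [sd_a0, r_d, p_input, boundary, ndt_mean, ndt_sd].
DEFAULT_PARTICIPANT_SD = np.array([0.6, 0.025, 0.15, 15.0, 30.0, 10.0])


def default_condition_profiles() -> dict:
    """Condition-mean SSP parameters of the three inductions."""
    common = {"p_input": 0.6, "boundary": 60.0}
    return {
        "FA": SSPParameters(sd_a0=0.42, r_d=0.001, ndt_mean=271.2, ndt_sd=17.65, **common),
        "OM": SSPParameters(sd_a0=4.63, r_d=0.105, ndt_mean=285.0, ndt_sd=31.42, **common),
        "C": SSPParameters(sd_a0=4.43, r_d=0.081, ndt_mean=273.0, ndt_sd=18.64, **common),
    }


@dataclass
class StudyDesign:
    """Shape and generative parameters of one synthetic study."""

    n_participants: int = 29
    conditions: tuple = CONDITIONS
    trials_per_condition: int = 512  # half congruent, half incongruent
    condition_profiles: dict = field(default_factory=default_condition_profiles)
    participant_sd: np.ndarray = field(default_factory=lambda: DEFAULT_PARTICIPANT_SD.copy())

    def __post_init__(self):
        self.participant_sd = np.asarray(self.participant_sd, dtype=float)
        if self.n_participants < 1 or self.trials_per_condition < 2:
            raise ValueError("need at least one participant and two trials per condition")
        if self.trials_per_condition % 2:
            raise ValueError("trials_per_condition must be even (half per congruency)")


def _draw_participant_deltas(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean truncated-normal participant baselines, one row each.

    Truncation keeps every composed profile + delta inside
    [simulation floor, stage upper bounds] for all conditions.
    """
    profiles = np.stack([design.condition_profiles[c].to_array() for c in design.conditions])
    lo = (SIMULATION_FLOOR - profiles).max(axis=0)
    hi = (STAGE_UPPER - profiles).min(axis=0)
    out = np.zeros((design.n_participants, N_PARAMS))
    for j in range(N_PARAMS):
        sd = design.participant_sd[j]
        if sd == 0:
            continue
        col = np.empty(design.n_participants)
        filled = 0
        while filled < design.n_participants:
            draw = sd * rng.standard_normal(design.n_participants * 2 + 8)
            ok = draw[(draw >= lo[j]) & (draw <= hi[j])]
            take = min(ok.size, design.n_participants - filled)
            col[filled : filled + take] = ok[:take]
            filled += take
        out[:, j] = col
    return out


def generate_study(
    design: StudyDesign | None = None,
    sim_config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full study; returns (trial table, ground-truth table).

    The trial table has one row per simulated trial (participant, condition,
    congruency, rt_ms, accuracy, responded); censored trials carry NaN RT.
    The truth table records each observation's generating parameter vector
    and whether any component was clipped into bounds, for recovery testing.
    """
    design = design or StudyDesign()
    sim_config = sim_config or SimulationConfig()
    rng = np.random.default_rng() if rng is None else rng

    deltas = _draw_participant_deltas(design, rng)
    half = design.trials_per_condition // 2

    trial_parts = []
    truth_rows = []
    for p_idx in range(design.n_participants):
        participant = f"P{p_idx + 1:02d}"
        for condition in design.conditions:
            raw = design.condition_profiles[condition].to_array() + deltas[p_idx]
            vec = np.clip(raw, SIMULATION_FLOOR, STAGE_UPPER)
            clipped = bool(np.any(vec != raw))
            params = SSPParameters.from_array(vec)
            trials = ssp_core.simulate_dataset(params, half, half, sim_config, rng)
            trials.insert(0, "participant", participant)
            trials.insert(1, "condition", condition)
            trial_parts.append(trials)
            truth_rows.append(
                {
                    "participant": participant,
                    "condition": condition,
                    **dict(zip(PARAM_NAMES, vec)),
                    "clipped": clipped,
                }
            )

    trial_table = pd.concat(trial_parts, ignore_index=True)
    truth_table = pd.DataFrame(truth_rows)
    return trial_table, truth_table
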