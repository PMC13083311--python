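"""Parameter vectors and simulation configuration for the shrinking-spotlight model.

The model describes one observer performing an arrow flanker task. Attention is
a Gaussian spotlight over the five-item array (target centered at 0, unit item
width) whose standard deviation ``sd_a0`` narrows linearly at rate ``r_d``
(width units per ms). Each item's activation is the spotlight mass over its
spatial window; drift is the signed, activation-weighted sum scaled by the
perceptual input gain ``p_input``. Evidence accumulates in a single diffusion
process between symmetric boundaries at ``+/- boundary``; the response time
adds a nondecision component with mean ``ndt_mean`` and trial-to-trial
variability ``ndt_sd`` (both ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical parameter order used by every array-valued interface.
PARAM_NAMES = ("sd_a0", "r_d", "p_input", "boundary", "ndt_mean", "ndt_sd")

N_PARAMS = len(PARAM_NAMES)

# Population-stage start distribution (truncated normal) for
# [sd_a0, r_d, p_input, boundary, ndt_mean, ndt_sd].
START_MEANS = np.array([1.8, 0.017, 0.6, 60.0, 250.0, 30.0])
START_SDS = np.array([1.2, 0.05, 0.3, 30.0, 60.0, 20.0])
START_LOWER = np.array([0.8, 0.005, 0.2, 20.0, 175.0, 10.0])
START_UPPER = np.array([4.0, 0.15, 2.0, 150.0, 375.0, 50.0])

# Deviation stages draw zero-mean starts with these SDs; composed sums
# (population + deltas) are kept within [0, STAGE_UPPER].
DELTA_SDS = START_SDS.copy()
STAGE_LOWER = np.zeros(N_PARAMS)
STAGE_UPPER = np.array([6.0, 0.2, 5.0, 200.0, 450.0, 90.0])

#: Diffusion noise scale (evidence units per sqrt(ms)); fixed, not fitted —
#: drift, boundary and noise are not jointly identifiable.
SIGMA = 7.0

#: Minimum attentional window width.
WIDTH_FLOOR = 0.001

#: Condition labels of the within-subject design: focused attention,
#: open monitoring, active control.
CONDITIONS = ("FA", "OM", "C")
CONGRUENCIES = ("congruent", "incongruent")

# Hard floors applied before simulating a candidate parameter vector so the
# generative process stays defined (widths, gains and boundaries positive;
# rates and SDs allowed to reach zero).
SIMULATION_FLOOR = np.array([WIDTH_FLOOR, 0.0, 1e-6, 1e-3, 0.0, 0.0])


@dataclass(frozen=True)
class SSPParameters:
    """Six-parameter vector governing one simulated observer.

    Units: ``sd_a0`` in stimulus widths (target width = 1), ``r_d`` in widths
    per ms, ``p_input`` in evidence units per ms per unit activation,
    ``boundary`` in evidence units, ``ndt_mean``/``ndt_sd`` in ms.
    """

    sd_a0: float
    r_d: float
    p_input: float
    boundary: float
    ndt_mean: float
    ndt_sd: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite parameter in {arr}")
        if self.sd_a0 <= 0 or self.p_input <= 0 or self.boundary <= 0:
            raise ValueError(
                "sd_a0, p_input and boundary must be strictly positive, got "
                f"sd_a0={self.sd_a0}, p_input={self.p_input}, boundary={self.boundary}"
            )
        if self.r_d < 0 or self.ndt_mean < 0 or self.ndt_sd < 0:
            raise ValueError("r_d, ndt_mean and ndt_sd must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.sd_a0, self.r_d, self.p_input, self.boundary, self.ndt_mean, self.ndt_sd],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr) -> "SSPParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters, got shape {arr.shape}")
        return cls(*arr)

    def replace(self, **kwargs) -> "SSPParameters":
        vals = {name: getattr(self, name) for name in PARAM_NAMES}
        vals.update(kwargs)
        return SSPParameters(**vals)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings of the trial simulator.

    ``sigma`` is the diffusion scale per sqrt(ms) (per-step SD at dt = 1 ms);
    ``dt`` the Euler step in ms; ``width_floor`` the minimum spotlight width;
    ``max_decision_time`` the censoring horizon of the decision process in ms
    (the task's response window).
    """

    sigma: float = SIGMA
    dt: float = 1.0
    width_floor: float = WIDTH_FLOOR
    max_decision_time: float = 950.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.dt <= 0 or self.width_floor <= 0:
            raise ValueError("sigma, dt and width_floor must be strictly positive")
        if self.max_decision_time <= 0:
            raise ValueError("max_decision_time must be strictly positive")

    @property
    def n_steps(self) -> int:
        return int(np.ceil(self.max_decision_time / self.dt))

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "dt": self.dt,
            "width_floor": self.width_floor,
            "max_decision_time": self.max_decision_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**{k: d[k] for k in ("sigma", "dt", "width_floor", "max_decision_time") if k in d})
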