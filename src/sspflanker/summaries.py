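"""Distributional fitting targets and goodness of fit.

The model is fit to binned response distributions, one set per trial type
(congruent, incongruent):

* CDF cells — correct-response RTs partitioned at the (0.1, 0.3, 0.5, 0.7,
  0.9, 1) quantiles, giving six bins whose observed masses are about
  (.1, .2, .2, .2, .2, .1) of the correct trials;
* CAF cells — all responded trials partitioned at RT quartiles
  (0.25, 0.5, 0.75, 1.0); the error counts within each quartile carry the
  error information.

Per trial type the ten cell counts sum to the trial count, so the observed
cell proportions form a partition of unity. The objective is the summed
-2 log binomial likelihood of the observed counts under the model's predicted
cell probabilities; fit quality is assessed with Pearson's chi-square
``sum_i N_i sum_j (p_ij - pi_ij)^2 / pi_ij`` and an RMSEA derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CDF_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
CAF_PROBS = (0.25, 0.5, 0.75, 1.0)

#: Free parameters of the generative model, used in the default df convention.
N_FREE_PARAMS = 6

__all__ = [
    "DistributionSummary",
    "FitStatistics",
    "summarize",
    "summarize_by_type",
    "classify_cells",
    "predicted_proportions",
    "neg2_log_binomial",
    "deviance",
    "chi_square",
    "rmsea",
    "goodness_of_fit",
    "summary_to_frame",
]


@dataclass(frozen=True)
class DistributionSummary:
    """Binned RT/accuracy summary of one trial type; the fitting target."""

    trial_type: str
    cdf_probs: tuple
    cdf_edges: np.ndarray  # RT values at the CDF quantiles (last = max)
    caf_probs: tuple
    caf_edges: np.ndarray  # RT values at the CAF quartiles (last = max)
    caf_accuracy: np.ndarray  # proportion correct within each quartile group
    n_trials: int  # responded trials of this type
    cell_counts: np.ndarray  # len 10: six correct-CDF cells + four error-CAF cells

    @property
    def observed_proportions(self) -> np.ndarray:
        return self.cell_counts / self.n_trials

    @property
    def n_cells(self) -> int:
        return self.cell_counts.size


@dataclass(frozen=True)
class FitStatistics:
    """Goodness of fit of one dataset (both trial types)."""

    neg2_loglik: float
    chi_square: float
    df: int
    acceptable: bool
    rmsea: float


def _rank_partition_counts(n: int, probs) -> np.ndarray:
    """Group sizes when n sorted trials are cut at cumulative ``probs``."""
    cum = np.round(np.asarray(probs, dtype=float) * n).astype(int)
    cum[-1] = n
    return np.diff(np.concatenate([[0], cum]))


def summarize(trials: pd.DataFrame, trial_type: str, cdf_probs=CDF_PROBS, caf_probs=CAF_PROBS) -> DistributionSummary:
    """Summarize responded trials of one trial type into CDF/CAF cells.

    ``trials`` needs columns ``rt_ms`` and ``accuracy``; censored trials
    (``responded`` False or NaN RT) are dropped first.
    """
    if "responded" in trials:
        trials = trials[trials["responded"]]
    trials = trials.dropna(subset=["rt_ms"])
    n = len(trials)
    if n == 0:
        raise ValueError(f"no responded trials in cell {trial_type!r}")
    rt = trials["rt_ms"].to_numpy(dtype=float)
    acc = trials["accuracy"].to_numpy(dtype=int)
    correct_rt = np.sort(rt[acc == 1])
    n_corr = correct_rt.size
    if n_corr == 0:
        raise ValueError(f"no correct trials in cell {trial_type!r}; CDF quantiles undefined")

    cdf_edges = np.quantile(correct_rt, cdf_probs)
    caf_edges = np.quantile(rt, caf_probs)

    # Observed counts by rank partition (exact multinomial cell sizes).
    cdf_counts = _rank_partition_counts(n_corr, cdf_probs)
    order = np.argsort(rt, kind="stable")
    caf_sizes = _rank_partition_counts(n, caf_probs)
    caf_acc = np.empty(len(caf_probs))
    err_counts = np.zeros(len(caf_probs), dtype=int)
    start = 0
    for k, size in enumerate(caf_sizes):
        grp = order[start : start + size]
        if size > 0:
            correct_in_grp = int(acc[grp].sum())
            caf_acc[k] = correct_in_grp / size
            err_counts[k] = size - correct_in_grp
        else:
            caf_acc[k] = np.nan
        start += size

    return DistributionSummary(
        trial_type=trial_type,
        cdf_probs=tuple(cdf_probs),
        cdf_edges=cdf_edges,
        caf_probs=tuple(caf_probs),
        caf_edges=caf_edges,
        caf_accuracy=caf_acc,
        n_trials=n,
        cell_counts=np.concatenate([cdf_counts, err_counts]),
    )


def summarize_by_type(trials: pd.DataFrame, **kwargs) -> dict:
    """Summaries for both congruencies, keyed by trial type."""
    out = {}
    for trial_type in ("congruent", "incongruent"):
        sub = trials[trials["congruency"] == trial_type]
        out[trial_type] = summarize(sub, trial_type, **kwargs)
    return out


def classify_cells(summary: DistributionSummary, rt: np.ndarray, acc: np.ndarray) -> np.ndarray:
    """Count trials in the summary's ten cells.

    Correct trials go to the six CDF bins cut at the observed quantile edges
    (mass above the 0.9 quantile falls in the last bin); errors go to the four
    CAF quartile bins.
    """
    rt = np.asarray(rt, dtype=float)
    acc = np.asarray(acc)
    counts = np.zeros(summary.n_cells, dtype=int)
    corr = acc == 1
    n_cdf = len(summary.cdf_probs)
    if corr.any():
        idx = np.searchsorted(summary.cdf_edges[:-1], rt[corr], side="left")
        counts[:n_cdf] = np.bincount(idx, minlength=n_cdf)
    if (~corr).any():
        idx = np.searchsorted(summary.caf_edges[:-1], rt[~corr], side="left")
        counts[n_cdf:] = np.bincount(idx, minlength=len(summary.caf_probs))
    return counts


def predicted_proportions(
    summary: DistributionSummary,
    sim_rt: np.ndarray,
    sim_acc: np.ndarray,
    floor: float | None = None,
) -> np.ndarray:
    """Model cell probabilities pi_ij from simulated trials.

    Proportions are floored at ``1 / (10 * n_sim)`` (empty simulated bins
    would otherwise make the deviance infinite) and renormalized to sum 1.
    """
    sim_rt = np.asarray(sim_rt, dtype=float)
    keep = np.isfinite(sim_rt)
    sim_rt = sim_rt[keep]
    sim_acc = np.asarray(sim_acc)[keep]
    n_sim = sim_rt.size
    if n_sim == 0:
        raise ValueError("no responded simulated trials")
    if floor is None:
        floor = 1.0 / (10.0 * n_sim)
    pi = classify_cells(summary, sim_rt, sim_acc) / n_sim
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def neg2_log_binomial(cell_counts: np.ndarray, n_trials: int, pi: np.ndarray) -> float:
    """Summed -2 log binomial PMF of the observed cell counts under ``pi``."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    return float(-2.0 * stats.binom.logpmf(cell_counts, n_trials, pi).sum())


def deviance(summaries: dict, sim_trials: pd.DataFrame) -> float:
    """Objective over both trial types: simulated trials vs observed cells."""
    total = 0.0
    for trial_type, summary in summaries.items():
        sub = sim_trials[sim_trials["congruency"] == trial_type]
        sub = sub[sub["responded"]] if "responded" in sub else sub
        pi = predicted_proportions(summary, sub["rt_ms"].to_numpy(), sub["accuracy"].to_numpy())
        total += neg2_log_binomial(summary.cell_counts, summary.n_trials, pi)
    return total


def chi_square(
    observed: list[np.ndarray],
    predicted: list[np.ndarray],
    n_trials: list[int],
    n_free_params: int = N_FREE_PARAMS,
    alpha: float = 0.05,
) -> tuple[float, int, bool]:
    """Pearson chi-square over trial types: ``sum_i N_i sum_j (p-pi)^2/pi``.

    df = (cells - 1 per trial type) - ``n_free_params`` (convention; set
    ``n_free_params=0`` for the raw multinomial df). ``acceptable`` is a
    nonsignificant statistic at level ``alpha``.
    """
    chi2 = 0.0
    df = -n_free_params
    for p, pi, n in zip(observed, predicted, n_trials):
        p = np.asarray(p, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if np.any(pi <= 0):
            raise ValueError("predicted bin probabilities must be strictly positive")
        chi2 += n * float(((p - pi) ** 2 / pi).sum())
        df += p.size - 1
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom: {df}")
    acceptable = chi2 < stats.chi2.ppf(1.0 - alpha, df)
    return chi2, df, bool(acceptable)


def rmsea(chi_sq: float, df: int, n_observations: int) -> float:
    """Root mean square error of approximation.

    ``sqrt(max(chi2 - df, 0) / (df * (n - 1)))``; values below 0.05 are read
    as acceptable approximate fit.
    """
    if df <= 0:
        raise ValueError("df must be strictly positive")
    if n_observations <= 1:
        raise ValueError("n_observations must exceed 1")
    return float(np.sqrt(max(chi_sq - df, 0.0) / (df * (n_observations - 1))))


def goodness_of_fit(
    summaries: dict,
    sim_trials: pd.DataFrame,
    n_free_params: int = N_FREE_PARAMS,
    alpha: float = 0.05,
) -> FitStatistics:
    """Deviance, chi-square, df, acceptability and RMSEA for one dataset."""
    obs, pred, ns = [], [], []
    dev = 0.0
    for trial_type, summary in summaries.items():
        sub = sim_trials[sim_trials["congruency"] == trial_type]
        sub = sub[sub["responded"]] if "responded" in sub else sub
        pi = predicted_proportions(summary, sub["rt_ms"].to_numpy(), sub["accuracy"].to_numpy())
        dev += neg2_log_binomial(summary.cell_counts, summary.n_trials, pi)
        obs.append(summary.observed_proportions)
        pred.append(pi)
        ns.append(summary.n_trials)
    chi2, df, acceptable = chi_square(obs, pred, ns, n_free_params=n_free_params, alpha=alpha)
    n_total = int(sum(ns))
    return FitStatistics(
        neg2_loglik=dev,
        chi_square=chi2,
        df=df,
        acceptable=acceptable,
        rmsea=rmsea(chi2, df, n_total),
    )


def summary_to_frame(summary: DistributionSummary) -> pd.DataFrame:
    """One row per cell, for inspection and regression tests."""
    n_cdf = len(summary.cdf_probs)
    rows = []
    for j in range(n_cdf):
        rows.append(
            {
                "trial_type": summary.trial_type,
                "cell": f"cdf_{summary.cdf_probs[j]}",
                "edge_ms": summary.cdf_edges[j],
                "count": int(summary.cell_counts[j]),
                "proportion": summary.cell_counts[j] / summary.n_trials,
            }
        )
    for k in range(len(summary.caf_probs)):
        rows.append(
            {
                "trial_type": summary.trial_type,
                "cell": f"caf_err_{summary.caf_probs[k]}",
                "edge_ms": summary.caf_edges[k],
                "count": int(summary.cell_counts[n_cdf + k]),
                "proportion": summary.cell_counts[n_cdf + k] / summary.n_trials,
            }
        )
    return pd.DataFrame(rows)
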