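"""Condition-effect statistics on estimated model parameters.

Two analysis levels mirror the two estimate types the hierarchy produces:

* ``within_transformed`` — population + condition + participant sums. The
  condition deltas are common to all participants, so these values are
  already denoised; they are analyzed with a general linear model with
  condition as a fixed effect (residual = participant variation).
* ``observation`` — observation-level sums (with noise deltas). Analyzed as
  a one-way repeated-measures ANOVA on complete cases, with paired follow-up
  contrasts.

Effect-size conventions: partial eta squared for the omnibus test; for
pairwise contrasts Cohen's d is the marginal-mean difference over the root
mean square error at the ``within_transformed`` level and the standardized
mean pairwise difference (d_z) at the ``observation`` level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .params import PARAM_NAMES

__all__ = [
    "PairwiseContrast",
    "ConditionEffectReport",
    "condition_anova",
    "convergence_ratio",
    "analyze_parameters",
    "report_text",
]


@dataclass(frozen=True)
class PairwiseContrast:
    pair: tuple
    t: float
    df: float
    p: float
    cohen_d: float


@dataclass(frozen=True)
class ConditionEffectReport:
    parameter: str
    F: float
    df: tuple
    p: float
    eta_sq_p: float
    pairwise: list


def _glm_anova(df: pd.DataFrame, value_col: str) -> ConditionEffectReport:
    """One-way fixed-effect ANOVA with condition as the only factor."""
    groups = {c: g[value_col].to_numpy(dtype=float) for c, g in df.groupby("condition", sort=False)}
    conditions = list(groups)
    n_total = sum(len(v) for v in groups.values())
    grand = df[value_col].mean()
    ss_cond = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df1, df2 = len(conditions) - 1, n_total - len(conditions)
    mse = ss_err / df2 if df2 > 0 else 0.0
    if ss_cond == 0.0:
        F, p = 0.0, 1.0
    elif mse == 0.0:
        F, p = np.inf, 0.0
    else:
        F = (ss_cond / df1) / mse
        p = float(stats.f.sf(F, df1, df2))
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0

    pairwise = []
    for a, b in combinations(conditions, 2):
        diff = groups[a].mean() - groups[b].mean()
        se = np.sqrt(mse * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        t = 0.0 if diff == 0 else (diff / se if se > 0 else np.inf * np.sign(diff))
        p_t = float(2 * stats.t.sf(abs(t), df2)) if np.isfinite(t) else 0.0
        d = 0.0 if diff == 0 else (diff / np.sqrt(mse) if mse > 0 else np.inf * np.sign(diff))
        pairwise.append(PairwiseContrast((a, b), float(t), float(df2), p_t, float(d)))
    return ConditionEffectReport(value_col, float(F), (df1, df2), float(p), float(eta), pairwise)


def _rm_anova(df: pd.DataFrame, value_col: str) -> ConditionEffectReport:
    """One-way repeated-measures ANOVA on complete cases, paired contrasts."""
    wide = df.pivot(index="participant", columns="condition", values=value_col).dropna()
    if wide.shape[1] < 2:
        raise ValueError("need at least two conditions")
    conditions = list(wide.columns)
    n, k = wide.shape
    long = wide.reset_index().melt(id_vars="participant", var_name="condition", value_name=value_col)

    cond_means = wide.mean(axis=0)
    ss_cond = float(n * ((cond_means - wide.to_numpy().mean()) ** 2).sum())
    if ss_cond == 0.0:
        F, p, eta = 0.0, 1.0, 0.0
        df1, df2 = k - 1, (k - 1) * (n - 1)
    else:
        aov = pg.rm_anova(data=long, dv=value_col, within="condition", subject="participant", detailed=True)
        row = aov.loc[aov["Source"] == "condition"].iloc[0]
        err = aov.loc[aov["Source"] == "Error"].iloc[0]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        F, p = float(row["F"]), float(row[p_col])
        eta = float(row["SS"] / (row["SS"] + err["SS"]))  # partial eta squared
        df1, df2 = int(row["DF"]), int(err["DF"])

    pairwise = []
    for a, b in combinations(conditions, 2):
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        sd = diff.std(ddof=1)
        if sd == 0.0:
            t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
            p_t = 1.0 if t == 0.0 else 0.0
            d = t if not np.isfinite(t) else 0.0
        else:
            t, p_t = stats.ttest_rel(wide[a], wide[b])
            d = diff.mean() / sd
        pairwise.append(PairwiseContrast((a, b), float(t), float(n - 1), float(p_t), float(d)))
    return ConditionEffectReport(value_col, float(F), (df1, df2), float(p), float(eta), pairwise)


def condition_anova(values: pd.DataFrame, value_col: str, level: str = "within_transformed") -> ConditionEffectReport:
    """Omnibus condition effect plus pairwise contrasts for one parameter.

    ``values`` needs columns participant, condition and ``value_col``.
    ``level='within_transformed'`` runs a condition-only GLM;
    ``level='observation'`` a repeated-measures ANOVA on complete cases.
    """
    if values["condition"].nunique() < 2:
        raise ValueError("need at least two conditions")
    if level == "within_transformed":
        return _glm_anova(values, value_col)
    if level == "observation":
        return _rm_anova(values, value_col)
    raise ValueError(f"unknown analysis level: {level!r}")


def convergence_ratio(sd_a0, r_d):
    """Time (ms) for the spotlight to reach its minimum width: sd_a0 / r_d.

    A trade-invariant index of narrowing speed; computed per observation and
    then averaged, never as a ratio of averages.
    """
    sd_a0 = np.asarray(sd_a0, dtype=float)
    r_d = np.asarray(r_d, dtype=float)
    if np.any(r_d <= 0):
        raise ValueError("r_d must be strictly positive (the spotlight never converges)")
    ratio = sd_a0 / r_d
    return ratio if ratio.ndim else float(ratio)


def analyze_parameters(
    values: pd.DataFrame,
    level: str = "within_transformed",
    include_ratio: bool = True,
) -> dict:
    """Condition ANOVA for each model parameter (and the convergence ratio).

    The ratio is skipped when any observation has non-positive r_d (it is
    undefined there), which can happen for untruncated within-transformed sums.
    """
    reports = {}
    for name in PARAM_NAMES:
        reports[name] = condition_anova(values, name, level=level)
    if include_ratio:
        if np.all(values["r_d"].to_numpy() > 0):
            vals = values[["participant", "condition"]].copy()
            vals["convergence_ratio"] = convergence_ratio(values["sd_a0"], values["r_d"])
            reports["convergence_ratio"] = condition_anova(vals, "convergence_ratio", level=level)
    return reports


def report_text(reports: dict) -> str:
    """Human-readable log mirroring the F(df1, df2), p, eta2p, t/d format."""
    lines = []
    for name, rep in reports.items():
        lines.append(
            f"{name}: F({rep.df[0]}, {rep.df[1]}) = {rep.F:.2f}, "
            f"p = {rep.p:.4f}, eta2p = {rep.eta_sq_p:.3f}"
        )
        for c in rep.pairwise:
            lines.append(
                f"  {c.pair[0]} vs {c.pair[1]}: t({c.df:.0f}) = {c.t:.2f}, "
                f"p = {c.p:.4f}, d = {c.cohen_d:.2f}"
            )
    return "\n".join(lines)


def reports_to_frame(reports: dict) -> pd.DataFrame:
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "parameter": name,
                "term": "omnibus",
                "statistic": rep.F,
                "df1": rep.df[0],
                "df2": rep.df[1],
                "p": rep.p,
                "effect_size": rep.eta_sq_p,
            }
        )
        for c in rep.pairwise:
            rows.append(
                {
                    "parameter": name,
                    "term": f"{c.pair[0]}-{c.pair[1]}",
                    "statistic": c.t,
                    "df1": np.nan,
                    "df2": c.df,
                    "p": c.p,
                    "effect_size": c.cohen_d,
                }
            )
    return pd.DataFrame(rows)
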