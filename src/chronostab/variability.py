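"""Within- vs between-person variance decomposition of nightly sleep timing.

Two models per outcome (mid-sleep, sleep onset, wake-up time), following the
two-step workflow: an intercept-only mixed model whose variance components
yield the intraclass correlation, then a day-type-adjusted model with fixed
and random effects for whether the waking day and the previous day were
workdays, fitted with the singular-fit simplification ladder. The headline
quantity of the adjusted model is the ratio of the within-person (residual)
variance to the between-person (random-intercept) variance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .lmm import INTERCEPT, LmmFit, LmmSpec, DesignError, fit_from_frame, fit_with_ladder

__all__ = [
    "VariabilityReport",
    "icc_intercept_only",
    "variance_ratio",
    "run_variability_study",
    "OUTCOME_COLUMNS",
]

OUTCOME_COLUMNS = {
    "mid_sleep": "mid_sleep_h",
    "sleep_onset": "sleep_onset_h",  # midnight-centered
    "wake_time": "wake_h",
}

INTERACTION = "workday_today:workday_yesterday"

ADJUSTED_SPEC_TEMPLATE = dict(
    fixed=("workday_today", "workday_yesterday", INTERACTION),
    random=(INTERCEPT, "workday_today", "workday_yesterday", INTERACTION),
    correlated=True,
    ladder=(INTERACTION, "workday_yesterday", "workday_today"),
)


@dataclass
class VariabilityReport:
    """Variance components and derived summaries for one outcome/model."""

    outcome: str
    model: str  # "intercept_only" | "workday_adjusted"
    var_between: float
    var_within: float
    sd_between: float
    sd_within: float
    icc: float | None
    ratio_within_over_between: float | None
    fixed_effects: dict
    slope_variances: dict
    n_obs: int
    n_participants: int
    singular: bool
    dropped_random_terms: list

    def to_dict(self) -> dict:
        return asdict(self)


def icc_intercept_only(var_between: float, var_within: float) -> float:
    """Intraclass correlation: share of total variance between participants."""
    if var_between < 0 or var_within < 0:
        raise ValueError("variance components must be non-negative")
    total = var_between + var_within
    if total == 0:
        raise ValueError("ICC undefined: both variance components are zero")
    return var_between / total


def variance_ratio(var_within: float, var_between: float) -> float:
    """Within-person variance as a multiple of the between-person variance."""
    if var_between <= 0:
        raise ValueError("variance ratio undefined: between-person variance is zero")
    return var_within / var_between


def _report(outcome: str, model: str, fit: LmmFit, dropped: list) -> VariabilityReport:
    vb = fit.var_between
    vw = fit.sigma2_within
    slope_vars = {
        name: float(fit.cov_between[i, i])
        for i, name in enumerate(fit.re_names)
        if name != INTERCEPT
    }
    return VariabilityReport(
        outcome=outcome,
        model=model,
        var_between=vb,
        var_within=vw,
        sd_between=float(np.sqrt(vb)),
        sd_within=float(np.sqrt(vw)),
        icc=icc_intercept_only(vb, vw) if model == "intercept_only" else None,
        ratio_within_over_between=variance_ratio(vw, vb) if vb > 0 else None,
        fixed_effects={n: float(b) for n, b in zip(fit.fe_names, fit.beta)},
        slope_variances=slope_vars,
        n_obs=fit.n_obs,
        n_participants=fit.n_groups,
        singular=fit.singular,
        dropped_random_terms=dropped,
    )


def run_variability_study(diary: pd.DataFrame, outcome: str = "mid_sleep", **fit_kwargs):
    """Run both models on a scored diary table for one outcome.

    Returns ``(intercept_only_report, workday_adjusted_report)``. Rows
    lacking the lagged day-type factor (first nights, nights after a gap)
    enter the intercept-only model but are dropped from the adjusted model,
    which uses that factor. The between-person variance in the adjusted
    model is the random-intercept variance; slope variances are reported
    separately and excluded from the within/between ratio.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {outcome!r}; choose from {sorted(OUTCOME_COLUMNS)}")
    col = OUTCOME_COLUMNS[outcome]
    if col not in diary.columns:
        raise DesignError(f"diary table lacks scored column {col!r}; run score_diary first")
    data = diary.dropna(subset=[col])
    n_participants = data["participant_id"].nunique()
    if n_participants < 2:
        raise DesignError("need at least 2 participants")
    if data.groupby("participant_id").size().max() < 2:
        raise DesignError("need at least one participant with 2+ nights")

    spec0 = LmmSpec(response=col)
    fit0 = fit_from_frame(data, spec0, **fit_kwargs)
    report0 = _report(outcome, "intercept_only", fit0, [])

    spec1 = LmmSpec(response=col, **ADJUSTED_SPEC_TEMPLATE)
    fit1, fitted_spec = fit_with_ladder(data, spec1, **fit_kwargs)
    dropped = [t for t in spec1.random if t not in fitted_spec.random]
    report1 = _report(outcome, "workday_adjusted", fit1, dropped)
    return report0, report1
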