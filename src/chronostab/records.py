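"""Parsing, scoring, and filtering of sleep-diary and MCTQ chronotype data.

All times are decimal hours. Evening-side events (bed time, lights off,
sleep onset) live on a midnight-centered axis in (-12, 12], so 23:30 maps
to -0.5 and 01:00 to 1.0; wake-side events live on [0, 24). Mid-sleep is
expressed in hours after midnight. The centered axis removes wrap-around
arithmetic for people who fall asleep on either side of midnight.

Diary CSV schema (one row per participant-night)::

    participant_id, day_index, [date], bed_time, lights_off, latency_min,
    wake_time, alarm(0/1), workday_today(0/1)

MCTQ CSV schema (one row per participant)::

    participant_id, w_lights_off, w_latency_min, w_wake,
    f_lights_off, f_latency_min, f_wake, workdays_per_week
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClockTimeError",
    "ValidationError",
    "parse_clock_time",
    "format_clock_time",
    "compute_sleep_onset",
    "compute_mid_sleep",
    "score_diary",
    "code_day_types",
    "score_mctq",
    "ExclusionRule",
    "build_rules",
    "default_diary_rules",
    "default_panel_rules",
    "apply_exclusions",
    "response_rate",
    "read_diary_csv",
    "read_mctq_csv",
    "read_panel_csv",
]

_CLOCK_RE = re.compile(r"^\s*([01]?\d|2[0-3]):([0-5]\d)\s*$")

DIARY_COLUMNS = [
    "participant_id",
    "day_index",
    "bed_time",
    "lights_off",
    "latency_min",
    "wake_time",
    "alarm",
    "workday_today",
]

MCTQ_COLUMNS = [
    "participant_id",
    "w_lights_off",
    "w_latency_min",
    "w_wake",
    "f_lights_off",
    "f_latency_min",
    "f_wake",
    "workdays_per_week",
]

PANEL_COLUMNS = [
    "participant_id",
    "age_t1",
    "sex",
    "education",
    "interval_years",
    "msf_t1",
    "msf_t2",
    "msw_t1",
    "msw_t2",
]


class ClockTimeError(ValueError):
    """Malformed clock-time text."""


class ValidationError(ValueError):
    """Input violates a scoring precondition."""


def parse_clock_time(text: str, side: str = "evening") -> float:
    """Parse ``"HH:MM"`` into decimal hours.

    Parameters
    ----------
    text : str
        Clock time in 24-h ``HH:MM`` notation.
    side : {"evening", "wake"}
        ``"evening"`` returns midnight-centered hours in (-12, 12]
        (23:30 -> -0.5); ``"wake"`` returns hours in [0, 24).
    """
    if side not in ("evening", "wake"):
        raise ValueError(f"side must be 'evening' or 'wake', got {side!r}")
    m = _CLOCK_RE.match(str(text))
    if m is None:
        raise ClockTimeError(f"not a valid HH:MM clock time: {text!r}")
    hours = int(m.group(1)) + int(m.group(2)) / 60.0
    if side == "evening" and hours > 12.0:
        hours -= 24.0
    return hours


def format_clock_time(hours: float) -> str:
    """Format decimal hours (either axis) back to ``"HH:MM"``.

    Rounds to the nearest minute; inverse of :func:`parse_clock_time`
    for minute-resolution inputs.
    """
    minutes = int(round(float(hours) * 60.0)) % (24 * 60)
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def compute_sleep_onset(lights_off: float, latency_min: float):
    """Sleep onset = lights-off time plus sleep latency, on the centered axis."""
    lights_off = np.asarray(lights_off, dtype=float)
    latency_min = np.asarray(latency_min, dtype=float)
    if np.any(latency_min < 0):
        raise ValidationError("sleep latency must be non-negative")
    out = lights_off + latency_min / 60.0
    return float(out) if out.ndim == 0 else out

def compute_mid_sleep(onset, wake, plausible_duration=(0.0, 24.0)):
    """Nightly sleep duration and mid-sleep from onset and wake-up time.

    ``duration = wake - onset`` with onset midnight-centered and wake on
    [0, 24); ``mid_sleep = onset + duration / 2`` in hours after midnight.

    Returns ``(duration_h, mid_sleep_h, implausible)`` where ``implausible``
    flags durations outside ``plausible_duration`` (records are flagged, not
    silently dropped; exclusion rules decide their fate downstream).
    """
    onset = np.asarray(onset, dtype=float)
    wake = np.asarray(wake, dtype=float)
    duration = wake - onset
    lo, hi = plausible_duration
    implausible = (duration <= lo) | (duration >= hi) | ~np.isfinite(duration)
    mid = onset + duration / 2.0
    if duration.ndim == 0:
        return float(duration), float(mid), bool(implausible)
    return duration, mid, implausible


def _parse_column(series: pd.Series, side: str, column: str) -> pd.Series:
    out = np.empty(len(series), dtype=float)
    for i, (idx, value) in enumerate(series.items()):
        if pd.isna(value):
            out[i] = np.nan
            continue
        try:
            out[i] = parse_clock_time(value, side)
        except ClockTimeError as exc:
            raise ClockTimeError(f"row {idx}, column {column!r}: {exc}") from exc
    return pd.Series(out, index=series.index)


def score_diary(diary: pd.DataFrame, plausible_duration=(0.0, 24.0)) -> pd.DataFrame:
    """Score a raw diary table into analysis-ready nightly variables.

    Adds ``bed_h``, ``lights_off_h``, ``wake_h`` (parsed), ``sleep_onset_h``
    (centered), ``sleep_duration_h``, ``mid_sleep_h``, the implausible-duration
    flag, and the lagged ``workday_yesterday`` factor (via
    :func:`code_day_types`).
    """
    missing = [c for c in DIARY_COLUMNS if c not in diary.columns]
    if missing:
        raise ValidationError(f"diary table is missing columns: {missing}")
    df = diary.copy()
    df["bed_h"] = _parse_column(df["bed_time"], "evening", "bed_time")
    df["lights_off_h"] = _parse_column(df["lights_off"], "evening", "lights_off")
    df["wake_h"] = _parse_column(df["wake_time"], "wake", "wake_time")
    latency = pd.to_numeric(df["latency_min"], errors="coerce")
    if (latency.dropna() < 0).any():
        raise ValidationError("latency_min contains negative values")
    df["latency_min"] = latency
    df["sleep_onset_h"] = df["lights_off_h"] + latency / 60.0
    duration, mid, implausible = compute_mid_sleep(
        df["sleep_onset_h"].to_numpy(), df["wake_h"].to_numpy(), plausible_duration
    )
    df["sleep_duration_h"] = duration
    df["mid_sleep_h"] = mid
    df["implausible_duration"] = implausible
    df["alarm"] = df["alarm"].astype(bool)
    df["workday_today"] = df["workday_today"].astype(bool)
    return code_day_types(df)


def code_day_types(days: pd.DataFrame) -> pd.DataFrame:
    """Fill the lagged day-type factor ``workday_yesterday``.

    For each participant, sorted by ``day_index``, night *k* inherits
    ``workday_today`` of night *k-1* when that night exists and is adjacent
    (``day_index`` differs by exactly 1); a participant's first recorded
    night, or a night after a gap, gets a missing value.
    """
    if days.duplicated(["participant_id", "day_index"]).any():
        dupes = days[days.duplicated(["participant_id", "day_index"], keep=False)]
        raise ValidationError(
            "duplicate (participant_id, day_index) pairs: "
            f"{sorted(set(map(tuple, dupes[['participant_id', 'day_index']].values)))[:5]}"
        )
    df = days.sort_values(["participant_id", "day_index"], kind="stable").copy()
    prev_flag = df.groupby("participant_id")["workday_today"].shift(1)
    prev_idx = df.groupby("participant_id")["day_index"].shift(1)
    adjacent = (df["day_index"] - prev_idx) == 1
    yesterday = prev_flag.where(adjacent)
    df["workday_yesterday"] = yesterday.astype("boolean")
    return df


def score_mctq(mctq: pd.DataFrame, plausible_duration=(0.0, 24.0)) -> pd.DataFrame:
    """Score MCTQ work/free-day items into MSW, MSF, durations, and MSFsc.

    MSW and MSF are the midpoints between schedule-specific sleep onset
    (lights-off + latency) and wake-up time. MSFsc applies the standard
    sleep-debt correction, generalized to the reported workdays per week WD:

        SDweek = (WD * SDw + (7 - WD) * SDf) / 7
        MSFsc  = MSF - (SDf - SDweek) / 2   if SDf > SDw, else MSF.

    Rows with a missing schedule are scored as missing and flagged in
    ``incomplete`` rather than dropped.
    """
    missing = [c for c in MCTQ_COLUMNS if c not in mctq.columns]
    if missing:
        raise ValidationError(f"MCTQ table is missing columns: {missing}")
    df = mctq.copy()
    w_off = _parse_column(df["w_lights_off"], "evening", "w_lights_off")
    f_off = _parse_column(df["f_lights_off"], "evening", "f_lights_off")
    w_wake = _parse_column(df["w_wake"], "wake", "w_wake")
    f_wake = _parse_column(df["f_wake"], "wake", "f_wake")
    w_lat = pd.to_numeric(df["w_latency_min"], errors="coerce")
    f_lat = pd.to_numeric(df["f_latency_min"], errors="coerce")
    if (w_lat.dropna() < 0).any() or (f_lat.dropna() < 0).any():
        raise ValidationError("MCTQ latencies must be non-negative")
    onset_w = w_off + w_lat / 60.0
    onset_f = f_off + f_lat / 60.0
    sd_w, msw, _ = compute_mid_sleep(onset_w.to_numpy(), w_wake.to_numpy(), plausible_duration)
    sd_f, msf, _ = compute_mid_sleep(onset_f.to_numpy(), f_wake.to_numpy(), plausible_duration)
    wd = pd.to_numeric(df["workdays_per_week"], errors="coerce").to_numpy(dtype=float)
    if np.any((wd < 0) | (wd > 7) | ~np.isfinite(wd)):
        raise ValidationError("workdays_per_week must be in 0..7")
    sd_week = (wd * sd_w + (7.0 - wd) * sd_f) / 7.0
    msfsc = np.where(sd_f > sd_w, msf - (sd_f - sd_week) / 2.0, msf)
    df["MSW_h"] = msw
    df["MSF_h"] = msf
    df["SDw_h"] = sd_w
    df["SDf_h"] = sd_f
    df["MSFsc_h"] = msfsc
    df["incomplete"] = ~np.isfinite(msw) | ~np.isfinite(msf)
    return df


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionRule:
    """A named, logged filter over scored records.

    ``predicate`` receives the full table and returns a boolean mask of rows
    to *exclude*. ``scope`` is ``"night"`` (row-wise) or ``"participant"``
    (the predicate marks participants; all their rows are removed).
    """

    name: str
    scope: str
    predicate: Callable[[pd.DataFrame], pd.Series]
    description: str = ""

    def mask(self, df: pd.DataFrame) -> pd.Series:
        excl = pd.Series(np.asarray(self.predicate(df), dtype=bool), index=df.index)
        if self.scope == "participant":
            bad = set(df.loc[excl, "participant_id"])
            excl = df["participant_id"].isin(bad)
        elif self.scope != "night":
            raise ValidationError(f"unknown rule scope {self.scope!r}")
        return excl


def _rule_min_duration(threshold: float = 4.0) -> ExclusionRule:
    return ExclusionRule(
        "min_duration", "night",
        lambda df: df["sleep_duration_h"] < threshold,
        f"nightly sleep duration < {threshold} h",
    )


def _rule_max_duration(threshold: float = 16.0) -> ExclusionRule:
    return ExclusionRule(
        "max_duration", "night",
        lambda df: df["sleep_duration_h"] > threshold,
        f"nightly sleep duration > {threshold} h",
    )


def _rule_max_latency(threshold: float = 180.0) -> ExclusionRule:
    return ExclusionRule(
        "max_latency", "night",
        lambda df: df["latency_min"] > threshold,
        f"sleep latency > {threshold} min",
    )


def _rule_missing_items(columns: Sequence[str] = ("lights_off_h", "latency_min", "wake_h")) -> ExclusionRule:
    cols = list(columns)
    return ExclusionRule(
        "missing_items", "night",
        lambda df: df[cols].isna().any(axis=1),
        f"missing any of {cols}",
    )


def _rule_mean_duration_below(threshold: float = 4.0, columns: Sequence[str] = ("sleep_duration_h",)) -> ExclusionRule:
    cols = list(columns)

    def predicate(df: pd.DataFrame) -> pd.Series:
        mean_dur = df[cols].mean(axis=1)
        per_person = mean_dur.groupby(df["participant_id"]).transform("mean")
        return per_person < threshold

    return ExclusionRule(
        "mean_duration_below", "participant", predicate,
        f"participant mean sleep duration < {threshold} h",
    )


def _rule_flag_true(column: str) -> ExclusionRule:
    return ExclusionRule(
        f"flag_{column}", "participant",
        lambda df: df[column].fillna(False).astype(bool),
        f"participant flagged on {column!r}",
    )


def _rule_max_interval(threshold: float = 5.0) -> ExclusionRule:
    return ExclusionRule(
        "max_interval", "participant",
        lambda df: df["interval_years"] > threshold,
        f"retest interval > {threshold} years",
    )


def _rule_implausible_duration() -> ExclusionRule:
    return ExclusionRule(
        "implausible_duration", "night",
        lambda df: df["implausible_duration"].astype(bool),
        "non-positive or out-of-window sleep duration",
    )


_RULE_BUILDERS: dict[str, Callable[..., ExclusionRule]] = {
    "min_duration": _rule_min_duration,
    "max_duration": _rule_max_duration,
    "max_latency": _rule_max_latency,
    "missing_items": _rule_missing_items,
    "mean_duration_below": _rule_mean_duration_below,
    "flag_true": _rule_flag_true,
    "max_interval": _rule_max_interval,
    "implausible_duration": _rule_implausible_duration,
}


def build_rules(specs: Iterable) -> list[ExclusionRule]:
    """Build exclusion rules from config entries.

    Each entry is either a rule name or a ``{"name": ..., **kwargs}`` mapping.
    Unknown names raise a configuration error.
    """
    rules = []
    for spec in specs:
        if isinstance(spec, str):
            name, kwargs = spec, {}
        else:
            spec = dict(spec)
            name = spec.pop("name")
            kwargs = spec
        if name not in _RULE_BUILDERS:
            raise ValidationError(
                f"unknown exclusion rule {name!r}; known: {sorted(_RULE_BUILDERS)}"
            )
        rules.append(_RULE_BUILDERS[name](**kwargs))
    return rules


def default_diary_rules() -> list[ExclusionRule]:
    """Configurable surrogate for the per-night diary filters: duration
    bounds [4 h, 16 h], missing core items, latency > 180 min."""
    return build_rules(
        ["implausible_duration", "missing_items", "min_duration", "max_duration", "max_latency"]
    )


def default_panel_rules() -> list[ExclusionRule]:
    """Two-wave panel filters: missing mid-sleep items, short sleepers
    (mean duration < 4 h at either wave when duration columns exist), and
    retest intervals longer than 5 years."""
    rules = [
        ExclusionRule(
            "missing_items", "participant",
            lambda df: df[["msf_t1", "msf_t2", "msw_t1", "msw_t2"]].isna().any(axis=1),
            "missing mid-sleep at either wave",
        ),
        _rule_max_interval(5.0),
    ]
    return rules


def apply_exclusions(records: pd.DataFrame, rules: Sequence[ExclusionRule]):
    """Apply exclusion rules in order; return ``(kept, log)``.

    Rules are applied sequentially, each to the survivors of the previous
    one, so per-rule counts mirror a participant-flow diagram. The log has
    one row per removed record (rule name, scope, participant, and day index
    where present); ``kept`` plus logged rows partition the input. Applying
    the same rule set twice is a no-op.
    """
    kept = records
    log_rows = []
    for rule in rules:
        if kept.empty:
            break
        excl = rule.mask(kept)
        removed = kept.loc[excl]
        for idx, row in removed.iterrows():
            log_rows.append(
                {
                    "rule": rule.name,
                    "scope": rule.scope,
                    "participant_id": row.get("participant_id"),
                    "day_index": row.get("day_index", pd.NA),
                    "row": idx,
                }
            )
        kept = kept.loc[~excl]
    log = pd.DataFrame(log_rows, columns=["rule", "scope", "participant_id", "day_index", "row"])
    return kept, log


def response_rate(n_completed: int, n_possible: int) -> float:
    """Survey completion as a percentage of scheduled measurements."""
    if n_possible <= 0:
        raise ValidationError("n_possible must be positive")
    return 100.0 * n_completed / n_possible


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _read_csv(path, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{label} file {path} is missing columns: {missing}")
    return df


def read_diary_csv(path) -> pd.DataFrame:
    return _read_csv(path, DIARY_COLUMNS, "diary")


def read_mctq_csv(path) -> pd.DataFrame:
    return _read_csv(path, MCTQ_COLUMNS, "MCTQ")


def read_panel_csv(path) -> pd.DataFrame:
    return _read_csv(path, PANEL_COLUMNS, "panel")
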