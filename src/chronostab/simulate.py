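"""Seeded generators for diary, MCTQ-recall, and two-wave panel data.

The generators emulate the statistical structure the analyses assume so
every pipeline stage is testable without access-restricted data:

* ``simulate_diary`` — a 2-week experience-sampling diary: per-person latent
  chronotype (between-person SD ``sigma_b``), nightly Gaussian noise
  (``sigma_w``), fixed free-vs-workday shifts for the waking day and the
  previous day, optional correlated per-person random slopes, a weekly 5+2
  work schedule with a per-person phase (or a Bernoulli alternative), and
  independent night-level missingness. Diary items (lights-off, latency,
  wake time) are minute-resolution and derived so that scoring reproduces
  the generated mid-sleep exactly.
* ``simulate_mctq_recall`` — per-person questionnaire recall built from true
  diary day-type means plus Gaussian recall noise on onset and wake.
* ``simulate_panel`` — a two-wave MCTQ panel with an age-dependent retest
  correlation curve rho(age) (quadratic, clipped to [0, 0.999]) and a
  cross-measure correlation between mid-sleep on free and workdays.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd

from .records import format_clock_time
from .stability import t_transform_inverse

__all__ = [
    "DiarySimConfig",
    "PanelSimConfig",
    "SimulatedDiary",
    "simulate_diary",
    "simulate_mctq_recall",
    "simulate_panel",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _from_dict(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


@dataclass(frozen=True)
class DiarySimConfig:
    """Generative parameters of the diary study.

    Defaults reproduce the experience-sampling regime: 111 students over 14
    days (7 of them with 13 scheduled days), between-person SD 1.2 h,
    nightly noise SD 1.0 h, a dominant ~0.5 h free-day shift for the waking
    day plus a smaller previous-day shift, and 87.98% completion.
    """

    n_participants: int = 111
    n_days: int = 14
    n_short: int = 7          # participants scheduled for n_days - 1
    mu_mid: float = 5.0       # population mean mid-sleep, hours after midnight
    sigma_b: float = 1.2      # between-person SD of latent mid-sleep (h)
    sigma_w: float = 1.0      # within-person nightly SD (h)
    beta_today: float = 0.5   # free-minus-work shift, waking day (h)
    beta_yesterday: float = 0.15
    beta_interaction: float = 0.0
    sd_slope_today: float = 0.3
    sd_slope_yesterday: float = 0.2
    sd_slope_interaction: float = 0.0
    re_corr: float = 0.3      # common correlation among random effects
    mean_duration_h: float = 8.0
    sd_duration_between: float = 0.5
    sd_duration_within: float = 0.5
    latency_median_min: float = 15.0
    latency_log_sigma: float = 0.6
    schedule: str = "weekly"  # "weekly" (5+2 with per-person phase) | "bernoulli"
    p_workday: float = 5.0 / 7.0
    completion_rate: float = 0.8798
    seed: int = 0

    def __post_init__(self):
        sds = (self.sigma_b, self.sigma_w, self.sd_slope_today,
               self.sd_slope_yesterday, self.sd_slope_interaction,
               self.sd_duration_between, self.sd_duration_within)
        if any(s < 0 for s in sds):
            raise ConfigError("all SDs must be non-negative")
        if not (0.0 < self.completion_rate <= 1.0):
            raise ConfigError("completion_rate must be in (0, 1]")
        if self.schedule not in ("weekly", "bernoulli"):
            raise ConfigError("schedule must be 'weekly' or 'bernoulli'")
        if not (0 <= self.n_short <= self.n_participants):
            raise ConfigError("n_short must be in 0..n_participants")
        if abs(self.re_corr) >= 1:
            raise ConfigError("re_corr must be in (-1, 1)")

    @classmethod
    def from_dict(cls, mapping: dict) -> "DiarySimConfig":
        return _from_dict(cls, mapping)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PanelSimConfig:
    """Generative parameters of the two-wave panel.

    The retest correlation follows ``rho(age) = clip(a*age^2 + b*age + c,
    0, 0.999)``; ``curve_scale`` declares whether the quadratic lives on the
    correlation scale or on the t-transformed stability scale (in which case
    it is mapped back through the inverse transform). The default curve is
    sharply peaked at age 50 (rho = 0.75 - 0.0013*(age-50)^2 for mid-sleep
    on free days, peak 0.70 for workdays), expressing the sharp rise of
    stability from young adulthood to a middle-age peak and its later
    decline. Mid-sleep moments default to the panel's printed values.
    """

    n_participants: int = 681
    age_mean: float = 47.73
    age_sd: float = 15.89
    age_range: tuple = (18, 87)
    curve_msf: tuple = (-0.0013, 0.13, -2.5)     # a, b, c on rho scale
    curve_msw: tuple = (-0.0013, 0.13, -2.55)
    curve_scale: str = "correlation"             # or "t"
    msf_mean: tuple = (3.79, 3.71)
    msf_sd: tuple = (1.19, 1.18)
    msw_mean: tuple = (2.91, 2.92)
    msw_sd: tuple = (0.83, 0.89)
    cross_corr: float = 0.70                     # MSF-MSW correlation within wave
    interval_probs: tuple = (63, 220, 293, 54, 51)  # weights for 0-1..5 years
    p_female: float = 0.505
    education_probs: tuple = (0.101, 0.533, 0.366)
    seed: int = 0

    def __post_init__(self):
        if self.curve_scale not in ("correlation", "t"):
            raise ConfigError("curve_scale must be 'correlation' or 't'")
        if not (0 <= self.cross_corr < 1):
            raise ConfigError("cross_corr must be in [0, 1)")
        ages = np.arange(self.age_range[0], self.age_range[1] + 1, dtype=float)
        if self.curve_scale == "correlation":
            # negative excursions clip to 0, but a curve exceeding 1 anywhere
            # in the age range is not a correlation and is rejected outright
            for curve in (self.curve_msf, self.curve_msw):
                a, b, c = curve
                raw = a * ages**2 + b * ages + c
                if np.any(raw > 0.999):
                    raise ConfigError("stability curve exceeds 0.999 inside the age range")

    def _curve_values(self, curve, ages) -> np.ndarray:
        a, b, c = curve
        raw = a * np.asarray(ages, dtype=float) ** 2 + b * np.asarray(ages, dtype=float) + c
        if self.curve_scale == "t":
            # quadratic lives on the t-transformed scale; map back through
            # the inverse transform (t >= 0 <-> i12 in [0, 1])
            raw = t_transform_inverse(np.clip(raw, 0.0, 3.8))
        return np.clip(raw, 0.0, 0.999)

    def rho(self, ages, measure: str = "msf") -> np.ndarray:
        curve = self.curve_msf if measure == "msf" else self.curve_msw
        return self._curve_values(curve, ages)

    @classmethod
    def from_dict(cls, mapping: dict) -> "PanelSimConfig":
        mapping = dict(mapping)
        for key in ("curve_msf", "curve_msw", "age_range", "msf_mean", "msf_sd",
                    "msw_mean", "msw_sd", "interval_probs", "education_probs"):
            if key in mapping and isinstance(mapping[key], list):
                mapping[key] = tuple(mapping[key])
        return _from_dict(cls, mapping)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDiary:
    """Diary CSV table plus the latent truth used to generate it."""

    diary: pd.DataFrame
    nightly_truth: pd.DataFrame
    person_truth: pd.DataFrame
    n_scheduled: int


def _random_effects(cfg: DiarySimConfig, rng, n: int) -> np.ndarray:
    """Draw (intercept, slope_today, slope_yesterday, slope_interaction)
    with an exchangeable correlation among the non-degenerate terms."""
    sds = np.array([cfg.sigma_b, cfg.sd_slope_today, cfg.sd_slope_yesterday,
                    cfg.sd_slope_interaction])
    corr = np.full((4, 4), cfg.re_corr)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    # eigen factorization tolerates zero-variance rows
    vals, vecs = np.linalg.eigh(cov)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    return rng.standard_normal((n, 4)) @ root.T


def simulate_diary(cfg: DiarySimConfig | None = None, seed: int | None = None) -> SimulatedDiary:
    """Generate a diary table (raw CSV schema) with its latent truth.

    Nightly mid-sleep is latent chronotype + day-type effects (fixed and
    per-person random, on +-0.5 free/work contrasts) + Gaussian noise.
    Duration is drawn separately; onset and wake are back-computed, then
    lights-off/latency/wake are snapped to whole minutes and the recorded
    truth re-derived from the snapped items, so scoring the CSV reproduces
    ``mid_sleep_true`` exactly. Nights are then dropped independently with
    probability ``1 - completion_rate``.
    """
    cfg = cfg or DiarySimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_participants
    ids = [f"P{i + 1:03d}" for i in range(n)]
    days_per = np.full(n, cfg.n_days)
    if cfg.n_short:
        short = rng.choice(n, size=cfg.n_short, replace=False)
        days_per[short] = cfg.n_days - 1

    re = _random_effects(cfg, rng, n)
    chronotype = cfg.mu_mid + re[:, 0]
    dur_person = cfg.mean_duration_h + rng.normal(0, cfg.sd_duration_between, n)
    phase = rng.integers(0, 7, n)

    rows = []
    for i in range(n):
        nd = int(days_per[i])
        day_index = np.arange(1, nd + 1)
        if cfg.schedule == "weekly":
            dow = (day_index - 1 + phase[i]) % 7
            workday = dow < 5
        else:
            workday = rng.random(nd) < cfg.p_workday
        x_today = np.where(workday, -0.5, 0.5)
        # lag within the scheduled sequence; first scheduled day has no lag
        x_yest = np.empty(nd)
        x_yest[0] = np.nan
        x_yest[1:] = x_today[:-1]
        x_int = x_today * x_yest
        effects = (
            (cfg.beta_today + re[i, 1]) * x_today
            + np.nan_to_num((cfg.beta_yesterday + re[i, 2]) * x_yest)
            + np.nan_to_num((cfg.beta_interaction + re[i, 3]) * x_int)
        )
        mid = chronotype[i] + effects + rng.normal(0, cfg.sigma_w, nd)
        duration = np.clip(
            dur_person[i] + rng.normal(0, cfg.sd_duration_within, nd), 3.0, 14.0
        )
        onset = mid - duration / 2.0
        wake = mid + duration / 2.0
        latency_min = np.clip(
            np.round(np.exp(rng.normal(np.log(cfg.latency_median_min), cfg.latency_log_sigma, nd))),
            0, 120,
        )
        # snap diary items to whole minutes; re-derive the recorded truth
        lights_off = np.round((onset - latency_min / 60.0) * 60.0) / 60.0
        wake = np.round(wake * 60.0) / 60.0
        onset_rec = lights_off + latency_min / 60.0
        duration_rec = wake - onset_rec
        mid_rec = onset_rec + duration_rec / 2.0
        bed = lights_off - rng.integers(5, 60, nd) / 60.0
        alarm = np.where(workday, rng.random(nd) < 0.9, rng.random(nd) < 0.3)
        for k in range(nd):
            rows.append(
                {
                    "participant_id": ids[i],
                    "day_index": int(day_index[k]),
                    "bed_time": format_clock_time(bed[k]),
                    "lights_off": format_clock_time(lights_off[k]),
                    "latency_min": int(latency_min[k]),
                    "wake_time": format_clock_time(wake[k]),
                    "alarm": int(alarm[k]),
                    "workday_today": int(workday[k]),
                    "mid_sleep_true": mid_rec[k],
                    "onset_true": onset_rec[k],
                    "wake_true": wake[k],
                    "duration_true": duration_rec[k],
                }
            )
    nightly = pd.DataFrame(rows)
    n_scheduled = int(days_per.sum())
    keep = rng.random(len(nightly)) < cfg.completion_rate
    nightly = nightly.loc[keep].reset_index(drop=True)
    diary = nightly[
        ["participant_id", "day_index", "bed_time", "lights_off", "latency_min",
         "wake_time", "alarm", "workday_today"]
    ].copy()
    persons = pd.DataFrame(
        {
            "participant_id": ids,
            "chronotype": chronotype,
            "slope_today": re[:, 1],
            "slope_yesterday": re[:, 2],
            "slope_interaction": re[:, 3],
            "mean_duration": dur_person,
        }
    )
    return SimulatedDiary(diary=diary, nightly_truth=nightly,
                          person_truth=persons, n_scheduled=n_scheduled)


def simulate_mctq_recall(
    nightly_truth: pd.DataFrame,
    recall_noise_sd_h: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Build an MCTQ table from per-person diary day-type means plus recall noise.

    Onset and wake each receive independent Gaussian noise with SD
    ``sqrt(2) * recall_noise_sd_h`` so the implied mid-sleep recall error has
    SD ``recall_noise_sd_h``. Participants without both day types are
    flagged (items left missing).
    """
    if recall_noise_sd_h < 0:
        raise ConfigError("recall noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    item_sd = np.sqrt(2.0) * recall_noise_sd_h
    for pid, sub in nightly_truth.groupby("participant_id", sort=True):
        work = sub[sub["workday_today"] == 1]
        free = sub[sub["workday_today"] == 0]
        row = {"participant_id": pid,
               "workdays_per_week": int(round(7.0 * len(work) / len(sub)))}
        if len(work) == 0 or len(free) == 0:
            row.update({c: np.nan for c in ("w_lights_off", "w_latency_min", "w_wake",
                                            "f_lights_off", "f_latency_min", "f_wake")})
            row["incomplete_schedule"] = True
        else:
            for prefix, part in (("w", work), ("f", free)):
                onset = part["onset_true"].mean() + rng.normal(0, item_sd)
                wake = part["wake_true"].mean() + rng.normal(0, item_sd)
                latency = float(np.round(part["latency_min"].mean()))
                row[f"{prefix}_lights_off"] = format_clock_time(onset - latency / 60.0)
                row[f"{prefix}_latency_min"] = latency
                row[f"{prefix}_wake"] = format_clock_time(wake)
            row["incomplete_schedule"] = False
        rows.append(row)
    cols = ["participant_id", "w_lights_off", "w_latency_min", "w_wake",
            "f_lights_off", "f_latency_min", "f_wake", "workdays_per_week",
            "incomplete_schedule"]
    return pd.DataFrame(rows)[cols]


def simulate_panel(cfg: PanelSimConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate a two-wave panel table on the panel CSV schema.

    Per participant: age from a truncated normal, retest interval from the
    configured weights, standardized T1 scores for MSF and MSW correlated at
    ``cross_corr``, T2 scores built as ``rho(age) * z1 + sqrt(1 - rho^2) * e``
    with the T2 innovations sharing the same cross-measure correlation, then
    rescaled to the configured means and SDs.
    """
    cfg = cfg or PanelSimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_participants
    lo, hi = cfg.age_range
    age = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.age_mean, cfg.age_sd, 2 * n)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        age[filled:filled + take] = draw[:take]
        filled += take
    age = np.floor(age).astype(int)

    probs = np.asarray(cfg.interval_probs, dtype=float)
    probs = probs / probs.sum()
    interval = rng.choice(np.arange(1, 6), size=n, p=probs)

    lam = cfg.cross_corr
    mix = np.array([[1.0, 0.0], [lam, np.sqrt(1.0 - lam * lam)]])
    base_t1 = rng.standard_normal((n, 2)) @ mix.T  # columns: msf, msw
    innov = rng.standard_normal((n, 2)) @ mix.T

    rho_f = cfg.rho(age, "msf")
    rho_w = cfg.rho(age, "msw")
    z1_f, z1_w = base_t1[:, 0], base_t1[:, 1]
    z2_f = rho_f * z1_f + np.sqrt(1.0 - rho_f ** 2) * innov[:, 0]
    z2_w = rho_w * z1_w + np.sqrt(1.0 - rho_w ** 2) * innov[:, 1]

    sex = np.where(rng.random(n) < cfg.p_female, "F", "M")
    education = rng.choice(
        ["basic", "secondary", "higher"], size=n, p=np.asarray(cfg.education_probs)
    )
    panel = pd.DataFrame(
        {
            "participant_id": [f"B{i + 1:04d}" for i in range(n)],
            "age_t1": age,
            "sex": sex,
            "education": education,
            "interval_years": interval,
            "msf_t1": cfg.msf_mean[0] + cfg.msf_sd[0] * z1_f,
            "msf_t2": cfg.msf_mean[1] + cfg.msf_sd[1] * z2_f,
            "msw_t1": cfg.msw_mean[0] + cfg.msw_sd[0] * z1_w,
            "msw_t2": cfg.msw_mean[1] + cfg.msw_sd[1] * z2_w,
        }
    )
    return panel
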