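"""Survey-style synthetic forager records for central-place supermarket trips.

Generates tables with the statistical structure the downstream analysis
assumes: every trip shares one gain curve; each forager's true round-trip
travel time is drawn from a bounded distribution; the true residence time is
the MVT optimum for that travel time; and the *reported* times and gains are
the true values plus independent Gaussian reporting error, rounded to the
granularity people use when answering a survey ("about 10 minutes",
"around 12.50 Euro"). Context attributes (main-patch flag, trip type,
transport mode, demographics) are drawn from configurable mixtures so the
subset filters and categorization steps can be exercised, and key fields can
be blanked to exercise the exclusion rule.

The generator emulates reporting noise and rounding, not within-store
movement: records are independent and the errors are isotropic Gaussian,
which is exactly the assumption under which orthogonal residuals are the
natural fit criterion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import GainCurve, gain, solve_residence_time

__all__ = [
    "SimulationConfig",
    "simulate_foragers",
    "plateau_gain",
    "write_survey",
    "KEY_FIELDS",
]

#: The three fields whose absence triggers the exclusion rule downstream.
KEY_FIELDS = ("gain_euro", "travel_time_min", "patch_time_min")

#: Reported times are floored here: a respondent never reports a zero or
#: negative number of minutes.
MIN_REPORT_MIN = 1.0

#: Free-form shopping-frequency answers the generator can emit, with draw
#: probabilities. Strings mirror the vagueness of real survey answers.
_FREQ_CHOICES: tuple[tuple[str, float], ...] = (
    ("less than once a week", 0.10),
    ("once a week", 0.20),
    ("twice a week", 0.20),
    ("2-3 times a week", 0.10),
    ("3 or 4 times a week", 0.20),
    ("5 or 6 times a week", 0.12),
    ("daily", 0.08),
)

_WORK_STATUS = (
    ("student", 0.353),
    ("employed_full_time", 0.347),
    ("employed_part_time", 0.079),
    ("retired", 0.074),
    ("pupil", 0.042),
    ("self_employed", 0.021),
    ("trainee", 0.021),
    ("other", 0.063),
)

_GENDER = (("male", 0.578), ("female", 0.406), ("nonbinary", 0.011), ("agender", 0.005))

_HOUSEHOLD = ((1, 0.45), (2, 0.35), (3, 0.12), (4, 0.06), (5, 0.02))

_GROUP_SIZE = ((1, 0.75), (2, 0.20), (3, 0.05))


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic survey generator.

    Defaults describe a single urban supermarket patch: a shared gain curve
    with asymptote ``A_true`` = 60 Euro and initial rate ``k_true`` =
    0.08/min, round-trip travel times log-normally distributed and truncated
    to [2, 20] minutes, reporting error of 2 min on both times and 5 Euro on
    spend, and answers rounded to 1 minute / 0.50 Euro. The filter-attribute
    probabilities give an expected analysable-subset fraction of roughly a
    third of the sample.
    """

    A_true: float = 60.0          # Euro
    k_true: float = 0.08          # 1/min
    n: int = 190
    # true round-trip travel time distribution (positive minutes)
    travel_family: str = "lognormal"   # {lognormal | uniform}
    travel_mu: float = 2.1             # log-minutes (lognormal) / lower bound (uniform)
    travel_sigma: float = 0.55         # log-sd (lognormal) / upper bound (uniform)
    travel_lo: float = 2.0             # truncation bounds, minutes
    travel_hi: float = 20.0
    # gain-curve shape used for the truth
    curve_shape: str = "exponential"   # {exponential | plateau}
    plateau_slope: float = 2.5         # Euro/min, plateau shape only
    plateau_T: float = 20.0            # min, plateau corner
    plateau_jitter_sd: float = 1.0     # min, sd of residence-time jitter at the corner
    # reporting error (sd of additive Gaussian noise)
    sigma_T: float = 2.0               # min, patch residence time
    sigma_t: float = 2.0               # min, travel time
    sigma_g: float = 5.0               # Euro, gain
    # reporting granularity (0 disables rounding)
    round_T: float = 1.0               # min
    round_t: float = 1.0               # min
    round_g: float = 0.5               # Euro
    # filter attributes
    p_main_patch: float = 0.70
    p_home_roundtrip: float = 0.70
    p_foot: float = 0.65
    # demographics
    age_mean: float = 35.5             # years
    age_sd: float = 15.9
    age_lo: float = 18.0
    age_hi: float = 90.0
    p_exhausted: float = 0.20
    mean_item_price: float = 2.5       # Euro, converts gain to a product count
    # missingness of the three key fields (independent per field)
    p_missing_key: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("sigma_T", "sigma_t", "sigma_g", "round_T", "round_t", "round_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_main_patch", "p_home_roundtrip", "p_foot", "p_exhausted",
                     "p_missing_key"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.travel_family not in ("lognormal", "uniform"):
            raise ValueError(f"unknown travel distribution family {self.travel_family!r}")
        if self.curve_shape not in ("exponential", "plateau"):
            raise ValueError(f"unknown curve shape {self.curve_shape!r}")
        if not 0 < self.travel_lo < self.travel_hi:
            raise ValueError("require 0 < travel_lo < travel_hi")
        if self.curve_shape == "plateau" and not (
            self.plateau_slope > 0 and self.plateau_T > 0
        ):
            raise ValueError("plateau shape needs plateau_slope > 0 and plateau_T > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def plateau_gain(slope: float, plateau_T: float, T):
    """Piecewise-linear feedback curve: ``slope * min(T, plateau_T)``.

    Linear accumulation until the patch's shelf runs out at ``plateau_T``,
    then flat. Used only as an alternative truth when probing robustness of
    the exponential fit.
    """
    if not slope > 0:
        raise ValueError("slope must be > 0")
    if not plateau_T > 0:
        raise ValueError("plateau_T must be > 0")
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("T must be >= 0")
    out = slope * np.minimum(T, plateau_T)
    return float(out) if out.ndim == 0 else out


def _draw_travel_times(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Positive true round-trip travel times, truncated to [lo, hi] by rejection."""
    out = np.empty(cfg.n)
    filled = 0
    while filled < cfg.n:
        m = max(cfg.n - filled, 16)
        if cfg.travel_family == "lognormal":
            draw = rng.lognormal(cfg.travel_mu, cfg.travel_sigma, size=2 * m)
        else:
            draw = rng.uniform(cfg.travel_mu, cfg.travel_sigma, size=2 * m)
        draw = draw[(draw >= cfg.travel_lo) & (draw <= cfg.travel_hi)]
        take = min(draw.size, cfg.n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _categorical(rng, table, size):
    vals = [v for v, _ in table]
    probs = np.array([p for _, p in table])
    return rng.choice(vals, p=probs / probs.sum(), size=size)


def _round_to(x: np.ndarray, step: float) -> np.ndarray:
    return np.round(x / step) * step if step > 0 else x


def simulate_foragers(config: SimulationConfig) -> pd.DataFrame:
    """Generate one survey table of forager records.

    Returns a DataFrame with one row per shopping trip and the documented
    survey columns; missing values are ``NaN``. Generation bookkeeping
    (true parameter values, count of records with a blanked key field) is
    attached in ``df.attrs`` so tests can cross-check downstream accounting.
    Identical config and seed give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    t_true = _draw_travel_times(config, rng)          # positive minutes
    if config.curve_shape == "exponential":
        curve = GainCurve(config.A_true, config.k_true)
        T_true = np.asarray(solve_residence_time(curve, -t_true))
        g_true = np.asarray(gain(curve, T_true))
    else:
        # For a linear-plateau truth the tangent optimum sits at the corner
        # for every negative travel time (marginal gain drops from `slope`
        # to zero there), so true residence times cluster at the corner.
        T_true = config.plateau_T + rng.normal(0.0, config.plateau_jitter_sd, n)
        T_true = np.maximum(T_true, 0.1 * config.plateau_T)
        g_true = np.asarray(plateau_gain(config.plateau_slope, config.plateau_T, T_true))

    T_rep = T_true + rng.normal(0.0, config.sigma_T, n)
    t_rep = t_true + rng.normal(0.0, config.sigma_t, n)
    g_rep = g_true + rng.normal(0.0, config.sigma_g, n)
    T_rep = np.maximum(_round_to(T_rep, config.round_T), MIN_REPORT_MIN)
    t_rep = np.maximum(_round_to(t_rep, config.round_t), MIN_REPORT_MIN)
    g_rep = np.maximum(_round_to(g_rep, config.round_g), 0.0)

    n_products = rng.poisson(np.maximum(g_true, 0.0) / config.mean_item_price) + 1

    main_patch = rng.random(n) < config.p_main_patch
    home_rt = rng.random(n) < config.p_home_roundtrip
    trip_type = np.where(
        home_rt, "home_roundtrip", np.where(rng.random(n) < 0.5, "en_route", "other")
    )
    foot = rng.random(n) < config.p_foot
    transport = np.where(
        foot,
        "foot",
        _categorical(rng, (("bike", 0.35), ("car", 0.45), ("public", 0.20)), n),
    )

    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), config.age_lo, config.age_hi
    ).round(0)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "travel_time_min": t_rep,
            "patch_time_min": T_rep,
            "gain_euro": g_rep,
            "n_products": n_products,
            "main_patch": main_patch,
            "trip_type": trip_type,
            "transport": transport,
            "shop_freq_raw": _categorical(rng, _FREQ_CHOICES, n),
            "household_n": _categorical(rng, _HOUSEHOLD, n).astype(int),
            "group_size": _categorical(rng, _GROUP_SIZE, n).astype(int),
            "age": age,
            "gender": _categorical(rng, _GENDER, n),
            "work_status": _categorical(rng, _WORK_STATUS, n),
            "exhaustion": rng.random(n) < config.p_exhausted,
        }
    )

    # Blank key fields independently; the exclusion rule drops a record when
    # any of the three is missing.
    missing_any = np.zeros(n, dtype=bool)
    for col in KEY_FIELDS:
        mask = rng.random(n) < config.p_missing_key
        df.loc[mask, col] = np.nan
        missing_any |= mask

    df.attrs["simulation"] = {
        "A_true": config.A_true,
        "k_true": config.k_true,
        "curve_shape": config.curve_shape,
        "n_missing_key": int(missing_any.sum()),
        "n_complete": int(n - missing_any.sum()),
        "seed": config.seed,
    }
    return df


def write_survey(df: pd.DataFrame, path: str | Path) -> None:
    """Write records as UTF-8 CSV with a header row; blanks mark missing."""
    df.to_csv(path, index=False, na_rep="", encoding="utf-8")
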