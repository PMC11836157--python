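"""Reading survey CSVs, exclusion rules, subset selection and categorization.

The analysable subset keeps foragers for whom the single-patch MVT model is
cleanly interpretable: they (a) mainly shop at the surveyed supermarket (so
they know the patch), (b) travel from home to the patch and back (a true
central-place round trip), and (c) travel by foot (so time is a commensurate
cost measure). Records missing any of gain, travel time or patch residence
time are excluded before any filtering.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyFormatError",
    "SubsetReport",
    "read_survey",
    "exclude_incomplete",
    "select_mvt_subset",
    "categorize",
    "median_split",
    "KEY_COLUMNS",
    "MANDATORY_COLUMNS",
]

KEY_COLUMNS = ("gain_euro", "travel_time_min", "patch_time_min")
FILTER_COLUMNS = ("main_patch", "trip_type", "transport")
MANDATORY_COLUMNS = KEY_COLUMNS + FILTER_COLUMNS

#: Column dropped on read: objective distance estimates had too little
#: uptake to be analysable and never enter the pipeline.
DISTANCE_COLUMNS = ("distance_km_est", "distance_km_maps")

_NUMERIC_COLUMNS = (
    "travel_time_min",
    "patch_time_min",
    "gain_euro",
    "n_products",
    "household_n",
    "group_size",
    "age",
)
_BOOL_COLUMNS = ("main_patch", "exhaustion")

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


class SurveyFormatError(ValueError):
    """Raised when a survey CSV does not match the documented layout."""


def read_survey(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a survey CSV into a typed record table.

    Blanks become NaN; unknown columns are preserved untouched as opaque
    extras. ``column_map`` optionally renames deposit-specific column names
    to the documented ones before validation (useful for externally
    deposited tables).

    Raises
    ------
    SurveyFormatError
        If a mandatory column is absent (the error names the missing ones)
        or a numeric cell cannot be parsed (the error lists row indices).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if column_map:
        df = df.rename(columns=column_map)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"missing mandatory columns: {missing}")

    for col in DISTANCE_COLUMNS:
        if col in df.columns:
            logger.info("dropping distance column %r before analysis", col)
            df = df.drop(columns=col)

    df = df.replace({"": None})

    bad: list[tuple[int, str, str]] = []
    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        broken = parsed.isna() & df[col].notna()
        for idx in df.index[broken]:
            bad.append((int(idx), col, str(df.at[idx, col])))
        df[col] = parsed
    if bad:
        lines = "; ".join(f"row {r}, column {c}: {v!r}" for r, c, v in bad)
        raise SurveyFormatError(f"malformed numeric cells: {lines}")

    for col in _BOOL_COLUMNS:
        if col not in df.columns:
            continue
        low = df[col].map(lambda v: v.strip().lower() if isinstance(v, str) else v)
        unknown = low.dropna()[~low.dropna().isin(_TRUE | _FALSE)]
        if len(unknown):
            rows = ", ".join(str(i) for i in unknown.index[:10])
            raise SurveyFormatError(
                f"column {col!r}: unrecognized boolean values at rows {rows}"
            )
        df[col] = low.map(lambda v: None if v is None else v in _TRUE)
    return df


def exclude_incomplete(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, excluded) by the key-field completeness rule.

    A record is excluded iff any of gain, travel time or patch residence
    time is missing. The two frames partition the input (indices preserved).
    """
    missing = records[list(KEY_COLUMNS)].isna().any(axis=1)
    return records[~missing].copy(), records[missing].copy()


@dataclass
class SubsetReport:
    """Attrition accounting for the exclusion and subset filters.

    The filters are applied in a fixed order purely so that the per-filter
    drop counts are reproducible; the final subset itself is a conjunction
    and does not depend on the order.
    """

    n_input: int
    n_excluded_incomplete: int
    n_after_exclusion: int
    drop_not_main_patch: int
    drop_not_home_roundtrip: int
    drop_not_foot: int
    n_subset: int
    filter_order: tuple[str, ...] = ("incomplete", "main_patch", "home_roundtrip", "foot")

    def __post_init__(self) -> None:
        assert self.n_input == self.n_excluded_incomplete + self.n_after_exclusion
        assert (
            self.n_after_exclusion
            - self.drop_not_main_patch
            - self.drop_not_home_roundtrip
            - self.drop_not_foot
            == self.n_subset
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__ | {"filter_order": list(self.filter_order)}, fh,
                      indent=2, sort_keys=True)


def select_mvt_subset(records: pd.DataFrame) -> tuple[pd.DataFrame, SubsetReport]:
    """Select the analysable MVT subset with per-filter attrition accounting.

    Input should already have passed :func:`exclude_incomplete`; records
    with a missing key field are excluded here again (idempotence) and
    counted as incomplete.
    """
    kept, excluded = exclude_incomplete(records)
    n_input = len(records)

    m_main = kept["main_patch"].fillna(False).astype(bool)
    after_a = kept[m_main]
    m_home = after_a["trip_type"] == "home_roundtrip"
    after_b = after_a[m_home]
    m_foot = after_b["transport"] == "foot"
    subset = after_b[m_foot].copy()

    report = SubsetReport(
        n_input=n_input,
        n_excluded_incomplete=len(excluded),
        n_after_exclusion=len(kept),
        drop_not_main_patch=int((~m_main).sum()),
        drop_not_home_roundtrip=int((~m_home).sum()),
        drop_not_foot=int((~m_foot).sum()),
        n_subset=len(subset),
    )
    logger.info(
        "subset selection: %d -> %d complete -> %d in MVT subset",
        n_input, report.n_after_exclusion, report.n_subset,
    )
    return subset, report


# --- categorization ---------------------------------------------------------

#: Fixed, documented bin edges. The source data do not print exact
#: cut-points, so these are package defaults; change them via the arguments
#: of :func:`categorize`.
FREQ_LABELS = ("<1/wk", "1-2/wk", "3-4/wk", "5+/wk")
HOUSEHOLD_LABELS = ("1", "2", ">2")
AGE_BINS = ((18, 29), (30, 49), (50, 200))
AGE_LABELS = ("18-29", "30-49", "50+")

_FREQ_WORDS = {
    "once": 1, "twice": 2, "one": 1, "two": 2, "three": 3, "four": 4,
    "five": 5, "six": 6, "seven": 7, "daily": 7, "everyday": 7,
}


def _parse_frequency(raw: object) -> float | None:
    """Times-per-week from a free-form frequency report, or None."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip().lower()
    if not s:
        return None
    if "daily" in s or "every day" in s or "everyday" in s:
        return 7.0
    less = "less than" in s or "fewer than" in s
    nums = [float(x) for x in re.findall(r"\d+(?:\.\d+)?", s)]
    if not nums:
        nums = [float(v) for w, v in _FREQ_WORDS.items() if re.search(rf"\b{w}\b", s)]
    if not nums:
        logger.warning("unparseable shopping-frequency report %r -> missing", raw)
        return None
    per_week = sum(nums) / len(nums)   # "3 or 4 times" -> 3.5
    if "month" in s:
        per_week /= 4.0
    if "day" in s and "week" not in s:
        per_week *= 7.0
    if less:
        per_week -= 0.5
    return per_week


def _freq_category(per_week: float | None) -> str | None:
    if per_week is None:
        return None
    if per_week < 1:
        return FREQ_LABELS[0]
    if per_week < 3:   # 1-2 per week
        return FREQ_LABELS[1]
    if per_week < 5:   # 3-4 per week
        return FREQ_LABELS[2]
    return FREQ_LABELS[3]


def _household_category(n: float | None) -> str | None:
    if n is None or (isinstance(n, float) and np.isnan(n)):
        return None
    return HOUSEHOLD_LABELS[0] if n <= 1 else HOUSEHOLD_LABELS[1] if n <= 2 else HOUSEHOLD_LABELS[2]


def _age_category(age: float | None) -> str | None:
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return None
    for (lo, hi), label in zip(AGE_BINS, AGE_LABELS):
        if lo <= age <= hi:
            return label
    return None


def categorize(records: pd.DataFrame) -> pd.DataFrame:
    """Add category columns and 0/1 dummy columns for the survey attributes.

    Shopping frequency is parsed from the free-form report and binned to
    {<1/wk, 1-2/wk, 3-4/wk, 5+/wk}; household size to {1, 2, >2}; age to
    {18-29, 30-49, 50+}. Each category variable (including trip type,
    transport, gender, work status and the boolean flags) is expanded into
    dummy columns named ``<var>__<level>``; rows whose source value is
    missing get NaN dummies. The input frame is not modified.
    """
    df = records.copy()
    if "shop_freq_raw" in df.columns:
        df["shop_freq_cat"] = df["shop_freq_raw"].map(
            lambda v: _freq_category(_parse_frequency(v))
        )
    if "household_n" in df.columns:
        df["household_cat"] = df["household_n"].map(_household_category)
    if "age" in df.columns:
        df["age_cat"] = df["age"].map(_age_category)

    cat_vars = [
        c for c in (
            "shop_freq_cat", "household_cat", "age_cat", "trip_type",
            "transport", "gender", "work_status",
        ) if c in df.columns
    ]
    for var in cat_vars:
        dummies = pd.get_dummies(df[var], prefix=var, prefix_sep="__", dtype=float)
        miss = df[var].isna()
        dummies.loc[miss, :] = np.nan
        df = pd.concat([df, dummies], axis=1)
    for var in ("main_patch", "exhaustion", "group_size"):
        if var not in df.columns:
            continue
        if var == "group_size":
            df[f"{var}__alone"] = (df[var] == 1).astype(float)
            df.loc[df[var].isna(), f"{var}__alone"] = np.nan
        else:
            df[f"{var}__true"] = df[var].astype(float)
    return df


def median_split(values) -> np.ndarray:
    """Dichotomize at the sample median: value <= median -> "low", else "high".

    Missing values stay unlabeled (None). Ties at the median go to "low".
    Requires at least two non-missing values.
    """
    arr = np.asarray(pd.to_numeric(pd.Series(values), errors="raise"), dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        raise ValueError("median_split needs at least 2 non-missing values")
    med = np.median(arr[finite])
    labels = np.where(arr <= med, "low", "high").astype(object)
    labels[~finite] = None
    return labels
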