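"""Common axes and gridded containers.

Every population-level quantity in the projection lives on the same grid:
single-year ages 30..99 crossed with sex.  Arrays are indexed
``[sex, age]`` with sex 0 = male, 1 = female and age offset ``age - 30``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

AGE_MIN = 30
AGE_MAX = 99
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = AGES.size
SEXES = ("male", "female")
N_SEXES = 2

# decade bands used in rendered projection tables
AGE_GROUPS = tuple((lo, lo + 9) for lo in range(30, 100, 10))


def age_group_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise ValidationError(f"unknown sex label {sex!r}; expected one of {SEXES}") from None


def validate_age_sex_grid(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != (N_SEXES, N_AGES):
        raise ValidationError(
            f"{name} must have shape {(N_SEXES, N_AGES)} (sex x single-year age 30..99), "
            f"got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite cells")
    return arr


@dataclass(frozen=True)
class CostSurface:
    """Chronic management cost per person-year, by sex x single-year age x follow-up year.

    ``values[s, a, f]`` is the annual cost (AUD/person-year) for sex ``s``,
    age ``30 + a``, follow-up year ``f + 1``; the final slot is carried
    forward for anyone beyond ``n_follow_up`` years since their MI (the
    "K+" tunnel cap).
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[:2] != (N_SEXES, N_AGES) or v.shape[2] < 1:
            raise ValidationError(
                f"cost surface must have shape (2, {N_AGES}, K>=1), got {v.shape}"
            )
        if not np.all(np.isfinite(v)) or np.any(v <= 0.0):
            raise ValidationError("cost surface cells must all be finite and > 0")
        object.__setattr__(self, "values", v)

    @property
    def n_follow_up(self) -> int:
        return self.values.shape[2]

    def to_frame(self) -> pd.DataFrame:
        s, a, f = np.meshgrid(
            np.arange(N_SEXES), AGES, np.arange(1, self.n_follow_up + 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                "sex": np.asarray(SEXES)[s.ravel()],
                "age": a.ravel(),
                "follow_up_year": f.ravel(),
                "cost": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CostSurface":
        required = {"sex", "age", "follow_up_year", "cost"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"cost surface table missing column(s): {sorted(missing)}")
        k = int(frame["follow_up_year"].max())
        values = np.full((N_SEXES, N_AGES, k), np.nan)
        if frame.duplicated(["sex", "age", "follow_up_year"]).any():
            dup = frame[frame.duplicated(["sex", "age", "follow_up_year"])].iloc[0]
            raise FormatError(
                f"duplicate cost surface key (sex={dup['sex']}, age={dup['age']}, "
                f"follow_up_year={dup['follow_up_year']})"
            )
        for _, row in frame.iterrows():
            values[sex_index(row["sex"]), int(row["age"]) - AGE_MIN, int(row["follow_up_year"]) - 1] = row["cost"]
        if np.isnan(values).any():
            n_missing = int(np.isnan(values).sum())
            raise ValidationError(f"cost surface grid incomplete: {n_missing} missing cell(s)")
        return cls(values=values)
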