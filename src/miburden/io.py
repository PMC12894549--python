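"""Delimited-text input/output for cohort and projection tables.

All tables are UTF-8 CSV with a header row; write/read round-trips preserve
values to full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .grids import AGES, AGE_MIN, CostSurface, N_AGES, N_SEXES, SEXES
from .markov import TransitionRates
from .synthetic import ProjectionInputs

COHORT_COLUMNS = (
    "person_id", "age_band", "age_mid", "sex", "mi_type", "diabetes",
    "hypertension", "irsd_quintile", "follow_up_year", "annual_cost",
    "person_years",
)
RATE_COLUMNS = ("sex", "age", "incidence", "mortality_other", "mortality_post_mi", "p_fatal")

_NUMERIC_COHORT = ("age_mid", "diabetes", "hypertension", "irsd_quintile",
                   "follow_up_year", "annual_cost", "person_years")


def _require_columns(frame: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{what} missing column(s): {missing}")


def _numeric(frame: pd.DataFrame, columns, what: str) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{what} column {col!r} has non-numeric value "
                f"{frame[col].iloc[row]!r} at row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise FormatError(f"{what} column {col!r} has a missing value at row {row}")
        frame[col] = coerced
    return frame


def write_cohort(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, COHORT_COLUMNS, "cohort table")
    frame = _numeric(frame, _NUMERIC_COHORT, "cohort table")
    if (frame["annual_cost"] < 0).any():
        row = int(frame.index[frame["annual_cost"] < 0][0])
        raise ValidationError(f"cohort table has negative annual_cost at row {row}")
    bad_py = ~((frame["person_years"] > 0) & (frame["person_years"] <= 1))
    if bad_py.any():
        row = int(frame.index[bad_py][0])
        raise ValidationError(f"cohort table person_years outside (0, 1] at row {row}")
    return frame


def rates_to_frame(rates: TransitionRates) -> pd.DataFrame:
    s, a = np.meshgrid(np.arange(N_SEXES), AGES, indexing="ij")
    return pd.DataFrame(
        {
            "sex": np.asarray(SEXES)[s.ravel()],
            "age": a.ravel(),
            "incidence": rates.incidence.ravel(),
            "mortality_other": rates.mortality_other.ravel(),
            "mortality_post_mi": rates.mortality_post_mi.ravel(),
            "p_fatal": rates.p_fatal.ravel(),
        }
    )


def frame_to_rates(frame: pd.DataFrame) -> TransitionRates:
    _require_columns(frame, RATE_COLUMNS, "rate table")
    frame = _numeric(frame.copy(), RATE_COLUMNS[2:] + ("age",), "rate table")
    if frame.duplicated(["sex", "age"]).any():
        dup = frame[frame.duplicated(["sex", "age"])].iloc[0]
        raise FormatError(f"duplicate rate table key (sex={dup['sex']}, age={int(dup['age'])})")
    grids = {c: np.full((N_SEXES, N_AGES), np.nan) for c in RATE_COLUMNS[2:]}
    for _, row in frame.iterrows():
        try:
            si = SEXES.index(row["sex"])
        except ValueError:
            raise FormatError(f"rate table has unknown sex label {row['sex']!r}") from None
        ai = int(row["age"]) - AGE_MIN
        if not 0 <= ai < N_AGES:
            raise ValidationError(f"rate table age {int(row['age'])} outside 30..99")
        for c in grids:
            grids[c][si, ai] = row[c]
    incomplete = [c for c, g in grids.items() if np.isnan(g).any()]
    if incomplete:
        raise ValidationError(f"rate table grid incomplete for column(s): {incomplete}")
    return TransitionRates(
        incidence=grids["incidence"],
        mortality_other=grids["mortality_other"],
        mortality_post_mi=grids["mortality_post_mi"],
        p_fatal=grids["p_fatal"],
    )


def write_rates(rates: TransitionRates, path) -> None:
    rates_to_frame(rates).to_csv(path, index=False)


def read_rates(path) -> TransitionRates:
    return frame_to_rates(pd.read_csv(path))


def write_surface(surface: CostSurface, path) -> None:
    surface.to_frame().to_csv(path, index=False)


def read_surface(path) -> CostSurface:
    return CostSurface.from_frame(pd.read_csv(path))


def write_projection_inputs(inputs: ProjectionInputs, out_dir) -> None:
    """Serialize a full input set to a directory of CSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s, a = np.meshgrid(np.arange(N_SEXES), AGES, indexing="ij")
    pd.DataFrame(
        {
            "sex": np.asarray(SEXES)[s.ravel()],
            "age": a.ravel(),
            "population": inputs.initial_population.ravel(),
            "mi_prevalence": inputs.mi_prevalence.ravel(),
            "net_migration": inputs.net_migration.ravel(),
        }
    ).to_csv(out / "population.csv", index=False)
    write_rates(inputs.rates, out / "rates.csv")
    write_surface(inputs.chronic_surface, out / "chronic_surface.csv")
    manifest = {
        "entry_cohort": {s: float(v) for s, v in zip(SEXES, inputs.entry_cohort)},
        "acute_unit_cost": float(inputs.acute_unit_cost),
        "meta": inputs.meta,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_projection_inputs(in_dir) -> ProjectionInputs:
    src = Path(in_dir)
    pop_frame = pd.read_csv(src / "population.csv")
    _require_columns(pop_frame, ("sex", "age", "population", "mi_prevalence", "net_migration"),
                     "population table")
    pop_frame = _numeric(pop_frame, ("age", "population", "mi_prevalence", "net_migration"),
                         "population table")
    if pop_frame.duplicated(["sex", "age"]).any():
        dup = pop_frame[pop_frame.duplicated(["sex", "age"])].iloc[0]
        raise FormatError(
            f"duplicate population key (sex={dup['sex']}, age={int(dup['age'])})"
        )
    grids = {c: np.full((N_SEXES, N_AGES), np.nan)
             for c in ("population", "mi_prevalence", "net_migration")}
    for _, row in pop_frame.iterrows():
        si = SEXES.index(row["sex"])
        ai = int(row["age"]) - AGE_MIN
        for c in grids:
            grids[c][si, ai] = row[c]
    incomplete = [c for c, g in grids.items() if np.isnan(g).any()]
    if incomplete:
        raise ValidationError(f"population grid incomplete for column(s): {incomplete}")
    manifest = json.loads((src / "manifest.json").read_text())
    inputs = ProjectionInputs(
        initial_population=grids["population"],
        mi_prevalence=grids["mi_prevalence"],
        rates=read_rates(src / "rates.csv"),
        net_migration=grids["net_migration"],
        entry_cohort=np.array([manifest["entry_cohort"][s] for s in SEXES]),
        acute_unit_cost=manifest["acute_unit_cost"],
        chronic_surface=read_surface(src / "chronic_surface.csv"),
        meta=manifest.get("meta", {}),
    )
    inputs.validate()
    return inputs
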