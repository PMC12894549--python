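"""Rendering of estimate and projection tables to CSV and Markdown."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .costing import ProjectionCostResult
from .psa import PSAResult

__all__ = [
    "projection_table",
    "scenario_table",
    "frame_to_markdown",
    "render_tables",
]

_COMPONENTS = ("acute", "chronic", "total")


def _psa_lookup(psa: PSAResult, quantity: str):
    table = psa.quantities.set_index("quantity")
    if quantity not in table.index:
        raise ValidationError(f"PSA result lacks uncertainty for quantity {quantity!r}")
    row = table.loc[quantity]
    return float(row["ui_lb"]), float(row["ui_ub"])


def projection_table(
    result: ProjectionCostResult, component: str, psa: PSAResult | None = None
) -> pd.DataFrame:
    """Age-group x sex table for one cost component, with UI columns when PSA given.

    Rows are decade bands 30-39 .. 90-99 plus a Total row, for male, female
    and the total population.  ``n`` is the component's own count base
    (acute-costed events for acute, MI person-years for chronic, their sum
    for total).
    """
    if component not in _COMPONENTS:
        raise ValidationError(f"component must be one of {_COMPONENTS}")
    groups = result.by_age_group()
    n = groups["acute_n"] if component == "acute" else (
        groups["chronic_n"] if component == "chronic"
        else groups["acute_n"] + groups["chronic_n"]
    )
    out = pd.DataFrame(
        {
            "sex": groups["sex"],
            "age_group": groups["age_group"],
            "n": n,
            "cost": groups[component],
        }
    )
    if psa is not None:
        bounds = [
            _psa_lookup(psa, _group_quantity(component, s, g))
            for s, g in zip(out["sex"], out["age_group"])
        ]
        out["lb"] = [b[0] for b in bounds]
        out["ub"] = [b[1] for b in bounds]
    return out


def _group_quantity(component: str, sex: str, age_group: str) -> str:
    return f"{component}_cost_{sex}_{age_group}"


def scenario_table(results: dict) -> pd.DataFrame:
    """Long-format scenario grid: one row per scenario x component."""
    rows = []
    for name, result in results.items():
        totals = result.grand_totals()
        rows.append(
            {
                "scenario": name,
                "acute_n": totals["acute_n"],
                "chronic_n": totals["chronic_n"],
                "acute": totals["acute"],
                "chronic": totals["chronic"],
                "total": totals["total"],
            }
        )
    return pd.DataFrame(rows)


def frame_to_markdown(frame: pd.DataFrame, float_format: str = "{:,.0f}") -> str:
    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return float_format.format(v)
        return str(v)

    header = "| " + " | ".join(frame.columns) + " |"
    rule = "| " + " | ".join("---" for _ in frame.columns) + " |"
    body = [
        "| " + " | ".join(fmt(v) for v in row) + " |"
        for row in frame.itertuples(index=False)
    ]
    return "\n".join([header, rule, *body]) + "\n"


def render_tables(
    out_dir,
    estimates: pd.DataFrame | None = None,
    base_result: ProjectionCostResult | None = None,
    scenario_results: dict | None = None,
    psa: PSAResult | None = None,
) -> list[Path]:
    """Write every available table as CSV + Markdown; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(frame: pd.DataFrame, stem: str, float_format="{:,.0f}"):
        csv_path = out / f"{stem}.csv"
        frame.to_csv(csv_path, index=False)
        md_path = out / f"{stem}.md"
        md_path.write_text(frame_to_markdown(frame, float_format))
        written.extend([csv_path, md_path])

    if estimates is not None:
        emit(estimates, "chronic_cost_estimates")
    if base_result is not None:
        for component in _COMPONENTS:
            emit(
                projection_table(base_result, component, psa=psa),
                f"projected_{component}_cost",
            )
    if scenario_results is not None:
        emit(scenario_table(scenario_results), "scenario_analyses")
    return written
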