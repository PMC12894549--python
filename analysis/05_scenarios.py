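"""Scenario analyses: discount rate, all-fatal acute costing, 10-year horizon.

Runs the standard scenario set against the base case and reports the
percent change and absolute difference of the total healthcare cost under
each scenario, plus the chronic/acute cost shares.
"""

import argparse
from dataclasses import replace
from pathlib import Path

from miburden import STANDARD_SCENARIOS, compare_scenarios, cost_share, run_scenario
from miburden.io import read_projection_inputs, read_surface
from miburden.reporting import render_tables


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", default="results/data")
    parser.add_argument("--out-dir", default="results")
    args = parser.parse_args()

    out = Path(args.out_dir)
    inputs = read_projection_inputs(Path(args.data_dir) / "projection_inputs")
    surface_path = out / "chronic_cost_surface.csv"
    if surface_path.exists():
        inputs = replace(inputs, chronic_surface=read_surface(surface_path))

    results = {cfg.name: run_scenario(inputs, cfg) for cfg in STANDARD_SCENARIOS}
    render_tables(out, scenario_results=results)

    base = results["base"].grand_totals()
    shares = cost_share([("chronic", base["chronic"]), ("acute", base["acute"])])
    print("base case: " + ", ".join(f"{label} {pct}%" for label, pct in shares))
    for name, result in results.items():
        if name == "base":
            continue
        cmp = compare_scenarios(base["total"], result.grand_totals()["total"])
        print(
            f"{name}: total {cmp.scenario / 1e9:.1f}B, "
            f"{cmp.percent_change_rendered:+.1f}% "
            f"({cmp.difference_billions_rendered:+.1f}B AUD) vs base"
        )


if __name__ == "__main__":
    main()
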