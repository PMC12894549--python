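"""Project the 20-year population cost burden of MI (base case).

Runs the dynamic multistate Markov model on the projection inputs, using
the GLM-predicted chronic cost surface from step 02, and writes the
age-group x sex acute/chronic/total cost tables (5% discounting,
2019-2038).
"""

import argparse
from dataclasses import replace
from pathlib import Path

from miburden import (
    BASE_CASE,
    run_scenario,
)
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
        print("using GLM-predicted chronic cost surface from step 02")

    result = run_scenario(inputs, BASE_CASE)
    totals = result.grand_totals()
    print(
        f"2019-2038 discounted healthcare cost of MI: "
        f"AUD {totals['total'] / 1e9:.1f} billion "
        f"(acute {totals['acute'] / 1e9:.1f}B, chronic {totals['chronic'] / 1e9:.1f}B; "
        f"chronic share {100 * totals['chronic'] / totals['total']:.1f}%)"
    )
    print(
        f"acute-costed events: {totals['acute_n']:,.0f}; "
        f"person-years lived with MI: {totals['chronic_n']:,.0f}"
    )
    render_tables(out, base_result=result)
    result.by_year().to_csv(out / "projected_costs_by_year.csv", index=False)


if __name__ == "__main__":
    main()
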