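"""Generate the synthetic analysis inputs.

Writes a person-year cohort table (the unit of analysis for the chronic
cost GLM) and the projection input set (population, rates, prevalence,
migration, acute unit cost, parametric chronic cost surface) under
``results/data/``.
"""

import argparse
from pathlib import Path

from miburden import SyntheticCohortConfig, generate_cohort, generate_projection_inputs
from miburden.io import write_cohort, write_projection_inputs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2019)
    parser.add_argument("--out-dir", default="results/data")
    args = parser.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    config = SyntheticCohortConfig(seed=args.seed)
    cohort = generate_cohort(config)
    write_cohort(cohort, out / "cohort.csv")
    print(
        f"cohort: {cohort['person_id'].nunique():,} people, "
        f"{len(cohort):,} person-year rows, "
        f"{cohort['person_years'].sum():,.0f} person-years of follow-up"
    )

    inputs = generate_projection_inputs(seed=args.seed)
    write_projection_inputs(inputs, out / "projection_inputs")
    print(
        f"projection inputs: initial population {inputs.initial_population.sum():,.0f}, "
        f"entry cohort {inputs.entry_cohort.sum():,.0f}/cycle, "
        f"acute unit cost AUD {inputs.acute_unit_cost:,.0f}"
    )


if __name__ == "__main__":
    main()
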