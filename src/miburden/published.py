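"""Published headline figures for the Australian MI cost burden, 2019-2038.

These are the printed population-level results of the published Australian
cost-of-illness analysis that this package's pipeline re-implements: the
per-person chronic management cost estimate, the projected 20-year acute /
chronic / total healthcare costs under each scenario, and the crude
per-person component costs.  They are reference *inputs* for the comparison
arithmetic (scenario contrasts, cost shares) -- the projection itself is
driven by rate and cost tables, not by these totals.

All values in 2019 AUD.  The printed scenario totals differ from the sum of
their own printed components in the last few digits (consistent with
low-precision storage in the source); totals here are the printed ones.
"""

# per-person annual chronic management cost (adjusted), with 95% CI
CHRONIC_COST_PER_PERSON = 14_412.0
CHRONIC_COST_PER_PERSON_CI = (14_282.0, 14_542.0)

# 20-year projected totals, base case (5% discount, half of fatal MIs costed)
ACUTE_COST_BASE = 5_466_355_840.0
CHRONIC_COST_BASE = 79_613_548_544.0
TOTAL_COST_BASE = 85_079_904_256.0

# scenario totals (total population)
TOTAL_COST_DISCOUNT_3PCT = 100_495_816_704.0
TOTAL_COST_DISCOUNT_0PCT = 132_947_144_704.0
ACUTE_COST_ALL_FATAL = 5_569_528_320.0
TOTAL_COST_ALL_FATAL = 85_183_076_352.0
TOTAL_COST_10YR = 49_883_547_648.0

# crude per-person component costs of the chronic management estimate
COMPONENT_COSTS = (
    ("hospital", 8_789.0),
    ("pharmaceutical", 2_636.0),
    ("medicare", 2_422.0),
)
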