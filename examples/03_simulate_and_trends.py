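"""Simulate a linked cohort and compute cohort-level use trends.

Generates 2,000 participants with the default archetype mix and
corruption rates, runs the filtering cascade and period construction, and
prints annual prevalence for one year, the covered-day shares by method
type, and the filter report.
"""

from hcepi import SimulationConfig, build_periods, censor_by_pregnancy, prepare_purchases, simulate_cohort
from hcepi.trends import annual_prevalence, covered_days_shares

cohort = simulate_cohort(SimulationConfig(n_participants=2000, seed=1))
prepared = prepare_purchases(cohort.purchases, cohort.participants, cohort.bmi)
print("Filter cascade (removed rows per step):")
print(prepared.report.to_frame().to_string(index=False))

periods = censor_by_pregnancy(
    build_periods(prepared.purchases, participants=prepared.participants), cohort.diagnoses
)
prev = annual_prevalence(periods, prepared.participants)
print("\nAnnual prevalence of active users, 2015:")
print(prev[prev["year"] == 2015].to_string(index=False))

shares = covered_days_shares(periods, participants=prepared.participants)
year = shares[(shares["year"] == 2015) & (shares["age_group"] == "20-29")]
print("\nCovered-day shares by method type, 2015, ages 20-29:")
print(year.to_string(index=False))
print(
    "\nPrevalence divides active users (any period overlapping the year)"
    "\nby the participants of that age group; shares apportion each"
    "\nperiod's covered days to calendar years by exact day overlap."
)
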