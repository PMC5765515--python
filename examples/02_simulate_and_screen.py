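"""Simulate a small spontaneous-report database and screen it monthly.

Builds a two-substance synthetic database with one injected quality-defect
episode, aggregates monthly counts per substance-PT pair, screens every
month, and prints the flagged months.  The injected episode (8-fold
elevation of one SMQ's PTs in early 2009) should dominate the detections.
"""

import datetime as dt

import pandas as pd

from uifscan import ScreenConfig, monthly_counts, screen, simulate
from uifscan.synthetic_data import InjectionSpec, SimScenario

scenario = SimScenario(
    n_substances=2,
    pts_per_substance=6,
    baseline_mu=2.0,          # mean monthly reports per drug-event pair
    dispersion_alpha=0.3,     # NB2 over-dispersion: var = mu + 0.3 mu^2
    months=("2008-01", "2009-06"),
    injections=[
        InjectionSpec(
            substance="sub01",
            grouping_term=("SMQ", "smq_01"),
            start_month="2009-01",
            duration_months=2,
            fold_increase=8.0,
            concern_type="QD",
            index_date=dt.date(2009, 1, 15),
            concern_id="contamination-episode",
        )
    ],
    seed=7,
)

records, concerns, hierarchy = simulate(scenario)
print(f"simulated {len(records)} reports, ground truth: {concerns[0].concern_id}")

config = ScreenConfig(threshold_tau=5)
series = monthly_counts(records, config, hierarchy, scenario.months)
print(f"{len(series)} substance-PT count series")

first = pd.Period(scenario.months[0], freq="M") + config.window_months
for t0 in pd.period_range(first, scenario.months[1], freq="M"):
    for det in screen(series, t0, config):
        bound = f", bound {det.forecast.upper_bound:.1f}" if det.forecast else ""
        print(
            f"  {det.month}  {det.drug_key[1]} / {det.event_key[1]}: "
            f"y0={det.y0} ({det.branch}{bound})"
        )
# Most flags should fall on sub01 PTs of smq_01 in 2009-01/02 - the
# injected episode; anything else is a background false alarm.
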