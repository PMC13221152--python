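"""Reconstruct contraceptive usage periods from a handful of purchases.

Builds a five-purchase history for one person — a combined pill bought
three times, a pregnancy in between, then a switch to a progestin-only
pill — and prints the inferred exposure episodes.
"""

import pandas as pd

from hcepi import build_periods, censor_by_pregnancy

purchases = pd.DataFrame(
    {
        "participant_id": ["P1"] * 4,
        "purchase_date": pd.to_datetime(
            ["2010-01-01", "2010-03-15", "2010-06-01", "2011-02-01"]
        ),
        "purchased_atc": ["G03AA12", "G03AA12", "G03AA12", "G03AC09"],
        "prescribed_atc": ["G03AA12", "G03AA12", "G03AA12", "G03AC09"],
        "dosage": [3.0, 3.0, 3.0, 3.0],
        "package_content": [21] * 4,
        "iud_dose_label": [None] * 4,
    }
)
diagnoses = pd.DataFrame(
    {"participant_id": ["P1"], "date": pd.to_datetime(["2010-07-10"]), "icd10": ["O04"]}
)

periods = censor_by_pregnancy(build_periods(purchases), diagnoses)
cols = ["formulation_key", "start_date", "end_date", "length_days", "n_purchases", "censor_reason"]
print(periods[cols].to_string(index=False))
print(
    "\nThe three pill purchases merge into one period (refill gaps < 90 days);"
    "\nthe pregnancy code ends it on the diagnosis date (censor_reason ="
    "\n'pregnancy'); the progestin-only pill starts a separate period."
)
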