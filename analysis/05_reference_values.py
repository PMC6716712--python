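"""Age-and-sex ESR reference values from the fitted model.

Produces the suggested cut-point table (average predicted 90th/95th/
97.5th percentile within each age-and-sex group) and tidy percentile
curves (P50/P90/P95/P97.5 over age, per sex, at reference covariate
values) for plotting.
"""

import numpy as np
import pandas as pd

from common import RESULTS, fit_final, load_derived
from esrref import percentile_curve, reference_table


def main():
    derived = load_derived()
    fitted = fit_final(derived)
    RESULTS.mkdir(exist_ok=True)

    rt = reference_table(fitted, derived)
    rt.to_csv(RESULTS / "reference_table.csv", index=False)
    print("suggested ESR cut points (mm/h), average predicted percentile per group:")
    print(rt.to_string(index=False))

    # reference profile: never-smoking abstainer with low activity, normal
    # weight, no metabolic syndrome, sex-typical hemoglobin, mcv 90
    curves = []
    ages = np.linspace(18.0, 90.0, 37)
    for sex, hb in (("female", 13.4), ("male", 15.1)):
        profile = {
            "smoking_category": "never",
            "alcohol_category": "abstainer_occasional",
            "activity_category": "low",
            "bmi_class": "normal",
            "metabolic_syndrome": False,
            "hemoglobin": hb,
            "mcv": 90.0,
        }
        for p in (0.5, 0.9, 0.95, 0.975):
            curves.append(percentile_curve(fitted, sex, profile, ages, p))
    pd.concat(curves, ignore_index=True).round(2).to_csv(
        RESULTS / "percentile_curves.csv", index=False
    )
    print("\npercentile curves written for the reference covariate profile")


if __name__ == "__main__":
    main()
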