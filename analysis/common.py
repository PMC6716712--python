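"""Shared plumbing for the analysis drivers.

Large intermediates (raw cohort, derived table, pickled fits) live under
scratch/; only small summary tables are written to results/.
"""

from pathlib import Path
import pickle

import esrref as E

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

COHORT_SEED = 42

# the fully adjusted distributional model: smooth age effect plus the
# demographic, lifestyle, metabolic and hematologic covariates on log-mu;
# sex on log-sigma; constant shape
FINAL_SPEC = E.ModelSpec(
    mu_terms=(
        E.Term("age", "pspline"),
        E.Term("sex", "linear"),
        E.Term("smoking_category", "linear"),
        E.Term("alcohol_category", "linear"),
        E.Term("activity_category", "linear"),
        E.Term("bmi_class", "linear"),
        E.Term("metabolic_syndrome", "linear"),
        E.Term("hemoglobin", "linear"),
        E.Term("mcv", "linear"),
    ),
    sigma_terms=(E.Term("sex", "linear"),),
    name="adjusted",
)


def load_cohort():
    SCRATCH.mkdir(exist_ok=True)
    path = SCRATCH / "cohort.csv"
    if path.exists():
        return E.read_cohort_csv(path)
    cohort = E.simulate_cohort(E.SimulationConfig(seed=COHORT_SEED))
    out = cohort.copy()
    for c in ("ever_smoked", "on_antihypertensives", "on_antidiabetics"):
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)
    return cohort


def load_derived():
    path = SCRATCH / "derived.csv"
    if path.exists():
        import pandas as pd
        return pd.read_csv(path, dtype={"id": str})
    derived = E.derive_table(load_cohort())
    E.write_derived_csv(derived, path)
    return derived


def fit_final(derived):
    path = SCRATCH / "final_fit.pkl"
    if path.exists():
        with open(path, "rb") as fh:
            return pickle.load(fh)
    fitted = E.fit(derived, FINAL_SPEC)
    with open(path, "wb") as fh:
        pickle.dump(fitted, fh)
    return fitted
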