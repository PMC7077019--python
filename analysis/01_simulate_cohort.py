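"""Build the study dataset: the 46-item reference bank and a synthetic
clinical cohort of 521 respondents.

The cohort mirrors the validation-study design: a standard-normal latent
trait on the calibration metric, an 80/20 split by primary complaint
location (arm/shoulder vs hand/wrist), and mild uniform DIF planted on two
fine-motor items for the hand/wrist group — the pattern the DIF screen is
expected to pick up downstream.  Demographic covariates without any planted
effect are added for the DIF battery.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gradedcat import (
    DIFInjection,
    SimulationDesign,
    generate_responses,
    promis_ue_bank,
    write_bank_json,
    write_responses_csv,
)

SEED = 20
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

bank = promis_ue_bank()
design = SimulationDesign(
    n_persons=521,
    theta_mean=(0.0, 0.0),
    theta_sd=(1.0, 1.0),
    group_proportions=(0.8, 0.2),  # arm/shoulder vs hand/wrist
    dif_injections=(
        DIFInjection("PFA20", "uniform", 0.4),    # cutting food
        DIFInjection("PFB21r1", "uniform", 0.4),  # picking up coins
    ),
    seed=SEED,
)
matrix, thetas, groups = generate_responses(bank, design)

rng = np.random.default_rng(SEED + 1)
covariates = pd.DataFrame(
    {
        "person_id": matrix.persons,
        "age": rng.normal(51, 17, matrix.n_persons).round(0),
        "gender": rng.integers(0, 2, matrix.n_persons),
        "center": rng.integers(0, 2, matrix.n_persons),
        "duration_6m": rng.integers(0, 2, matrix.n_persons),
        "location_handwrist": groups,
    }
)

write_bank_json(bank, OUT / "bank.json")
write_responses_csv(matrix, OUT / "responses.csv")
pd.DataFrame({"person_id": matrix.persons, "theta": thetas}).to_csv(
    OUT / "thetas.csv", index=False
)
covariates.to_csv(OUT / "covariates.csv", index=False)

print(f"cohort: {matrix.n_persons} persons x {matrix.n_items} items")
print(f"groups: {np.bincount(groups).tolist()} (arm/shoulder, hand/wrist)")
print(f"planted uniform DIF (+0.4 thresholds) on PFA20, PFB21r1 for group 1")
print(f"wrote {OUT}/bank.json, responses.csv, thetas.csv, covariates.csv")
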