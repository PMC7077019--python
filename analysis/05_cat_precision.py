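"""Precision of four applications of the calibrated bank: full bank,
7-item short form, standard CAT (SE stop 3.0 / max 12 items) and fixed
7-item CAT.  Produces the SE-versus-T overlay and the percent-reliable
summaries."""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gradedcat import (
    CATRules,
    cat_precision_curve,
    percent_reliable,
    plot_precision_curves,
    precision_curve,
    read_bank_json,
    read_responses_csv,
    score_instrument,
    short_form_7a_ids,
    simulate_cat_cohort,
)

OUT = Path("results/precision")
OUT.mkdir(parents=True, exist_ok=True)

matrix = read_responses_csv("results/data/responses.csv")
bank = read_bank_json("results/calibration/bank_estimated.json")
sf_ids = short_form_7a_ids()

est_full, _ = score_instrument(matrix, bank)
est_sf, _ = score_instrument(matrix, bank, item_ids=sf_ids)
records_std, sum_std = simulate_cat_cohort(matrix, bank, CATRules())
records_fix, sum_fix = simulate_cat_cohort(
    matrix, bank, CATRules(se_stop_t=None, fixed_length=7)
)

curves = {
    "full bank (46 items)": precision_curve(bank, estimates=est_full),
    "short form (7 items)": precision_curve(bank, item_ids=sf_ids,
                                            estimates=est_sf),
    "standard CAT": cat_precision_curve(records_std, label="standard CAT"),
    "fixed 7-item CAT": cat_precision_curve(records_fix, label="fixed CAT"),
}
pd.concat(
    [pd.DataFrame({"application": lbl, "t": c.t_grid, "se_t": c.se_t})
     for lbl, c in curves.items()]
).to_csv(OUT / "curves.csv", index=False)
plot_precision_curves(curves, OUT / "precision_curves.svg")

summary = {
    "pct_reliable_full_bank": percent_reliable(est_full),
    "pct_reliable_short_form": percent_reliable(est_sf),
    "pct_reliable_standard_cat": sum_std["pct_reliable"],
    "pct_reliable_fixed_cat": sum_fix["pct_reliable"],
    "standard_cat_mean_items": sum_std["mean_items"],
    "standard_cat_pct_fewer_than_7": sum_std["pct_fewer_than_7"],
    "standard_cat_stop_reasons": sum_std["pct_stop_by_reason"],
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=1))

print(f"reliability > 0.90 achieved for: full bank "
      f"{100*summary['pct_reliable_full_bank']:.1f}%, short form "
      f"{100*summary['pct_reliable_short_form']:.1f}%, standard CAT "
      f"{100*summary['pct_reliable_standard_cat']:.1f}%, fixed 7-item CAT "
      f"{100*summary['pct_reliable_fixed_cat']:.1f}% of persons")
print(f"standard CAT: mean {summary['standard_cat_mean_items']:.1f} items; "
      f"{100*summary['standard_cat_pct_fewer_than_7']:.1f}% of persons "
      "needed fewer than 7 items")
print(f"wrote SE curves and {OUT}/precision_curves.svg")
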