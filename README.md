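# gradedcat

Psychometric validation toolkit for graded-response item banks: marginal
maximum-likelihood calibration, IRT-assumption screening, differential item
functioning (DIF), computerized adaptive testing (CAT) simulation, and
precision / relative-efficiency comparison. The package is organised around
the validation workflow of patient-reported outcome item banks such as the
PROMIS upper-extremity bank, and ships the published 46-item upper-extremity
parameter table as its reference fixture.

## Who this is for

Researchers validating an ordinal item bank (or short forms / CATs derived
from it) who need the full analysis chain in one tested codebase:

1. **Model** — the logistic graded response model (GRM). For item *i* with
   slope *a<sub>i</sub>*, ordered thresholds *b<sub>i1</sub> < … <
   b<sub>i,K−1</sub>* and latent trait θ,

   P(X<sub>i</sub> ≥ k | θ) = 1 / (1 + exp(−a<sub>i</sub>(θ − b<sub>ik</sub>))),

   category probabilities are differences of adjacent cumulative curves, and
   Fisher information I(θ) gives the score precision SE(θ) = 1/√I(θ).
   Scores are reported as T-scores (T = 50 + 10 θ) with reliability
   r = 1 − (SE<sub>T</sub>/10)².
2. **Assumptions** — polychoric correlations, eigenvalue rules (first factor
   ≥ 20 % of variance, first/second ratio > 4), Schmid–Leiman bifactor
   indices (ω-H > 0.80, ECV > 0.60), residual-correlation local-dependence
   screening (flag pairs more than 0.20 above the mean residual), and Mokken
   scalability (H<sub>i</sub> ≥ 0.30, scale H ≥ 0.50).
3. **Calibration & fit** — Bock–Aitkin EM estimation of (a, b) and the
   polytomous Orlando–Thissen S-X² item-fit test (misfit at p ≤ 0.001).
4. **Measurement invariance** — per-item nested proportional-odds models
   (trait; + group; + trait×group) flagged by a McFadden pseudo-R² change of
   0.02, with anchored rescoring to quantify DIF impact on scores.
5. **CAT** — post-hoc maximum-information simulation with the standard
   stopping rule (SE ≤ 3 on the T metric, max 12 items) or a fixed length,
   EAP scoring throughout, plus SE-versus-T precision curves and relative
   efficiency (information per administered item, ratio of cohort means).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (n = 521, one latent trait, mild uniform DIF planted on two fine-motor
items for the hand/wrist subgroup):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_assumptions.py
python analysis/03_calibrate.py
python analysis/04_dif.py
python analysis/05_cat_precision.py
python analysis/06_relative_efficiency.py
```

Output of `02_assumptions.py` on the default seed:

```
eigenvalues: 31.4 / 0.8 (ratio 41.4; criterion > 4)
first factor share: 68% (criterion >= 20%)
bifactor: omega-H 0.99 (> 0.80), ECV 1.00 (> 0.60)
residuals: mean -0.000, critical 0.20, 0 of 1035 pairs flagged, SRMR 0.022
Mokken: H 0.63 (>= 0.50), item H_i range 0.55-0.70 (>= 0.30)
all criteria met
```

The cohort is generated unidimensional, and every screen agrees: the first
eigenvalue dominates, the bifactor general factor carries all common
variance, no item pair is locally dependent, and the Mokken coefficients sit
in the range typical of a strong clinical bank.

`04_dif.py` recovers exactly one of the two planted DIF items (the other
falls below the 2 % pseudo-R² change at this subgroup size) and shows the
score impact is negligible:

```
location_handwrist: 1 item(s) flagged [('PFA20', 'uniform')]
impact of location DIF on scores: central 50% of initial-minus-corrected
differences in [-0.001, 0.004] theta points (max |diff| 0.036)
```

`05_cat_precision.py` summarises the four scoring applications:

```
reliability > 0.90 achieved for: full bank 96.9%, short form 47.4%,
standard CAT 95.0%, fixed 7-item CAT 87.1% of persons
standard CAT: mean 5.0 items; 81.6% of persons needed fewer than 7 items
```

The standard CAT reaches near-full-bank reliability with about five items
per person; `06_relative_efficiency.py` quantifies this as a relative
efficiency of 1.92 versus administering the whole bank.

The same machinery is available as a library (`gradedcat.run_pipeline`
drives every stage from one config mapping), and all readers/writers use
plain JSON and CSV (`bank.json` round-trips losslessly; response CSVs accept
0- or 1-based category codes).

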