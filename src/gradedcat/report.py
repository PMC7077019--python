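"""Precision curves, reliability summaries, relative efficiency and the
end-to-end pipeline.

Precision is reported as the standard error of the T-score across the score
range (SE(theta) = 1/sqrt(I(theta)), mapped through the reporting metric);
relative efficiency compares instruments as information gathered per item
administered, averaged over persons, following the ratio-of-means
definition: RE(a, b) = mean_p[(1/SE_p,a)^2 / n_p,a] / mean_p[(1/SE_p,b)^2 /
n_p,b].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assumptions as assumptions_mod
from .calibrate import fit_grm, s_x2_item_fit
from .cat import CATRecord, CATRules, simulate_cat_cohort
from .dif import dif_battery, dif_corrected_theta
from .grm import (
    ItemBank,
    Metric,
    Quadrature,
    ResponseMatrix,
    ThetaEstimate,
    eap_score_matrix,
    reliability_from_se,
    test_information_and_se,
)
from .io import write_bank_json, write_responses_csv
from .simulate import (
    DIFInjection,
    SimulationDesign,
    generate_responses,
    promis_ue_bank,
    short_form_7a_ids,
)

__all__ = [
    "PrecisionCurve",
    "ScoredPerson",
    "precision_curve",
    "cat_precision_curve",
    "percent_reliable",
    "score_instrument",
    "relative_efficiency",
    "efficiency_table",
    "reverse_scores",
    "compare_instruments",
    "run_pipeline",
    "plot_precision_curves",
]


@dataclass
class PrecisionCurve:
    label: str
    t_grid: np.ndarray
    se_t: np.ndarray
    hist_counts: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    hist_edges: np.ndarray = field(default_factory=lambda: np.empty(0))


def precision_curve(
    bank: ItemBank,
    item_ids: list[str] | None = None,
    theta_grid: np.ndarray | None = None,
    estimates: list[ThetaEstimate] | None = None,
    label: str = "",
) -> PrecisionCurve:
    """SE-of-T curve for a bank or item subset over a theta grid, with an
    optional cohort T-score histogram attached."""
    theta_grid = np.linspace(-4, 4, 81) if theta_grid is None else np.asarray(theta_grid)
    se_t = np.array(
        [test_information_and_se(t, bank, item_ids)[2] for t in theta_grid]
    )
    m = bank.metric
    t_axis = m.reference_mean + m.reference_sd * theta_grid
    counts, edges = np.empty(0, int), np.empty(0)
    if estimates:
        scores = [e.t_score for e in estimates]
        counts, edges = np.histogram(scores, bins=20)
    return PrecisionCurve(
        label or (bank.label if item_ids is None else f"{len(item_ids)} items"),
        t_axis, se_t, counts, edges,
    )


def cat_precision_curve(
    records: list[CATRecord], bin_width: float = 2.0, label: str = "CAT"
) -> PrecisionCurve:
    """Binned-median SE curve from per-person CAT results (final T, final
    SE), bin width in T-score points."""
    t = np.array([r.final.t_score for r in records])
    se = np.array([r.final.se_t for r in records])
    lo = np.floor(t.min() / bin_width) * bin_width
    hi = np.ceil(t.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 1e-9, bin_width)
    centers, medians = [], []
    for i in range(edges.size - 1):
        sel = (t >= edges[i]) & (t < edges[i + 1])
        if sel.any():
            centers.append((edges[i] + edges[i + 1]) / 2)
            medians.append(float(np.median(se[sel])))
    counts, hedges = np.histogram(t, bins=20)
    return PrecisionCurve(label, np.array(centers), np.array(medians),
                          counts, hedges)


def percent_reliable(
    estimates: list[ThetaEstimate],
    r_threshold: float = 0.90,
    metric: Metric | None = None,
) -> float:
    """Share of persons whose score reliability strictly exceeds the
    threshold."""
    if not estimates:
        raise ValueError("no estimates")
    metric = metric or Metric()
    rel = np.array([reliability_from_se(e.se_t, metric) for e in estimates])
    return float((rel > r_threshold).mean())


# ---------------------------------------------------------------------------
# relative efficiency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoredPerson:
    """Per-person scoring outcome of one instrument application."""

    person: str
    se_theta: float
    n_items: int


def _as_scored(records) -> list[ScoredPerson]:
    out = []
    for r in records:
        if isinstance(r, ScoredPerson):
            out.append(r)
        elif isinstance(r, CATRecord):
            out.append(ScoredPerson(r.person, r.final.se_theta, len(r.administered)))
        else:
            raise TypeError(f"cannot interpret record {r!r}")
    return out


def score_instrument(
    matrix: ResponseMatrix,
    bank: ItemBank,
    item_ids: list[str] | None = None,
    grid: Quadrature | None = None,
) -> tuple[list[ThetaEstimate], list[ScoredPerson]]:
    """EAP-score every person on a bank (or fixed item subset, e.g. a short
    form)."""
    sub = bank if item_ids is None else bank.subset(item_ids)
    codes = matrix.align_to(sub)
    est = eap_score_matrix(codes, sub, grid)
    scored = [
        ScoredPerson(p, e.se_theta, e.n_items_used)
        for p, e in zip(matrix.persons, est)
    ]
    return est, scored


def relative_efficiency(records_a, records_b) -> float:
    """Mean information-per-item of instrument a over instrument b, on the
    same persons."""
    a = _as_scored(records_a)
    b = _as_scored(records_b)
    pa = [r.person for r in a]
    pb = [r.person for r in b]
    if set(pa) != set(pb):
        raise ValueError("record sets cover different persons")
    order = {p: i for i, p in enumerate(pb)}
    b = [b[order[p]] for p in pa]

    def eff(rs):
        return np.array([(1.0 / r.se_theta**2) / r.n_items for r in rs])

    return float(eff(a).mean() / eff(b).mean())


def efficiency_table(instruments: dict[str, list]) -> pd.DataFrame:
    """Pairwise relative-efficiency matrix (row vs column)."""
    labels = list(instruments)
    out = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for la in labels:
        for lb in labels:
            out.loc[la, lb] = relative_efficiency(instruments[la], instruments[lb])
    return out


# ---------------------------------------------------------------------------
# comparative precision across instruments
# ---------------------------------------------------------------------------

def reverse_scores(matrix: ResponseMatrix) -> ResponseMatrix:
    """Reverse the coding direction of every item (code -> K-1-code), e.g.
    to turn disability scores into functioning scores."""
    codes = matrix.codes.copy()
    for j in range(matrix.n_items):
        k = int(matrix.n_categories[j])
        obs = codes[:, j] >= 0
        codes[obs, j] = k - 1 - codes[obs, j]
    return ResponseMatrix(
        list(matrix.persons), list(matrix.item_ids), codes,
        n_categories=matrix.n_categories.copy(),
    )


def compare_instruments(
    instruments: dict[str, ResponseMatrix],
    reverse: tuple[str, ...] = (),
    theta_grid: np.ndarray | None = None,
    grid: Quadrature | None = None,
    auto_collapse: bool = True,
) -> tuple[dict[str, PrecisionCurve], pd.DataFrame,
           dict[str, list[ThetaEstimate]]]:
    """Fit a GRM per instrument, EAP-score the (shared) cohort, and compare
    SE curves and relative efficiency.

    Each instrument is placed on its own T metric (T = 50 + 10 theta on its
    calibration sample); no cross-instrument linking is attempted.  With
    ``auto_collapse``, response categories left empty in the sample are
    merged into their neighbours before calibration.
    """
    from .calibrate import suggest_collapse_plan
    from .simulate import collapse_categories

    curves: dict[str, PrecisionCurve] = {}
    scored: dict[str, list] = {}
    estimates: dict[str, list[ThetaEstimate]] = {}
    for label, matrix in instruments.items():
        if label in reverse:
            matrix = reverse_scores(matrix)
        if auto_collapse:
            plan = suggest_collapse_plan(matrix)
            if plan:
                matrix = collapse_categories(matrix, plan)
        try:
            fit = fit_grm(matrix, grid=grid, label=label)
        except Exception as exc:
            raise RuntimeError(f"instrument {label!r}: GRM fit failed") from exc
        est, sc = score_instrument(matrix, fit.bank, grid=grid)
        curves[label] = precision_curve(
            fit.bank, theta_grid=theta_grid, estimates=est, label=label
        )
        scored[label] = sc
        estimates[label] = est
    return curves, efficiency_table(scored), estimates


def plot_precision_curves(
    curves: dict[str, PrecisionCurve], path: str | Path,
    se_line: float | None = 3.2,
) -> None:
    """SE-versus-T overlay of several instrument applications."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, c in curves.items():
        ax.plot(c.t_grid, c.se_t, label=label)
    if se_line is not None:
        ax.axhline(se_line, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("T-score")
    ax.set_ylabel("SE (T metric)")
    ax.set_ylim(0, 12)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {"n_persons": 521, "missing_rate": 0.0},
    "dif_threshold": 0.02,
    "misfit_alpha": 0.001,
    "residual_offset": 0.20,
    "cat": {"se_stop_t": 3.0, "max_items": 12, "fixed_length": 7},
    "skip": [],
}


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run simulate -> calibrate -> assumptions -> dif -> cat -> report and
    persist a JSON+CSV bundle under ``outdir``.

    ``config`` may be a mapping or a path to a YAML file; omitted keys take
    the standard thresholds (DIF 0.02, misfit 0.001, residual offset 0.20,
    SE stop 3, max 12 items, fixed length 7).  Stages listed in ``skip``
    are omitted; any stage failure halts with the stage name while earlier
    outputs remain on disk.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = {**_DEFAULT_CONFIG, **config}
    cfg["simulate"] = {**_DEFAULT_CONFIG["simulate"], **cfg.get("simulate", {})}
    cfg["cat"] = {**_DEFAULT_CONFIG["cat"], **cfg.get("cat", {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set(cfg.get("skip", []))
    outputs: dict = {"config": cfg}

    def stage(name):
        return name not in skip

    try:
        bank = promis_ue_bank()
        sim = cfg["simulate"]
        inj = tuple(
            DIFInjection(d["item_id"], d["type"], d["magnitude"])
            for d in sim.get("dif_injections", [])
        )
        n_groups = len(sim.get("group_proportions", [1.0]))
        design = SimulationDesign(
            n_persons=sim["n_persons"],
            theta_mean=tuple(sim.get("theta_mean", [0.0] * n_groups)),
            theta_sd=tuple(sim.get("theta_sd", [1.0] * n_groups)),
            group_proportions=tuple(sim.get("group_proportions", [1.0])),
            dif_injections=inj,
            missing_rate=sim["missing_rate"],
            seed=int(cfg["seed"]),
        )
        matrix, thetas, groups = generate_responses(bank, design)
        write_bank_json(bank, outdir / "bank.json")
        write_responses_csv(matrix, outdir / "responses.csv")
        pd.DataFrame({"person_id": matrix.persons, "theta": thetas,
                      "group": groups}).to_csv(outdir / "thetas.csv", index=False)
        outputs["matrix"] = matrix
    except Exception as exc:
        raise RuntimeError("pipeline stage 'simulate' failed") from exc

    fitted_bank = bank
    if stage("calibrate"):
        try:
            cal = fit_grm(matrix, label="sample calibration")
            fitted_bank = cal.bank
            fits = s_x2_item_fit(fitted_bank, matrix, alpha=cfg["misfit_alpha"])
            pd.DataFrame(
                [
                    {"item_id": f.item_id, "s_x2": f.s_x2, "df": f.df,
                     "p_value": f.p_value, "misfit": f.misfit}
                    for f in fits
                ]
            ).to_csv(outdir / "fit.csv", index=False)
            write_bank_json(fitted_bank, outdir / "bank_estimated.json")
            outputs["calibration"] = cal
            outputs["item_fit"] = fits
        except Exception as exc:
            raise RuntimeError("pipeline stage 'calibrate' failed") from exc

    if stage("assumptions"):
        try:
            rep = assumptions_mod.assumption_report(
                matrix, residual_offset=cfg["residual_offset"]
            )
            doc = {
                "eigenvalue_1": float(rep.eigenvalues[0]),
                "eigenvalue_2": float(rep.eigenvalues[1]),
                "pct_variance_first": rep.pct_variance_first,
                "ratio_first_second": rep.ratio_first_second,
                "omega_h": rep.omega_h,
                "ecv": rep.ecv,
                "residual_mean": rep.residual_mean,
                "residual_critical": rep.residual_critical,
                "n_flagged_pairs": len(rep.flagged_pairs),
                "srmr": rep.srmr,
                "mokken_H": rep.mokken_H,
                "criteria_met": rep.criteria_met,
            }
            (outdir / "assumptions.json").write_text(json.dumps(doc, indent=1))
            outputs["assumptions"] = rep
        except Exception as exc:
            raise RuntimeError("pipeline stage 'assumptions' failed") from exc

    if stage("dif"):
        try:
            cov = pd.DataFrame({"group": groups})
            tables = dif_battery(
                matrix, fitted_bank, cov, threshold=cfg["dif_threshold"]
            )
            for name, res in tables.items():
                pd.DataFrame(
                    [
                        {"item_id": r.item_id, "r2_m1": r.r2_m1,
                         "r2_m2": r.r2_m2, "r2_m3": r.r2_m3,
                         "delta_total": r.delta_total, "flag": r.flag}
                        for r in res
                    ]
                ).to_csv(outdir / f"dif_{name}.csv", index=False)
            if len(np.unique(groups)) == 2:
                impact = dif_corrected_theta(
                    matrix, fitted_bank, tables["group"], groups
                )
                pd.DataFrame(
                    {"person_id": matrix.persons,
                     "theta_initial": impact.theta_initial,
                     "theta_corrected": impact.theta_corrected,
                     "difference": impact.differences}
                ).to_csv(outdir / "impact.csv", index=False)
            outputs["dif"] = tables
        except Exception as exc:
            raise RuntimeError("pipeline stage 'dif' failed") from exc

    if stage("cat"):
        try:
            cat_cfg = cfg["cat"]
            std_rules = CATRules(
                se_stop_t=cat_cfg["se_stop_t"], max_items=cat_cfg["max_items"]
            )
            records, summary = simulate_cat_cohort(matrix, fitted_bank, std_rules)
            fixed_rules = CATRules(
                se_stop_t=None, fixed_length=cat_cfg["fixed_length"],
                max_items=max(cat_cfg["max_items"], cat_cfg["fixed_length"]),
            )
            records_f, summary_f = simulate_cat_cohort(
                matrix, fitted_bank, fixed_rules
            )
            (outdir / "cat_summary.json").write_text(
                json.dumps({"standard": summary, "fixed": summary_f}, indent=1)
            )
            rows = [
                {"person_id": r.person, "step": s + 1, "item_id": iid,
                 "theta": r.interim[s].theta, "se_t": r.interim[s].se_t,
                 "stop_reason": r.stop_reason}
                for r in records
                for s, iid in enumerate(r.administered)
            ]
            pd.DataFrame(rows).to_csv(outdir / "cat_records.csv", index=False)
            outputs["cat"] = (records, summary)
            outputs["cat_fixed"] = (records_f, summary_f)
        except Exception as exc:
            raise RuntimeError("pipeline stage 'cat' failed") from exc

    if stage("report"):
        try:
            est_full, sc_full = score_instrument(matrix, fitted_bank)
            sf_ids = [i for i in short_form_7a_ids() if i in fitted_bank.item_ids]
            est_sf, sc_sf = score_instrument(matrix, fitted_bank, item_ids=sf_ids)
            curves = {
                "full_bank": precision_curve(
                    fitted_bank, estimates=est_full, label="full bank"
                ),
                "short_form": precision_curve(
                    fitted_bank, item_ids=sf_ids, estimates=est_sf,
                    label="7-item short form",
                ),
            }
            instruments = {"full_bank": sc_full, "short_form": sc_sf}
            if "cat" in outputs:
                records = outputs["cat"][0]
                curves["standard_cat"] = cat_precision_curve(records)
                instruments["standard_cat"] = records
                records_f = outputs["cat_fixed"][0]
                instruments["fixed_cat"] = records_f
            eff = efficiency_table(instruments)
            eff.to_csv(outdir / "efficiency.csv")
            pd.concat(
                [
                    pd.DataFrame({"instrument": lbl, "t": c.t_grid, "se_t": c.se_t})
                    for lbl, c in curves.items()
                ]
            ).to_csv(outdir / "curves.csv", index=False)
            summary = {
                "pct_reliable_full": percent_reliable(est_full),
                "pct_reliable_short_form": percent_reliable(est_sf),
            }
            if "cat" in outputs:
                summary["pct_reliable_standard_cat"] = outputs["cat"][1]["pct_reliable"]
                summary["mean_items_standard_cat"] = outputs["cat"][1]["mean_items"]
            (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
            outputs["curves"] = curves
            outputs["efficiency"] = eff
            outputs["summary"] = summary
        except Exception as exc:
            raise RuntimeError("pipeline stage 'report' failed") from exc

    log = {
        "seed": int(cfg["seed"]),
        "thresholds": {
            "dif": cfg["dif_threshold"],
            "misfit": cfg["misfit_alpha"],
            "residual_offset": cfg["residual_offset"],
            "se_stop_t": cfg["cat"]["se_stop_t"],
            "max_items": cfg["cat"]["max_items"],
            "fixed_length": cfg["cat"]["fixed_length"],
        },
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages_skipped": sorted(skip),
    }
    (outdir / "log.json").write_text(json.dumps(log, indent=1))
    return outputs
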