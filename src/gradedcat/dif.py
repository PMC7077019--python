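"""Differential item functioning (DIF) by ordinal logistic regression.

For each item, three nested proportional-odds models of the response are
fitted: M1 with the trait estimate theta only, M2 adding the group main
effect, M3 adding the theta x group interaction.  The flagging statistic is
the change in McFadden's pseudo-R2; an item is flagged when the total change
(M3 vs M1) reaches the critical value (default 0.02), and classified as
uniform DIF when the group main effect carries at least as much of the
change as the interaction, non-uniform otherwise.

Impact of DIF on scores is quantified by rescoring with group-specific
parameters for the flagged items (re-estimated with the unflagged items as
fixed anchors) and comparing the corrected trait estimates with the initial
pooled ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .calibrate import fit_grm
from .grm import (
    MISSING,
    ItemBank,
    Quadrature,
    ResponseMatrix,
    eap_score_matrix,
)

__all__ = [
    "DIFResult",
    "DIFImpact",
    "detect_dif",
    "dif_corrected_theta",
    "dif_battery",
    "score_for_dif",
]


@dataclass(frozen=True)
class DIFResult:
    item_id: str
    r2_m1: float
    r2_m2: float
    r2_m3: float
    delta_uniform: float
    delta_nonuniform: float
    delta_total: float
    flag: str  # none | uniform | nonuniform | unstable


@dataclass
class DIFImpact:
    theta_initial: np.ndarray
    theta_corrected: np.ndarray
    differences: np.ndarray
    quartiles: dict[str, float]


def _mcfadden_r2(y: np.ndarray, x: np.ndarray) -> float:
    """McFadden pseudo-R2 of a proportional-odds fit; the intercept-only
    model reproduces the marginal category proportions, so its
    log-likelihood has the closed multinomial form."""
    counts = np.bincount(y)
    counts = counts[counts > 0]
    ll0 = float((counts * np.log(counts / y.size)).sum())
    model = OrderedModel(y, x, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="lbfgs", maxiter=200, disp=False)
    if not np.isfinite(res.llf):
        raise RuntimeError("ordinal fit did not converge")
    return 1.0 - res.llf / ll0


def detect_dif(
    matrix: ResponseMatrix,
    theta: np.ndarray,
    group: np.ndarray,
    threshold: float = 0.02,
) -> list[DIFResult]:
    """Per-item nested proportional-odds DIF screen.

    ``theta`` is the trait estimate used as the matching variable (finite,
    one per person); ``group`` holds binary labels.  Items where the fits
    fail or the nested log-likelihoods are inconsistent are reported with
    flag ``unstable`` rather than dropped.
    """
    theta = np.asarray(theta, dtype=float)
    group = np.asarray(group)
    if not np.isfinite(theta).all():
        raise ValueError("theta must be finite")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels")
    g01 = (group == levels[1]).astype(float)
    results: list[DIFResult] = []
    for j, iid in enumerate(matrix.item_ids):
        obs = matrix.codes[:, j] != MISSING
        y_all = matrix.codes[obs, j]
        th = theta[obs]
        gg = g01[obs]
        # recode to consecutive categories observed in the pooled sample
        cats = np.unique(y_all)
        y = np.searchsorted(cats, y_all)
        for lvl in (0.0, 1.0):
            sub = y[gg == lvl]
            present = np.unique(sub)
            if present.size and present.size < cats.size:
                warnings.warn(
                    f"item {iid!r}: empty categories in one group; "
                    "consider collapse_categories before DIF testing"
                )
                break
        if cats.size < 2 or np.unique(gg).size < 2:
            results.append(DIFResult(iid, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, "unstable"))
            continue
        try:
            r2_1 = _mcfadden_r2(y, th[:, None])
            r2_2 = _mcfadden_r2(y, np.column_stack([th, gg]))
            r2_3 = _mcfadden_r2(y, np.column_stack([th, gg, th * gg]))
        except Exception:
            results.append(DIFResult(iid, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, np.nan, "unstable"))
            continue
        if r2_2 < r2_1 - 1e-6 or r2_3 < r2_2 - 1e-6:
            results.append(DIFResult(iid, r2_1, r2_2, r2_3,
                                     np.nan, np.nan, np.nan, "unstable"))
            continue
        d_unif = max(0.0, r2_2 - r2_1)
        d_nonunif = max(0.0, r2_3 - r2_2)
        d_total = max(0.0, r2_3 - r2_1)
        if d_total >= threshold:
            flag = "uniform" if d_unif >= d_nonunif else "nonuniform"
        else:
            flag = "none"
        results.append(
            DIFResult(iid, r2_1, r2_2, r2_3, d_unif, d_nonunif, d_total, flag)
        )
    return results


def score_for_dif(
    matrix: ResponseMatrix,
    bank: ItemBank,
    exclude_items: list[str] | None = None,
    grid: Quadrature | None = None,
) -> np.ndarray:
    """Pooled EAP trait estimates used as the DIF matching variable,
    optionally excluding (purifying away) flagged items."""
    codes = matrix.align_to(bank)
    if exclude_items:
        for iid in exclude_items:
            codes[:, bank.index(iid)] = MISSING
    est = eap_score_matrix(codes, bank, grid)
    return np.array([e.theta for e in est])


def dif_corrected_theta(
    matrix: ResponseMatrix,
    bank: ItemBank,
    dif_flags: list[DIFResult],
    group: np.ndarray,
    grid: Quadrature | None = None,
) -> DIFImpact:
    """Initial (pooled) vs DIF-corrected EAP estimates.

    Flagged items are re-estimated separately per group with all unflagged
    items fixed at their pooled parameters (anchored calibration); every
    person is then rescored with their group's bank.
    """
    flagged = [r.item_id for r in dif_flags if r.flag in ("uniform", "nonuniform")]
    group = np.asarray(group)
    levels = np.unique(group)
    codes = matrix.align_to(bank)
    initial = eap_score_matrix(codes, bank, grid)
    theta_init = np.array([e.theta for e in initial])
    if not flagged:
        zeros = np.zeros_like(theta_init)
        return DIFImpact(theta_init, theta_init.copy(), zeros,
                         {"q25": 0.0, "q50": 0.0, "q75": 0.0})
    if len(flagged) == len(bank):
        raise ValueError("all items flagged: no anchor items left")
    theta_corr = np.empty_like(theta_init)
    for lvl in levels:
        sel = group == lvl
        sub = ResponseMatrix(
            [p for p, s in zip(matrix.persons, sel) if s],
            list(matrix.item_ids),
            matrix.codes[sel],
            n_categories=matrix.n_categories.copy(),
        )
        fit = fit_grm(
            sub, grid=grid, init_bank=bank, free_items=flagged,
            label=f"group {lvl} anchored",
        )
        est = eap_score_matrix(sub.align_to(fit.bank), fit.bank, grid)
        theta_corr[sel] = [e.theta for e in est]
    diff = theta_init - theta_corr
    q = {f"q{p}": float(np.percentile(diff, p)) for p in (25, 50, 75)}
    return DIFImpact(theta_init, theta_corr, diff, q)


def binarize_covariate(values: pd.Series) -> tuple[np.ndarray, str] | None:
    """Two-level covariate as 0/1; continuous covariates get a median split.
    Returns None when only one level is present."""
    vals = pd.Series(values)
    if vals.nunique(dropna=True) < 2:
        return None
    if vals.nunique(dropna=True) == 2:
        levels = np.sort(vals.dropna().unique())
        return (vals == levels[1]).to_numpy().astype(int), f"{levels[0]} vs {levels[1]}"
    if np.issubdtype(vals.dtype, np.number):
        med = float(vals.median())
        return (vals >= med).to_numpy().astype(int), f"< {med:g} vs >= {med:g}"
    raise ValueError("non-numeric covariate with more than 2 levels")


def dif_battery(
    matrix: ResponseMatrix,
    bank: ItemBank,
    covariates: pd.DataFrame,
    threshold: float = 0.02,
    purify: bool = False,
    grid: Quadrature | None = None,
) -> dict[str, list[DIFResult]]:
    """Run the DIF screen once per covariate column; continuous covariates
    are median-split.  Covariates with a single level are skipped with a
    warning."""
    if len(covariates) != matrix.n_persons:
        raise ValueError("covariate table does not match matrix persons")
    theta = score_for_dif(matrix, bank, grid=grid)
    tables: dict[str, list[DIFResult]] = {}
    for name in covariates.columns:
        binar = binarize_covariate(covariates[name])
        if binar is None:
            warnings.warn(f"covariate {name!r} has a single level; skipped")
            continue
        g, _ = binar
        res = detect_dif(matrix, theta, g, threshold)
        if purify:
            flagged = [r.item_id for r in res if r.flag in ("uniform", "nonuniform")]
            if flagged and len(flagged) < len(bank):
                theta_p = score_for_dif(matrix, bank, exclude_items=flagged, grid=grid)
                res = detect_dif(matrix, theta_p, g, threshold)
        tables[name] = res
    return tables
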