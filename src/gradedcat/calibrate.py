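"""Marginal maximum-likelihood GRM calibration and S-X2 item-fit testing.

Calibration is Bock–Aitkin EM: the E-step places posterior weight on a fixed
quadrature grid under a standard-normal prior (which also identifies the
latent metric); the M-step updates each item's slope and thresholds by
Fisher scoring with step-halving on the expected complete-data
log-likelihood.  Thresholds are parameterised as (b1, log-gaps) so ordering
can never break during optimisation.

Item fit is the polytomous generalisation of the Orlando–Thissen S-X2:
observed category frequencies within rest-score groups are compared with
model-expected frequencies obtained from the Lord–Wingersky summed-score
recursion integrated against the prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm

from .grm import (
    MISSING,
    ItemBank,
    ItemParameters,
    Metric,
    Quadrature,
    ResponseMatrix,
)

__all__ = [
    "CalibrationResult",
    "ItemFitResult",
    "fit_grm",
    "s_x2_item_fit",
    "lord_wingersky",
    "suggest_collapse_plan",
]


@dataclass
class CalibrationResult:
    bank: ItemBank
    loglik: float
    n_iterations: int
    converged: bool
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    se_of_parameters: dict | None = None


@dataclass(frozen=True)
class ItemFitResult:
    item_id: str
    s_x2: float
    df: int
    p_value: float
    misfit: bool


# ---------------------------------------------------------------------------
# parameterisation helpers: x = (a, b1, log g2 .. log g_{K-1})
# ---------------------------------------------------------------------------

def _params_to_x(a: float, thresholds: np.ndarray) -> np.ndarray:
    gaps = np.diff(thresholds)
    return np.concatenate([[a, thresholds[0]], np.log(np.maximum(gaps, 1e-6))])


def _x_to_thresholds(x: np.ndarray, k: int) -> np.ndarray:
    b = np.empty(k - 1)
    b[0] = x[1]
    if k > 2:
        b[1:] = x[1] + np.cumsum(np.exp(x[2:k]))
    return b


def _validate_items(codes: np.ndarray, ks: np.ndarray, item_ids) -> None:
    for j, k in enumerate(ks):
        counts = np.bincount(codes[codes[:, j] >= 0, j], minlength=k)[:k]
        if (counts == 0).any():
            empty = np.where(counts == 0)[0].tolist()
            raise ValueError(
                f"item {item_ids[j]!r} has empty response categories {empty}; "
                "merge sparse categories with collapse_categories() first"
            )
        if k < 2:
            raise ValueError(f"item {item_ids[j]!r} has fewer than 2 categories")


def suggest_collapse_plan(
    matrix: ResponseMatrix, min_count: int = 1
) -> dict[str, dict[int, int]]:
    """Merge plan joining adjacent categories until every retained category
    has at least ``min_count`` observed responses.  Returns only items that
    need collapsing."""
    plan: dict[str, dict[int, int]] = {}
    for j, iid in enumerate(matrix.item_ids):
        k = int(matrix.n_categories[j])
        counts = np.bincount(
            matrix.codes[matrix.codes[:, j] >= 0, j], minlength=k
        )[:k]
        groups: list[list[int]] = []
        run = 0
        cur: list[int] = []
        for c in range(k):
            cur.append(c)
            run += counts[c]
            if run >= min_count:
                groups.append(cur)
                cur, run = [], 0
        if cur:  # sparse tail merges into the last closed group
            if groups:
                groups[-1].extend(cur)
            else:
                groups.append(cur)
        if len(groups) < k:
            mapping = {c: gi for gi, grp in enumerate(groups) for c in grp}
            plan[iid] = mapping
    return plan


# ---------------------------------------------------------------------------
# EM calibration
# ---------------------------------------------------------------------------

def _prob_tables(a, b, ks, nodes):
    """P (I, Q, Kmax) with padded categories exactly 0."""
    star = expit(a[:, None, None] * (nodes[None, :, None] - b[:, None, :]))
    star = np.concatenate(
        [np.ones(star.shape[:-1] + (1,)), star, np.zeros(star.shape[:-1] + (1,))],
        axis=-1,
    )
    return star[..., :-1] - star[..., 1:]


def _expected_loglik(p, r, real_cat):
    pc = np.where(real_cat[:, None, :] & (p > 1e-300), p, 1.0)
    return (r * np.log(pc)).sum(axis=(1, 2))


def _m_step(x, r, ks, nodes, slope_bounds, free, n_inner=5):
    """Batched Fisher-scoring update of all free items.  Returns updated x."""
    n_items, d_max = x.shape
    kmax = int(ks.max())
    real_cat = np.arange(kmax)[None, :] < ks[:, None]          # (I, K)
    real_thr = np.arange(kmax - 1)[None, :] < (ks - 1)[:, None]  # (I, K-1)
    real_par = np.arange(d_max)[None, :] < ks[:, None]          # (I, D)
    q = nodes.size

    def curves(xc):
        a = xc[:, 0]
        gaps = np.exp(xc[:, 2:]) * real_thr[:, 1:]
        b = xc[:, 1][:, None] + np.concatenate(
            [np.zeros((n_items, 1)), np.cumsum(gaps, axis=1)], axis=1
        )
        b = np.where(real_thr, b, np.inf)
        return a, b, gaps

    def objective(xc):
        a, b, _ = curves(xc)
        p = _prob_tables(a, b, ks, nodes)
        return _expected_loglik(p, r, real_cat)

    f = objective(x)
    for _ in range(n_inner):
        a, b, gaps = curves(x)
        star = expit(a[:, None, None] * (nodes[None, :, None] - b[:, None, :]))
        u = star * (1.0 - star)                                  # (I, Q, K-1)
        p = _prob_tables(a, b, ks, nodes)
        p_safe = np.where(real_cat[:, None, :] & (p > 1e-12), p, 1.0)

        # jacobian of the K-1 cumulative curves wrt the D parameters
        tj = np.zeros((n_items, kmax - 1, d_max))  # db_k/dx_d for d >= 1
        tj[:, :, 1] = 1.0
        for m in range(2, d_max):
            km = np.arange(kmax - 1) >= (m - 1)
            tj[:, km, m] = gaps[:, m - 2 : m - 1]
        tj *= real_thr[:, :, None]
        bt = np.where(real_thr, b, 0.0)
        dstar = np.empty((n_items, q, kmax - 1, d_max))
        dstar[..., 0] = u * (nodes[None, :, None] - bt[:, None, :])
        dstar[..., 1:] = -(a[:, None, None, None] * u[..., None]) * tj[:, None, :, 1:]
        dstar *= real_thr[:, None, :, None]
        zero = np.zeros((n_items, q, 1, d_max))
        dse = np.concatenate([zero, dstar, zero], axis=2)
        dp = dse[:, :, :-1, :] - dse[:, :, 1:, :]                # (I, Q, K, D)

        grad = np.einsum("iqk,iqkd->id", r / p_safe, dp)
        nq = r.sum(axis=2)                                        # (I, Q)
        w = nq[:, :, None] / p_safe
        h = np.einsum("iqk,iqkd,iqke->ide", w, dp, dp)
        h += 1e-8 * np.eye(d_max)[None]
        # freeze padded / non-free parameters
        par_mask = real_par & free[:, None]
        grad = np.where(par_mask, grad, 0.0)
        eye = np.eye(d_max, dtype=bool)[None]
        h = np.where(par_mask[:, None, :] & par_mask[:, :, None], h, 0.0)
        h[np.broadcast_to(eye, h.shape) & ~(par_mask[:, None, :] & par_mask[:, :, None])] = 1.0

        try:
            step = np.linalg.solve(h, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.einsum("idd->id", h), 1.0)
        step = np.clip(step, -2.0, 2.0)

        alpha = np.ones(n_items)
        x_new = x.copy()
        for _ in range(12):
            trial = x + alpha[:, None] * step
            trial[:, 0] = np.clip(trial[:, 0], *slope_bounds)
            trial[:, 1] = np.clip(trial[:, 1], -20.0, 20.0)
            trial[:, 2:] = np.clip(trial[:, 2:], -9.0, 3.0)
            f_new = objective(trial)
            improved = f_new >= f - 1e-12
            x_new = np.where(improved[:, None], trial, x_new)
            f = np.where(improved, f_new, f)
            alpha = np.where(improved, alpha, alpha / 2.0)
            if improved.all():
                break
        x = np.where(free[:, None], x_new, x)
        if np.abs(grad).max() < 1e-7:
            break
    return x


def fit_grm(
    matrix: ResponseMatrix,
    *,
    grid: Quadrature | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    slope_bounds: tuple[float, float] = (0.05, 10.0),
    init_bank: ItemBank | None = None,
    free_items: list[str] | None = None,
    label: str = "",
) -> CalibrationResult:
    """Bock–Aitkin EM fit of the GRM on the sample metric (prior N(0, 1)).

    ``init_bank``/``free_items`` support anchored recalibration: items not in
    ``free_items`` keep their ``init_bank`` parameters fixed (used when
    re-estimating DIF-flagged items against anchor items).
    """
    grid = grid or Quadrature.default()
    matrix = matrix.drop_empty_persons()
    codes = matrix.codes
    ks = matrix.n_categories.astype(int)
    item_ids = matrix.item_ids
    n_items = len(item_ids)
    kmax = int(ks.max())
    d_max = kmax  # 1 slope + (kmax-1) threshold parameters

    free = np.ones(n_items, dtype=bool)
    if free_items is not None:
        free = np.array([iid in set(free_items) for iid in item_ids])
    # anchored (fixed) items need no category validation
    free_idx = np.where(free)[0]
    _validate_items(codes[:, free_idx], ks[free_idx],
                    [item_ids[j] for j in free_idx])

    # initial values: slope 1.5, thresholds from marginal cumulative splits
    x = np.zeros((n_items, d_max))
    for j in range(n_items):
        if init_bank is not None and item_ids[j] in init_bank.item_ids:
            it = init_bank[item_ids[j]]
            xj = _params_to_x(it.slope, np.asarray(it.thresholds))
        else:
            obs = codes[codes[:, j] >= 0, j]
            props = np.bincount(obs, minlength=ks[j])[: ks[j]] / obs.size
            cum = 1.0 - np.cumsum(props)[:-1]  # P(X >= k), k=1..K-1
            cum = np.clip(cum, 1.0 / (2 * obs.size), 1 - 1.0 / (2 * obs.size))
            b0 = -norm.ppf(cum) * 1.3
            b0 = np.maximum.accumulate(b0 + 1e-3 * np.arange(ks[j] - 1))
            b0 += 1e-3 * np.arange(ks[j] - 1)  # enforce strict order
            xj = _params_to_x(1.5, b0)
        x[j, : ks[j]] = xj[: ks[j]]

    nodes, wq = grid.nodes, grid.weights
    real_cat = np.arange(kmax)[None, :] < ks[:, None]
    history = []
    converged = False
    it_count = 0
    prev_nat = None
    for it_count in range(1, max_iter + 1):
        a = x[:, 0]
        b = np.stack([
            np.pad(_x_to_thresholds(x[j], ks[j]), (0, kmax - ks[j]),
                   constant_values=np.inf)
            for j in range(n_items)
        ])
        p = _prob_tables(a, b, ks, nodes)
        logp = np.log(np.where(real_cat[:, None, :] & (p > 1e-300), p, 1.0))

        ll = np.zeros((codes.shape[0], nodes.size))
        for j in range(n_items):
            answered = codes[:, j] != MISSING
            if answered.any():
                ll[answered] += logp[j][:, codes[answered, j]].T
        joint = ll + np.log(wq)[None, :]
        loglik = float(logsumexp(joint, axis=1).sum())
        history.append(loglik)

        post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        r = np.zeros((n_items, nodes.size, kmax))
        for j in range(n_items):
            for k in range(ks[j]):
                sel = codes[:, j] == k
                if sel.any():
                    r[j, :, k] = post[sel].sum(axis=0)

        x = _m_step(x, r, ks, nodes, slope_bounds, free)

        # natural-scale parameters for the convergence test
        nat = np.full((n_items, d_max), 0.0)
        nat[:, 0] = x[:, 0]
        for j in range(n_items):
            nat[j, 1 : ks[j]] = _x_to_thresholds(x[j], ks[j])
        if prev_nat is not None:
            delta = np.abs(nat[free] - prev_nat[free]).max() if free.any() else 0.0
            if delta < tol:
                converged = True
                break
        prev_nat = nat.copy()

    items = []
    for j in range(n_items):
        items.append(
            ItemParameters(
                item_ids[j], float(x[j, 0]),
                tuple(_x_to_thresholds(x[j], ks[j])), int(ks[j]),
            )
        )
    bank = ItemBank(items, metric=Metric(), label=label or "calibrated bank")
    if not converged:
        warnings.warn("EM did not converge; best iterate returned")
    return CalibrationResult(
        bank=bank,
        loglik=history[-1],
        n_iterations=it_count,
        converged=converged,
        loglik_history=np.array(history),
    )


# ---------------------------------------------------------------------------
# S-X2 item fit
# ---------------------------------------------------------------------------

def lord_wingersky(prob_tables: list[np.ndarray]) -> np.ndarray:
    """Summed-score likelihoods: input per-item category-probability tables
    (Q, K_i); output (Q, S+1) with S = sum_i (K_i - 1).  Rows sum to 1 at
    every quadrature node."""
    q = prob_tables[0].shape[0]
    out = np.ones((q, 1))
    for p in prob_tables:
        k = p.shape[1]
        new = np.zeros((q, out.shape[1] + k - 1))
        for c in range(k):
            new[:, c : c + out.shape[1]] += out * p[:, c : c + 1]
        out = new
    return out


def _merge_rows(o: np.ndarray, e: np.ndarray, min_expected: float):
    """Greedily pool adjacent rest-score rows until all expected cells of a
    pooled row reach ``min_expected``."""
    rows_o, rows_e = [], []
    acc_o = np.zeros(o.shape[1])
    acc_e = np.zeros(o.shape[1])
    for s in range(o.shape[0]):
        acc_o += o[s]
        acc_e += e[s]
        if (acc_e >= min_expected).all():
            rows_o.append(acc_o)
            rows_e.append(acc_e)
            acc_o, acc_e = np.zeros(o.shape[1]), np.zeros(o.shape[1])
    if acc_e.sum() > 0 or acc_o.sum() > 0:
        if rows_o:
            rows_o[-1] = rows_o[-1] + acc_o
            rows_e[-1] = rows_e[-1] + acc_e
        else:
            rows_o.append(acc_o)
            rows_e.append(acc_e)
    return rows_o, rows_e


def _merge_cells(o_row: np.ndarray, e_row: np.ndarray, min_expected: float):
    """Pool adjacent category cells within a row until all expected >= min."""
    cells_o, cells_e = [], []
    acc_o = acc_e = 0.0
    for c in range(o_row.size):
        acc_o += o_row[c]
        acc_e += e_row[c]
        if acc_e >= min_expected:
            cells_o.append(acc_o)
            cells_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:
        if cells_o:
            cells_o[-1] += acc_o
            cells_e[-1] += acc_e
        else:
            cells_o.append(acc_o)
            cells_e.append(acc_e)
    return np.array(cells_o), np.array(cells_e)


def s_x2_item_fit(
    bank: ItemBank,
    matrix: ResponseMatrix,
    *,
    grid: Quadrature | None = None,
    min_expected: float = 1.0,
    alpha: float = 0.001,
) -> list[ItemFitResult]:
    """Orlando–Thissen S-X2 for every bank item, on complete cases.

    Rest-score groups (summed score over the other items) with expected
    cells below ``min_expected`` are pooled with adjacent groups; degrees of
    freedom are sum over rows of (cells - 1) minus the item's parameter
    count.  Items with fewer than 2 usable score groups are skipped with a
    warning."""
    grid = grid or Quadrature.default()
    cc = matrix.complete_cases()
    if set(cc.item_ids) != set(bank.item_ids):
        raise ValueError("matrix and bank must cover the same items")
    codes = cc.align_to(bank)
    a, b, ks = bank.arrays()
    p_tables = _prob_tables(a, b, ks, grid.nodes)  # (I, Q, Kmax)
    results: list[ItemFitResult] = []
    n_items = len(bank)
    for i in range(n_items):
        others = [j for j in range(n_items) if j != i]
        rest = codes[:, others].sum(axis=1)
        lw = lord_wingersky([p_tables[j][:, : ks[j]] for j in others])
        s_max = lw.shape[1] - 1
        d = (grid.weights[:, None] * lw).sum(axis=0)            # (S+1,)
        numer = (grid.weights[:, None] * lw).T @ p_tables[i][:, : ks[i]]
        n_s = np.bincount(rest, minlength=s_max + 1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(d[:, None] > 0, numer / d[:, None], 0.0)
        e = n_s[:, None] * cond
        o = np.zeros_like(e)
        for k in range(ks[i]):
            o[:, k] = np.bincount(rest[codes[:, i] == k], minlength=s_max + 1)
        keep = n_s > 0
        rows_o, rows_e = _merge_rows(o[keep], e[keep], min_expected)
        if len(rows_o) < 2:
            warnings.warn(
                f"item {bank.item_ids[i]!r}: fewer than 2 usable score groups; skipped"
            )
            continue
        stat = 0.0
        n_cells = 0
        n_rows = len(rows_o)
        for o_row, e_row in zip(rows_o, rows_e):
            oc, ec = _merge_cells(o_row, e_row, min_expected)
            stat += float((((oc - ec) ** 2) / ec).sum())
            n_cells += oc.size
        n_params = int(ks[i])  # slope + K-1 thresholds
        df = n_cells - n_rows - n_params
        if df < 1:
            warnings.warn(
                f"item {bank.item_ids[i]!r}: non-positive degrees of freedom; skipped"
            )
            continue
        p_val = float(chi2.sf(stat, df))
        results.append(
            ItemFitResult(bank.item_ids[i], stat, df, p_val, p_val <= alpha)
        )
    return results
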