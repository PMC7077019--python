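"""IRT assumption screening for ordinal item banks.

Covers the standard pre-calibration checks: polychoric correlations,
eigenvalue-based unidimensionality criteria, a forced two-factor varimax
solution, Schmid–Leiman bifactor indices (omega-H and explained common
variance), residual-correlation local-dependence screening with SRMR, and
Mokken scalability coefficients for monotonicity.

The polychoric estimator is the usual two-step one: item thresholds from the
univariate margins by inverse-normal transform, then each pairwise latent
correlation by maximising the bivariate-normal likelihood of the observed
contingency table.  The bivariate normal CDF is evaluated through Owen's T
function, which keeps the 1000+ pairwise optimisations of a 46-item bank
fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import owens_t
from scipy.stats import norm

from .grm import MISSING, ResponseMatrix

__all__ = [
    "AssumptionReport",
    "ResidualReport",
    "bvn_cdf",
    "polychoric_matrix",
    "efa_criteria",
    "forced_two_factor_varimax",
    "bifactor_indices",
    "residual_analysis",
    "mokken_scalability",
    "assumption_report",
]


# ---------------------------------------------------------------------------
# bivariate normal CDF (Owen, 1956)
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation
    ``rho``; vectorised over h, k."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    # finite surrogates for +/- infinity keep the formula exact to ~1e-17
    h = np.clip(h, -8.5, 8.5)
    k = np.clip(k, -8.5, 8.5)
    rho = float(np.clip(rho, -0.9999, 0.9999))
    if rho == 0.0:
        return norm.cdf(h) * norm.cdf(k)
    # avoid the removable singularities at h == 0 or k == 0
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    denom = np.sqrt(1.0 - rho * rho)
    a1 = (k - rho * h) / (h * denom)
    a2 = (h - rho * k) / (k * denom)
    beta = np.where(h * k > 0, 0.0, 0.5)
    out = (
        0.5 * (norm.cdf(h) + norm.cdf(k))
        - owens_t(h, a1)
        - owens_t(k, a2)
        - beta
    )
    return np.clip(out, 0.0, 1.0)


def _cell_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Category cell probabilities from latent thresholds tx, ty."""
    ex = np.concatenate([[-np.inf], tx, [np.inf]])
    ey = np.concatenate([[-np.inf], ty, [np.inf]])
    corner = bvn_cdf(ex[:, None], ey[None, :], rho)
    return np.diff(np.diff(corner, axis=0), axis=1)


def _pair_rho(table: np.ndarray, tx: np.ndarray, ty: np.ndarray) -> float:
    def nll(rho: float) -> float:
        p = np.clip(_cell_probs(tx, ty, rho), 1e-12, 1.0)
        return -float((table * np.log(p)).sum())

    res = optimize.minimize_scalar(
        nll, bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x)


def polychoric_matrix(matrix: ResponseMatrix) -> np.ndarray:
    """Two-step polychoric correlation matrix (symmetric, unit diagonal);
    repaired to the nearest positive semi-definite matrix if needed."""
    p = matrix.n_items
    codes = matrix.codes
    thresholds: list[np.ndarray] = []
    for j in range(p):
        obs = codes[codes[:, j] >= 0, j]
        if obs.size == 0 or obs.min() == obs.max():
            raise ValueError(
                f"item {matrix.item_ids[j]!r} has zero variance; "
                "polychoric correlation undefined"
            )
        k = int(matrix.n_categories[j])
        props = np.bincount(obs, minlength=k)[:k] / obs.size
        cum = np.clip(np.cumsum(props)[:-1], 1e-10, 1 - 1e-10)
        thresholds.append(norm.ppf(cum))
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            both = (codes[:, i] >= 0) & (codes[:, j] >= 0)
            ki = int(matrix.n_categories[i])
            kj = int(matrix.n_categories[j])
            table = np.zeros((ki, kj))
            np.add.at(table, (codes[both, i], codes[both, j]), 1.0)
            r[i, j] = r[j, i] = _pair_rho(table, thresholds[i], thresholds[j])
    eigval = np.linalg.eigvalsh(r)
    if eigval.min() < -1e-8:
        warnings.warn("polychoric matrix not PSD; applying eigenvalue clipping")
        w, v = np.linalg.eigh(r)
        w = np.clip(w, 1e-8, None)
        r = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
    return r


# ---------------------------------------------------------------------------
# factor-analytic criteria
# ---------------------------------------------------------------------------

def efa_criteria(
    corr: np.ndarray, pct_threshold: float = 0.20, ratio_threshold: float = 4.0
) -> tuple[np.ndarray, float, float, dict[str, bool]]:
    """Eigenvalues plus the first-factor share and first/second ratio rules."""
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    pct_first = float(eig[0] / corr.shape[0])
    ratio = float(eig[0] / eig[1])
    flags = {
        "first_factor_pct": pct_first >= pct_threshold,
        "first_to_second_ratio": ratio > ratio_threshold,
    }
    return eig, pct_first, ratio, flags


def _principal_axis(corr: np.ndarray, n_factors: int, n_iter: int = 100) -> np.ndarray:
    """Principal-axis factoring with iterated communalities; Heywood
    communalities clipped at 0.999."""
    p = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
        h2 = 1.0 - 1.0 / np.diag(inv)  # squared multiple correlations
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.05, 0.999)
    loadings = np.zeros((p, n_factors))
    for _ in range(n_iter):
        rr = corr.copy()
        np.fill_diagonal(rr, h2)
        w, v = np.linalg.eigh(rr)
        idx = np.argsort(w)[::-1][:n_factors]
        lam = np.clip(w[idx], 0.0, None)
        loadings = v[:, idx] * np.sqrt(lam)[None, :]
        h2_new = np.clip((loadings**2).sum(axis=1), 0.0, 0.999)
        if np.abs(h2_new - h2).max() < 1e-6:
            h2 = h2_new
            break
        h2 = h2_new
    # orient each factor positively
    signs = np.sign(loadings.sum(axis=0))
    signs[signs == 0] = 1.0
    return loadings * signs[None, :]


def _varimax_criterion(lam: np.ndarray) -> float:
    l2 = lam**2
    return float((l2**2).mean(axis=0).sum() - (l2.mean(axis=0) ** 2).sum())


def _varimax(loadings: np.ndarray, n_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation; several deterministic starts guard against the
    saddle at the unrotated solution."""
    p, k = loadings.shape
    rng = np.random.default_rng(12345)
    starts = [np.eye(k)] + [
        np.linalg.qr(rng.normal(size=(k, k)))[0] for _ in range(7)
    ]
    best, best_val = loadings, -np.inf
    for rot0 in starts:
        rot = rot0
        var = 0.0
        for _ in range(n_iter):
            lam = loadings @ rot
            u, s, vt = np.linalg.svd(
                loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
            )
            rot = u @ vt
            if s.sum() < var * (1 + tol):
                break
            var = s.sum()
        lam = loadings @ rot
        val = _varimax_criterion(lam)
        if val > best_val:
            best, best_val = lam, val
    return best


def forced_two_factor_varimax(corr: np.ndarray) -> np.ndarray:
    """Two principal factors, varimax-rotated; columns ordered by explained
    variance."""
    loadings = _varimax(_principal_axis(corr, 2))
    ss = (loadings**2).sum(axis=0)
    loadings = loadings[:, np.argsort(ss)[::-1]]
    signs = np.sign(loadings.sum(axis=0))
    signs[signs == 0] = 1.0
    return loadings * signs[None, :]


def _quartimin_gpa(a: np.ndarray, n_iter: int = 500, tol: float = 1e-6):
    """Oblique gradient-projection rotation with the quartimin (oblimin,
    gamma = 0) criterion; returns rotated loadings and factor correlations.

    Starts from the varimax solution: the unrotated principal-axis loadings
    are a stationary (saddle) point of the quartimin criterion whenever the
    first factor is a near-uniform general factor, and gradient projection
    cannot leave it."""
    k = a.shape[1]
    nmat = np.ones((k, k)) - np.eye(k)

    def obj(lam):
        l2 = lam**2
        b = l2 @ nmat
        return float((l2 * b).sum()) / 4.0, lam * b

    a_vm = _varimax(a)
    t, *_ = np.linalg.lstsq(a, a_vm, rcond=None)
    # re-orthonormalise (varimax transform is orthogonal up to round-off)
    u, _, vt = np.linalg.svd(t)
    t = u @ vt
    ti = np.linalg.inv(t)
    lam = a @ ti.T
    f, gq = obj(lam)
    g = -(lam.T @ gq @ ti).T
    alpha = 1.0
    for _ in range(n_iter):
        gp = g - t @ np.diag((t * g).sum(axis=0))
        s = np.sqrt((gp**2).sum())
        if s < tol:
            break
        alpha = 2.0 * alpha
        for _ in range(20):
            x = t - alpha * gp
            x = x / np.sqrt((x**2).sum(axis=0))[None, :]
            ti = np.linalg.inv(x)
            lam = a @ ti.T
            f_new, gq = obj(lam)
            if f_new < f - 0.5 * s**2 * alpha:
                break
            alpha /= 2.0
        t = x
        f = f_new
        g = -(lam.T @ gq @ np.linalg.inv(t)).T
    phi = t.T @ t
    return lam, phi


def _second_order_loadings(phi: np.ndarray) -> np.ndarray:
    """One general factor over the group-factor correlations.  With two
    group factors the model is just-identified up to sign and the loadings
    are both sqrt(phi_12)."""
    k = phi.shape[0]
    if k == 2:
        rho = float(np.clip(phi[0, 1], 0.0, 0.995))
        return np.full(2, np.sqrt(rho))

    def loss(g):
        fitted = np.outer(g, g)
        d = phi - fitted
        return d[np.triu_indices(k, 1)]

    g0 = np.sqrt(np.clip(np.abs(phi).mean(axis=0), 0.05, 0.95))
    res = optimize.least_squares(loss, g0, bounds=(0.0, 0.9975))
    return res.x


def bifactor_indices(
    corr: np.ndarray, n_group_factors: int = 2
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Schmid–Leiman bifactor indices from an oblique EFA.

    Returns (omega_h, ecv, general loadings, group loadings).  ECV is the
    general factor's share of common variance; omega-H is the share of total
    score variance attributable to the general factor.
    """
    if n_group_factors < 2:
        raise ValueError("need at least 2 group factors")
    a = _principal_axis(corr, n_group_factors)
    lam, phi = _quartimin_gpa(a)
    signs = np.sign(lam.sum(axis=0))
    signs[signs == 0] = 1.0
    lam = lam * signs[None, :]
    phi = phi * np.outer(signs, signs)

    # Hierarchical solutions are only identified when every first-order
    # factor is defined by salient content (>= 2 loadings of 0.30 or more).
    # Undefined factors are dropped; if a single factor remains, the matrix
    # is effectively unidimensional: no group variance, ECV = 1 and
    # omega-H = omega-total.
    salient = (np.abs(lam) >= 0.30).sum(axis=0)
    keep = salient >= 2
    if keep.sum() < 2:
        general = _principal_axis(corr, 1)[:, 0]
        group = np.zeros((corr.shape[0], n_group_factors))
        psi2 = np.clip(1.0 - general**2, 0.001, 1.0)
        num = float(general.sum()) ** 2
        omega_total = num / (num + float(psi2.sum()))
        return omega_total, 1.0, general, group
    if not keep.all():
        lam = lam[:, keep]
        phi = phi[np.ix_(keep, keep)]
    gamma = _second_order_loadings(phi)
    general = lam @ gamma
    group = lam * np.sqrt(np.clip(1.0 - gamma**2, 0.0, 1.0))[None, :]
    h2 = np.clip(general**2 + (group**2).sum(axis=1), 0.0, 0.999)
    if (general**2 + (group**2).sum(axis=1) > 0.999).any():
        warnings.warn("Heywood case: communalities clipped at 0.999")
    psi2 = 1.0 - h2
    common_g = float((general**2).sum())
    common_s = float((group**2).sum())
    ecv = common_g / (common_g + common_s) if common_g + common_s > 0 else 1.0
    num = float(general.sum()) ** 2
    denom = num + float((group.sum(axis=0) ** 2).sum()) + float(psi2.sum())
    omega_h = num / denom
    return float(np.clip(omega_h, 0, 1)), float(np.clip(ecv, 0, 1)), general, group


# ---------------------------------------------------------------------------
# local dependence
# ---------------------------------------------------------------------------

@dataclass
class ResidualReport:
    residuals: np.ndarray
    mean: float
    critical: float
    flagged_pairs: list[tuple[int, int, float]]
    srmr: float
    loadings: np.ndarray
    n_pairs: int
    negative_pairs_beyond: int = 0


def residual_analysis(
    corr: np.ndarray,
    loadings: np.ndarray | None = None,
    offset: float = 0.20,
) -> ResidualReport:
    """Residual correlations after removing a single common factor.

    The one-factor loadings are an unweighted-least-squares fit of the
    off-diagonal correlations; pairs with residuals more than ``offset``
    above the mean residual are flagged as locally dependent.
    """
    p = corr.shape[0]
    iu = np.triu_indices(p, 1)
    if loadings is None:
        lam0 = _principal_axis(corr, 1)[:, 0]

        def loss(lam):
            return (corr - np.outer(lam, lam))[iu]

        res = optimize.least_squares(loss, lam0, bounds=(-1.0, 1.0))
        loadings = res.x
    resid = corr - np.outer(loadings, loadings)
    np.fill_diagonal(resid, 0.0)
    vals = resid[iu]
    mean = float(vals.mean())
    critical = mean + offset
    flagged = [
        (int(i), int(j), float(resid[i, j]))
        for i, j in zip(*iu)
        if resid[i, j] > critical
    ]
    srmr = float(np.sqrt((vals**2).mean()))
    negative_beyond = int((vals < mean - offset).sum())
    return ResidualReport(
        residuals=resid,
        mean=mean,
        critical=critical,
        flagged_pairs=flagged,
        srmr=srmr,
        loadings=np.asarray(loadings),
        n_pairs=vals.size,
        negative_pairs_beyond=negative_beyond,
    )


# ---------------------------------------------------------------------------
# Mokken scalability
# ---------------------------------------------------------------------------

def _comonotone_exy(counts_x: np.ndarray, counts_y: np.ndarray) -> float:
    """E[XY] under the comonotone coupling of two empirical margins
    (northwest-corner allocation on cumulative counts)."""
    n = counts_x.sum()
    exy = 0.0
    i = j = 0
    rem_x = counts_x[0]
    rem_y = counts_y[0]
    while i < counts_x.size and j < counts_y.size:
        mass = min(rem_x, rem_y)
        exy += mass * i * j
        rem_x -= mass
        rem_y -= mass
        if rem_x == 0:
            i += 1
            rem_x = counts_x[i] if i < counts_x.size else 0
        if rem_y == 0:
            j += 1
            rem_y = counts_y[j] if j < counts_y.size else 0
    return exy / n


def mokken_scalability(
    matrix: ResponseMatrix,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Scalability coefficients H (scale), H_i (items), H_ij (pairs).

    H_ij is the observed covariance divided by its maximum given the
    observed margins (attained by the comonotone joint distribution).
    Constant items are excluded with a warning.
    """
    codes = matrix.codes
    keep = []
    for j in range(matrix.n_items):
        obs = codes[codes[:, j] >= 0, j]
        if obs.size and obs.min() != obs.max():
            keep.append(j)
        else:
            warnings.warn(
                f"item {matrix.item_ids[j]!r} is constant; excluded from H"
            )
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant items")
    m = len(keep)
    cov = np.zeros((m, m))
    cov_max = np.zeros((m, m))
    for ai in range(m):
        for aj in range(ai + 1, m):
            i, j = keep[ai], keep[aj]
            both = (codes[:, i] >= 0) & (codes[:, j] >= 0)
            xi = codes[both, i].astype(float)
            xj = codes[both, j].astype(float)
            c = float(np.mean(xi * xj) - xi.mean() * xj.mean())
            ki = int(matrix.n_categories[i])
            kj = int(matrix.n_categories[j])
            cx = np.bincount(codes[both, i], minlength=ki)[:ki]
            cy = np.bincount(codes[both, j], minlength=kj)[:kj]
            cmax = _comonotone_exy(cx, cy) - xi.mean() * xj.mean()
            cov[ai, aj] = cov[aj, ai] = c
            cov_max[ai, aj] = cov_max[aj, ai] = cmax
    h_ij = np.where(cov_max > 0, cov / np.where(cov_max > 0, cov_max, 1.0), np.nan)
    h_i = cov.sum(axis=1) / cov_max.sum(axis=1)
    iu = np.triu_indices(m, 1)
    h = float(cov[iu].sum() / cov_max[iu].sum())
    return h, h_i, h_ij


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

@dataclass
class AssumptionReport:
    eigenvalues: np.ndarray
    pct_variance_first: float
    ratio_first_second: float
    omega_h: float
    ecv: float
    residual_mean: float
    residual_critical: float
    flagged_pairs: list[tuple[str, str, float]]
    srmr: float
    mokken_H: float
    mokken_Hi: np.ndarray
    criteria_met: dict[str, bool] = field(default_factory=dict)


def assumption_report(
    matrix: ResponseMatrix,
    n_group_factors: int = 2,
    residual_offset: float = 0.20,
) -> AssumptionReport:
    """Run the full assumption screen on one response matrix."""
    corr = polychoric_matrix(matrix)
    eig, pct, ratio, efa_flags = efa_criteria(corr)
    omega_h, ecv, _, _ = bifactor_indices(corr, n_group_factors)
    res = residual_analysis(corr, offset=residual_offset)
    h, h_i, _ = mokken_scalability(matrix)
    flagged = [
        (matrix.item_ids[i], matrix.item_ids[j], v)
        for i, j, v in res.flagged_pairs
    ]
    criteria = {
        **efa_flags,
        "omega_h": omega_h > 0.80,
        "ecv": ecv > 0.60,
        "mokken_scale": h >= 0.50,
        "mokken_items": bool((h_i >= 0.30).all()),
    }
    return AssumptionReport(
        eigenvalues=eig,
        pct_variance_first=pct,
        ratio_first_second=ratio,
        omega_h=omega_h,
        ecv=ecv,
        residual_mean=res.mean,
        residual_critical=res.critical,
        flagged_pairs=flagged,
        srmr=res.srmr,
        mokken_H=h,
        mokken_Hi=h_i,
        criteria_met=criteria,
    )
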