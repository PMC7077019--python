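"""Core graded response model (GRM) mathematics.

The GRM describes ordered polytomous item responses through cumulative
logistic curves.  For an item with ``K`` categories, slope ``a`` and ordered
thresholds ``b_1 < ... < b_{K-1}``, the probability of responding in category
``k`` or higher is ``P*_k(theta) = expit(a * (theta - b_k))``, and the
category probability is the difference of adjacent cumulative curves.
Everything downstream — Fisher information, standard errors, expected a
posteriori (EAP) scoring, and the T-score reporting metric — is derived from
these curves.

Slopes are on the plain logistic metric (no 1.702 scaling constant), matching
the convention of published PROMIS item parameter tables.  Category codes are
0-based throughout; ``-1`` marks a missing response inside code arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Metric",
    "ItemParameters",
    "ItemBank",
    "ResponseMatrix",
    "ThetaEstimate",
    "Quadrature",
    "category_probabilities",
    "item_information",
    "bank_information",
    "test_information_and_se",
    "t_score",
    "reliability_from_se",
    "eap_score",
    "eap_score_matrix",
]

MISSING = -1

#: categories with probability below this bound contribute nothing to
#: information or likelihood (guards 0/0 in the tails).
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class Metric:
    """Linear reporting metric: T = reference_mean + reference_sd * theta."""

    reference_mean: float = 50.0
    reference_sd: float = 10.0

    def __post_init__(self) -> None:
        if not self.reference_sd > 0:
            raise ValueError("reference_sd must be positive")


@dataclass(frozen=True)
class ItemParameters:
    """Slope and ordered thresholds of one graded-response item."""

    item_id: str
    slope: float
    thresholds: tuple[float, ...]
    n_categories: int = 0  # 0 -> derived from thresholds

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        k = self.n_categories or len(thr) + 1
        object.__setattr__(self, "n_categories", k)
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise ValueError(f"item {self.item_id}: slope must be positive")
        if k < 2 or len(thr) != k - 1:
            raise ValueError(
                f"item {self.item_id}: need n_categories - 1 thresholds"
            )
        if not all(np.isfinite(thr)):
            raise ValueError(f"item {self.item_id}: non-finite threshold")
        if any(t2 <= t1 for t1, t2 in zip(thr, thr[1:])):
            raise ValueError(
                f"item {self.item_id}: thresholds must be strictly increasing"
            )


class ItemBank:
    """Ordered collection of calibrated items plus the reporting metric."""

    def __init__(
        self,
        items: Iterable[ItemParameters],
        metric: Metric | None = None,
        label: str = "",
    ) -> None:
        self.items: list[ItemParameters] = list(items)
        self.metric = metric or Metric()
        self.label = label
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        self._index = {iid: i for i, iid in enumerate(ids)}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, key: int | str) -> ItemParameters:
        if isinstance(key, str):
            return self.items[self._index[key]]
        return self.items[key]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def index(self, item_id: str) -> int:
        return self._index[item_id]

    def subset(self, item_ids: Sequence[str], label: str = "") -> "ItemBank":
        return ItemBank(
            [self[i] for i in item_ids], metric=self.metric,
            label=label or f"{self.label}[{len(item_ids)} items]",
        )

    # -- padded array view (for vectorised code) ----------------------------
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (slopes (I,), thresholds (I, Kmax-1) padded with +inf,
        n_categories (I,))."""
        ks = np.array([it.n_categories for it in self.items], dtype=int)
        kmax = int(ks.max())
        a = np.array([it.slope for it in self.items], dtype=float)
        b = np.full((len(self.items), kmax - 1), np.inf)
        for i, it in enumerate(self.items):
            b[i, : it.n_categories - 1] = it.thresholds
        return a, b, ks


@dataclass
class ResponseMatrix:
    """Persons x items ordinal response codes; ``-1`` codes a missing cell."""

    persons: list[str]
    item_ids: list[str]
    codes: np.ndarray
    n_categories: np.ndarray | None = None
    category_labels: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.shape != (len(self.persons), len(self.item_ids)):
            raise ValueError("codes shape does not match persons x items")
        if self.codes.size and self.codes.min() < MISSING:
            raise ValueError("codes must be >= -1")
        if self.n_categories is None:
            observed = np.where(self.codes >= 0, self.codes, 0).max(axis=0, initial=1)
            self.n_categories = np.maximum(observed + 1, 2).astype(int)
        else:
            self.n_categories = np.asarray(self.n_categories, dtype=int)
            over = (self.codes >= self.n_categories[None, :]).any(axis=0)
            if over.any():
                bad = [self.item_ids[j] for j in np.where(over)[0]]
                raise ValueError(f"codes exceed n_categories for items {bad}")

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def complete_cases(self) -> "ResponseMatrix":
        keep = ~self.missing_mask().any(axis=1)
        return ResponseMatrix(
            [p for p, k in zip(self.persons, keep) if k],
            list(self.item_ids),
            self.codes[keep],
            n_categories=self.n_categories.copy(),
            category_labels=self.category_labels,
        )

    def drop_empty_persons(self) -> "ResponseMatrix":
        keep = (self.codes != MISSING).any(axis=1)
        return ResponseMatrix(
            [p for p, k in zip(self.persons, keep) if k],
            list(self.item_ids),
            self.codes[keep],
            n_categories=self.n_categories.copy(),
            category_labels=self.category_labels,
        )

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            list(self.persons),
            [self.item_ids[j] for j in idx],
            self.codes[:, idx],
            n_categories=self.n_categories[idx],
        )

    def align_to(self, bank: ItemBank) -> np.ndarray:
        """Codes reordered to bank order; items absent from the matrix become
        missing columns."""
        out = np.full((self.n_persons, len(bank)), MISSING, dtype=np.int16)
        for j, iid in enumerate(bank.item_ids):
            if iid in self.item_ids:
                out[:, j] = self.codes[:, self.item_ids.index(iid)]
        return out


@dataclass(frozen=True)
class ThetaEstimate:
    """EAP trait estimate with its standard error on both metrics."""

    theta: float
    se_theta: float
    t_score: float
    se_t: float
    n_items_used: int
    method: str = "EAP"


@dataclass(frozen=True)
class Quadrature:
    """Fixed quadrature grid with (renormalised) standard-normal weights."""

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def default(cls, n_nodes: int = 61, lo: float = -4.0, hi: float = 4.0) -> "Quadrature":
        nodes = np.linspace(lo, hi, n_nodes)
        w = np.exp(-0.5 * nodes**2)
        return cls(nodes=nodes, weights=w / w.sum())


# ---------------------------------------------------------------------------
# category curves and information
# ---------------------------------------------------------------------------

def _cumulative(theta: np.ndarray, item: ItemParameters) -> np.ndarray:
    """P*(X >= k) for k = 0..K, shape (..., K+1); P*_0 = 1, P*_K = 0."""
    b = np.asarray(item.thresholds)
    core = expit(item.slope * (np.asarray(theta)[..., None] - b))
    shape = core.shape[:-1]
    return np.concatenate(
        [np.ones(shape + (1,)), core, np.zeros(shape + (1,))], axis=-1
    )


def category_probabilities(theta: float, item: ItemParameters) -> np.ndarray:
    """P(X = k | theta) for k = 0..K-1 as differences of cumulative curves."""
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    star = _cumulative(np.asarray(theta, dtype=float), item)
    p = star[..., :-1] - star[..., 1:]
    return np.clip(p, 0.0, 1.0)


def item_information(theta: float, item: ItemParameters) -> float | np.ndarray:
    """Fisher information of one item: sum_k P'_k(theta)^2 / P_k(theta)."""
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    star = _cumulative(np.asarray(theta, dtype=float), item)
    u = star * (1.0 - star)  # P*(1-P*); 0 at the constant ends
    dstar = item.slope * u
    p = star[..., :-1] - star[..., 1:]
    dp = dstar[..., :-1] - dstar[..., 1:]
    contrib = np.where(p > _P_FLOOR, dp**2 / np.where(p > _P_FLOOR, p, 1.0), 0.0)
    info = contrib.sum(axis=-1)
    return float(info) if info.ndim == 0 else info


def bank_information(bank: ItemBank, theta) -> np.ndarray:
    """Per-item information at theta; shape (I,) for scalar theta, (I, T)
    for a grid."""
    theta = np.asarray(theta, dtype=float)
    a, b, _ = bank.arrays()
    star = expit(a[:, None, None] * (theta.reshape(1, -1, 1) - b[:, None, :]))
    star = np.concatenate(
        [np.ones(star.shape[:-1] + (1,)), star, np.zeros(star.shape[:-1] + (1,))],
        axis=-1,
    )
    u = star * (1.0 - star)
    dstar = a[:, None, None] * u
    p = star[..., :-1] - star[..., 1:]
    dp = dstar[..., :-1] - dstar[..., 1:]
    contrib = np.where(p > _P_FLOOR, dp**2 / np.where(p > _P_FLOOR, p, 1.0), 0.0)
    info = contrib.sum(axis=-1)
    return info[:, 0] if theta.ndim == 0 else info


def test_information_and_se(
    theta: float, bank: ItemBank, item_ids: Sequence[str] | None = None
) -> tuple[float, float, float]:
    """Test information and SE(theta) = 1 / sqrt(I); zero information yields
    an infinite SE (flag value, not an exception)."""
    sub = bank if item_ids is None else bank.subset(item_ids)
    if len(sub) == 0:
        raise ValueError("need at least one item")
    info = float(np.sum(bank_information(sub, float(theta))))
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    return info, se, sub.metric.reference_sd * se


def t_score(theta: float, metric: Metric) -> float:
    return metric.reference_mean + metric.reference_sd * theta


def reliability_from_se(se_t: float, metric: Metric) -> float:
    """IRT reliability implied by an SE on the reporting metric:
    r = 1 - (SE_T / reference_sd)^2, clamped below at 0."""
    if se_t < 0:
        raise ValueError("se_t must be non-negative")
    return max(0.0, 1.0 - (se_t / metric.reference_sd) ** 2)


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------

def _log_prob_tables(bank: ItemBank, nodes: np.ndarray) -> np.ndarray:
    """log P(X_i = k | theta_q), shape (I, Q, Kmax); padded categories -inf."""
    a, b, ks = bank.arrays()
    star = expit(a[:, None, None] * (nodes[None, :, None] - b[:, None, :]))
    star = np.concatenate(
        [np.ones(star.shape[:-1] + (1,)), star, np.zeros(star.shape[:-1] + (1,))],
        axis=-1,
    )
    p = np.clip(star[..., :-1] - star[..., 1:], _P_FLOOR, 1.0)
    logp = np.log(p)
    kmax = logp.shape[-1]
    pad = np.arange(kmax)[None, :] >= ks[:, None]
    logp[np.broadcast_to(pad[:, None, :], logp.shape)] = -np.inf
    return logp


def _normalise_responses(
    responses, bank: ItemBank
) -> np.ndarray:
    """Accept a mapping item_id -> code, or a sequence aligned to bank order
    (None / -1 = missing); return an int array in bank order."""
    if isinstance(responses, Mapping):
        out = np.full(len(bank), MISSING, dtype=np.int16)
        for iid, code in responses.items():
            if iid not in bank._index:
                raise KeyError(f"response references unknown item {iid!r}")
            if code is not None and code != MISSING:
                out[bank.index(iid)] = int(code)
        return out
    arr = np.array(
        [MISSING if c is None else int(c) for c in responses], dtype=np.int16
    )
    if arr.shape != (len(bank),):
        raise ValueError("response vector length does not match bank")
    return arr


def _check_codes(codes: np.ndarray, bank: ItemBank) -> None:
    ks = np.array([it.n_categories for it in bank.items])
    bad = (codes >= ks) & (codes != MISSING)
    if bad.any():
        raise ValueError("response code out of range for its item")


def eap_score(
    responses, bank: ItemBank, grid: Quadrature | None = None
) -> ThetaEstimate:
    """Expected a posteriori trait estimate under a standard-normal prior.

    With no answered items the prior mean (0) and prior SD (1) are returned
    and ``n_items_used`` is 0.
    """
    grid = grid or Quadrature.default()
    codes = _normalise_responses(responses, bank)
    _check_codes(codes[None, :], bank)
    est = eap_score_matrix(codes[None, :], bank, grid)
    return est[0]


def eap_score_matrix(
    codes: np.ndarray, bank: ItemBank, grid: Quadrature | None = None
) -> list[ThetaEstimate]:
    """Vectorised EAP over a persons x items code array in bank order."""
    grid = grid or Quadrature.default()
    codes = np.asarray(codes, dtype=np.int16)
    _check_codes(codes, bank)
    logp = _log_prob_tables(bank, grid.nodes)  # (I, Q, K)
    n, n_items = codes.shape
    ll = np.zeros((n, grid.nodes.size))
    for i in range(n_items):
        answered = codes[:, i] != MISSING
        if answered.any():
            ll[answered] += logp[i][:, codes[answered, i]].T
    n_used = (codes != MISSING).sum(axis=1)
    ll -= ll.max(axis=1, keepdims=True)
    post = grid.weights[None, :] * np.exp(ll)
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ grid.nodes
    var = (post * (grid.nodes[None, :] - mean[:, None]) ** 2).sum(axis=1)
    sd = np.sqrt(np.maximum(var, 0.0))
    m = bank.metric
    out = []
    for p in range(n):
        if n_used[p] == 0:
            th, se = 0.0, 1.0  # prior mean and SD
        else:
            th, se = float(mean[p]), float(sd[p])
        out.append(
            ThetaEstimate(
                theta=th,
                se_theta=se,
                t_score=t_score(th, m),
                se_t=m.reference_sd * se,
                n_items_used=int(n_used[p]),
            )
        )
    return out
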