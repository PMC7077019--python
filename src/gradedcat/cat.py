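"""Post-hoc computerized adaptive testing (CAT) simulation.

Replays recorded full-bank response vectors through a maximum-information
CAT: start at the item most informative at the starting trait level, rescore
by EAP after every administered response, and continue with the most
informative unadministered item at the interim estimate.  Two stopping
regimes are supported: the standard variable-length rule (stop once the
standard error on the reporting metric drops to ``se_stop_t``, default 3.0,
or after ``max_items``, default 12) and a fixed test length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grm import (
    MISSING,
    ItemBank,
    Quadrature,
    ResponseMatrix,
    ThetaEstimate,
    bank_information,
    reliability_from_se,
    t_score,
    _log_prob_tables,
    _normalise_responses,
)

__all__ = ["CATRules", "CATRecord", "select_start_item", "run_cat",
           "simulate_cat_cohort"]


@dataclass(frozen=True)
class CATRules:
    """Stopping rules; exactly one of the SE rule (se_stop_t with max_items)
    and fixed_length may be active."""

    se_stop_t: float | None = 3.0
    max_items: int = 12
    fixed_length: int | None = None
    min_items: int = 0
    start_theta: float = 0.0
    inclusive_stop: bool = True  # stop at se_t == se_stop_t ("is reached")

    def __post_init__(self) -> None:
        if self.fixed_length is not None:
            if self.se_stop_t is not None:
                raise ValueError(
                    "fixed_length and the SE stopping rule are exclusive"
                )
            if self.fixed_length < 1:
                raise ValueError("fixed_length must be >= 1")
        if self.min_items > self.max_items:
            raise ValueError("min_items must not exceed max_items")


@dataclass
class CATRecord:
    person: str
    administered: list[str]
    interim: list[ThetaEstimate]
    final: ThetaEstimate
    stop_reason: str  # se_reached | max_items | fixed_length | items_exhausted


def select_start_item(bank: ItemBank, theta0: float) -> str:
    """Item with maximum information at theta0; ties go to bank order."""
    if len(bank) == 0:
        raise ValueError("empty bank")
    info = bank_information(bank, float(theta0))
    return bank.item_ids[int(np.argmax(info))]


def _estimate(post_w, nodes, metric, n_used) -> ThetaEstimate:
    post = post_w / post_w.sum()
    mean = float(post @ nodes)
    sd = float(np.sqrt(max((post @ (nodes - mean) ** 2), 0.0)))
    return ThetaEstimate(
        theta=mean, se_theta=sd, t_score=t_score(mean, metric),
        se_t=metric.reference_sd * sd, n_items_used=n_used,
    )


def run_cat(
    person_responses,
    bank: ItemBank,
    rules: CATRules,
    grid: Quadrature | None = None,
    person_id: str = "",
    start_item: str | None = None,
) -> CATRecord:
    """Simulate one adaptive administration against a recorded vector.

    The person must have a recorded response for every item the selector
    may pick (post-hoc design); hitting a missing response raises.
    ``start_item`` overrides the information-optimal first item.
    """
    grid = grid or Quadrature.default()
    codes = _normalise_responses(person_responses, bank)
    logp = _log_prob_tables(bank, grid.nodes)
    ll = np.zeros(grid.nodes.size)
    administered: list[str] = []
    interim: list[ThetaEstimate] = []
    remaining = list(range(len(bank)))
    nxt = bank.index(start_item) if start_item else bank.index(
        select_start_item(bank, rules.start_theta)
    )
    target_len = rules.fixed_length if rules.fixed_length is not None else rules.max_items
    est = None
    stop_reason = None
    while True:
        code = codes[nxt]
        if code == MISSING:
            raise ValueError(
                f"person {person_id!r} lacks a response for selected item "
                f"{bank.item_ids[nxt]!r}"
            )
        ll += logp[nxt][:, code]
        remaining.remove(nxt)
        administered.append(bank.item_ids[nxt])
        post_w = grid.weights * np.exp(ll - ll.max())
        est = _estimate(post_w, grid.nodes, bank.metric, len(administered))
        interim.append(est)
        if rules.fixed_length is not None:
            if len(administered) >= rules.fixed_length:
                stop_reason = "fixed_length"
                break
        else:
            se_hit = rules.se_stop_t is not None and (
                est.se_t <= rules.se_stop_t
                if rules.inclusive_stop
                else est.se_t < rules.se_stop_t
            )
            if se_hit and len(administered) >= rules.min_items:
                stop_reason = "se_reached"
                break
            if len(administered) >= rules.max_items:
                stop_reason = "max_items"
                break
        if not remaining:
            stop_reason = "items_exhausted"
            break
        info = bank_information(bank, est.theta)
        nxt = remaining[int(np.argmax(info[remaining]))]
    return CATRecord(
        person=person_id,
        administered=administered,
        interim=interim,
        final=est,
        stop_reason=stop_reason,
    )


def simulate_cat_cohort(
    matrix: ResponseMatrix,
    bank: ItemBank,
    rules: CATRules,
    grid: Quadrature | None = None,
    r_threshold: float = 0.90,
) -> tuple[list[CATRecord], dict]:
    """Replay a whole cohort through the CAT; persons with incomplete
    response vectors are dropped (post-hoc simulation needs full vectors)."""
    grid = grid or Quadrature.default()
    cc = matrix.complete_cases()
    if cc.n_persons < matrix.n_persons:
        warnings.warn(
            f"{matrix.n_persons - cc.n_persons} incomplete persons excluded "
            "from the CAT simulation"
        )
    if cc.n_persons == 0:
        return [], {"n_persons": 0, "empty": True}
    codes = cc.align_to(bank)
    start = select_start_item(bank, rules.start_theta)
    records = [
        run_cat(codes[p], bank, rules, grid, person_id=cc.persons[p],
                start_item=start)
        for p in range(cc.n_persons)
    ]
    n_items = np.array([len(r.administered) for r in records])
    rel = np.array(
        [reliability_from_se(r.final.se_t, bank.metric) for r in records]
    )
    t_final = np.array([r.final.t_score for r in records])
    reasons, counts = np.unique(
        [r.stop_reason for r in records], return_counts=True
    )
    summary = {
        "n_persons": int(cc.n_persons),
        "mean_items": float(n_items.mean()),
        "median_items": float(np.median(n_items)),
        "pct_stop_by_reason": {
            str(k): float(c / len(records)) for k, c in zip(reasons, counts)
        },
        "pct_reliable": float((rel > r_threshold).mean()),
        "pct_fewer_than_7": float((n_items < 7).mean()),
        "t_mean": float(t_final.mean()),
        "t_sd": float(t_final.std(ddof=1)) if len(records) > 1 else 0.0,
    }
    return records, summary
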