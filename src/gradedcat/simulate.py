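"""Synthetic graded-response data with the structure the analyses assume.

The generator draws a unidimensional latent trait per person, produces
5-category graded responses under the GRM, and can inject the disturbances
the downstream modules are built to detect: uniform DIF (a common shift of
all thresholds of an item in the focal group), non-uniform DIF (a slope
change in the focal group), a minor second factor on a designated item
subset (emulating a fine-tactile vs heavy-lifting split), and completely-at-
random missingness.

Also houses the published 46-item upper-extremity reference bank (Dutch
metric), used as the standard fixture throughout the test-suite and the
analysis scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import MISSING, ItemBank, ItemParameters, Metric, ResponseMatrix

__all__ = [
    "SimulationDesign",
    "DIFInjection",
    "MinorFactor",
    "generate_responses",
    "promis_ue_bank",
    "short_form_7a_ids",
    "collapse_categories",
]

# Published GRM parameters of the 46-item upper-extremity bank, on the
# calibration-sample (Dutch) metric: slope a and ordered thresholds b1-b4.
# Items marked sf=True form the standard 7-item short form (7a).
_UE_BANK_TABLE: list[tuple[str, float, float, float, float, float, bool]] = [
    ("PFA14r1", 1.862, -0.613, -0.227, 0.415, 1.054, True),
    ("PFA16r1", 2.780, -1.757, -1.097, -0.397, 0.444, False),
    ("PFA17",   1.670, -1.156, -0.587, -0.046, 0.657, False),
    ("PFA18",   3.027, -0.768, -0.421, -0.059, 0.361, False),
    ("PFA20",   3.028, -1.553, -0.985, -0.376, 0.172, False),
    ("PFA28",   3.404, -0.738, -0.431, -0.111, 0.463, False),
    ("PFA29r1", 2.266, -1.068, -0.534, -0.066, 0.771, False),
    ("PFA34",   1.989, -0.906, -0.343, 0.249, 1.077, True),
    ("PFA35",   2.572, -2.203, -1.347, -0.704, 0.099, False),
    ("PFA36",   1.968, -2.736, -1.438, -0.495, 0.604, True),
    ("PFA38",   2.378, -1.488, -0.923, -0.181, 0.682, False),
    ("PFA40",   2.545, -1.992, -1.446, -0.922, -0.342, False),
    ("PFA43r1", 2.345, -1.857, -1.371, -0.843, -0.401, False),
    ("PFA44",   2.222, -2.361, -1.439, -0.624, 0.473, False),
    ("PFA48",   2.983, -1.187, -0.877, -0.491, 0.058, False),
    ("PFA50",   2.310, -2.416, -2.001, -1.292, -0.614, False),
    ("PFA54",   2.783, -1.871, -1.330, -0.730, 0.084, False),
    ("PFB11",   2.928, -1.421, -0.825, -0.375, 0.303, False),
    ("PFB13",   1.926, -1.262, -0.808, -0.126, 0.580, True),
    ("PFB15r1", 3.067, -1.280, -1.012, -0.571, -0.001, False),
    ("PFB16r1", 2.165, -2.651, -2.110, -1.510, -0.950, False),
    ("PFB18",   3.073, -1.810, -1.411, -0.841, -0.101, False),
    ("PFB19r1", 3.177, -2.142, -1.667, -1.055, -0.410, False),
    ("PFB20r1", 3.313, -1.624, -1.229, -0.844, -0.310, False),
    ("PFB21r1", 2.164, -2.350, -1.916, -1.389, -0.677, False),
    ("PFB22",   2.965, -1.488, -1.153, -0.639, 0.103, False),
    ("PFB23r1", 3.046, -1.692, -1.373, -0.798, -0.151, False),
    ("PFB25",   2.157, -2.353, -1.524, -0.966, -0.182, False),
    ("PFB26",   2.907, -1.470, -1.009, -0.496, 0.287, False),
    ("PFB27",   3.027, -1.429, -0.959, -0.570, 0.042, False),
    ("PFB28r1", 2.040, -0.198, 0.224, 0.670, 1.350, True),
    ("PFB30",   3.590, -1.449, -0.990, -0.520, 0.100, False),
    ("PFB31r1", 2.906, -1.773, -1.330, -0.798, -0.181, False),
    ("PFB33",   2.045, -1.626, -1.104, -0.576, 0.209, False),
    ("PFB34",   2.357, -0.717, -0.357, 0.079, 0.824, True),
    ("PFB36",   2.061, -2.009, -1.148, -0.265, 0.618, False),
    ("PFB37r1", 3.125, -1.980, -1.547, -0.978, 0.348, False),
    ("PFB39r1", 2.218, -0.886, -0.533, -0.055, 0.705, False),
    ("PFB41",   2.352, -1.487, -1.091, -0.547, 0.001, False),
    ("PFB56r1", 1.816, -1.004, -0.604, -0.191, 0.508, False),
    ("PFC43",   2.853, -1.755, -1.243, -0.713, -0.069, False),
    ("PFC49",   3.091, -1.807, -1.431, -1.056, -0.463, False),
    ("PFM2",    2.786, -0.431, -0.083, 0.377, 1.208, False),
    ("PFM16",   2.698, -0.212, 0.176, 0.677, 1.469, True),
    ("PFM18",   1.941, -0.339, 0.091, 0.553, 1.239, False),
    # b2 of PFC8 is printed with a dropped sign in the source table; -0.999
    # restores the strict threshold ordering the model requires.
    ("PFC8",    2.460, -1.903, -0.999, -0.365, 0.391, False),
]


def promis_ue_bank() -> ItemBank:
    """The 46-item upper-extremity reference bank (5 categories per item)."""
    items = [
        ItemParameters(iid, a, (b1, b2, b3, b4))
        for iid, a, b1, b2, b3, b4, _ in _UE_BANK_TABLE
    ]
    return ItemBank(items, metric=Metric(), label="UE v2.0 item bank")


def short_form_7a_ids() -> list[str]:
    """Item ids of the standard 7-item short form."""
    return [row[0] for row in _UE_BANK_TABLE if row[6]]


@dataclass(frozen=True)
class DIFInjection:
    """DIF planted in the focal group (group 1).

    ``uniform`` adds ``magnitude`` to every threshold of the item;
    ``nonuniform`` multiplies the slope by ``1 + magnitude``.
    """

    item_id: str
    type: str  # "uniform" | "nonuniform"
    magnitude: float

    def __post_init__(self) -> None:
        if self.type not in ("uniform", "nonuniform"):
            raise ValueError("DIF type must be 'uniform' or 'nonuniform'")
        if not np.isfinite(self.magnitude):
            raise ValueError("DIF magnitude must be finite")


@dataclass(frozen=True)
class MinorFactor:
    """Second latent variable on ``item_subset``: those items respond to
    theta* = sqrt(1-s) * theta + sqrt(s) * eta with s = loading_share."""

    item_subset: tuple[str, ...]
    loading_share: float

    def __post_init__(self) -> None:
        if not 0 <= self.loading_share < 1:
            raise ValueError("loading_share must be in [0, 1)")


@dataclass(frozen=True)
class SimulationDesign:
    """Study design for one synthetic cohort.

    Defaults mirror the validation-study conditions: a single clinical sample
    of n = 521 with a standard-normal trait on the calibration metric.
    """

    n_persons: int = 521
    theta_mean: tuple[float, ...] = (0.0,)
    theta_sd: tuple[float, ...] = (1.0,)
    group_proportions: tuple[float, ...] = (1.0,)
    dif_injections: tuple[DIFInjection, ...] = ()
    minor_factor: MinorFactor | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.theta_mean) == len(self.theta_sd) == len(self.group_proportions)):
            raise ValueError("per-group parameter lengths differ")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _group_banks(bank: ItemBank, design: SimulationDesign) -> list[ItemBank]:
    """Reference-group bank plus a focal-group bank with DIF applied."""
    known = set(bank.item_ids)
    for inj in design.dif_injections:
        if inj.item_id not in known:
            raise KeyError(f"DIF item {inj.item_id!r} not in bank")
    banks = [bank]
    n_groups = len(design.group_proportions)
    for g in range(1, n_groups):
        items = []
        for it in bank.items:
            slope, thr = it.slope, np.array(it.thresholds)
            for inj in design.dif_injections:
                if inj.item_id != it.item_id:
                    continue
                if inj.type == "uniform":
                    thr = thr + inj.magnitude
                else:
                    slope = slope * (1.0 + inj.magnitude)
            items.append(ItemParameters(it.item_id, slope, tuple(thr)))
        banks.append(ItemBank(items, metric=bank.metric, label=bank.label))
    return banks


def generate_responses(
    bank: ItemBank, design: SimulationDesign
) -> tuple[ResponseMatrix, np.ndarray, np.ndarray]:
    """Draw a cohort: returns (responses, true thetas, group labels).

    Identical seeds reproduce outputs bit-for-bit (integer-state PCG64).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_persons
    n_groups = len(design.group_proportions)
    groups = rng.choice(n_groups, size=n, p=np.asarray(design.group_proportions))
    theta = np.empty(n)
    for g in range(n_groups):
        sel = groups == g
        theta[sel] = rng.normal(
            design.theta_mean[g], design.theta_sd[g], size=sel.sum()
        )

    # effective trait per item: minor-factor items respond to a mixture
    eta = rng.normal(size=n)
    banks = _group_banks(bank, design)
    minor_ids = set(design.minor_factor.item_subset) if design.minor_factor else set()
    if minor_ids - set(bank.item_ids):
        raise KeyError("minor_factor references unknown items")
    s = design.minor_factor.loading_share if design.minor_factor else 0.0
    theta_minor = np.sqrt(1.0 - s) * theta + np.sqrt(s) * eta

    codes = np.empty((n, len(bank)), dtype=np.int16)
    u = rng.random((n, len(bank)))
    for g in range(n_groups):
        sel = groups == g
        if not sel.any():
            continue
        a, b, _ = banks[g].arrays()
        for j, iid in enumerate(bank.item_ids):
            t = theta_minor[sel] if iid in minor_ids else theta[sel]
            # P(X >= k) for k=1..K-1; response = number of exceeded curves
            star = 1.0 / (1.0 + np.exp(-a[j] * (t[:, None] - b[j][None, :])))
            codes[sel, j] = (u[sel, j][:, None] < star).sum(axis=1)

    if design.missing_rate > 0:
        drop = rng.random(codes.shape) < design.missing_rate
        codes[drop] = MISSING

    persons = [f"p{i:05d}" for i in range(n)]
    ks = np.array([it.n_categories for it in bank.items])
    matrix = ResponseMatrix(persons, bank.item_ids, codes, n_categories=ks)
    return matrix, theta, groups


def collapse_categories(
    matrix: ResponseMatrix, plan: dict[str, dict[int, int]]
) -> ResponseMatrix:
    """Merge adjacent response categories per the (order-preserving) plan.

    ``plan`` maps item_id -> {original code -> new code}; new codes must be
    contiguous from 0, weakly increasing in the original code, and step by at
    most one (only adjacent categories merge).
    """
    codes = matrix.codes.copy()
    ks = matrix.n_categories.copy()
    for iid, mapping in plan.items():
        if iid not in matrix.item_ids:
            raise KeyError(f"collapse plan references unknown item {iid!r}")
        j = matrix.item_ids.index(iid)
        k = int(ks[j])
        old = list(range(k))
        if sorted(mapping) != old:
            raise ValueError(f"{iid}: plan must map every code 0..{k-1}")
        new = [mapping[c] for c in old]
        if new[0] != 0:
            raise ValueError(f"{iid}: new codes must start at 0")
        steps = np.diff(new)
        if ((steps < 0) | (steps > 1)).any():
            raise ValueError(
                f"{iid}: only order-preserving merges of adjacent categories"
            )
        lut = np.array(new + [MISSING], dtype=np.int16)  # -1 maps to itself
        codes[:, j] = lut[codes[:, j]]
        ks[j] = new[-1] + 1
    return ResponseMatrix(
        list(matrix.persons), list(matrix.item_ids), codes, n_categories=ks
    )
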