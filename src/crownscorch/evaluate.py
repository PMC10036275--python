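"""Evaluation arithmetic: detection scores, classification accuracy,
scorch-height regression, and crown-volume-scorched agreement."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classify import BurnCall

__all__ = [
    "ClassificationSummary",
    "AgreementSummary",
    "summarize_classification",
    "scorch_height_regression",
    "cvs_agreement",
    "round_percent",
]


def round_percent(value: float, decimals: int = 1) -> float:
    """Round half away from zero, as report percentages are conventionally printed."""
    scale = 10**decimals
    return float(np.sign(value) * np.floor(abs(value) * scale + 0.5) / scale)


@dataclass
class ClassificationSummary:
    """Burned/unburned confusion summary against reference labels."""

    n: int
    unburned_total: int
    unburned_correct: int
    burned_total: int
    burned_correct: int

    @property
    def unburned_accuracy(self) -> float:
        return 100.0 * self.unburned_correct / self.unburned_total

    @property
    def burned_accuracy(self) -> float:
        return 100.0 * self.burned_correct / self.burned_total

    @property
    def overall_accuracy(self) -> float:
        return 100.0 * (self.unburned_correct + self.burned_correct) / self.n


@dataclass
class AgreementSummary:
    """Agreement between estimated and reference crown volume scorched."""

    n: int
    differences: np.ndarray  # reference - estimated, percentage points
    fraction_within_10: float
    fraction_within_30: float
    bin_centers: np.ndarray  # ±10-point bins centered at 0
    bin_counts: np.ndarray


def summarize_classification(
    burn_calls: Sequence[BurnCall],
    field_labels: Mapping[int, str],
) -> ClassificationSummary:
    """Score burn calls against per-tree reference labels keyed by tree id."""
    missing = [c.tree_id for c in burn_calls if c.tree_id not in field_labels]
    if missing:
        raise ValueError(f"no field label for tree ids: {missing}")
    ub_total = ub_ok = b_total = b_ok = 0
    for call in burn_calls:
        truth = field_labels[call.tree_id]
        if truth not in ("burned", "unburned"):
            raise ValueError(f"bad field label {truth!r} for tree {call.tree_id}")
        if truth == "unburned":
            ub_total += 1
            ub_ok += call.label == "unburned"
        else:
            b_total += 1
            b_ok += call.label == "burned"
    return ClassificationSummary(
        n=len(burn_calls),
        unburned_total=ub_total,
        unburned_correct=ub_ok,
        burned_total=b_total,
        burned_correct=b_ok,
    )


def scorch_height_regression(estimated, observed) -> tuple[float, float, float]:
    """OLS of observed on estimated scorch heights: (slope, R², RMSE)."""
    est = np.asarray(estimated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(est) != len(obs) or len(est) < 3:
        raise ValueError("need at least 3 paired heights")
    if np.var(est) == 0 or np.var(obs) == 0:
        raise ValueError("zero variance in heights")
    slope, intercept = np.polyfit(est, obs, 1)
    pred = slope * est + intercept
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean(resid**2)))
    return float(slope), r_squared, rmse


def cvs_agreement(estimated, observed) -> AgreementSummary:
    """Bin signed CVS differences and report within-threshold fractions.

    Differences are reference minus estimated, in percentage points; bins are
    ±10-point bins with mid-points at 0, ±10, ±20, ...; the within-threshold
    fractions use |difference| with inclusive boundaries.
    """
    est = np.asarray(estimated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(est) != len(obs):
        raise ValueError("length mismatch")
    diff = obs - est
    n = len(diff)
    if n == 0:
        return AgreementSummary(0, diff, 0.0, 0.0, np.empty(0), np.empty(0, int))
    within10 = float(np.mean(np.abs(diff) <= 10))
    within30 = float(np.mean(np.abs(diff) <= 30))
    k = int(np.ceil((np.abs(diff).max() + 5) / 10))
    centers = np.arange(-k, k + 1) * 10.0
    edges = np.arange(-k * 10 - 5, k * 10 + 6, 10.0)
    counts, _ = np.histogram(diff, bins=edges)
    return AgreementSummary(n, diff, within10, within30, centers, counts)
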