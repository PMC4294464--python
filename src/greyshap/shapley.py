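"""Shapley-value error apportionment and combined forecasting.

The total error of a combined forecast is treated as the value of a
cooperative game among the member models.  Each member's Shapley share of
the joint error — the average of its marginal contributions over all join
orders — is converted into a combination weight so that a member blamed
for less error receives more weight:

    omega_i = (E - share_i) / ((n - 1) * E),

where E is the grand-coalition error.  Efficiency (shares sum to E)
guarantees the weights sum to one.  Coalition values are the arithmetic
means of the member comprehensive errors in the subset, so no joint
refitting is involved.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ValidationError
from .series import AnnualSeries

__all__ = [
    "MemberErrors",
    "CoalitionTable",
    "ShapleyAllocation",
    "CombinedForecast",
    "coalition_errors",
    "shapley_shares",
    "weights",
    "combine",
    "allocate",
]


@dataclass(frozen=True)
class MemberErrors:
    """Comprehensive error (%) of each member model, with labels."""

    labels: tuple[str, ...]
    errors: np.ndarray

    def __post_init__(self) -> None:
        errors = np.asarray(self.errors, dtype=np.float64)
        object.__setattr__(self, "errors", errors)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(errors):
            raise ValidationError("labels and errors must have the same length")
        if len(errors) < 2:
            raise ValidationError("need at least two member models")
        if np.any(errors < 0):
            raise ValidationError("member errors must be >= 0")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class CoalitionTable:
    """Error E(s) for every nonempty subset s of members (2^n - 1 entries)."""

    labels: tuple[str, ...]
    values: dict[frozenset[int], float]

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def grand_total(self) -> float:
        return self.values[frozenset(range(self.n))]


@dataclass(frozen=True)
class ShapleyAllocation:
    """Shares of the joint error and the derived combination weights."""

    labels: tuple[str, ...]
    total_error: float
    shares: np.ndarray
    weights: np.ndarray


@dataclass(frozen=True)
class CombinedForecast:
    """Weighted sum of member prediction series."""

    labels: tuple[str, ...]
    members: tuple[AnnualSeries, ...]
    weights: np.ndarray  # as applied, in member order
    mapping: str
    combined: AnnualSeries


def coalition_errors(members: MemberErrors) -> CoalitionTable:
    """Coalition error table: E(s) = mean of member errors over s."""
    n = members.n
    values: dict[frozenset[int], float] = {}
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            values[frozenset(subset)] = float(members.errors[list(subset)].mean())
    return CoalitionTable(labels=members.labels, values=values)


def shapley_shares(table: CoalitionTable) -> np.ndarray:
    """Shapley share of each member under the coalition table.

    share_i = sum over subsets s containing i of
              (n - |s|)! (|s| - 1)! / n! * (E(s) - E(s \\ {i})),
    with E(empty) = 0.  Efficiency makes the shares sum to E.
    """
    n = table.n
    expected = [frozenset(s) for size in range(1, n + 1)
                for s in itertools.combinations(range(n), size)]
    missing = [set(s) for s in expected if s not in table.values]
    if missing:
        raise ValidationError(f"incomplete coalition table; missing subsets {missing}")
    shares = np.zeros(n)
    for i in range(n):
        for s in expected:
            if i not in s:
                continue
            weight = math.factorial(n - len(s)) * math.factorial(len(s) - 1) / math.factorial(n)
            without = s - {i}
            previous = table.values[without] if without else 0.0
            shares[i] += weight * (table.values[s] - previous)
    return shares


def weights(shares: np.ndarray, total_error: float) -> np.ndarray:
    """Combination weights omega_i = (E - share_i) / ((n - 1) * E).

    A member whose share exceeds E receives a negative weight; it is
    reported with a warning, never clamped, and the weights still sum to
    one.  If E = 0 (all members perfect) equal weights are returned with
    a warning.
    """
    shares = np.asarray(shares, dtype=np.float64)
    n = len(shares)
    if total_error == 0:
        warnings.warn(
            "total error is zero (all members perfect); falling back to equal weights",
            stacklevel=2,
        )
        return np.full(n, 1.0 / n)
    if total_error < 0:
        raise ValidationError("total error must be >= 0")
    omega = (total_error - shares) / ((n - 1) * total_error)
    if np.any(omega < 0):
        bad = np.nonzero(omega < 0)[0].tolist()
        warnings.warn(
            f"negative combination weight(s) for member(s) {bad}: a member's "
            "error share exceeds the total; weights are reported unclamped",
            stacklevel=2,
        )
    return omega


def allocate(members: MemberErrors) -> ShapleyAllocation:
    """Full allocation pipeline: coalition table -> shares -> weights."""
    table = coalition_errors(members)
    shares = shapley_shares(table)
    total = table.grand_total
    return ShapleyAllocation(
        labels=members.labels,
        total_error=total,
        shares=shares,
        weights=weights(shares, total),
    )


def combine(
    members: list[AnnualSeries],
    member_weights: np.ndarray,
    mapping: str = "paper",
    labels: tuple[str, ...] | None = None,
) -> CombinedForecast:
    """Form the combined forecast as a weighted sum of member series.

    ``mapping`` controls the weight-to-model assignment:

    ``"consistent"``
        weight i multiplies member i — the assignment in which each
        weight attaches to the model whose error share produced it.

    ``"paper"`` (default, two members only)
        the two weights are swapped before applying, reproducing the
        published combination in which the weight derived from one
        member's error share is applied to the *other* member.
    """
    member_weights = np.asarray(member_weights, dtype=np.float64)
    if len(members) != len(member_weights):
        raise ValidationError("one weight per member series required")
    if len(members) < 2:
        raise ValidationError("need at least two member series")
    first = members[0]
    for other in members[1:]:
        try:
            first.assert_aligned(other)
        except AlignmentError as exc:
            raise AlignmentError(f"member series are not aligned: {exc}") from exc
    if mapping == "paper":
        if len(members) != 2:
            raise ValidationError('mapping="paper" is defined only for two members')
        applied = member_weights[::-1].copy()
    elif mapping == "consistent":
        applied = member_weights.copy()
    else:
        raise ValidationError(f"unknown mapping {mapping!r}")
    stacked = np.vstack([m.values for m in members])
    combined = AnnualSeries(first.years, applied @ stacked)
    if labels is None:
        labels = tuple(f"member_{i + 1}" for i in range(len(members)))
    return CombinedForecast(
        labels=tuple(labels),
        members=tuple(members),
        weights=applied,
        mapping=mapping,
        combined=combined,
    )
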