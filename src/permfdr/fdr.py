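"""Benjamini-Hochberg FDR control over protein p-values.

The step-up BH procedure is applied to the N target-protein p-values;
its two standard views are exposed: the accepted set at a level alpha,
and the full FDR-vs-identification-count curve (the BH q-value of the
n-th smallest p-value, for n = 1..N).

Plain BH is used (no Benjamini-Yekutieli dependence correction). Ties in
p are sorted stably by input index and share the adjusted value of their
last rank, so a tie at the acceptance boundary is accepted as a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PValueSet:
    """Per-target-protein p-values of one sample, in input order."""

    sample_id: str
    accessions: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if len(self.p) != len(self.accessions):
            raise ValueError("accessions and p must have equal length")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def N(self) -> int:
        return len(self.p)


@dataclass
class FdrCurve:
    """BH output: estimated FDR at each identification count, plus q-values.

    ``points[n-1] = (n, fdr)`` gives the estimated FDR when the n
    highest-confidence proteins are accepted; ``qvalues`` maps each input
    protein to its BH-adjusted p-value.
    """

    points: list[tuple[int, float]]
    qvalues: np.ndarray


def bh_adjust(p) -> np.ndarray:
    """BH-adjusted p-values (q-values), mapped back to input order.

    q(i) = min over ranks j >= rank(i) of N * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return np.array([], dtype=float)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q


def accept_at(p, alpha: float) -> tuple[int, np.ndarray]:
    """Step-up BH acceptance at level ``alpha``.

    Returns (count, accepted indices): count is the largest i with
    p_(i) <= i * alpha / N (0 if none), and the accepted indices are the
    input positions of the count smallest p-values (stable in input
    order among ties).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return 0, np.array([], dtype=int)
    order = np.argsort(p, kind="stable")
    thresholds = alpha * np.arange(1, n + 1) / n
    passing = np.nonzero(p[order] <= thresholds)[0]
    count = int(passing[-1]) + 1 if passing.size else 0
    return count, order[:count]


def fdr_curve(p) -> FdrCurve:
    """Estimated FDR as a function of the number of accepted proteins."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("cannot build an FDR curve from zero p-values")
    q = bh_adjust(p)
    q_sorted = np.sort(q)  # q is monotone along the sorted-p order
    points = [(n + 1, float(q_sorted[n])) for n in range(len(p))]
    return FdrCurve(points=points, qvalues=q)
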