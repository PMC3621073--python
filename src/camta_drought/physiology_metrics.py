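"""Closed-form physiology and qPCR computations.

Relative water content from fresh/turgid/dry leaf weights, recovery survival
rate, Livak delta-delta-Ct relative expression, and the classical two-sample
Student's t comparison used to place significance asterisks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PhysiologyRecord:
    """Leaf weights (any consistent mass unit) and the derived RWC (%)."""

    FW: float
    TW: float
    DW: float

    @property
    def RWC(self) -> float:
        return rwc(self.FW, self.TW, self.DW)

    @property
    def plausible(self) -> bool:
        """DW <= FW <= TW, the regime where RWC lies in [0, 100]."""
        return self.DW <= self.FW <= self.TW


@dataclass(frozen=True)
class QpcrRecord:
    """Threshold cycles for target and reference gene in two samples."""

    ct_target_condition: float
    ct_ref_condition: float
    ct_target_control: float
    ct_ref_control: float

    @property
    def ddct(self) -> float:
        dct_cond = self.ct_target_condition - self.ct_ref_condition
        dct_ctrl = self.ct_target_control - self.ct_ref_control
        return dct_cond - dct_ctrl

    @property
    def fold_change(self) -> float:
        return 2.0 ** (-self.ddct)


def rwc(FW: float, TW: float, DW: float) -> float:
    """Relative water content, 100 * (FW - DW) / (TW - DW), in percent.

    TW must exceed DW; FW < DW (negative water content) is permitted but
    reported as a negative percentage for the caller to flag.
    """
    if not all(math.isfinite(v) for v in (FW, TW, DW)):
        raise ValueError("weights must be finite")
    if TW == DW:
        raise ValueError("turgid and dry weight are equal; RWC undefined")
    return 100.0 * (FW - DW) / (TW - DW)


def ddct_fold_change(record: QpcrRecord) -> float:
    """Relative expression 2^(-ddCt) of the target vs the reference gene."""
    values = (record.ct_target_condition, record.ct_ref_condition,
              record.ct_target_control, record.ct_ref_control)
    if not all(math.isfinite(v) for v in values):
        raise ValueError("Ct values must be finite")
    return record.fold_change


def survival_rate(n_survived: int, n_total: int) -> int:
    """Recovery survival in integer percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_survived <= n_total:
        raise ValueError("need 0 <= n_survived <= n_total")
    return round(100.0 * n_survived / n_total)


def two_sample_t(x, y, alpha: float = 0.05,
                 welch: bool = False) -> tuple[float, float, bool]:
    """Two-sample t comparison; returns (t, two-sided p, significant flag).

    Equal-variance Student's t by default (``welch=True`` for the unequal
    variance form). Two degenerate constant groups with equal means give
    t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0, False
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p), bool(p < alpha)


def asterisk(significant: bool) -> str:
    """The figure-legend marker for a significant comparison."""
    return "*" if significant else ""
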