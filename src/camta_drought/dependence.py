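"""Classify drought-responsive genes as CAMTA1-dependent or -independent.

For every gene that is drought-responsive in the wild type (call UP or
DOWN), the mutant response is compared to the wild-type response through the
log2 fold-change ratio

    rho_g = mut_log2fc_g / wt_log2fc_g,    attenuation a_g = 1 - rho_g,

so a_g = 0 means the mutant responds exactly like the wild type and a_g = 1
means the response is abolished. Genes oppositely regulated in the mutant
(rho < 0) get a > 1 and count as dependent. Descriptive column statistics
of the attenuation values give a data-driven cutoff: the upper bound of the
99% t-confidence interval of the mean attenuation. A gene is DEPENDENT iff
a_g >= that cutoff; dependence crossed with the wild-type direction yields
the four classes

    CDPRG (dependent, WT UP)    CIDIG (independent, WT UP)
    CDNRG (dependent, WT DOWN)  CIDRG (independent, WT DOWN)

which partition the WT-responsive genes exactly. A percentile cutoff on the
attenuation column itself is available as an alternative (method
"percentile"). With a zero-variance attenuation column the cutoff equals the
common value and ties go to INDEPENDENT (dependence requires strict
evidence of attenuation).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import CALL_DOWN, CALL_UP

logger = logging.getLogger(__name__)

CLASS_NAMES = ("CDPRG", "CDNRG", "CIDIG", "CIDRG")

RATIO_COLUMNS = ["gene_id", "wt_log2fc", "mut_log2fc", "rho", "attenuation",
                 "wt_call"]


@dataclass(frozen=True)
class ColumnStats:
    """Descriptive statistics with a t-interval for the mean."""

    n: int
    mean: float
    sd: float
    sem: float
    ci_level: float
    ci_low: float
    ci_high: float


@dataclass
class DependenceClassification:
    """Four-class partition of WT drought-responsive genes for one tissue."""

    tissue: str
    table: pd.DataFrame          # RATIO_COLUMNS + class_label
    threshold: float
    stats: ColumnStats | None
    ci_level: float
    method: str = "ci_mean"

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["class_label"].value_counts()
        return {name: int(c.get(name, 0)) for name in CLASS_NAMES}

    def genes_of_class(self, *names: str) -> list[str]:
        mask = self.table["class_label"].isin(names)
        return list(self.table.loc[mask, "gene_id"])

    def class_map(self) -> pd.Series:
        return self.table.set_index("gene_id")["class_label"]


def response_ratio(de_wt: pd.DataFrame, de_mut: pd.DataFrame) -> pd.DataFrame:
    """Ratio records for WT-significant genes (log2 scale).

    Both DE tables must cover the same gene universe; a WT-significant gene
    missing from the mutant table is fatal.
    """
    wt = de_wt.set_index("gene_id")
    mut = de_mut.set_index("gene_id")
    sig = wt[wt["call"].isin((CALL_UP, CALL_DOWN))]
    missing = sig.index.difference(mut.index)
    if len(missing):
        raise ValueError(
            f"gene(s) missing from mutant DE table: {sorted(missing)[:5]} "
            f"({len(missing)} total); the two universes must match")
    wt_fc = sig["log2fc"].to_numpy(dtype=float)
    mut_fc = mut.loc[sig.index, "log2fc"].to_numpy(dtype=float)
    # the WT gate (|FC| >= 2 i.e. |log2fc| >= 1) guarantees wt_fc != 0
    rho = mut_fc / wt_fc
    return pd.DataFrame({
        "gene_id": sig.index,
        "wt_log2fc": wt_fc,
        "mut_log2fc": mut_fc,
        "rho": rho,
        "attenuation": 1.0 - rho,
        "wt_call": sig["call"].to_numpy(),
    }).reset_index(drop=True)


def column_stats(values, ci_level: float = 0.99) -> ColumnStats:
    """Mean, sd (n-1), sem and the t-interval for the mean."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError(f"column statistics need n >= 2, got n = {n}")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie in (0, 1)")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    sem = sd / np.sqrt(n)
    tcrit = float(stats.t.ppf((1.0 + ci_level) / 2.0, n - 1))
    half = tcrit * sem
    return ColumnStats(n=n, mean=mean, sd=sd, sem=sem, ci_level=ci_level,
                       ci_low=mean - half, ci_high=mean + half)


def classify_dependence(de_wt: pd.DataFrame, de_mut: pd.DataFrame,
                        ci_level: float = 0.99,
                        tissue: str = "",
                        method: str = "ci_mean") -> DependenceClassification:
    """Partition WT drought-responsive genes into the four dependence classes.

    ``method="ci_mean"`` (default) thresholds attenuation at the upper bound
    of the ``ci_level`` confidence interval of its mean; ``"percentile"``
    uses the ``ci_level`` empirical quantile of the attenuation column.
    """
    if method not in ("ci_mean", "percentile"):
        raise ValueError("method must be 'ci_mean' or 'percentile'")
    ratios = response_ratio(de_wt, de_mut)
    if ratios.empty:
        warnings.warn("no WT drought-responsive genes; classification is empty")
        table = ratios.assign(class_label=pd.Series(dtype=str))
        return DependenceClassification(tissue, table, float("nan"), None,
                                        ci_level, method)
    a = ratios["attenuation"].to_numpy()
    strict = False
    if len(a) == 1:
        cs = None
        threshold, strict = float(a[0]), True
    elif method == "percentile":
        cs = column_stats(a, ci_level)
        threshold = float(np.quantile(a, ci_level))
    else:
        cs = column_stats(a, ci_level)
        if cs.sd == 0:
            threshold, strict = cs.mean, True  # ties -> INDEPENDENT
        else:
            threshold = cs.ci_high
    dependent = (a > threshold) if strict else (a >= threshold)
    up = ratios["wt_call"] == CALL_UP
    label = np.where(dependent, np.where(up, "CDPRG", "CDNRG"),
                     np.where(up, "CIDIG", "CIDRG"))
    table = ratios.assign(class_label=label)
    cls = DependenceClassification(tissue, table, float(threshold), cs,
                                   ci_level, method)
    counts = cls.counts
    n_up, n_down = int(up.sum()), int((~up).sum())
    assert counts["CDPRG"] + counts["CIDIG"] == n_up
    assert counts["CDNRG"] + counts["CIDRG"] == n_down
    logger.info("dependence %s: threshold a >= %.4f; "
                "CDPRG=%d CIDIG=%d (of %d UP), CDNRG=%d CIDRG=%d (of %d DOWN)",
                tissue or "-", threshold, counts["CDPRG"], counts["CIDIG"],
                n_up, counts["CDNRG"], counts["CIDRG"], n_down)
    return cls


def partition_complement(n_total: int, n_dependent: int) -> int:
    """Independent complement of a published (total, dependent) pair."""
    if not 0 <= n_dependent <= n_total:
        raise ValueError("need 0 <= n_dependent <= n_total")
    return n_total - n_dependent


def partition_summary(
    classifications: DependenceClassification | list[DependenceClassification],
) -> pd.DataFrame:
    """Per-tissue class counts with the WT UP/DOWN partition identities."""
    if isinstance(classifications, DependenceClassification):
        classifications = [classifications]
    rows = []
    for cls in classifications:
        c = cls.counts
        rows.append({
            "tissue": cls.tissue,
            **c,
            "wt_up": c["CDPRG"] + c["CIDIG"],
            "wt_down": c["CDNRG"] + c["CIDRG"],
            "total": sum(c.values()),
        })
    if not rows:
        rows = [{"tissue": "", **{k: 0 for k in CLASS_NAMES},
                 "wt_up": 0, "wt_down": 0, "total": 0}]
    return pd.DataFrame(rows)
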