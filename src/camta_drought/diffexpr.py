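"""Drought-responsive gene calling with a SAM-style permutation d-statistic.

For each genotype and tissue the drought/control contrast is scored with

    d_g = (mean_drought - mean_control) / (s_g + s0)

where ``s_g`` is the two-sample pooled standard error of the mean
difference and ``s0`` a small "fudge" constant (default: the median of the
per-gene ``s_g``) that stabilizes low-variance genes. Significance comes
from a condition-label permutation null pooled across genes:

    p_g = (1 + #{permuted |d*| >= |d_g|}) / (1 + N_permuted)

When the number of distinct label assignments is small (3 vs 3 replicates
gives C(6,3) = 20), all assignments other than the observed one are
enumerated exactly; otherwise random label shuffles are drawn. q-values use
the SAM ratio of the median permuted false-positive count to the observed
count at each gene's |d|, monotonized to be non-increasing in |d|.

Genes are called UP when linear fold change >= fc_threshold and
p <= p_threshold, DOWN symmetrically, otherwise NS (all gates inclusive,
signed linear fold convention: -2 means halved).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io_formats import ExperimentDesign, ExpressionMatrix

logger = logging.getLogger(__name__)

CALL_UP, CALL_DOWN, CALL_NS = "UP", "DOWN", "NS"

DE_COLUMNS = ["gene_id", "log2fc", "fc_linear", "d_stat", "p_value", "q_value",
              "call"]


@dataclass(frozen=True)
class ContrastSpec:
    """Drought-vs-control contrast within one tissue and genotype."""

    tissue: str
    genotype: str
    numerator: str = "DROUGHT"
    denominator: str = "CONTROL"

    def columns(self, design: ExperimentDesign) -> tuple[list[str], list[str]]:
        num = design.samples_for(self.tissue, self.genotype, self.numerator)
        den = design.samples_for(self.tissue, self.genotype, self.denominator)
        if len(num) < 2 or len(den) < 2:
            raise ValueError(
                f"contrast {self} needs >=2 replicates per cell "
                f"(got {len(num)} vs {len(den)})")
        return num, den


@dataclass
class SAMParams:
    """Tuning of the d-statistic and its permutation null."""

    s0: float | None = None           # None -> median per-gene s_g
    n_permutations: int = 1000
    seed: int = 0
    p_threshold: float = 0.05
    fc_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.s0 is not None and self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.n_permutations < 100:
            raise ValueError("need n_permutations >= 100 for q-value estimation")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def log2_fold_change(matrix: ExpressionMatrix, design: ExperimentDesign,
                     contrast: ContrastSpec) -> pd.Series:
    """Per-gene mean(log2 drought) - mean(log2 control)."""
    num, den = contrast.columns(design)
    v = matrix.values
    return (v[num].mean(axis=1) - v[den].mean(axis=1)).rename("log2fc")


def signed_linear_fc(log2fc: pd.Series | np.ndarray) -> np.ndarray:
    """Signed fold convention: +2 doubled, -2 halved, magnitude >= 1."""
    arr = np.asarray(log2fc, dtype=float)
    return np.sign(arr) * np.power(2.0, np.abs(arr)) + (arr == 0) * 1.0


def _pooled_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled standard error of the difference of group means (rows = genes)."""
    n1, n2 = a.shape[1], b.shape[1]
    var = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) \
        / (n1 + n2 - 2)
    return np.sqrt(var * (1.0 / n1 + 1.0 / n2))


def _d_from_groups(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    diff = a.mean(axis=1) - b.mean(axis=1)
    denom = _pooled_se(a, b) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / denom
        # zero difference over zero spread is no evidence, not NaN; nonzero
        # difference over zero spread is infinitely extreme
        d = np.where(denom == 0,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf), d)
    return d


def sam_d_statistic(matrix: ExpressionMatrix, design: ExperimentDesign,
                    contrast: ContrastSpec,
                    s0: float | None = None) -> tuple[pd.Series, float]:
    """The SAM d-statistic per gene; returns (d, s0 actually used)."""
    num, den = contrast.columns(design)
    a = matrix.values[num].to_numpy(dtype=float)
    b = matrix.values[den].to_numpy(dtype=float)
    if s0 is None:
        s0 = float(np.median(_pooled_se(a, b)))
    d = _d_from_groups(a, b, s0)
    return pd.Series(d, index=matrix.values.index, name="d_stat"), s0


def _distinct_assignments(n_num: int, n_den: int) -> list[tuple[int, ...]]:
    """All ways to pick which of the pooled samples carry the numerator
    label, excluding the observed assignment (indices 0..n_num-1)."""
    observed = tuple(range(n_num))
    return [c for c in combinations(range(n_num + n_den), n_num) if c != observed]


def permutation_pq(matrix: ExpressionMatrix, design: ExperimentDesign,
                   contrast: ContrastSpec,
                   params: SAMParams) -> pd.DataFrame:
    """Pooled permutation p- and q-values for the contrast's d-statistics.

    Returns a frame indexed by gene with columns d_stat, p_value, q_value.
    Deterministic given ``params.seed``; exhaustive whenever the number of
    distinct non-observed label assignments does not exceed
    ``params.n_permutations``.
    """
    num, den = contrast.columns(design)
    pooled_cols = num + den
    x = matrix.values[pooled_cols].to_numpy(dtype=float)
    n1, n2 = len(num), len(den)
    d_obs, s0 = sam_d_statistic(matrix, design, contrast, params.s0)

    all_assignments = _distinct_assignments(n1, n2)
    if len(all_assignments) <= params.n_permutations:
        assignments = all_assignments
        logger.info(
            "contrast %s/%s: enumerating all %d distinct label assignments "
            "exactly", contrast.tissue, contrast.genotype, len(assignments))
    else:
        rng = np.random.default_rng(params.seed)
        assignments = []
        for _ in range(params.n_permutations):
            perm = rng.permutation(n1 + n2)
            assignments.append(tuple(sorted(perm[:n1])))

    n_genes = x.shape[0]
    perm_abs = np.empty((len(assignments), n_genes))
    for i, idx in enumerate(assignments):
        sel = np.zeros(n1 + n2, dtype=bool)
        sel[list(idx)] = True
        perm_abs[i] = np.abs(_d_from_groups(x[:, sel], x[:, ~sel], s0))

    pool = np.sort(perm_abs.ravel())
    abs_obs = np.abs(d_obs.to_numpy())
    n_pool = pool.size
    # count of pooled |d*| >= |d_g|; searchsorted('left') gives # strictly below
    ge_counts = n_pool - np.searchsorted(pool, abs_obs, side="left")
    p = (1.0 + ge_counts) / (1.0 + n_pool)

    # SAM q: median over permutations of per-permutation false-positive
    # counts at threshold |d_g|, over the observed count, monotonized
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    obs_counts = np.arange(1, n_genes + 1)  # genes with |d| >= threshold
    per_perm_sorted = np.sort(perm_abs, axis=1)
    fp = np.empty((len(assignments), n_genes))
    for i in range(len(assignments)):
        fp[i] = n_genes - np.searchsorted(per_perm_sorted[i], thresholds,
                                          side="left")
    median_fp = np.median(fp, axis=0)
    q_sorted = np.clip(median_fp / obs_counts, 0.0, 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n_genes)
    q[order] = q_sorted

    return pd.DataFrame({"d_stat": d_obs, "p_value": p, "q_value": q},
                        index=matrix.values.index)


def call_de(de_table: pd.DataFrame, params: SAMParams) -> pd.DataFrame:
    """Apply the inclusive FC and p gates; adds fc_linear and call columns."""
    out = de_table.copy()
    out["fc_linear"] = signed_linear_fc(out["log2fc"])
    up = (out["fc_linear"] >= params.fc_threshold) \
        & (out["p_value"] <= params.p_threshold)
    down = (out["fc_linear"] <= -params.fc_threshold) \
        & (out["p_value"] <= params.p_threshold)
    out["call"] = np.where(up, CALL_UP, np.where(down, CALL_DOWN, CALL_NS))
    return out


def differential_expression(matrix: ExpressionMatrix, design: ExperimentDesign,
                            contrast: ContrastSpec,
                            params: SAMParams | None = None) -> pd.DataFrame:
    """Full DE table for one contrast: log2fc, fc_linear, d, p, q, call."""
    params = params or SAMParams()
    table = permutation_pq(matrix, design, contrast, params)
    table.insert(0, "log2fc", log2_fold_change(matrix, design, contrast))
    table = call_de(table, params)
    table.index.name = "gene_id"
    n_up = int((table["call"] == CALL_UP).sum())
    n_down = int((table["call"] == CALL_DOWN).sum())
    logger.info("DE %s/%s: %d genes, %d UP, %d DOWN (p<=%g, |FC|>=%g)",
                contrast.tissue, contrast.genotype, len(table), n_up, n_down,
                params.p_threshold, params.fc_threshold)
    return table.reset_index()[DE_COLUMNS]
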