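"""Cross-tabulation of dependence classes against annotation gene sets.

Three surfaces, mirroring how curated stress / hormone / transcription-factor
lists are used downstream of the classifier:

* three-set Venn partitions of a query gene list (exclusive region counts);
* class x set contingency tables with percentages of the class's annotated
  genes (half-up rounding to one decimal, the reporting convention used for
  hormone classes), optionally with motif co-annotation counts;
* one-sided Fisher (hypergeometric upper tail) over-representation tests
  with Benjamini-Yekutieli adjustment, the singular-enrichment-analysis
  semantics of AgriGO-style tools.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

VENN_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one digit)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VennPartition3:
    """Exclusive-region counts of a query against three sets."""

    names: tuple[str, str, str]
    regions: dict[str, int]      # keys VENN_REGIONS, exclusive counts
    outside: int                 # query genes in none of the three sets

    @property
    def covered(self) -> int:
        return sum(self.regions.values())


def venn3(query_genes: Iterable[str], set_a: Iterable[str],
          set_b: Iterable[str], set_c: Iterable[str],
          names: tuple[str, str, str] = ("A", "B", "C")) -> VennPartition3:
    """Exclusive 3-set region counts of ``query`` members."""
    q = set(query_genes)
    a, b, c = set(set_a) & q, set(set_b) & q, set(set_c) & q
    regions = {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }
    part = VennPartition3(names=tuple(names), regions=regions,
                          outside=len(q - a - b - c))
    assert part.covered == len(a | b | c)
    return part


def venn3_table(part: VennPartition3) -> pd.DataFrame:
    rows = [(region, part.regions[region]) for region in VENN_REGIONS]
    rows.append(("outside", part.outside))
    return pd.DataFrame(rows, columns=["region", "count"]).assign(
        sets="|".join(part.names))


def crosstab_classes(class_map: Mapping[str, str] | pd.Series,
                     gene_sets: GeneSetCollection,
                     motif_counts: pd.DataFrame | None = None,
                     ) -> pd.DataFrame:
    """Class x set member counts and percentages of class-annotated genes.

    The percentage denominator is the number of genes of the class that are
    annotated to at least one set of the collection (the convention behind
    "14 of 35 hormone-annotated genes = 40.0%"); rounding is half-up to one
    decimal. Genes absent from the collection's universe are counted as
    unannotated (with a warning). When ``motif_counts`` (per-gene occurrence
    counts, one column per motif) is given, per-cell counts of
    motif-bearing genes are appended.
    """
    classes = pd.Series(dict(class_map))
    stray = [g for g in classes.index if g not in gene_sets.universe]
    if stray:
        import warnings
        warnings.warn(f"{len(stray)} gene(s) not in the annotation universe; "
                      "counted as unannotated")
    annotated_any = set().union(*gene_sets.sets.values()) if gene_sets.sets else set()
    rows = []
    for label in sorted(classes.unique()):
        members = set(classes.index[classes == label])
        denom = len(members & annotated_any)
        for name in gene_sets.names():
            inset = members & gene_sets[name]
            pct = round_half_up(100.0 * len(inset) / denom) if denom else float("nan")
            row = {"class_label": label, "set": name, "n_class": len(members),
                   "n_annotated": denom, "count": len(inset),
                   "pct_of_annotated": pct}
            if motif_counts is not None:
                for motif in motif_counts.columns:
                    bearing = set(motif_counts.index[motif_counts[motif] > 0])
                    row[f"n_with_{motif}"] = len(inset & bearing)
            rows.append(row)
    return pd.DataFrame(rows)


def fisher_enrichment(query: Iterable[str],
                      term_sets: GeneSetCollection | Mapping[str, Iterable[str]],
                      universe: Iterable[str] | None = None) -> pd.DataFrame:
    """One-sided over-representation tests for every term.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n) where N = |universe|,
    K = |term|, n = |query|, k = |query & term|. Odds ratios come from the
    2x2 table with a 0.5 continuity correction when any cell is zero.
    Adjusted p-values use the Benjamini-Yekutieli step-up.
    """
    if isinstance(term_sets, GeneSetCollection):
        if universe is None:
            universe = term_sets.universe
        terms = {name: set(term_sets[name]) for name in term_sets.names()}
    else:
        terms = {name: set(members) for name, members in term_sets.items()}
        if universe is None:
            raise ValueError("universe is required with a plain mapping of terms")
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q = set(query) & uni
    rows = []
    for name, members in terms.items():
        members = members & uni
        N, K, n = len(uni), len(members), len(q)
        k = len(q & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n and K else 1.0
        a, b, c, d = k, n - k, K - k, N - K - (n - k)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append({"term": name, "k": k, "K": K, "n": n, "N": N,
                     "odds_ratio": (a * d) / (b * c), "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = adjust_by(out["p_value"].to_numpy())
        out = out.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
    else:
        out["p_adjusted"] = []
    return out


def adjust_by(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (valid under any dependence)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]
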