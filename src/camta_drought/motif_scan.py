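"""Degenerate (IUPAC) cis-element scanning of promoter sequences.

Locates the CAMTA recognition elements — the CGCG box ``MCGCGB`` =
(A/C)CGCG(C/G/T) and the ABRE-overlapping ``MCGTGT`` = (A/C)CGTGT — in
upstream sequences and summarizes, per gene class, the percentage of genes
carrying at least one occurrence.

Coordinates are 0-based half-open on the promoter string (position 0 = the
most-upstream base). Strand '-' hits are found by scanning the reverse
complement and mapping positions back to the forward strand; the stored
matched substring is the forward-strand slice, so its reverse complement is
a word of the motif. Overlapping occurrences are all reported. ``N`` in a
sequence matches no motif symbol.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate pattern over the IUPAC nucleotide alphabet."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = sorted(set(self.pattern.upper()) - set(IUPAC_CODES))
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) {bad} in {self.pattern!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def width(self) -> int:
        return len(self.pattern)

    @property
    def degeneracy(self) -> int:
        out = 1
        for sym in self.pattern:
            out *= len(IUPAC_CODES[sym])
        return out

    def expand(self) -> frozenset[str]:
        """Full enumeration of the concrete words the pattern denotes."""
        choices = [IUPAC_CODES[sym] for sym in self.pattern]
        return frozenset("".join(w) for w in itertools.product(*choices))

    def regex(self) -> re.Pattern[str]:
        # lookahead so overlapping occurrences are all found
        body = "".join(f"[{IUPAC_CODES[sym]}]" for sym in self.pattern)
        return re.compile(f"(?=({body}))")


def iupac_expand(motif: IUPACMotif | str) -> frozenset[str]:
    if isinstance(motif, str):
        motif = IUPACMotif(motif, motif)
    return motif.expand()


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    start: int        # 0-based
    end: int          # half-open
    strand: str       # '+' or '-'
    matched: str      # forward-strand slice seq[start:end]


def parse_motifs(spec: str | Iterable[str]) -> tuple[IUPACMotif, ...]:
    """Parse 'MCGCGB,MCGTGT' (or an iterable of patterns) into motifs."""
    if isinstance(spec, str):
        spec = [s for s in spec.split(",") if s]
    return tuple(IUPACMotif(p, p) for p in spec)


def scan_sequence(sequence: str, motif: IUPACMotif,
                  strand_policy: str = "both",
                  gene_id: str = "") -> list[MotifHit]:
    """All occurrences of ``motif`` in ``sequence`` under the strand policy.

    Sequences shorter than the motif yield an empty list. Hits are ordered
    by start, '+' before '-'.
    """
    if strand_policy not in ("forward", "both"):
        raise ValueError("strand_policy must be 'forward' or 'both'")
    seq = sequence.upper()
    w = motif.width
    hits: list[MotifHit] = []
    if len(seq) < w:
        return hits
    pat = motif.regex()
    for m in pat.finditer(seq):
        s = m.start()
        hits.append(MotifHit(gene_id, motif.name, s, s + w, "+", seq[s:s + w]))
    if strand_policy == "both":
        rc = reverse_complement(seq)
        L = len(seq)
        for m in pat.finditer(rc):
            start = L - m.start() - w
            hits.append(MotifHit(gene_id, motif.name, start, start + w, "-",
                                 seq[start:start + w]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_promoters(promoters, motifs: Iterable[IUPACMotif],
                   strand_policy: str = "both") -> pd.DataFrame:
    """Scan every promoter for every motif; returns the hit table.

    Columns: gene_id, start, end, motif, strand, matched.
    """
    rows = []
    for gid, seq in promoters.sequences.items():
        for motif in motifs:
            for h in scan_sequence(seq, motif, strand_policy, gene_id=gid):
                rows.append((h.gene_id, h.start, h.end, h.motif, h.strand, h.matched))
    return pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "motif", "strand", "matched"])


def motif_gene_frequency(hits: pd.DataFrame,
                         gene_classes: Mapping[str, str] | pd.Series,
                         motif_names: Iterable[str] | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class, per-motif gene frequencies plus per-gene occurrence counts.

    ``gene_classes`` maps gene id -> class label for every gene to tabulate
    (genes without hits included). Returns ``(freq, per_gene)`` where
    ``freq`` has one row per (class, motif) with the count of genes carrying
    >= 1 hit and the percentage of class genes doing so (NaN for an empty
    class), and ``per_gene`` carries per-gene occurrence counts per motif
    with a compact "2-MCGCGB; 5-MCGTGT"-style summary column.
    """
    classes = pd.Series(dict(gene_classes), name="class_label")
    if motif_names is None:
        motif_names = sorted(hits["motif"].unique()) if len(hits) else []
    motif_names = list(motif_names)
    counts = pd.DataFrame(0, index=classes.index, columns=motif_names, dtype=int)
    if len(hits):
        tab = (hits[hits["gene_id"].isin(classes.index)]
               .groupby(["gene_id", "motif"]).size().unstack(fill_value=0))
        counts.loc[tab.index, tab.columns.intersection(motif_names)] = \
            tab[tab.columns.intersection(motif_names)]
    rows = []
    for label in sorted(classes.unique()):
        members = classes.index[classes == label]
        n = len(members)
        for motif in motif_names:
            with_hit = int((counts.loc[members, motif] > 0).sum()) if n else 0
            freq = 100.0 * with_hit / n if n else float("nan")
            rows.append((label, motif, n, with_hit, freq))
    freq = pd.DataFrame(
        rows, columns=["class_label", "motif", "n_genes", "n_with_hit",
                       "frequency_pct"])
    per_gene = counts.copy()
    per_gene.insert(0, "class_label", classes)
    per_gene["summary"] = [
        "; ".join(f"{int(row[m])}-{m}" for m in motif_names if row[m] > 0)
        for _, row in counts.iterrows()]
    per_gene.index.name = "gene_id"
    return freq, per_gene
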