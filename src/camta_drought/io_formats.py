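"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are TSV ('.' decimal, no quoting); promoters are plain
FASTA; annotation gene sets use the GMT dialect (name, description, members,
tab-separated). Motif hits are written BED-like with 0-based half-open
coordinates on the promoter string, position 0 being the most-upstream base.

Every reader validates strictly: malformed input raises :class:`FormatError`
with enough coordinates (file, line, row/column) to locate the defect.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOTYPES = ("WT", "MUT")
CONDITIONS = ("CONTROL", "DROUGHT")
TISSUES = ("LEAF", "ROOT")

DESIGN_COLUMNS = ["sample_id", "genotype", "condition", "tissue", "replicate"]
HIT_COLUMNS = ["gene_id", "start", "end", "motif", "strand", "matched"]

PROMOTER_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an on-disk file violates the format contract."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExperimentDesign:
    """Sample sheet for the genotype x condition x tissue factorial.

    The backing frame has columns ``sample_id, genotype, condition, tissue,
    replicate``. Genotype/condition/tissue values are normalized to upper
    case on construction. Invariants enforced:

    * sample ids unique;
    * every occupied (genotype, condition, tissue) cell has >= 2 replicates
      (required by the permutation d-statistic);
    * the design is rectangular per tissue: all four genotype x condition
      cells are present for each tissue that appears.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"design is missing columns {missing}")
        t = t[DESIGN_COLUMNS].reset_index(drop=True)
        for col in ("genotype", "condition", "tissue"):
            t[col] = t[col].astype(str).str.upper()
        t["sample_id"] = t["sample_id"].astype(str)
        t["replicate"] = pd.to_numeric(t["replicate"], errors="raise").astype(int)
        if (t["replicate"] < 1).any():
            raise FormatError("replicate numbers must be positive integers")
        for col, allowed in (("genotype", GENOTYPES), ("condition", CONDITIONS),
                             ("tissue", TISSUES)):
            bad = sorted(set(t[col]) - set(allowed))
            if bad:
                raise FormatError(f"invalid {col} value(s) {bad}; allowed: {allowed}")
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicated sample id(s): {sorted(set(dup))}")
        cells = t.groupby(["tissue", "genotype", "condition"])["sample_id"].count()
        small = cells[cells < 2]
        if len(small):
            raise FormatError(
                f"cells with fewer than 2 replicates: {list(small.index)}")
        for tissue in t["tissue"].unique():
            sub = t[t["tissue"] == tissue]
            present = set(zip(sub["genotype"], sub["condition"]))
            needed = {(g, c) for g in GENOTYPES for c in CONDITIONS}
            if present != needed:
                raise FormatError(
                    f"tissue {tissue}: missing design cell(s) {sorted(needed - present)}")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def samples_for(self, tissue: str, genotype: str, condition: str) -> list[str]:
        t = self.table
        m = ((t["tissue"] == tissue.upper())
             & (t["genotype"] == genotype.upper())
             & (t["condition"] == condition.upper()))
        return list(t.loc[m, "sample_id"])


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized log2 intensities.

    ``values`` is indexed by gene id with one column per sample id; all
    entries must be finite and both axes unique and non-empty.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise FormatError("expression matrix is empty")
        if v.index.duplicated().any():
            dup = sorted(set(v.index[v.index.duplicated()]))
            raise FormatError(f"duplicated gene id(s): {dup}")
        if v.columns.duplicated().any():
            dup = sorted(set(v.columns[v.columns.duplicated()]))
            raise FormatError(f"duplicated sample id(s): {dup}")
        arr = v.to_numpy()
        import numpy as np
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe (stands in for curated databases)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(s) for name, s in self.sets.items()}
        self.universe = frozenset(self.universe)
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise FormatError(
                    f"set {name!r} has member(s) outside the universe: "
                    f"{sorted(stray)[:5]}")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PromoterSet:
    """One upstream sequence per gene, uppercase, alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for gid, seq in self.sequences.items():
            s = str(seq).upper()
            if not s:
                raise FormatError(f"promoter for {gid!r} is empty")
            bad = set(s) - PROMOTER_ALPHABET
            if bad:
                raise FormatError(
                    f"promoter for {gid!r} contains invalid character(s) {sorted(bad)}")
            clean[str(gid)] = s
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gid: str) -> str:
        return self.sequences[gid]

    def lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.sequences.items()}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> ExperimentDesign:
    try:
        t = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot read design {path}: {exc}") from exc
    return ExperimentDesign(t)


def read_expression(path_matrix: str | Path,
                    path_design: str | Path) -> tuple[ExpressionMatrix, ExperimentDesign]:
    """Read and cross-validate a matrix/design pair.

    The matrix TSV has a header row of sample ids and gene ids in the first
    column; column order is preserved. Any sample present in one file but
    not the other is fatal, as is any non-numeric cell (reported with its
    row and column coordinates).
    """
    design = read_design(path_design)
    raw = pd.read_csv(path_matrix, sep="\t", dtype=str, index_col=0)
    raw.index = raw.index.astype(str)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}")
        if converted.isna().any():
            gene = raw.index[converted.isna().to_numpy().argmax()]
            raise FormatError(f"missing value at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    matrix = ExpressionMatrix(numeric)
    m_samples, d_samples = set(matrix.sample_ids), set(design.sample_ids)
    only_m = sorted(m_samples - d_samples)
    only_d = sorted(d_samples - m_samples)
    if only_m or only_d:
        parts = []
        if only_m:
            parts.append(f"samples in matrix but not design: {only_m}")
        if only_d:
            parts.append(f"samples in design but not matrix: {only_d}")
        raise FormatError("; ".join(parts))
    return matrix, design


def read_fasta_promoters(path: str | Path) -> PromoterSet:
    """Read promoter FASTA; record id = token before first whitespace."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate promoter id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return PromoterSet(records)


def read_gmt(path: str | Path,
             universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file; universe defaults to the union of all members."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(name, description, members...), got {len(fields)}")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(universe))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def write_fasta(promoters: PromoterSet, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=gid, description="")
            for gid, seq in promoters.sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_gmt(collection: GeneSetCollection, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hits_to_bed(hits: pd.DataFrame) -> pd.DataFrame:
    """Motif hits in the BED-like column order (0-based half-open)."""
    if hits.empty:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return hits[HIT_COLUMNS].sort_values(
        ["gene_id", "start", "strand"]).reset_index(drop=True)


def write_results(tables: Mapping[str, pd.DataFrame],
                  out_dir: str | Path) -> list[str]:
    """Write each table as ``<name>.tsv`` plus a MANIFEST.tsv listing them.

    Empty tables produce header-only files. Returns the list of files
    written (manifest last).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise FormatError(f"output directory {out_dir} is not writable: {exc}") from exc
    written: list[str] = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path.name)
    manifest = pd.DataFrame({
        "file": written,
        "n_rows": [len(tables[Path(f).stem]) for f in written],
    })
    manifest_path = out_dir / "MANIFEST.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    written.append(manifest_path.name)
    return [str(out_dir / f) for f in written]
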