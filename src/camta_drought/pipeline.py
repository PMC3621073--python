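"""End-to-end orchestration: simulate/load -> DE -> classify -> scan -> annotate.

Stages communicate only through files in the output directory, so every
stage can be re-run and inspected independently. A run is driven by one
YAML config (key: value) holding either a ``simulation`` block or an
``inputs`` block with file paths, plus DE parameters, the confidence level
of the dependence cutoff, the motif list and strand policy. Identical
config and seed give identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import crosstab_classes, fisher_enrichment, venn3, venn3_table
from .dependence import DependenceClassification, classify_dependence, partition_summary
from .diffexpr import ContrastSpec, SAMParams, differential_expression
from .io_formats import (FormatError, GeneSetCollection, hits_to_bed,
                         read_expression, read_fasta_promoters, read_gmt,
                         write_design, write_expression, write_fasta, write_gmt,
                         write_results)
from .motif_scan import motif_gene_frequency, parse_motifs, scan_promoters
from .synthetic_data import (SimulationConfig, simulate_expression,
                             simulate_gene_sets, simulate_promoters)

logger = logging.getLogger(__name__)

STRESS_SETS = ("drought", "cold", "salt")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "camta_run",
    "de": {"s0": None, "n_permutations": 1000, "p_threshold": 0.05,
           "fc_threshold": 2.0},
    "ci_level": 0.99,
    "motifs": ["MCGCGB", "MCGTGT"],
    "strand_policy": "both",
    "log_level": "INFO",
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the diagnosed cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated run configuration."""

    raw: dict

    def __post_init__(self) -> None:
        cfg = dict(DEFAULT_CONFIG)
        cfg.update(self.raw or {})
        has_sim = "simulation" in cfg and cfg["simulation"] is not None
        has_inputs = "inputs" in cfg and cfg["inputs"] is not None
        if has_sim == has_inputs:
            raise FormatError(
                "config must contain exactly one of 'simulation' or 'inputs'")
        if has_inputs:
            inputs = cfg["inputs"]
            for key in ("matrix", "design"):
                if key not in inputs:
                    raise FormatError(f"inputs block is missing {key!r}")
            for key, path in inputs.items():
                if path and not Path(path).exists():
                    raise FormatError(f"input file {key}={path!r} does not exist")
        self.raw = cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)

    def sam_params(self) -> SAMParams:
        de = self.raw["de"]
        return SAMParams(s0=de.get("s0"),
                         n_permutations=int(de.get("n_permutations", 1000)),
                         seed=int(self.raw["seed"]),
                         p_threshold=float(de.get("p_threshold", 0.05)),
                         fc_threshold=float(de.get("fc_threshold", 2.0)))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of a completed run: inputs, outputs and headline counts."""

    config_hash: str
    version: str
    files: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _load_stage(config: PipelineConfig, out_dir: Path):
    """Load or simulate the inputs; simulation writes its files to disk."""
    if config.get("simulation") is not None:
        sim_kwargs = dict(config["simulation"])
        sim_kwargs.setdefault("seed", int(config["seed"]))
        if "tissues" in sim_kwargs:
            sim_kwargs["tissues"] = tuple(sim_kwargs["tissues"])
        sim = SimulationConfig(**sim_kwargs)
        matrix, design, truth = simulate_expression(sim)
        motifs = parse_motifs(config["motifs"])
        promoters = simulate_promoters(sim, truth, motifs=motifs)
        gene_sets = simulate_gene_sets(sim, truth)
        write_expression(matrix, out_dir / "matrix.tsv")
        write_design(design, out_dir / "design.tsv")
        write_fasta(promoters, out_dir / "promoters.fa")
        write_gmt(gene_sets, out_dir / "gene_sets.gmt")
        truth.genes.to_csv(out_dir / "truth.tsv", sep="\t")
        return matrix, design, promoters, gene_sets, truth
    inputs = config["inputs"]
    matrix, design = read_expression(inputs["matrix"], inputs["design"])
    promoters = (read_fasta_promoters(inputs["promoters"])
                 if inputs.get("promoters") else None)
    gene_sets = (read_gmt(inputs["gene_sets"], universe=matrix.gene_ids)
                 if inputs.get("gene_sets") else None)
    return matrix, design, promoters, gene_sets, None


def run_pipeline(config: PipelineConfig | dict | str | Path,
                 out_dir: str | Path | None = None) -> RunManifest:
    """Execute every stage in dependency order; returns the run manifest.

    Per tissue: DE tables for both genotypes, the dependence classification,
    motif hits and per-class frequencies (when promoters are available), and
    Venn / crosstab / enrichment tables (when gene sets are available). Any
    stage failure aborts with the stage name; tables computed so far are
    retained with a ``.partial`` suffix.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_file(config)
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    out = Path(out_dir if out_dir is not None else config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, str(config.get("log_level", "INFO")).upper(), 20),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")

    manifest = RunManifest(config_hash=config.digest(), version=__version__)
    tables: dict[str, pd.DataFrame] = {}
    stage = "load"
    try:
        matrix, design, promoters, gene_sets, truth = _load_stage(config, out)
        params = config.sam_params()
        ci_level = float(config["ci_level"])
        motifs = parse_motifs(config["motifs"])
        strand_policy = config["strand_policy"]

        classifications: list[DependenceClassification] = []
        for tissue in design.tissues:
            key = tissue.lower()
            stage = f"de:{key}"
            de_wt = differential_expression(
                matrix, design, ContrastSpec(tissue, "WT"), params)
            de_mut = differential_expression(
                matrix, design, ContrastSpec(tissue, "MUT"), params)
            tables[f"{key}_de_wt"] = de_wt
            tables[f"{key}_de_mut"] = de_mut

            stage = f"classify:{key}"
            cls = classify_dependence(de_wt, de_mut, ci_level=ci_level,
                                      tissue=tissue)
            classifications.append(cls)
            tables[f"{key}_classes"] = cls.table
            c = cls.counts
            manifest.counts[key] = {
                **c,
                "wt_up": c["CDPRG"] + c["CIDIG"],
                "wt_down": c["CDNRG"] + c["CIDRG"],
            }

            class_map = cls.class_map()
            per_gene_counts = None
            if promoters is not None and len(class_map):
                stage = f"scan:{key}"
                class_proms = type(promoters)(
                    {g: promoters[g] for g in class_map.index
                     if g in promoters.sequences})
                hits = scan_promoters(class_proms, motifs, strand_policy)
                freq, per_gene = motif_gene_frequency(
                    hits, class_map, [m.name for m in motifs])
                tables[f"{key}_motif_hits"] = hits_to_bed(hits)
                tables[f"{key}_motif_frequencies"] = freq
                tables[f"{key}_motif_per_gene"] = per_gene.reset_index()
                per_gene_counts = per_gene[[m.name for m in motifs]]

            if gene_sets is not None and len(class_map):
                stage = f"annotate:{key}"
                if all(s in gene_sets.sets for s in STRESS_SETS):
                    venns = []
                    for label in sorted(class_map.unique()):
                        genes = class_map.index[class_map == label]
                        part = venn3(genes, gene_sets["drought"],
                                     gene_sets["cold"], gene_sets["salt"],
                                     names=STRESS_SETS)
                        venns.append(venn3_table(part).assign(class_label=label))
                    tables[f"{key}_venn_stress"] = pd.concat(
                        venns, ignore_index=True)
                tables[f"{key}_crosstab"] = crosstab_classes(
                    class_map, gene_sets, motif_counts=per_gene_counts)
                enr = []
                for label in sorted(class_map.unique()):
                    genes = class_map.index[class_map == label]
                    e = fisher_enrichment(genes, gene_sets,
                                          universe=matrix.gene_ids)
                    enr.append(e.assign(class_label=label))
                tables[f"{key}_enrichment"] = pd.concat(enr, ignore_index=True)

        stage = "summary"
        tables["partition_summary"] = partition_summary(classifications)
        stage = "write"
        manifest.files = write_results(tables, out)
        report_text = report(manifest, tables)
        (out / "report.md").write_text(report_text)
        manifest.files.append(str(out / "report.md"))
        (out / "manifest.json").write_text(manifest.to_json())
        manifest.files.append(str(out / "manifest.json"))
    except Exception as exc:
        for name, table in tables.items():
            path = out / f"{name}.tsv.partial"
            try:
                table.to_csv(path, sep="\t", index=False)
            except OSError:  # pragma: no cover
                pass
        raise PipelineError(stage, exc) from exc
    for path in manifest.files:
        assert Path(path).exists()
    return manifest


def report(manifest: RunManifest | None,
           tables: dict[str, pd.DataFrame]) -> str:
    """Human-readable markdown summary of a run's tables.

    Built purely from the tables, so a report regenerated from the saved
    TSVs equals the one produced by the live run.
    """
    lines = ["# CAMTA dependence pipeline report", ""]
    if manifest is not None:
        lines += [f"Config {manifest.config_hash}, package version "
                  f"{manifest.version}.", ""]
    summary = tables.get("partition_summary")
    if summary is not None and len(summary):
        lines.append("## Dependence classes per tissue")
        lines.append("")
        lines.append("tissue | CDPRG | CIDIG | WT up | CDNRG | CIDRG | WT down")
        lines.append("--- | --- | --- | --- | --- | --- | ---")
        for _, r in summary.iterrows():
            lines.append(f"{r['tissue']} | {r['CDPRG']} | {r['CIDIG']} | "
                         f"{r['wt_up']} | {r['CDNRG']} | {r['CIDRG']} | "
                         f"{r['wt_down']}")
        lines.append("")
    for key in sorted(tables):
        if key.endswith("_motif_frequencies") and len(tables[key]):
            lines.append(f"## Motif frequencies ({key.split('_')[0]})")
            lines.append("")
            for _, r in tables[key].iterrows():
                freq = r["frequency_pct"]
                shown = "NA" if pd.isna(freq) else f"{freq:.1f}%"
                lines.append(f"- {r['class_label']} / {r['motif']}: "
                             f"{int(r['n_with_hit'])}/{int(r['n_genes'])} "
                             f"genes ({shown})")
            lines.append("")
        if key.endswith("_venn_stress") and len(tables[key]):
            lines.append(f"## Stress-set Venn regions ({key.split('_')[0]})")
            lines.append("")
            for label, sub in tables[key].groupby("class_label"):
                regions = ", ".join(f"{r['region']}={int(r['count'])}"
                                    for _, r in sub.iterrows())
                lines.append(f"- {label}: {regions}")
            lines.append("")
        if key.endswith("_enrichment") and len(tables[key]):
            lines.append(f"## Top enrichment ({key.split('_')[0]})")
            lines.append("")
            for label, sub in tables[key].groupby("class_label"):
                top = sub.sort_values("p_adjusted", kind="stable").iloc[0]
                lines.append(f"- {label}: {top['term']} "
                             f"(k={int(top['k'])}/{int(top['K'])}, "
                             f"BY p={top['p_adjusted']:.3g})")
            lines.append("")
    if summary is None or not len(summary) or summary["total"].sum() == 0:
        lines.append("No WT drought-responsive genes were classified.")
        lines.append("")
    return "\n".join(lines)


def report_from_dir(out_dir: str | Path) -> str:
    """Rebuild the report from a run directory's saved tables."""
    out = Path(out_dir)
    manifest = None
    manifest_json = out / "manifest.json"
    if manifest_json.exists():
        manifest = RunManifest(**json.loads(manifest_json.read_text()))
    files = pd.read_csv(out / "MANIFEST.tsv", sep="\t")["file"]
    tables = {}
    for fname in files:
        stem = Path(fname).stem
        if stem == "MANIFEST":
            continue
        tables[stem] = pd.read_csv(out / fname, sep="\t")
    return report(manifest, tables)
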