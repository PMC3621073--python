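"""Synthetic factorial expression data, promoters and gene sets with ground truth.

The generator emulates the study design the pipeline targets: a 2 (genotype:
wild type vs knockout mutant) x 2 (condition: control vs drought) x 2 (tissue:
leaf vs root) factorial with three biological replicates per cell, log2-scale
expression with additive Gaussian noise, and a per-gene drought response that
is attenuated in the mutant for "dependent" genes:

    log2 x = b_g + delta_g * [drought] * (kappa_g if genotype == MUT else 1) + eps,
    eps ~ Normal(0, sigma^2)

Gene classes partition the genome: ``dep_pos``/``dep_neg`` respond to drought
in the wild type (delta = +/- effect_size) but are attenuated in the mutant
(kappa = attenuation < 1); ``indep_up``/``indep_down`` respond identically in
both genotypes (kappa = 1); ``null`` genes have delta = 0.

Promoters are random sequences of configurable GC content with concrete
instances of degenerate motifs planted at recorded positions; with
``clean_background`` the background is rejection-resampled so it contains no
accidental motif matches on either strand, making planted coordinates the
exact ground truth for the scanner. Gene sets are Bernoulli samples with
per-class inclusion rates, standing in for curated stress/hormone/TF lists.

One top-level seed drives three independent child streams (expression,
promoters, gene sets), so each generator is reproducible on its own.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ExperimentDesign, ExpressionMatrix, GeneSetCollection, PromoterSet
from .motif_scan import IUPACMotif, reverse_complement, scan_sequence

CLASS_LABELS = ("dep_pos", "dep_neg", "indep_up", "indep_down", "null")

DEFAULT_CLASS_FRACTIONS = {
    "dep_pos": 0.15,
    "dep_neg": 0.15,
    "indep_up": 0.10,
    "indep_down": 0.10,
    "null": 0.50,
}

DEFAULT_MOTIFS = (IUPACMotif("MCGCGB", "MCGCGB"), IUPACMotif("MCGTGT", "MCGTGT"))

#: default per-set, per-class inclusion probabilities for simulate_gene_sets;
#: stress sets are enriched in dependent genes, hormone classes modestly so,
#: TF families sparse -- scaled to yield set sizes of the order the curated
#: databases return for a few-thousand-gene universe.
DEFAULT_SET_RATES: dict[str, dict[str, float]] = {
    "drought": {"dep_pos": 0.12, "dep_neg": 0.08, "indep_up": 0.04,
                "indep_down": 0.04, "null": 0.01},
    "cold": {"dep_pos": 0.08, "dep_neg": 0.10, "indep_up": 0.04,
             "indep_down": 0.04, "null": 0.01},
    "salt": {"dep_pos": 0.10, "dep_neg": 0.08, "indep_up": 0.04,
             "indep_down": 0.04, "null": 0.01},
    "hormone_ABA": {"dep_pos": 0.05, "dep_neg": 0.02, "indep_up": 0.02,
                    "indep_down": 0.02, "null": 0.005},
    "hormone_auxin": {"dep_pos": 0.02, "dep_neg": 0.04, "indep_up": 0.02,
                      "indep_down": 0.02, "null": 0.005},
    "hormone_ethylene": {"dep_pos": 0.03, "dep_neg": 0.02, "indep_up": 0.01,
                         "indep_down": 0.01, "null": 0.005},
    "tf_AP2-EREBP": {"dep_pos": 0.02, "dep_neg": 0.02, "indep_up": 0.01,
                     "indep_down": 0.01, "null": 0.002},
    "tf_MYB": {"dep_pos": 0.01, "dep_neg": 0.02, "indep_up": 0.01,
               "indep_down": 0.01, "null": 0.002},
    "tf_bHLH": {"dep_pos": 0.01, "dep_neg": 0.015, "indep_up": 0.01,
                "indep_down": 0.01, "null": 0.002},
}


@dataclass
class SimulationConfig:
    """Parameters of the generative model (log2 units unless noted)."""

    n_genes: int = 2000
    n_reps: int = 3
    tissues: tuple[str, ...] = ("LEAF", "ROOT")
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    effect_size: float = 2.0          # |delta| for drought-responsive genes
    noise_sd: float = 0.25            # sigma of the replicate noise
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    attenuation: float = 0.0          # kappa for dependent genes, in [0, 1)
    promoter_length: int = 1000       # bp
    planted_hits_per_gene: int = 1
    gc_fraction: float = 0.35         # plant promoters are AT-rich
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reps < 1:
            raise ValueError("n_genes and n_reps must be positive")
        if set(self.class_fractions) != set(CLASS_LABELS):
            raise ValueError(f"class_fractions must have keys {CLASS_LABELS}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie in (0, 1)")
        if self.planted_hits_per_gene < 0:
            raise ValueError("planted_hits_per_gene must be >= 0")


@dataclass
class SyntheticTruth:
    """Per-gene ground truth recorded by the generators.

    ``genes`` has one row per gene (index = gene id) with columns
    ``class_label``, ``delta`` (signed drought effect in WT, log2) and
    ``kappa`` (mutant attenuation multiplier). ``planted`` maps gene id to
    the list of planted (motif name, start, strand) triples; ``memberships``
    maps set name to its member genes.
    """

    genes: pd.DataFrame
    planted: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    memberships: dict[str, frozenset[str]] = field(default_factory=dict)

    def genes_of_class(self, *labels: str) -> list[str]:
        mask = self.genes["class_label"].isin(labels)
        return list(self.genes.index[mask])

    @property
    def dependent_genes(self) -> frozenset[str]:
        return frozenset(self.genes_of_class("dep_pos", "dep_neg"))


def _child_rngs(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _assign_classes(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic class assignment: contiguous blocks by rounded fraction."""
    n = config.n_genes
    counts = {}
    allotted = 0
    for label in CLASS_LABELS[:-1]:
        counts[label] = int(round(config.class_fractions[label] * n))
        allotted += counts[label]
    counts["null"] = n - allotted
    if counts["null"] < 0:
        raise ValueError("class fractions produce a negative null count")
    labels = np.repeat(list(counts), list(counts.values()))
    gene_ids = [f"g{i:05d}" for i in range(1, n + 1)]
    sign = {"dep_pos": 1.0, "dep_neg": -1.0, "indep_up": 1.0,
            "indep_down": -1.0, "null": 0.0}
    kappa = {"dep_pos": config.attenuation, "dep_neg": config.attenuation,
             "indep_up": 1.0, "indep_down": 1.0, "null": 1.0}
    frame = pd.DataFrame({
        "class_label": labels,
        "delta": [sign[l] * config.effect_size for l in labels],
        "kappa": [kappa[l] for l in labels],
    }, index=pd.Index(gene_ids, name="gene_id"))
    return frame


def _build_design(config: SimulationConfig) -> ExperimentDesign:
    rows = []
    for tissue in config.tissues:
        for genotype in ("WT", "MUT"):
            for condition in ("CONTROL", "DROUGHT"):
                for rep in range(1, config.n_reps + 1):
                    sid = f"{tissue}_{genotype}_{condition}_{rep}"
                    rows.append((sid, genotype, condition, tissue, rep))
    return ExperimentDesign(pd.DataFrame(
        rows, columns=["sample_id", "genotype", "condition", "tissue", "replicate"]))


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExperimentDesign, SyntheticTruth]:
    """Draw an expression matrix from the generative model.

    Matrix dimensions are ``n_genes x (4 * n_reps * n_tissues)``. The same
    per-gene effects apply in every tissue; replicate noise is independent
    throughout. Identical config (including seed) gives bit-identical output.
    """
    rng, _, _ = _child_rngs(config.seed)
    genes = _assign_classes(config)
    design = _build_design(config)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    delta = genes["delta"].to_numpy()
    kappa = genes["kappa"].to_numpy()

    columns = design.sample_ids
    data = np.empty((config.n_genes, len(columns)))
    for j, sid in enumerate(columns):
        row = design.table.loc[design.table["sample_id"] == sid].iloc[0]
        drought = 1.0 if row["condition"] == "DROUGHT" else 0.0
        mult = kappa if row["genotype"] == "MUT" else np.ones_like(kappa)
        mean = baseline + delta * drought * mult
        noise = rng.normal(0.0, config.noise_sd, config.n_genes) \
            if config.noise_sd > 0 else 0.0
        data[:, j] = mean + noise
    matrix = ExpressionMatrix(pd.DataFrame(data, index=genes.index, columns=columns))
    return matrix, design, SyntheticTruth(genes=genes)


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, length: int,
                       gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=probs)


def _accidental_hits(seq: str, motifs: tuple[IUPACMotif, ...],
                     planted_spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = []
    for motif in motifs:
        for hit in scan_sequence(seq, motif, strand_policy="both"):
            if (hit.start, hit.end) not in planted_spans:
                spans.append((hit.start, hit.end))
    return sorted(set(spans))


def simulate_promoters(
    config: SimulationConfig,
    truth: SyntheticTruth,
    motifs: tuple[IUPACMotif, ...] = DEFAULT_MOTIFS,
    clean_background: bool = True,
    plant_probability: float | None = None,
    max_resample_rounds: int = 200,
) -> PromoterSet:
    """Generate one promoter per gene with planted motif instances.

    Each gene receives ``planted_hits_per_gene`` concrete motif instances
    (motif and strand chosen at random, positions non-overlapping); when
    ``plant_probability`` is given, each gene instead receives one instance
    with that probability. With ``clean_background`` the rest of the sequence
    is rejection-resampled until it contains no accidental match of any
    supplied motif on either strand, so planted coordinates are exhaustive
    ground truth. Planted coordinates are recorded in ``truth.planted``.
    """
    _, rng, _ = _child_rngs(config.seed)
    width_max = max(m.width for m in motifs)
    if config.promoter_length < width_max:
        raise ValueError("promoter_length is shorter than the longest motif")
    n_slots = config.promoter_length // (2 * width_max)
    sequences: dict[str, str] = {}
    truth.planted = {}
    for gid in truth.genes.index:
        if plant_probability is not None:
            n_plant = int(rng.random() < plant_probability)
        else:
            n_plant = config.planted_hits_per_gene
        if n_plant > n_slots:
            raise ValueError(
                f"cannot fit {n_plant} planted instances of width {width_max} "
                f"in a {config.promoter_length} bp promoter")
        seq = _random_background(rng, config.promoter_length, config.gc_fraction)
        # non-overlapping starts on a coarse grid, then jitter inside slots
        slot_ids = rng.choice(n_slots, size=n_plant, replace=False) if n_plant else []
        planted: list[tuple[str, int, str]] = []
        spans: list[tuple[int, int]] = []
        for slot in slot_ids:
            motif = motifs[int(rng.integers(len(motifs)))]
            strand = "+" if rng.random() < 0.5 else "-"
            words = sorted(motif.expand())
            word = words[int(rng.integers(len(words)))]
            if strand == "-":
                word = reverse_complement(word)
            lo = slot * 2 * width_max
            hi = min((slot + 1) * 2 * width_max, config.promoter_length) - motif.width
            start = int(rng.integers(lo, hi + 1))
            seq[start:start + motif.width] = list(word)
            planted.append((motif.name, start, strand))
            spans.append((start, start + motif.width))
        s = "".join(seq)
        if clean_background:
            for _ in range(max_resample_rounds):
                accidental = _accidental_hits(s, motifs, spans)
                if not accidental:
                    break
                arr = np.array(list(s))
                for (a, b) in accidental:
                    for pos in range(a, b):
                        if any(p0 <= pos < p1 for p0, p1 in spans):
                            continue
                        arr[pos] = _random_background(rng, 1, config.gc_fraction)[0]
                s = "".join(arr)
            else:  # pragma: no cover - probabilistically unreachable
                raise RuntimeError(f"could not clean background for {gid}")
        sequences[gid] = s
        truth.planted[gid] = sorted(planted, key=lambda t: t[1])
    return PromoterSet(sequences)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    config: SimulationConfig,
    truth: SyntheticTruth,
    rates: dict[str, dict[str, float]] | None = None,
) -> GeneSetCollection:
    """Bernoulli-sample named gene sets with per-class inclusion rates.

    ``rates[set_name][class_label]`` is the probability that a gene of that
    class is a member. Membership is recorded in ``truth.memberships``; the
    universe is the full simulated gene list.
    """
    _, _, rng = _child_rngs(config.seed)
    rates = rates if rates is not None else DEFAULT_SET_RATES
    labels = truth.genes["class_label"]
    sets: dict[str, frozenset[str]] = {}
    for name, class_rates in rates.items():
        for label, r in class_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(
                    f"rate for set {name!r}, class {label!r} is {r}; "
                    "must lie in [0, 1]")
        p = labels.map(lambda l: class_rates.get(l, 0.0)).to_numpy(dtype=float)
        draw = rng.random(len(p)) < p
        members = frozenset(truth.genes.index[draw])
        if members:
            sets[name] = members
        truth.memberships[name] = members
    return GeneSetCollection(sets, frozenset(truth.genes.index))


def simulate_all(config: SimulationConfig):
    """Convenience: expression + design + promoters + gene sets + truth."""
    matrix, design, truth = simulate_expression(config)
    promoters = simulate_promoters(config, truth)
    gene_sets = simulate_gene_sets(config, truth)
    return matrix, design, promoters, gene_sets, truth
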