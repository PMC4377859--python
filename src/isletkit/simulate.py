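"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a five-model knockout-vs-control islet study: three
LKB1-null and two AMPK-null strains, each with replicated KO and WT
libraries.  Counts are beta-binomial draws around gene proportions taken
from a long-tailed (lognormal sigma=2) baseline; planted gene groups have
their KO proportions multiplied by a fold effect in the models whose kinase
group they affect, and some genes are absent from some models entirely
(all-zero, excluded from DE rather than treated as zero expression).

The ``dispersion`` parameter is the squared biological coefficient of
variation of a gene's relative abundance across replicates — the same
quantity the differential-expression dispersion estimator recovers — and is
mapped per gene to a beta intra-class correlation ``rho_g = phi * pi_g /
(1 - pi_g)`` so that relative replicate noise is constant across the
dynamic range.

Alongside counts the module generates gene sets (one per planted group plus
random null sets), a tissue expression atlas with known home classes, and
promoter TFBS hit tables with planted enriched factors, each with a
ground-truth record for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import PromoterHitTable, TissueAtlas
from .gsea import GeneSet
from .quantify import CountMatrix

__all__ = [
    "ModelSpec",
    "PlantedGroup",
    "SimulationConfig",
    "GroundTruth",
    "CountStudy",
    "default_config",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_atlas",
    "simulate_promoter_hits",
    "DEFAULT_TISSUE_CLASSES",
]

KINASE_GROUPS = ("LKB1", "AMPK")


@dataclass(frozen=True)
class ModelSpec:
    """One knockout-vs-control comparison (a Cre strain)."""

    name: str
    kinase: str
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.kinase not in KINASE_GROUPS:
            raise ValueError(f"kinase group must be one of {KINASE_GROUPS}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")


@dataclass(frozen=True)
class PlantedGroup:
    """A gene group up-regulated by a given fold in the affected models."""

    name: str
    n_genes: int
    fold_effect: float
    kinases: tuple

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("group size must be positive")
        if self.fold_effect <= 0:
            raise ValueError("fold effect must be positive")
        bad = set(self.kinases) - set(KINASE_GROUPS)
        if bad:
            raise ValueError(f"unknown kinase groups: {sorted(bad)}")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int
    models: tuple
    library_size: int = 1_000_000
    dispersion: float = 0.05
    planted_groups: tuple = ()
    absence_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.library_size < 1:
            raise ValueError("library_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0.0 <= self.absence_rate < 1.0:
            raise ValueError("absence_rate must lie in [0, 1)")
        if not self.models:
            raise ValueError("at least one model is required")
        if len({m.name for m in self.models}) != len(self.models):
            raise ValueError("model names must be unique")
        total = sum(g.n_genes for g in self.planted_groups)
        if total > self.n_genes:
            raise ValueError("planted group sizes exceed n_genes")
        if len({g.name for g in self.planted_groups}) != len(self.planted_groups):
            raise ValueError("planted group names must be unique")


@dataclass
class GroundTruth:
    """Planted truth per gene: fold change and absence per model, group label."""

    fold_changes: pd.DataFrame  # genes x models, true KO/WT fold
    absent: pd.DataFrame  # genes x models, bool
    groups: pd.Series  # gene -> group name ("" if unplanted)

    @property
    def genes(self) -> pd.Index:
        return self.fold_changes.index

    def group_members(self, name: str) -> list:
        return list(self.groups.index[self.groups == name])


@dataclass
class CountStudy:
    """Per-model count matrices sharing a gene universe and gene lengths."""

    models: dict
    lengths: pd.Series
    truth: GroundTruth | None = None

    @property
    def model_names(self) -> list:
        return list(self.models)

    def __getitem__(self, name: str) -> CountMatrix:
        return self.models[name]


#: five-strain preset mirroring a three-LKB1-null / two-AMPK-null design
DEFAULT_MODELS = (
    ModelSpec("Ins1LKB1KO", "LKB1"),
    ModelSpec("RIP2LKB1KO", "LKB1"),
    ModelSpec("Pdx1CreERLKB1KO", "LKB1"),
    ModelSpec("Ins1AMPKdKO", "AMPK"),
    ModelSpec("RIP2AMPKdKO", "AMPK"),
)

#: planted structure: neuronal and hepatic groups up in LKB1-null models,
#: disallowed genes up in AMPK-null models, and a strongly induced core
#: group shared by every model.
DEFAULT_GROUPS = (
    PlantedGroup("neuronal", 40, 3.0, ("LKB1",)),
    PlantedGroup("hepatic", 15, 3.0, ("LKB1",)),
    PlantedGroup("disallowed", 16, 2.5, ("AMPK",)),
    PlantedGroup("shared_core", 12, 4.0, ("LKB1", "AMPK")),
)

DEFAULT_TISSUE_CLASSES = (
    ("neuronal", ("cortex", "hippocampus", "cerebellum", "spinal_cord")),
    ("hepatic_intestinal", ("liver", "small_intestine")),
    ("other", ("kidney", "lung", "spleen", "muscle", "heart", "skin")),
)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The five-model study preset used throughout the examples and tests."""
    kwargs = dict(
        n_genes=2000,
        models=DEFAULT_MODELS,
        library_size=1_000_000,
        dispersion=0.05,
        planted_groups=DEFAULT_GROUPS,
        absence_rate=0.05,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _beta_binomial_column(
    rng: np.random.Generator, pi: np.ndarray, phi: float, library_size: int
) -> np.ndarray:
    """One replicate's counts: beta noise on proportions, then binomial."""
    p = pi
    if phi > 0:
        pos = pi > 0
        rho = np.clip(phi * pi[pos] / (1.0 - pi[pos]), 1e-12, 0.99)
        a = pi[pos] * (1.0 - rho) / rho
        b = (1.0 - pi[pos]) * (1.0 - rho) / rho
        p = np.zeros_like(pi)
        p[pos] = rng.beta(a, b)
    return rng.binomial(library_size, np.clip(p, 0.0, 1.0))


def simulate_counts(config: SimulationConfig) -> tuple[CountStudy, GroundTruth]:
    """Draw the full study: per-model replicated KO/WT count matrices.

    Identical seeds give identical output.  Per model, absent genes are
    all-zero and flagged; KO proportions of planted-group member genes are
    multiplied by the group fold effect when the group affects the model's
    kinase, then renormalized.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(G)], name="gene")
    lengths = pd.Series(
        np.maximum(200, np.round(rng.lognormal(7.3, 0.7, G))).astype(int),
        index=genes,
        name="length",
    )
    base = rng.lognormal(0.0, 2.0, G)
    pi_base = base / base.sum()

    groups = pd.Series("", index=genes)
    free = np.arange(G)
    rng.shuffle(free)
    cursor = 0
    for grp in config.planted_groups:
        idx = free[cursor : cursor + grp.n_genes]
        groups.iloc[idx] = grp.name
        cursor += grp.n_genes

    model_names = [m.name for m in config.models]
    fold = pd.DataFrame(1.0, index=genes, columns=model_names)
    absent = pd.DataFrame(False, index=genes, columns=model_names)
    matrices: dict = {}
    for model in config.models:
        for grp in config.planted_groups:
            if model.kinase in grp.kinases:
                fold.loc[groups == grp.name, model.name] = grp.fold_effect
        ab = rng.random(G) < config.absence_rate
        absent[model.name] = ab

        pi_wt = np.where(ab, 0.0, pi_base)
        pi_wt = pi_wt / pi_wt.sum()
        pi_ko = np.where(ab, 0.0, pi_base * fold[model.name].to_numpy())
        pi_ko = pi_ko / pi_ko.sum()

        cols, data, meta = [], [], []
        for cond, pi in (("WT", pi_wt), ("KO", pi_ko)):
            for r in range(model.n_replicates):
                cols.append(f"{model.name}:{cond}:{r + 1}")
                data.append(
                    _beta_binomial_column(rng, pi, config.dispersion, config.library_size)
                )
                meta.append((model.name, cond, r + 1))
        counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
        samples = pd.DataFrame(meta, index=cols, columns=["model", "condition", "replicate"])
        matrices[model.name] = CountMatrix(
            counts=counts,
            samples=samples,
            lengths=lengths,
            name=model.name,
            absent=pd.Series(ab, index=genes),
        )

    truth = GroundTruth(fold_changes=fold, absent=absent, groups=groups)
    return CountStudy(models=matrices, lengths=lengths, truth=truth), truth


def simulate_gene_sets(
    truth: GroundTruth,
    n_null_sets: int = 20,
    set_size_range: tuple = (10, 50),
    seed: int = 0,
) -> list:
    """One gene set per planted group plus random null sets.

    Null-set sizes are uniform on ``set_size_range`` (inclusive); members
    are sampled without replacement from the whole gene universe.
    """
    genes = list(truth.genes)
    if not genes:
        raise ValueError("ground truth is empty")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid set size range")
    if hi > len(genes):
        raise ValueError("set size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    sets: list = []
    for name in pd.unique(truth.groups[truth.groups != ""]):
        members = tuple(sorted(truth.group_members(name)))
        sets.append(GeneSet(name=name, description="planted group", members=members))
    width = max(4, len(str(max(n_null_sets, 1))))
    for i in range(n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(sorted(rng.choice(genes, size=size, replace=False)))
        sets.append(
            GeneSet(name=f"null_{i:0{width}d}", description="random gene set", members=members)
        )
    return sets


def simulate_atlas(
    truth: GroundTruth,
    tissue_classes=DEFAULT_TISSUE_CLASSES,
    enrichment_factor: float = 10.0,
    seed: int = 0,
    noise_sd: float = 0.5,
    group_to_class: dict | None = None,
) -> TissueAtlas:
    """Tissue expression atlas with known per-gene home classes.

    Expression in a gene's home-class tissues exceeds the rest by
    ``enrichment_factor`` on average, under lognormal noise of standard
    deviation ``noise_sd`` (0 turns noise off).  Planted groups are mapped
    to the class whose name contains the group's name (e.g. the planted
    hepatic group lands in hepatic_intestinal); other genes draw a random
    home class.
    """
    if enrichment_factor <= 1:
        raise ValueError("enrichment_factor must exceed 1")
    tissue_classes = list(tissue_classes)
    if len(tissue_classes) < 2:
        raise ValueError("at least 2 tissue classes are required")
    class_names = [c for c, _ in tissue_classes]
    tissue_class = pd.Series(
        {t: c for c, tissues in tissue_classes for t in tissues}, name="class"
    )
    if group_to_class is None:
        group_to_class = {}
        for g in pd.unique(truth.groups[truth.groups != ""]):
            match = [c for c in class_names if g in c or c in g]
            if match:
                group_to_class[g] = match[0]

    rng = np.random.default_rng(seed)
    genes = truth.genes
    home = pd.Series(rng.choice(class_names, size=len(genes)), index=genes)
    for g, cls in group_to_class.items():
        if cls not in class_names:
            raise ValueError(f"group {g!r} mapped to unknown class {cls!r}")
        home[truth.groups == g] = cls

    tissues = list(tissue_class.index)
    base = rng.lognormal(2.0, 1.0, len(genes))
    expr = np.empty((len(genes), len(tissues)))
    for j, t in enumerate(tissues):
        boost = np.where(home.to_numpy() == tissue_class[t], enrichment_factor, 1.0)
        noise = rng.lognormal(0.0, noise_sd, len(genes)) if noise_sd > 0 else 1.0
        expr[:, j] = base * boost * noise
    return TissueAtlas(
        expression=pd.DataFrame(expr, index=genes, columns=tissues),
        tissue_class=tissue_class,
        home_class=home,
    )


def simulate_promoter_hits(
    n_tfs: int,
    n_submitted: int,
    genome_promoters: int,
    planted=(),
    seed: int = 0,
) -> PromoterHitTable:
    """Per-TF genome-wide and submitted-region motif hit counts.

    Genome hit counts K are drawn from a broad lognormal; submitted-region
    hits are Poisson with expectation ``n_submitted * K / G`` times the
    planted rate multiplier (1 for unplanted TFs).
    """
    if n_tfs < 1:
        raise ValueError("n_tfs must be positive")
    if genome_promoters <= 0 or n_submitted <= 0 or n_submitted > genome_promoters:
        raise ValueError("need 0 < n_submitted <= genome_promoters")
    planted = list(planted)
    for name, mult in planted:
        if mult <= 0:
            raise ValueError(f"rate multiplier for {name!r} must be positive")
    if len(planted) > n_tfs:
        raise ValueError("more planted TFs than TFs")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_tfs)))
    names = [name for name, _ in planted]
    names += [f"TF_{i:0{width}d}" for i in range(n_tfs - len(planted))]
    mult = np.ones(n_tfs)
    mult[: len(planted)] = [m for _, m in planted]

    K = np.maximum(1, np.round(rng.lognormal(np.log(8000.0), 1.0, n_tfs))).astype(int)
    mu = n_submitted * K / genome_promoters * mult
    k = rng.poisson(mu)
    hits = pd.DataFrame({"tf": names, "hits_submitted": k, "hits_genome": K})
    return PromoterHitTable(
        hits=hits, n_submitted=n_submitted, genome_promoters=genome_promoters
    )
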