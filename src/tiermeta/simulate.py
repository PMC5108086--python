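"""Synthetic multi-study, multi-disease expression data with planted pathway effects.

The generator emulates the statistical structure the three-tier analysis
assumes: several case/control studies per disease condition, partially
overlapping gene universes across studies (platform emulation via whole-gene
dropout), differential expression concentrated in designated "shared"
pathways across a configurable subset of diseases, per-disease background
differential expression outside those pathways, and an unlabeled healthy
cohort used to build permutation null distributions.

Expression is generated directly on the log-intensity scale: per-gene
baselines ``mu_g`` are drawn once and shared by every study, and samples are
i.i.d. ``Normal(mu_g, noise_sd^2)``.  Case samples of an affected disease
receive an additive shift of ``delta * noise_sd`` on a planted pathway's
genes, so ``delta`` is an effect size in baseline-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CASE, CONTROL, ExpressionStudy, GeneSetCollection

__all__ = [
    "PlantedPathway",
    "SimulationConfig",
    "generate_collection",
    "generate_disease_studies",
    "generate_null_cohort",
    "planted_config",
]

_BASELINE_MEAN = 8.0
_BASELINE_SD = 1.5  # spread of per-gene baselines mu_g, in log2 units


@dataclass(frozen=True)
class PlantedPathway:
    """A pathway carrying a true case/control effect in selected diseases."""

    pathway: str
    diseases: tuple[str, ...]
    effect: float  # delta, in units of noise_sd


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the planted-recovery scenario used throughout the test
    suite: 8 diseases x 3 studies x 20 samples per group (120 samples per
    disease, comfortably above the 30-sample floor real disease cohorts were
    required to meet), 2000 genes, 40 pathways of 10-30 genes.
    """

    n_diseases: int = 8
    studies_per_disease: int = 3
    samples_per_group: int = 20
    n_genes: int = 2000
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (10, 30)
    planted_pathways: tuple[PlantedPathway, ...] = ()
    background_de_fraction: float = 0.02
    gene_dropout_fraction: float = 0.10
    noise_sd: float = 1.0
    na_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid pathway_size_range {self.pathway_size_range}")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        for name, frac in [
            ("background_de_fraction", self.background_de_fraction),
            ("gene_dropout_fraction", self.gene_dropout_fraction),
            ("na_fraction", self.na_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        per_disease = 2 * self.samples_per_group * self.studies_per_disease
        if per_disease < 30:
            raise ValueError(
                f"only {per_disease} samples per disease; at least 30 are required"
            )

    @property
    def disease_ids(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_diseases)]

    @property
    def pathway_names(self) -> list[str]:
        return [f"PW{i + 1:02d}" for i in range(self.n_pathways)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


def planted_config(
    n_affected: int = 6,
    effect: float = 1.0,
    pathway: str = "PW01",
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Convenience config with one pathway planted in the first ``n_affected`` diseases."""
    cfg = SimulationConfig(seed=seed, **overrides)
    if n_affected > cfg.n_diseases:
        raise ValueError("n_affected exceeds n_diseases")
    planted = PlantedPathway(
        pathway=pathway, diseases=tuple(cfg.disease_ids[:n_affected]), effect=effect
    )
    return replace(cfg, planted_pathways=(planted,))


def generate_collection(config: SimulationConfig) -> GeneSetCollection:
    """Draw ``n_pathways`` random gene subsets as the pathway collection.

    Subsets are drawn independently, so pairwise overlaps can occur just as
    MSigDB pathways share genes.  Deterministic under ``config.seed``.
    """
    lo, hi = config.pathway_size_range
    if hi > config.n_genes:
        raise ValueError(
            f"pathway size up to {hi} requested but only {config.n_genes} genes exist"
        )
    rng = np.random.default_rng([config.seed, 1])
    genes = np.array(config.gene_ids)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for name in config.pathway_names:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[name] = (f"synthetic pathway {name}", frozenset(members.tolist()))
    return GeneSetCollection(sets=sets)


def _planted_shift(
    config: SimulationConfig,
    collection: GeneSetCollection,
    disease_id: str,
    gene_index: dict[str, int],
) -> np.ndarray:
    shift = np.zeros(config.n_genes)
    for planted in config.planted_pathways:
        if planted.pathway not in collection:
            raise ValueError(f"planted pathway {planted.pathway!r} not in collection")
        if disease_id in planted.diseases:
            for g in collection.genes(planted.pathway):
                shift[gene_index[g]] += planted.effect * config.noise_sd
    return shift


def generate_disease_studies(
    config: SimulationConfig, collection: GeneSetCollection
) -> list[ExpressionStudy]:
    """Generate every study of every disease under ``config``.

    Per disease, ``background_de_fraction`` of the genes *outside* all
    planted pathways get a disease-specific shift of random sign and
    magnitude drawn uniformly in ``[0.5, 1.5] * noise_sd`` (kept disjoint
    from planted pathways so recovery tests are unambiguous).  Per study,
    ``gene_dropout_fraction`` of gene rows are removed to emulate platform
    differences, and ``na_fraction`` of remaining cells are set missing.
    """
    rng = np.random.default_rng([config.seed, 2])
    gene_index = {g: i for i, g in enumerate(config.gene_ids)}
    mu = _BASELINE_MEAN + _BASELINE_SD * rng.standard_normal(config.n_genes)

    planted_genes: set[str] = set()
    for planted in config.planted_pathways:
        if planted.pathway not in collection:
            raise ValueError(f"planted pathway {planted.pathway!r} not in collection")
        planted_genes |= set(collection.genes(planted.pathway))
    free = np.array([i for g, i in gene_index.items() if g not in planted_genes])

    n_samples = 2 * config.samples_per_group
    labels = [CASE] * config.samples_per_group + [CONTROL] * config.samples_per_group
    case_cols = np.arange(config.samples_per_group)

    studies: list[ExpressionStudy] = []
    for disease_id in config.disease_ids:
        shift = _planted_shift(config, collection, disease_id, gene_index)
        n_bg = int(round(config.background_de_fraction * free.size))
        if n_bg:
            bg = rng.choice(free, size=n_bg, replace=False)
            mag = rng.uniform(0.5, 1.5, size=n_bg) * config.noise_sd
            sign = rng.choice([-1.0, 1.0], size=n_bg)
            shift[bg] += sign * mag
        for s in range(config.studies_per_disease):
            study_id = f"{disease_id}_S{s + 1}"
            keep = np.ones(config.n_genes, dtype=bool)
            n_drop = int(round(config.gene_dropout_fraction * config.n_genes))
            if n_drop:
                keep[rng.choice(config.n_genes, size=n_drop, replace=False)] = False
            values = mu[:, None] + config.noise_sd * rng.standard_normal(
                (config.n_genes, n_samples)
            )
            values[:, case_cols] += shift[:, None]
            values = values[keep]
            if config.na_fraction > 0:
                na = rng.random(values.shape) < config.na_fraction
                values[na] = np.nan
            genes = [g for g, k in zip(config.gene_ids, keep) if k]
            studies.append(
                ExpressionStudy(
                    study_id=study_id,
                    disease_id=disease_id,
                    genes=genes,
                    samples=[f"{study_id}_{lab}{i}" for i, lab in enumerate(labels)],
                    values=values,
                    labels=list(labels),
                )
            )
    return studies


def generate_null_cohort(
    n_samples: int = 109,
    n_genes: int = 2000,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> ExpressionStudy:
    """Unlabeled healthy cohort: i.i.d. Normal expression, no planted effects.

    The 109-sample default matches the size of the blood cohort of healthy
    individuals used to build the permutation null distributions.
    """
    if n_samples < 4:
        raise ValueError("null cohort needs at least 4 samples")
    rng = np.random.default_rng([seed, 3])
    mu = _BASELINE_MEAN + _BASELINE_SD * rng.standard_normal(n_genes)
    values = mu[:, None] + noise_sd * rng.standard_normal((n_genes, n_samples))
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    return ExpressionStudy(
        study_id="NULLCOHORT",
        disease_id="healthy",
        genes=genes,
        samples=[f"H{i + 1}" for i in range(n_samples)],
        values=values,
        labels=None,
    )
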