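"""End-to-end orchestration: simulate -> DE -> gene tier -> pathway tier ->
disease tier -> permutation-null calibration -> QQ diagnostics.

:func:`run_tiers` is the in-memory core (studies + collection in, tiered
result tables out); :func:`run_all` wraps it with simulation, file output,
per-stage logging, and a manifest of content hashes so runs are fully
reproducible under ``(config, seed)``.  Each randomized stage draws from
its own substream of the global seed, so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import bayes, classify, diffexpr, enrichment, meta_diseases, meta_genes, qq
from .io import (
    ExpressionStudy,
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_manifest,
)
from .simulate import PlantedPathway, SimulationConfig, generate_disease_studies, \
    generate_collection, generate_null_cohort

logger = logging.getLogger(__name__)

# substream tags: global seed -> per-stage independent RNG streams
_STAGE_SUBSTREAM = {"null_runs": 11, "classify": 12, "random_sets": 13}


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their standard defaults."""

    alpha: float = 0.05
    corr_threshold: float = 0.30
    set_size_range: tuple[int, int] = (10, 300)
    correction: str = "by"
    combine_policy: str = "include_ones"
    null_runs: int = 100
    cv_folds: int = 3
    classifiers: tuple[str, ...] = classify.CLASSIFIERS
    n_random: int = 100
    index_disease: str = "D1"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in meta_genes.CORRECTIONS:
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.combine_policy not in meta_diseases.POLICIES:
            raise ValueError(f"unknown combine policy {self.combine_policy!r}")
        if not self.index_disease:
            raise ValueError("index_disease must be set")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["simulation"]["planted_pathways"] = [
            dataclasses.asdict(p) if dataclasses.is_dataclass(p) else dict(p)
            for p in self.simulation.planted_pathways
        ]
        Path(path).write_text(yaml.safe_dump(_listify(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        planted = tuple(
            PlantedPathway(
                pathway=p["pathway"],
                diseases=tuple(p["diseases"]),
                effect=float(p["effect"]),
            )
            for p in sim.pop("planted_pathways", [])
        )
        if "pathway_size_range" in sim:
            sim["pathway_size_range"] = tuple(sim["pathway_size_range"])
        sim_cfg = SimulationConfig(planted_pathways=planted, **sim)
        if "set_size_range" in d:
            d["set_size_range"] = tuple(d["set_size_range"])
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(simulation=sim_cfg, **d)


def _listify(obj):
    """yaml-safe copy: tuples -> lists, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class TierResults:
    """In-memory results of the three analysis tiers."""

    de_tables: dict[str, pd.DataFrame]  # study_id -> moderated-t table
    gene_meta: dict[str, pd.DataFrame]  # disease_id -> gene-tier table
    gene_diagnostics: dict[str, pd.DataFrame]
    sig_genes: dict[str, frozenset[str]]  # disease_id -> selected genes
    universes: dict[str, frozenset[str]]  # disease_id -> measured-gene universe
    enrich_tables: dict[str, pd.DataFrame]  # disease_id -> pathway-tier table
    pathway_p: pd.DataFrame  # pathways x diseases wide table
    shared: pd.DataFrame  # tier-3 table after Bonferroni + index gate
    combined: pd.DataFrame  # tier-3 table before the index gate
    disease_diagnostics: pd.DataFrame


def run_tiers(
    studies: list[ExpressionStudy],
    collection: GeneSetCollection,
    correction: str = "by",
    alpha: float = 0.05,
    combine_policy: str = "include_ones",
    index_disease: str | None = None,
    set_size_range: tuple[int, int] = (10, 300),
    filter_sets: bool = True,
) -> TierResults:
    """Run the gene, pathway, and disease tiers on prepared studies."""
    if filter_sets:
        collection = enrichment.filter_collection(collection, *set_size_range)

    de_tables: dict[str, pd.DataFrame] = {}
    by_disease: dict[str, dict[str, pd.DataFrame]] = {}
    for study in studies:
        pre = diffexpr.preprocess(study)
        de = diffexpr.fit_moderated_t(pre)
        de_tables[study.study_id] = de
        by_disease.setdefault(study.disease_id, {})[study.study_id] = de

    gene_meta, gene_diag, sig_genes, universes, enrich_tables = {}, {}, {}, {}, {}
    for disease_id, tables in by_disease.items():
        meta, diag = meta_genes.combine_disease_genes(tables, disease_id)
        gene_meta[disease_id] = meta
        gene_diag[disease_id] = diag
        sig = meta_genes.select_significant(meta, correction=correction, alpha=alpha)
        universe = frozenset(meta["gene"])
        sig_genes[disease_id] = sig
        universes[disease_id] = universe
        enrich_tables[disease_id] = enrichment.enrich_disease(
            sig, universe, collection, disease_id=disease_id
        )

    pathway_p = pd.DataFrame(
        {d: t.set_index("pathway")["p"] for d, t in enrich_tables.items()}
    )
    combined, disease_diag = meta_diseases.combine_across_diseases(
        pathway_p, policy=combine_policy
    )
    combined = meta_diseases.bonferroni_family(combined, alpha=alpha)
    if index_disease is None:
        index_disease = next(iter(by_disease))
    shared = meta_diseases.filter_by_index_disease(combined, index_disease, alpha=alpha)
    return TierResults(
        de_tables=de_tables,
        gene_meta=gene_meta,
        gene_diagnostics=gene_diag,
        sig_genes=sig_genes,
        universes=universes,
        enrich_tables=enrich_tables,
        pathway_p=pathway_p,
        shared=shared,
        combined=combined,
        disease_diagnostics=disease_diag,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage, write all tables under ``out_dir``, return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if config.index_disease not in sim.disease_ids:
        raise ValueError(
            f"index disease {config.index_disease!r} not among {sim.disease_ids}"
        )
    written: list[Path] = []

    def save(df: pd.DataFrame, rel: str, index: bool = False) -> Path:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=index, na_rep="NA")
        written.append(path)
        return path

    logger.info("stage simulate: %s", sim)
    collection = generate_collection(sim)
    studies = generate_disease_studies(sim, collection)
    cohort = generate_null_cohort(
        n_genes=sim.n_genes, seed=sim.seed, noise_sd=sim.noise_sd
    )
    gmt_path = out / "collection.gmt"
    write_gmt(collection, gmt_path)
    written.append(gmt_path)
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    rows = []
    for study in studies:
        mp = data_dir / f"{study.study_id}.expr.tsv"
        pp = data_dir / f"{study.study_id}.pheno.tsv"
        write_expression(study, mp, pp)
        written += [mp, pp]
        rows.append(
            {
                "study_id": study.study_id,
                "disease_id": study.disease_id,
                # relative to the run directory, so manifests are relocatable
                "expression_path": str(mp.relative_to(out)),
                "phenotype_path": str(pp.relative_to(out)),
            }
        )
    write_manifest(pd.DataFrame(rows), out / "manifest.tsv")
    written.append(out / "manifest.tsv")
    write_expression(cohort, data_dir / "null_cohort.expr.tsv")
    written.append(data_dir / "null_cohort.expr.tsv")

    logger.info("stages de / combine-genes / enrich / combine-diseases")
    res = run_tiers(
        studies,
        collection,
        correction=config.correction,
        alpha=config.alpha,
        combine_policy=config.combine_policy,
        index_disease=config.index_disease,
        set_size_range=config.set_size_range,
    )
    for sid, de in res.de_tables.items():
        save(de, f"de/{sid}.tsv")
    for did, meta in res.gene_meta.items():
        save(meta, f"genes/{did}.tsv")
        save(res.gene_diagnostics[did], f"genes/{did}.correlations.tsv")
    for did, table in res.enrich_tables.items():
        save(table, f"enrich/{did}.tsv")
    save(res.disease_diagnostics, "disease_correlations.tsv")
    save(res.combined.reset_index(), "combined_pathways.tsv")
    save(res.shared.reset_index(), "shared_pathways.tsv")

    logger.info("stage posteriors: %d null runs", config.null_runs)
    filtered = enrichment.filter_collection(collection, *config.set_size_range)
    null_matrix = bayes.generate_null_distributions(
        cohort,
        filtered,
        R=config.null_runs,
        seed=int(np.random.SeedSequence([config.seed, _STAGE_SUBSTREAM["null_runs"]])
                 .generate_state(1)[0] % (2**31)),
        alpha=config.alpha,
    )
    save(null_matrix.runs, "null_matrix.tsv", index=True)
    priors = bayes.estimate_priors(null_matrix, alpha=config.alpha)
    save(priors.rename_axis("pathway").reset_index(), "priors.tsv")
    null_mean = bayes.average_null(null_matrix)
    disease_ids = sorted(res.enrich_tables)
    if not res.shared.empty:
        calib = bayes.calibrate_pathways(res.shared, disease_ids, priors)
    else:
        calib = pd.DataFrame(columns=bayes.CALIBRATION_COLUMNS)
    save(calib, "calibration.tsv")

    logger.info("stage qq")
    for did in disease_ids:
        series = qq.qq_uniform(res.pathway_p[did].dropna().to_numpy(), label=did)
        save(series.points, f"qq/{did}.uniform.tsv")
        combined_series = qq.qq_combined_with_null(
            res.pathway_p[did].dropna(), null_mean, label=did
        )
        pts = combined_series.points.copy()
        pts["inflation"] = combined_series.inflation
        save(pts, f"qq/{did}.with_null.tsv")

    manifest = {
        "config": _listify(dataclasses.asdict(config)),
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
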