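"""Readers, writers, and in-memory containers for the pipeline's file formats.

Formats handled here:

* GMT gene-set collections (tab-separated; ``name<TAB>description<TAB>gene...``
  per line), the de-facto standard used by MSigDB-style pathway collections.
* Expression matrices as TSV with a ``gene_id`` first column and one column
  per sample; empty cells and the literal ``NA`` are treated as missing.
* Phenotype tables as TSV with columns ``sample_id`` and ``group``
  (``case``/``control``, case-insensitive on read).
* Study manifests as TSV with columns ``study_id``, ``disease_id``,
  ``expression_path``, ``phenotype_path``; relative paths are resolved
  against the manifest's own directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
_VALID_GROUPS = frozenset({CASE, CONTROL})


@dataclass
class ExpressionStudy:
    """One case/control expression matrix with aligned sample labels.

    Parameters
    ----------
    study_id, disease_id
        Identifiers linking the study to its disease condition.
    genes, samples
        Ordered row and column identifiers of ``values``.
    values
        ``(len(genes), len(samples))`` float array of (log-)intensities;
        ``NaN`` marks missing cells.
    labels
        Per-sample group, ``"case"`` or ``"control"``, aligned 1:1 with
        ``samples``.  ``None`` marks an unlabeled cohort (used for the
        healthy null data set, which carries no phenotype).
    """

    study_id: str
    disease_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"study {self.study_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"study {self.study_id}: duplicate gene ids {dupes[:5]}")
        if self.labels is not None:
            if len(self.labels) != len(self.samples):
                raise ValueError(
                    f"study {self.study_id}: {len(self.labels)} labels for "
                    f"{len(self.samples)} samples"
                )
            bad = sorted(set(self.labels) - _VALID_GROUPS)
            if bad:
                raise ValueError(
                    f"study {self.study_id}: invalid group labels {bad}; "
                    f"expected {sorted(_VALID_GROUPS)}"
                )
            if not (CASE in self.labels and CONTROL in self.labels):
                raise ValueError(f"study {self.study_id}: both groups must be non-empty")

    @property
    def case_mask(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError(f"study {self.study_id} is unlabeled")
        return np.array([lab == CASE for lab in self.labels], dtype=bool)

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return len(self.samples) - self.n_case

    def with_values(self, genes: list[str], values: np.ndarray) -> "ExpressionStudy":
        """Copy of this study with a new gene axis (samples/labels unchanged)."""
        return ExpressionStudy(
            study_id=self.study_id,
            disease_id=self.disease_id,
            genes=list(genes),
            samples=list(self.samples),
            values=values,
            labels=None if self.labels is None else list(self.labels),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with their member-gene universe.

    ``sets`` maps each set name to a ``(description, frozenset_of_genes)``
    pair; ``universe`` is the union of all member genes.
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, (_, genes) in self.sets.items()}


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each non-empty line must have at least three tab-separated fields:
    name, description, and one or more member genes.  Duplicate genes
    within a line are removed with a logged warning; a duplicate set name
    is an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate gene(s) removed from set %s",
                    path, lineno, len(genes) - len(unique), name,
                )
            sets[name] = (desc, unique)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT, member genes in sorted order per line."""
    if len(collection) == 0:
        raise ValueError("refusing to write an empty gene-set collection")
    path = Path(path)
    with path.open("w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_expression(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    study_id: str,
    disease_id: str,
) -> ExpressionStudy:
    """Load one study from an expression-matrix TSV and a phenotype TSV.

    Samples must match 1:1 between the two files (order is taken from the
    matrix header); group labels are case-folded before validation.
    """
    mat = pd.read_csv(
        matrix_path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={0: str}
    )
    if mat.columns[0] != "gene_id":
        raise ValueError(f"{matrix_path}: first column must be 'gene_id', got {mat.columns[0]!r}")
    genes = mat["gene_id"].tolist()
    if len(set(genes)) != len(genes):
        dupes = mat["gene_id"][mat["gene_id"].duplicated()].unique()
        raise ValueError(f"{matrix_path}: duplicate gene_id values {list(dupes[:5])}")
    samples = [str(c) for c in mat.columns[1:]]
    values = mat.iloc[:, 1:].apply(pd.to_numeric).to_numpy(dtype=float)

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in pheno.columns:
            raise ValueError(f"{phenotype_path}: missing required column {col!r}")
    group_of = dict(zip(pheno["sample_id"], pheno["group"].str.casefold()))

    missing = [s for s in samples if s not in group_of]
    extra = [s for s in group_of if s not in set(samples)]
    if missing or extra:
        raise ValueError(
            f"sample mismatch between {matrix_path} and {phenotype_path}: "
            f"matrix-only={missing[:5]}, phenotype-only={extra[:5]}"
        )
    labels = [group_of[s] for s in samples]
    bad = sorted(set(labels) - _VALID_GROUPS)
    if bad:
        raise ValueError(f"{phenotype_path}: invalid group value(s) {bad}")
    return ExpressionStudy(
        study_id=study_id,
        disease_id=disease_id,
        genes=genes,
        samples=samples,
        values=values,
        labels=labels,
    )


def write_expression(
    study: ExpressionStudy,
    matrix_path: str | Path,
    phenotype_path: str | Path | None = None,
) -> None:
    """Write a study's matrix (and phenotype, if labeled) as TSV; NaN → ``NA``."""
    df = pd.DataFrame(study.values, columns=study.samples)
    df.insert(0, "gene_id", study.genes)
    df.to_csv(matrix_path, sep="\t", index=False, na_rep="NA")
    if phenotype_path is not None:
        if study.labels is None:
            raise ValueError(f"study {study.study_id} is unlabeled; no phenotype to write")
        pd.DataFrame({"sample_id": study.samples, "group": study.labels}).to_csv(
            phenotype_path, sep="\t", index=False
        )


MANIFEST_COLUMNS = ["study_id", "disease_id", "expression_path", "phenotype_path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a study manifest; paths are resolved relative to the manifest."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest column(s) {missing}")
    if df["study_id"].duplicated().any():
        dupes = df["study_id"][df["study_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate study_id values {dupes}")
    base = path.parent
    for col in ("expression_path", "phenotype_path"):
        df[col] = [str((base / p)) if not Path(p).is_absolute() else p for p in df[col]]
        for p in df[col]:
            if not Path(p).exists():
                raise FileNotFoundError(f"{path}: referenced file does not exist: {p}")
    return df[MANIFEST_COLUMNS]


def write_manifest(rows: pd.DataFrame | Iterable[Mapping[str, str]], path: str | Path) -> None:
    df = pd.DataFrame(rows)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing column(s) {missing}")
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def load_studies(manifest: pd.DataFrame) -> list[ExpressionStudy]:
    """Load every study referenced by a (resolved) manifest DataFrame."""
    return [
        read_expression(r.expression_path, r.phenotype_path, r.study_id, r.disease_id)
        for r in manifest.itertuples()
    ]
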