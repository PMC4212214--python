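"""Shared domain types and tab-separated I/O for the pipeline.

Everything the pipeline reads or writes is plain tab-separated text: an
expression matrix (gene_id + one column per sample), a sample-design table
(sample_id, tissue, hpe, replicate), a gene-annotation table and gene-set
lists.  Intensities are kept on the input absolute scale throughout — the
organ-identity cutoff (default 500) is defined on that scale, so no
re-normalisation is ever applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tissue",
    "Hormone",
    "SampleCondition",
    "ExpressionDataset",
    "GeneAnnotation",
    "GeneSet",
    "ROOT_HPE",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_gene_set",
    "write_gene_set",
]


class Tissue(str, Enum):
    """Sampled tissue: the rooting zone over time, leaves, or whole root."""

    STEM_BASE = "stem_base"
    LEAF_FRESH = "leaf_fresh"
    LEAF_WOUNDED = "leaf_wounded"
    ROOT = "root"


class Hormone(str, Enum):
    """Phytohormone category of an annotated gene (``none`` when absent)."""

    AUXIN = "auxin"
    ETHYLENE = "ethylene"
    JASMONATE = "jasmonate"
    ABSCISIC_ACID = "abscisic_acid"
    GIBBERELLIN = "gibberellin"
    CYTOKININ = "cytokinin"
    BRASSINOSTEROID = "brassinosteroid"
    SALICYLIC_ACID = "salicylic_acid"
    NONE = "none"


#: Conventional hpe tag for the root organ.  Leaf and root samples are organs,
#: not timepoints; comparisons involving them are keyed by tissue.  The tag
#: exists only so that (tissue, hpe, replicate) triples are well defined.
ROOT_HPE = -1.0

_CONVENTIONAL_HPE = {
    Tissue.LEAF_FRESH: 0.0,
    Tissue.LEAF_WOUNDED: 2.0,
    Tissue.ROOT: ROOT_HPE,
}


@dataclass(frozen=True, order=True)
class SampleCondition:
    """One array sample: tissue, hours post-excision and replicate index."""

    tissue: Tissue
    hpe: float
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")
        if self.tissue is Tissue.STEM_BASE and self.hpe < 0:
            raise ValueError(f"stem_base hpe must be non-negative, got {self.hpe}")

    @property
    def condition(self) -> tuple[Tissue, float]:
        return (self.tissue, self.hpe)

    @property
    def sample_id(self) -> str:
        return f"{self.tissue.value}_{self.hpe:g}_r{self.replicate}"

    @classmethod
    def conventional(cls, tissue: Tissue, replicate: int, hpe: float | None = None) -> "SampleCondition":
        """Build a condition using the bookkeeping hpe tag for non-stem organs."""
        if hpe is None:
            hpe = _CONVENTIONAL_HPE.get(tissue, 0.0)
        return cls(tissue, float(hpe), replicate)


@dataclass
class ExpressionDataset:
    """Genes x samples matrix of normalised intensities plus sample design.

    Invariants enforced on construction: unique gene ids, matrix shape
    matching the design, strictly finite non-negative intensities, unique
    (tissue, hpe, replicate) triples, and at least two replicates per
    condition.
    """

    gene_ids: list[str]
    values: np.ndarray
    design: list[SampleCondition]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_samples != len(self.design):
            raise ValueError(
                f"matrix has {n_samples} columns but design lists {len(self.design)} samples"
            )
        seen: dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            if g in seen:
                raise ValueError(f"duplicate gene id {g!r} (rows {seen[g]} and {i})")
            seen[g] = i
        bad = ~np.isfinite(self.values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite intensity at gene {self.gene_ids[r]!r}, "
                f"sample {self.design[c].sample_id!r}"
            )
        neg = self.values < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValueError(
                f"negative intensity {self.values[r, c]} at gene "
                f"{self.gene_ids[r]!r}, sample {self.design[c].sample_id!r}"
            )
        triples = [(s.tissue, s.hpe, s.replicate) for s in self.design]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (tissue, hpe, replicate) triples in design")
        for cond in self.conditions():
            if len(self.columns_for(*cond)) < 2:
                raise ValueError(
                    f"condition {cond[0].value}@{cond[1]:g} hpe has fewer than 2 replicates"
                )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- structure ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def conditions(self) -> list[tuple[Tissue, float]]:
        """Distinct (tissue, hpe) conditions in design order."""
        out: list[tuple[Tissue, float]] = []
        for s in self.design:
            if s.condition not in out:
                out.append(s.condition)
        return out

    def stem_timepoints(self) -> list[float]:
        return sorted({s.hpe for s in self.design if s.tissue is Tissue.STEM_BASE})

    def columns_for(self, tissue: Tissue, hpe: float | None = None) -> list[int]:
        if hpe is None:
            hpe = _CONVENTIONAL_HPE.get(tissue)
            if hpe is None:
                raise ValueError("hpe is required for stem_base samples")
        return [
            i
            for i, s in enumerate(self.design)
            if s.tissue is tissue and s.hpe == hpe
        ]

    def replicate_matrix(self, tissue: Tissue, hpe: float | None = None) -> np.ndarray:
        cols = self.columns_for(tissue, hpe)
        if not cols:
            raise ValueError(f"no samples for condition {tissue.value}@{hpe}")
        return self.values[:, cols]

    def condition_mean(self, tissue: Tissue, hpe: float | None = None) -> np.ndarray:
        """Arithmetic mean intensity per gene over the condition's replicates."""
        return self.replicate_matrix(tissue, hpe).mean(axis=1)


@dataclass
class GeneAnnotation:
    """Per-gene functional category and optional phytohormone category.

    Each gene maps to exactly one hierarchical category code (e.g. ``"Ib"``
    for storage, ``"VIa"`` for secondary metabolism).
    """

    table: pd.DataFrame  # index gene_id; columns category_code, category_name, hormone_category

    def __post_init__(self) -> None:
        required = {"category_code", "category_name", "hormone_category"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"gene {dup!r} annotated more than once")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def category_of(self, gene_id: str) -> str:
        return str(self.table.loc[gene_id, "category_code"])

    def category_sizes(self) -> pd.Series:
        return self.table["category_code"].value_counts()

    def genes_in_category(self, code: str) -> set[str]:
        return set(self.table.index[self.table["category_code"] == code])

    def hormone_sizes(self) -> pd.Series:
        tab = self.table[self.table["hormone_category"] != Hormone.NONE.value]
        return tab["hormone_category"].value_counts()

    def genes_in_hormone(self, hormone: str) -> set[str]:
        return set(self.table.index[self.table["hormone_category"] == hormone])


@dataclass(frozen=True)
class GeneSet:
    """A named gene collection with a provenance record of how it was made."""

    name: str
    gene_ids: frozenset[str]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def difference(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(
            name or f"{self.name}_minus_{other.name}",
            self.gene_ids - other.gene_ids,
            {"operation": "difference", "left": dict(self.provenance) | {"name": self.name},
             "right": dict(other.provenance) | {"name": other.name}},
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionDataset:
    """Read a tab-separated expression matrix together with its design table.

    The matrix has a header row of sample ids and a first column of gene ids;
    the design table has columns sample_id, tissue, hpe, replicate.  Column
    order of the returned matrix follows the design file.
    """
    design_df = pd.read_csv(design_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "tissue", "hpe", "replicate"}
    missing = required - set(design_df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    design: list[SampleCondition] = []
    for _, row in design_df.iterrows():
        try:
            tissue = Tissue(row["tissue"])
        except ValueError:
            raise ValueError(f"unknown tissue {row['tissue']!r} for sample {row['sample_id']!r}")
        design.append(SampleCondition(tissue, float(row["hpe"]), int(row["replicate"])))

    mat = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    mat.index = mat.index.astype(str)
    matrix_samples = list(mat.columns)
    design_samples = list(design_df["sample_id"])
    for s in design_samples:
        if s not in matrix_samples:
            raise ValueError(f"sample {s!r} listed in design but absent from matrix")
    for s in matrix_samples:
        if s not in design_samples:
            raise ValueError(f"sample {s!r} present in matrix but absent from design")
    mat = mat[design_samples]

    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in expression matrix")
    values = np.empty(mat.shape, dtype=float)
    for j, col in enumerate(mat.columns):
        converted = pd.to_numeric(mat[col], errors="coerce")
        bad = converted.isna() & mat[col].notna()
        if bad.any():
            g = mat.index[bad][0]
            raise ValueError(
                f"non-numeric intensity {mat.loc[g, col]!r} at gene {g!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionDataset(list(mat.index), values, design)


def write_expression(ds: ExpressionDataset, path: str | Path, design_path: str | Path) -> None:
    sample_ids = [s.sample_id for s in ds.design]
    frame = pd.DataFrame(ds.values, index=pd.Index(ds.gene_ids, name="gene_id"), columns=sample_ids)
    frame.to_csv(path, sep="\t", float_format="%.10g")
    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": [s.tissue.value for s in ds.design],
            "hpe": [s.hpe for s in ds.design],
            "replicate": [s.replicate for s in ds.design],
        }
    )
    design.to_csv(design_path, sep="\t", index=False)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a gene annotation table (gene_id, category_code, category_name,
    hormone_category).  Exact duplicate rows are dropped; conflicting
    annotations for one gene are a hard error, as is an unknown hormone."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(Hormone.NONE.value)
    required = {"gene_id", "category_code", "category_name", "hormone_category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    valid_hormones = {h.value for h in Hormone}
    bad = ~df["hormone_category"].isin(valid_hormones)
    if bad.any():
        val = df.loc[bad, "hormone_category"].iloc[0]
        raise ValueError(f"unknown hormone_category {val!r}")
    df = df.drop_duplicates()
    dup = df["gene_id"].duplicated()
    if dup.any():
        g = df.loc[dup, "gene_id"].iloc[0]
        raise ValueError(f"gene {g!r} annotated twice with different categories")
    return GeneAnnotation(df.set_index("gene_id"))


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="gene_id")


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """One gene per line; name and provenance in JSON-encoded header comments."""
    with open(path, "w") as fh:
        fh.write(f"# name={json.dumps(gene_set.name)}\n")
        fh.write(f"# provenance={json.dumps(dict(gene_set.provenance), sort_keys=True)}\n")
        for g in sorted(gene_set.gene_ids):
            fh.write(g + "\n")


def read_gene_set(path: str | Path) -> GeneSet:
    name = Path(path).stem
    provenance: dict[str, object] = {}
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# name="):
                name = json.loads(line[len("# name="):])
            elif line.startswith("# provenance="):
                provenance = json.loads(line[len("# provenance="):])
            elif line and not line.startswith("#"):
                genes.append(line)
    return GeneSet(name, frozenset(genes), provenance)
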