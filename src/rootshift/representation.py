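"""Functional-category over/under-representation and hormone time courses.

For each category and regulation direction the representation ratio is

    (n_xp / n_xt) / (n_ap / n_at)

with n_xp the regulated genes of the category, n_xt all genes of the
category, n_ap all regulated genes (same direction) and n_at all genes.
A ratio of 1 means the category is regulated exactly in proportion to its
size; a category is flagged over-represented when the ratio reaches the
fold criterion (default 2, i.e. |log2 ratio| >= 1) and under-represented at
its reciprocal.  Categories smaller than a minimum size are excluded as too
small for a reliable estimate.  The same machinery applied to phytohormone
categories across all timepoint comparisons yields the hormone time-course
profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneAnnotation, Hormone

__all__ = [
    "RepresentationInput",
    "representation_ratio",
    "category_profile",
    "hormone_timecourse",
    "write_representation",
]

DEFAULT_MIN_CATEGORY_SIZE = 10
DEFAULT_FOLD_CRITERION = 2.0


@dataclass(frozen=True)
class RepresentationInput:
    """The four counts entering the representation formula."""

    n_xp: int  # regulated genes in the category (one direction)
    n_xt: int  # all genes in the category
    n_ap: int  # all regulated genes (same direction)
    n_at: int  # all genes

    def __post_init__(self) -> None:
        if self.n_at <= 0:
            raise ValueError("n_at (total gene count) must be positive")
        if not 0 <= self.n_xp <= min(self.n_xt, self.n_ap):
            raise ValueError("n_xp must lie in [0, min(n_xt, n_ap)]")
        if self.n_xt > self.n_at:
            raise ValueError("category cannot be larger than the gene universe")
        if self.n_ap > self.n_at:
            raise ValueError("regulated genes cannot outnumber the gene universe")


def representation_ratio(counts: RepresentationInput) -> float:
    """(n_xp/n_xt) / (n_ap/n_at): observed over expected regulated fraction."""
    if counts.n_xt == 0:
        raise ValueError("n_xt is zero: empty category has no representation ratio")
    if counts.n_ap == 0:
        raise ValueError("n_ap is zero: no regulated genes to compare against")
    return (counts.n_xp / counts.n_xt) / (counts.n_ap / counts.n_at)


def _profile_rows(
    de: pd.DataFrame,
    groups: dict[str, set[str]],
    group_col: str,
    universe: set[str],
    min_category_size: int,
    fold_criterion: float,
) -> pd.DataFrame:
    calls = de.set_index("gene_id")["call"]
    calls = calls[calls.index.isin(universe)]
    n_at = len(universe)
    rows = []
    for direction in ("up", "down"):
        regulated = set(calls.index[calls == direction])
        n_ap = len(regulated)
        for code in sorted(groups):
            members = groups[code] & universe
            n_xt = len(members)
            n_xp = len(members & regulated)
            excluded = ""
            ratio = math.nan
            m = math.nan
            flag = "none"
            if n_xt < min_category_size:
                excluded = f"category size {n_xt} below minimum {min_category_size}"
            elif n_ap == 0:
                excluded = f"no {direction}-regulated genes in this comparison"
            else:
                ratio = representation_ratio(
                    RepresentationInput(n_xp=n_xp, n_xt=n_xt, n_ap=n_ap, n_at=n_at)
                )
                m = math.log2(ratio) if ratio > 0 else -math.inf
                if ratio >= fold_criterion:
                    flag = "over"
                elif ratio <= 1.0 / fold_criterion:
                    flag = "under"
            rows.append(
                {
                    group_col: code,
                    "direction": direction,
                    "n_xp": n_xp,
                    "n_xt": n_xt,
                    "n_ap": n_ap,
                    "n_at": n_at,
                    "ratio": ratio,
                    "m": m,
                    "flag": flag,
                    "excluded": bool(excluded),
                    "exclusion_reason": excluded,
                }
            )
    return pd.DataFrame(rows)


def category_profile(
    de: pd.DataFrame,
    annotation: GeneAnnotation,
    min_category_size: int = DEFAULT_MIN_CATEGORY_SIZE,
    fold_criterion: float = DEFAULT_FOLD_CRITERION,
    annotated_only: bool = False,
) -> pd.DataFrame:
    """Representation of every functional category in one comparison.

    One row per (category, direction).  By default unannotated genes still
    count toward the totals n_at and n_ap (they are genes and can be
    regulated); ``annotated_only`` restricts the universe to annotated
    genes.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    if fold_criterion <= 1:
        raise ValueError("fold_criterion must exceed 1")
    universe = set(de["gene_id"])
    if annotated_only:
        universe &= set(annotation.gene_ids)
    groups = {
        code: annotation.genes_in_category(code)
        for code in annotation.table["category_code"].unique()
    }
    return _profile_rows(de, groups, "category_code", universe, min_category_size, fold_criterion)


def hormone_timecourse(
    de_tables: dict[str, pd.DataFrame],
    annotation: GeneAnnotation,
    min_category_size: int = DEFAULT_MIN_CATEGORY_SIZE,
    fold_criterion: float = DEFAULT_FOLD_CRITERION,
    annotated_only: bool = False,
) -> pd.DataFrame:
    """Per-hormone representation across a series of comparisons.

    ``de_tables`` maps comparison labels (timepoints vs baseline, root vs
    stem base) to DE tables; the result has one row per (hormone category,
    comparison, direction) with the representation counts, log2 M-value and
    over/under flag, small categories marked excluded throughout.
    """
    hormones = [h.value for h in Hormone if h is not Hormone.NONE]
    groups = {h: annotation.genes_in_hormone(h) for h in hormones}
    groups = {h: g for h, g in groups.items() if g}
    if not groups:
        raise ValueError("annotation carries no hormone categories")
    frames = []
    for label, de in de_tables.items():
        universe = set(de["gene_id"])
        if annotated_only:
            universe &= set(annotation.gene_ids)
        rows = _profile_rows(
            de, groups, "hormone", universe, min_category_size, fold_criterion
        )
        rows.insert(1, "comparison", label)
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


def write_representation(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
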