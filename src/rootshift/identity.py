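"""Wound subtraction, organ-identity gene sets and the identity-shift table.

During adventitious rooting the excised stem base progressively loses
stem-base character and acquires root character.  This module quantifies
that transition: genes regulated by leaf wounding are subtracted from the
stem-base response to isolate rooting-specific regulation, organ-identity
gene sets (stem-base-specific, root-specific) are built from the three-organ
comparison, and their repression/induction is counted against an absolute
intensity cutoff (default 500) at every timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .de import Comparison, DEThresholds, compare_conditions
from .io import ROOT_HPE, ExpressionDataset, GeneSet, Tissue
from .rankprod import RPConfig

__all__ = [
    "IdentityConfig",
    "wound_regulated_genes",
    "subtract_wound",
    "organ_specific_genes",
    "identity_shift_table",
    "largest_shift_interval",
    "write_shift_table",
]


@dataclass(frozen=True)
class IdentityConfig:
    """Cutoff on the absolute intensity scale separating expressed from not."""

    expression_cutoff: float = 500.0
    thresholds: DEThresholds = field(default_factory=DEThresholds)

    def __post_init__(self) -> None:
        if self.expression_cutoff <= 0:
            raise ValueError("expression_cutoff must be positive")


def _called_genes(de: pd.DataFrame, calls: tuple[str, ...]) -> frozenset[str]:
    return frozenset(de.loc[de["call"].isin(calls), "gene_id"])


def wound_regulated_genes(de_leaf: pd.DataFrame, thresholds: DEThresholds | None = None) -> GeneSet:
    """Genes up- or down-regulated in wounded vs fresh leaves.

    ``de_leaf`` must be the DE table of the leaf comparison; its calls were
    already made under some thresholds, recorded in the provenance.
    """
    if de_leaf.empty:
        raise ValueError("leaf comparison DE table is empty")
    comparison = str(de_leaf["comparison"].iloc[0])
    prov: dict[str, object] = {"comparison": comparison}
    if thresholds is not None:
        prov |= {"m_cut": thresholds.m_cut, "p_cut": thresholds.p_cut,
                 "threshold_on": thresholds.threshold_on}
    return GeneSet("wound_regulated", _called_genes(de_leaf, ("up", "down")), prov)


def subtract_wound(ar_set: GeneSet, wound_set: GeneSet) -> GeneSet:
    """Set difference ar_set \\ wound_set, provenance chaining both parents."""
    return ar_set.difference(wound_set, name=f"{ar_set.name}_minus_wound")


_ORGAN_CONDITIONS: dict[Tissue, float] = {
    Tissue.STEM_BASE: 0.0,
    Tissue.LEAF_FRESH: 0.0,
    Tissue.ROOT: ROOT_HPE,
}


def organ_specific_genes(
    ds: ExpressionDataset,
    organ: Tissue,
    thresholds: DEThresholds = DEThresholds(),
    cutoff: float = 500.0,
    rp_config: RPConfig = RPConfig(),
) -> GeneSet:
    """Genes expressed specifically in one organ.

    A gene is organ-specific when it is significantly higher (per the joint
    M / rank-product rule) in the focal organ than in *each* of the other
    two organs, and its mean intensity in the focal organ exceeds the
    absolute cutoff.  Organs compared: stem base at 0 hpe, fresh leaf, and
    the developed root.
    """
    if organ not in _ORGAN_CONDITIONS:
        raise ValueError(f"{organ} is not one of the compared organs")
    for tissue, hpe in _ORGAN_CONDITIONS.items():
        if not ds.columns_for(tissue, hpe):
            raise ValueError(f"missing organ condition {tissue.value}@{hpe:g}")
    focal_hpe = _ORGAN_CONDITIONS[organ]
    keep = frozenset(ds.gene_ids)
    for other, other_hpe in _ORGAN_CONDITIONS.items():
        if other is organ:
            continue
        comp = Comparison(
            f"{organ.value}_vs_{other.value}", organ, focal_hpe, other, other_hpe
        )
        de = compare_conditions(ds, comp, rp_config, thresholds)
        keep &= _called_genes(de, ("up",))
    focal_mean = ds.condition_mean(organ, focal_hpe)
    expressed = frozenset(
        g for g, m in zip(ds.gene_ids, focal_mean) if m > cutoff
    )
    return GeneSet(
        f"{organ.value}_identity",
        keep & expressed,
        {
            "rule": "higher than each other organ and mean above cutoff",
            "cutoff": cutoff,
            "m_cut": thresholds.m_cut,
            "p_cut": thresholds.p_cut,
            "threshold_on": thresholds.threshold_on,
        },
    )


def identity_shift_table(
    ds: ExpressionDataset,
    stem_set: GeneSet,
    root_set: GeneSet,
    wound_set: GeneSet,
    de_by_timepoint: dict[float, pd.DataFrame],
    config: IdentityConfig = IdentityConfig(),
) -> pd.DataFrame:
    """Per-timepoint counts of rooting-regulated and identity genes.

    For each stem-base timepoint t > 0: the number of genes regulated
    against the 0 hpe baseline (all, and after wound subtraction), the
    number of stem-identity genes whose mean intensity at t has fallen below
    the cutoff, and the number of root-identity genes whose mean at t has
    risen above it.
    """
    cutoff = config.expression_cutoff
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    stem_idx = np.array([gene_index[g] for g in sorted(stem_set.gene_ids)], dtype=int)
    root_idx = np.array([gene_index[g] for g in sorted(root_set.gene_ids)], dtype=int)
    rows = []
    for t in sorted(de_by_timepoint):
        de = de_by_timepoint[t]
        regulated = _called_genes(de, ("up", "down"))
        mean_t = ds.condition_mean(Tissue.STEM_BASE, t)
        rows.append(
            {
                "hpe": t,
                "n_ar_regulated": len(regulated),
                "n_ar_regulated_minus_wound": len(regulated - wound_set.gene_ids),
                "n_stem_genes_repressed": int((mean_t[stem_idx] < cutoff).sum())
                if len(stem_idx)
                else 0,
                "n_root_genes_expressed": int((mean_t[root_idx] > cutoff).sum())
                if len(root_idx)
                else 0,
            }
        )
    return pd.DataFrame(rows)


def largest_shift_interval(table: pd.DataFrame) -> tuple[float, float]:
    """Consecutive timepoint pair with the largest identity shift.

    The shift of an interval is |change in repressed stem-identity count| +
    |change in induced root-identity count|; ties resolve to the earlier
    interval.
    """
    if len(table) < 2:
        raise ValueError("need at least two timepoints to locate a shift interval")
    tab = table.sort_values("hpe").reset_index(drop=True)
    best: tuple[float, float] | None = None
    best_shift = -1.0
    for i in range(len(tab) - 1):
        shift = abs(
            tab.loc[i + 1, "n_stem_genes_repressed"] - tab.loc[i, "n_stem_genes_repressed"]
        ) + abs(
            tab.loc[i + 1, "n_root_genes_expressed"] - tab.loc[i, "n_root_genes_expressed"]
        )
        if shift > best_shift:
            best_shift = shift
            best = (float(tab.loc[i, "hpe"]), float(tab.loc[i + 1, "hpe"]))
    assert best is not None
    return best


def write_shift_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
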