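"""M-values, the joint significance rule, and qPCR relative expression.

A comparison "A vs B" reports M = log2(mean_A / mean_B) per gene, where the
means are arithmetic means of replicate intensities.  A gene is called
up-regulated when M > m_cut and the up-direction rank-product p-value is
below p_cut; down-regulated when M < -m_cut with the down-direction p-value
below p_cut; otherwise not significant.  Defaults m_cut = 1 (two-fold) and
p_cut = 0.01.  A configuration switch applies the p_cut to the estimated
percentage of false positives (pfp) instead of the raw permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionDataset, Tissue
from .rankprod import DEFAULT_FLOOR, RPConfig, RPResult, rank_product_test

__all__ = [
    "DEThresholds",
    "Comparison",
    "m_value",
    "call_de",
    "compare_conditions",
    "standard_comparisons",
    "qpcr_relative_expression",
    "write_de_table",
    "read_de_table",
]


@dataclass(frozen=True)
class DEThresholds:
    """Joint significance rule: |M| > m_cut and p (or pfp) < p_cut."""

    m_cut: float = 1.0
    p_cut: float = 0.01
    threshold_on: str = "p"  # "p" (permutation p-value) or "pfp"

    def __post_init__(self) -> None:
        if self.m_cut <= 0:
            raise ValueError("m_cut must be positive")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must lie in (0, 1)")
        if self.threshold_on not in ("p", "pfp"):
            raise ValueError("threshold_on must be 'p' or 'pfp'")


@dataclass(frozen=True)
class Comparison:
    """A labelled condition pair; M is log2(mean of a / mean of b)."""

    label: str
    tissue_a: Tissue
    hpe_a: float
    tissue_b: Tissue
    hpe_b: float


def m_value(
    mean_a: float | np.ndarray,
    mean_b: float | np.ndarray,
    floor: float = DEFAULT_FLOOR,
) -> float | np.ndarray:
    """log2 ratio of two mean intensities (inputs floored at ``floor``)."""
    a = np.maximum(np.asarray(mean_a, dtype=float), floor)
    b = np.maximum(np.asarray(mean_b, dtype=float), floor)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("non-positive mean after flooring")
    out = np.log2(a / b)
    return float(out) if out.ndim == 0 else out


def call_de(
    rp: RPResult,
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    thresholds: DEThresholds = DEThresholds(),
    comparison: str = "A_vs_B",
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Apply the joint M / rank-product rule; one call per gene.

    Returns a DE table with columns gene_id, comparison, mean_a, mean_b, m,
    p_up, p_down, call where call is "up", "down" or "ns".
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    n = len(rp.gene_ids)
    if mean_a.shape != (n,) or mean_b.shape != (n,):
        raise ValueError("mean vectors do not match the rank-product gene set")
    m = m_value(mean_a, mean_b, floor=floor)
    stat_up = rp.p_up if thresholds.threshold_on == "p" else rp.pfp_up
    stat_down = rp.p_down if thresholds.threshold_on == "p" else rp.pfp_down
    call = np.full(n, "ns", dtype=object)
    call[(m > thresholds.m_cut) & (stat_up < thresholds.p_cut)] = "up"
    call[(m < -thresholds.m_cut) & (stat_down < thresholds.p_cut)] = "down"
    return pd.DataFrame(
        {
            "gene_id": rp.gene_ids,
            "comparison": comparison,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "m": m,
            "p_up": rp.p_up,
            "p_down": rp.p_down,
            "call": call,
        }
    )


def compare_conditions(
    ds: ExpressionDataset,
    comparison: Comparison,
    rp_config: RPConfig = RPConfig(),
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Rank-product test plus DE calls for one labelled condition pair."""
    a = ds.replicate_matrix(comparison.tissue_a, comparison.hpe_a)
    b = ds.replicate_matrix(comparison.tissue_b, comparison.hpe_b)
    rp = rank_product_test(a, b, ds.gene_ids, rp_config)
    return call_de(
        rp,
        a.mean(axis=1),
        b.mean(axis=1),
        thresholds,
        comparison=comparison.label,
        floor=rp_config.floor,
    )


def standard_comparisons(ds: ExpressionDataset) -> list[Comparison]:
    """The comparison set the analysis is built around.

    Every stem-base timepoint against the pre-excision baseline (0 hpe),
    consecutive stem-base timepoints, wounded vs fresh leaves, and the
    developed root against the stem base at 0 hpe.
    """
    tps = ds.stem_timepoints()
    if not tps or tps[0] != 0:
        raise ValueError("stem-base samples must include the 0 hpe baseline")
    comps: list[Comparison] = []
    for t in tps[1:]:
        comps.append(
            Comparison(f"sb{t:g}_vs_sb0", Tissue.STEM_BASE, t, Tissue.STEM_BASE, 0.0)
        )
    for t1, t2 in zip(tps[1:], tps[2:]):
        comps.append(
            Comparison(f"sb{t2:g}_vs_sb{t1:g}", Tissue.STEM_BASE, t2, Tissue.STEM_BASE, t1)
        )
    conds = {c for c in ds.conditions()}
    if any(t == Tissue.LEAF_WOUNDED for t, _ in conds) and any(
        t == Tissue.LEAF_FRESH for t, _ in conds
    ):
        comps.append(
            Comparison("leafw_vs_leaff", Tissue.LEAF_WOUNDED, 2.0, Tissue.LEAF_FRESH, 0.0)
        )
    if any(t == Tissue.ROOT for t, _ in conds):
        from .io import ROOT_HPE

        comps.append(Comparison("root_vs_sb0", Tissue.ROOT, ROOT_HPE, Tissue.STEM_BASE, 0.0))
    return comps


def qpcr_relative_expression(ct_target: float, ct_reference: float) -> float:
    """Relative qPCR expression 2^-dCT with dCT = CT_target - CT_reference."""
    ct_target = float(ct_target)
    ct_reference = float(ct_reference)
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("CT values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
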