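"""Synthetic time-course expression data with known planted structure.

The generator emulates the rooting-zone study design: stem-base samples at
0, 2, 6, 24, 72, 96, 144 and 192 hours post-excision (hpe), fresh and
wounded leaves, and a developed root, each with a configurable number of
biological replicates.  Intensities are strictly positive, on an absolute
scale where ~500 separates expressed from non-expressed genes, with
multiplicative log-normal replicate noise of configurable coefficient of
variation.

Planted structure (the ground truth every downstream stage is scored
against):

* per-comparison differentially expressed genes — an intensity pulse at one
  timepoint (for the timepoint-vs-baseline comparisons), a sustained step
  (for consecutive-timepoint comparisons), and dedicated wound-only and
  root-vs-stem DE genes;
* wound-shared genes — a fraction of the early (2 and 6 hpe) stem-base DE
  genes also regulated in wounded vs fresh leaves, in the same direction;
* stem-base identity genes — expressed (above the cutoff) in the stem base
  before excision and in no other organ, decaying below the cutoff at a
  scheduled timepoint;
* root identity genes — expressed in the root only, rising above the cutoff
  in the stem base at a scheduled timepoint;
* functional categories with a configurable enrichment ratio among the
  up-regulated genes of a reference comparison (or of every
  timepoint-vs-baseline comparison).

The returned :class:`SyntheticTruth` is derived from the noise-free
condition means, so it is exact and self-consistent across overlapping
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ROOT_HPE,
    ExpressionDataset,
    GeneAnnotation,
    Hormone,
    SampleCondition,
    Tissue,
)

__all__ = [
    "CategorySpec",
    "SimulationConfig",
    "SyntheticTruth",
    "default_category_plan",
    "generate_dataset",
    "generate_null_dataset",
]


@dataclass(frozen=True)
class CategorySpec:
    """One functional category in the simulation plan.

    ``up_enrichment`` is the planted representation ratio of the category
    among up-regulated genes of the enrichment comparison(s); 1.0 means
    proportional representation.  ``hormone`` tags all member genes with a
    phytohormone category.
    """

    code: str
    name: str
    size: int
    up_enrichment: float = 1.0
    hormone: str | None = None


def default_category_plan(n_genes: int) -> list[CategorySpec]:
    """Category plan mirroring the study's annotation structure.

    Five functional categories enriched among genes induced in the
    24-to-72 hpe window, hormone categories of realistic relative size with
    ethylene and jasmonate enriched among induced genes, and three hormone
    categories (cytokinin, brassinosteroid, salicylic acid) deliberately too
    small for a reliable representation estimate.
    """
    f = lambda frac: max(2, int(round(frac * n_genes)))
    return [
        CategorySpec("Ib", "Storage", f(0.030), up_enrichment=3.0),
        CategorySpec("IIIb", "Mineral nutrient responsive and acquisition", f(0.020), 2.5),
        CategorySpec("Vg", "Antioxidative metabolism and redox state", f(0.020), 2.5),
        CategorySpec("VIa", "Secondary metabolism", f(0.040), 2.5),
        CategorySpec("XIIa", "Biotic stimuli", f(0.030), 2.5),
        CategorySpec("Ha", "Auxin related", f(0.012), 1.0, hormone=Hormone.AUXIN.value),
        CategorySpec("Hb", "Ethylene related", f(0.008), 3.0, hormone=Hormone.ETHYLENE.value),
        CategorySpec("Hc", "Jasmonate related", f(0.006), 2.5, hormone=Hormone.JASMONATE.value),
        CategorySpec("Hd", "ABA related", f(0.005), 1.0, hormone=Hormone.ABSCISIC_ACID.value),
        CategorySpec("He", "Gibberellin related", f(0.004), 1.0, hormone=Hormone.GIBBERELLIN.value),
        CategorySpec("Hf", "Cytokinin related", 6, 1.0, hormone=Hormone.CYTOKININ.value),
        CategorySpec("Hg", "Brassinosteroid related", 5, 1.0, hormone=Hormone.BRASSINOSTEROID.value),
        CategorySpec("Hh", "Salicylic acid related", 4, 1.0, hormone=Hormone.SALICYLIC_ACID.value),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    n_genes: int = 25000
    timepoints_hpe: tuple[float, ...] = (0, 2, 6, 24, 72, 96, 144, 192)
    replicates: int = 3
    baseline_log_mean: float = 6.2  # exp(6.2) ~ 490, spanning tens to thousands
    baseline_log_sd: float = 1.0
    noise_cv: float = 0.3
    n_de_per_comparison: int = 200
    de_fold: float = 4.0
    de_fraction_up: float = 0.5
    frac_wound_shared: float = 0.3
    n_stem_identity: int = 339
    n_root_identity: int = 476
    identity_high: float = 2000.0
    identity_low: float = 100.0
    expression_cutoff: float = 500.0
    stem_decay_schedule: tuple[tuple[float, int], ...] | None = None
    root_rise_schedule: tuple[tuple[float, int], ...] | None = None
    category_plan: tuple[CategorySpec, ...] | None = None
    enrichment_comparison: str = "auto"
    enrichment_scope: str = "reference"  # or "per_timepoint"
    seed: int = 0

    # -- derived vocabulary -------------------------------------------------

    def vs0_labels(self) -> list[str]:
        return [f"sb{t:g}_vs_sb0" for t in self.timepoints_hpe[1:]]

    def consecutive_labels(self) -> list[str]:
        tps = self.timepoints_hpe
        return [f"sb{t2:g}_vs_sb{t1:g}" for t1, t2 in zip(tps[1:], tps[2:])]

    def all_labels(self) -> list[str]:
        return self.vs0_labels() + self.consecutive_labels() + ["leafw_vs_leaff", "root_vs_sb0"]

    def reference_label(self) -> str:
        if self.enrichment_comparison != "auto":
            return self.enrichment_comparison
        if "sb72_vs_sb24" in self.consecutive_labels():
            return "sb72_vs_sb24"
        cons = self.consecutive_labels()
        return cons[-1] if cons else self.vs0_labels()[-1]

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        tps = self.timepoints_hpe
        if len(tps) < 2 or tps[0] != 0 or list(tps) != sorted(set(tps)):
            raise ValueError("timepoints_hpe must start at 0 and increase strictly")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.de_fold <= 1:
            raise ValueError("de_fold must exceed 1")
        if not 0 <= self.de_fraction_up <= 1:
            raise ValueError("de_fraction_up must lie in [0, 1]")
        if not 0 <= self.frac_wound_shared <= 1:
            raise ValueError("frac_wound_shared must lie in [0, 1]")
        if not self.identity_high > self.expression_cutoff > self.identity_low:
            raise ValueError(
                "identity_high must exceed the expression cutoff and identity_low stay below it"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for sched, total, what in (
            (self.stem_decay_schedule, self.n_stem_identity, "stem_decay_schedule"),
            (self.root_rise_schedule, self.n_root_identity, "root_rise_schedule"),
        ):
            if sched is not None:
                if sum(n for _, n in sched) != total:
                    raise ValueError(f"{what} gene counts must sum to the identity-set size")
                if any(t not in tps[1:] for t, _ in sched):
                    raise ValueError(f"{what} references an hpe not in timepoints_hpe")
        n_comps = (len(tps) - 1) + (len(tps) - 2) + 2
        budget = self.n_stem_identity + self.n_root_identity + n_comps * self.n_de_per_comparison
        if budget > self.n_genes:
            raise ValueError(
                f"planted structure needs {budget} genes but n_genes={self.n_genes}"
            )
        plan = self.category_plan
        if plan is not None:
            if sum(s.size for s in plan) > self.n_genes:
                raise ValueError("category plan exceeds n_genes")
            if len({s.code for s in plan}) != len(plan):
                raise ValueError("duplicate category codes in plan")
            for s in plan:
                if s.up_enrichment < 0 or s.size < 0:
                    raise ValueError(f"invalid category spec {s.code}")
        if self.enrichment_scope not in ("reference", "per_timepoint"):
            raise ValueError("enrichment_scope must be 'reference' or 'per_timepoint'")


@dataclass
class SyntheticTruth:
    """Exact planted ground truth, derived from the noise-free condition means."""

    de_genes: dict[str, tuple[frozenset[str], frozenset[str]]]
    wound_genes: frozenset[str]
    stem_identity_genes: frozenset[str]
    root_identity_genes: frozenset[str]
    stem_switch_hpe: dict[str, float]
    root_rise_hpe: dict[str, float]
    enriched_categories: dict[str, float]

    def up(self, label: str) -> frozenset[str]:
        return self.de_genes[label][0]

    def down(self, label: str) -> frozenset[str]:
        return self.de_genes[label][1]

    def regulated(self, label: str) -> frozenset[str]:
        up, down = self.de_genes[label]
        return up | down

    def expected_identity_counts(self, timepoints: list[float]) -> pd.DataFrame:
        """Expected identity-shift table rows at zero noise, one per timepoint."""
        rows = []
        for t in timepoints:
            label = f"sb{t:g}_vs_sb0"
            reg = self.regulated(label)
            rows.append(
                {
                    "hpe": t,
                    "n_ar_regulated": len(reg),
                    "n_ar_regulated_minus_wound": len(reg - self.wound_genes),
                    "n_stem_genes_repressed": sum(
                        1 for s in self.stem_switch_hpe.values() if s <= t
                    ),
                    "n_root_genes_expressed": sum(
                        1 for r in self.root_rise_hpe.values() if r <= t
                    ),
                }
            )
        return pd.DataFrame(rows)


def _even_schedule(timepoints: tuple[float, ...], total: int) -> list[tuple[float, int]]:
    tps = list(timepoints[1:])
    base, extra = divmod(total, len(tps))
    return [(t, base + (1 if i < extra else 0)) for i, t in enumerate(tps)]


def _condition_order(config: SimulationConfig) -> list[tuple[Tissue, float]]:
    conds: list[tuple[Tissue, float]] = [(Tissue.STEM_BASE, float(t)) for t in config.timepoints_hpe]
    conds += [(Tissue.LEAF_FRESH, 0.0), (Tissue.LEAF_WOUNDED, 2.0), (Tissue.ROOT, ROOT_HPE)]
    return conds


def _derive_truth(
    gene_ids: list[str],
    means: np.ndarray,
    cond_index: dict[tuple[Tissue, float], int],
    config: SimulationConfig,
) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
    """Up/down sets per comparison from exact condition means (ratio != 1)."""
    genes = np.asarray(gene_ids, dtype=object)
    tps = config.timepoints_hpe

    def sets(col_a: int, col_b: int) -> tuple[frozenset[str], frozenset[str]]:
        ratio = means[:, col_a] / means[:, col_b]
        return (
            frozenset(genes[ratio > 1 + 1e-9]),
            frozenset(genes[ratio < 1 - 1e-9]),
        )

    out: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for t in tps[1:]:
        out[f"sb{t:g}_vs_sb0"] = sets(
            cond_index[(Tissue.STEM_BASE, float(t))], cond_index[(Tissue.STEM_BASE, 0.0)]
        )
    for t1, t2 in zip(tps[1:], tps[2:]):
        out[f"sb{t2:g}_vs_sb{t1:g}"] = sets(
            cond_index[(Tissue.STEM_BASE, float(t2))], cond_index[(Tissue.STEM_BASE, float(t1))]
        )
    out["leafw_vs_leaff"] = sets(
        cond_index[(Tissue.LEAF_WOUNDED, 2.0)], cond_index[(Tissue.LEAF_FRESH, 0.0)]
    )
    out["root_vs_sb0"] = sets(
        cond_index[(Tissue.ROOT, ROOT_HPE)], cond_index[(Tissue.STEM_BASE, 0.0)]
    )
    return out


def _assign_categories(
    gene_ids: list[str],
    truth_de: dict[str, tuple[frozenset[str], frozenset[str]]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assign one category per gene so planted enrichment ratios are met.

    For a category of size ``n_xt`` with enrichment ratio ``r`` against a
    comparison whose up set has ``n_ap`` genes, the quota drawn from that up
    set is ``round(r * n_xt * n_ap / n_at)`` — exactly the count that makes
    the representation ratio equal ``r``.
    """
    plan = list(config.category_plan) if config.category_plan is not None else default_category_plan(
        config.n_genes
    )
    if sum(s.size for s in plan) > config.n_genes:
        raise ValueError("category plan exceeds n_genes")
    n_at = config.n_genes
    if config.enrichment_scope == "reference":
        ref_labels = [config.reference_label()]
    else:
        ref_labels = config.vs0_labels()
    for lbl in ref_labels:
        if lbl not in truth_de:
            raise ValueError(f"enrichment comparison {lbl!r} is not among the computed comparisons")

    up_all = {lbl: set(truth_de[lbl][0]) for lbl in ref_labels}
    available_up = {lbl: set(s) for lbl, s in up_all.items()}
    any_ref_up = set().union(*up_all.values()) if up_all else set()
    unassigned = set(gene_ids)

    def draw(pool: set[str], k: int) -> list[str]:
        k = min(k, len(pool))
        if k == 0:
            return []
        chosen = rng.choice(sorted(pool), size=k, replace=False)
        return [str(c) for c in chosen]

    category: dict[str, CategorySpec] = {}
    for spec in plan:
        members: list[str] = []
        for lbl in ref_labels:
            n_ap = len(up_all[lbl])
            quota = int(round(spec.up_enrichment * spec.size * n_ap / n_at))
            quota = min(quota, spec.size - len(members))
            picked = draw(available_up[lbl] & unassigned, quota)
            members.extend(picked)
            for g in picked:
                unassigned.discard(g)
                for s in available_up.values():
                    s.discard(g)
        rest = spec.size - len(members)
        neutral_pool = unassigned - any_ref_up
        picked = draw(neutral_pool, rest)
        if len(picked) < rest:  # fall back to any unassigned gene
            picked += draw(unassigned - set(picked), rest - len(picked))
        members.extend(picked)
        for g in picked:
            unassigned.discard(g)
            for s in available_up.values():
                s.discard(g)
        for g in members:
            category[g] = spec

    background = CategorySpec("XX", "Unclassified", len(unassigned))
    for g in unassigned:
        category[g] = background

    table = pd.DataFrame(
        {
            "category_code": [category[g].code for g in gene_ids],
            "category_name": [category[g].name for g in gene_ids],
            "hormone_category": [
                category[g].hormone or Hormone.NONE.value for g in gene_ids
            ],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    enriched = {s.code: s.up_enrichment for s in plan if s.up_enrichment != 1.0}
    return table, enriched


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GeneAnnotation, SyntheticTruth]:
    """Generate a dataset, its annotation, and the exact planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    tps = config.timepoints_hpe

    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
    conds = _condition_order(config)
    cond_index = {c: i for i, c in enumerate(conds)}
    means = np.tile(baseline[:, None], (1, len(conds)))

    # disjoint allocation of planted genes from a shuffled pool
    pool = list(rng.permutation(n))
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        if cursor + k > n:
            raise ValueError("planted structure exceeds n_genes")
        out = np.asarray(pool[cursor : cursor + k], dtype=int)
        cursor += k
        return out

    sb_cols = {float(t): cond_index[(Tissue.STEM_BASE, float(t))] for t in tps}
    leaf_cols = [cond_index[(Tissue.LEAF_FRESH, 0.0)], cond_index[(Tissue.LEAF_WOUNDED, 2.0)]]
    root_col = cond_index[(Tissue.ROOT, ROOT_HPE)]

    # identity genes: step trajectories crossing the cutoff at a scheduled hpe
    stem_sched = (
        list(config.stem_decay_schedule)
        if config.stem_decay_schedule is not None
        else _even_schedule(tps, config.n_stem_identity)
    )
    root_sched = (
        list(config.root_rise_schedule)
        if config.root_rise_schedule is not None
        else _even_schedule(tps, config.n_root_identity)
    )
    stem_switch: dict[str, float] = {}
    for switch_t, count in stem_sched:
        idx = take(count)
        for t in tps:
            col = sb_cols[float(t)]
            means[idx, col] = config.identity_low if t >= switch_t else config.identity_high
        means[np.ix_(idx, leaf_cols)] = config.identity_low
        means[idx, root_col] = config.identity_low
        for i in idx:
            stem_switch[gene_ids[i]] = float(switch_t)
    root_rise: dict[str, float] = {}
    for rise_t, count in root_sched:
        idx = take(count)
        for t in tps:
            col = sb_cols[float(t)]
            means[idx, col] = config.identity_high if t >= rise_t else config.identity_low
        means[np.ix_(idx, leaf_cols)] = config.identity_low
        means[idx, root_col] = config.identity_high
        for i in idx:
            root_rise[gene_ids[i]] = float(rise_t)

    fold = config.de_fold
    n_de = config.n_de_per_comparison
    n_up = int(round(n_de * config.de_fraction_up))

    # pulse DE genes: regulated at exactly one timepoint vs the 0 hpe baseline
    pulse_up: dict[float, np.ndarray] = {}
    pulse_down: dict[float, np.ndarray] = {}
    for t in tps[1:]:
        idx = take(n_de)
        up, down = idx[:n_up], idx[n_up:]
        means[up, sb_cols[float(t)]] *= fold
        means[down, sb_cols[float(t)]] /= fold
        pulse_up[float(t)], pulse_down[float(t)] = up, down

    # step DE genes: sustained change from the later timepoint of each
    # consecutive comparison onwards
    for t1, t2 in zip(tps[1:], tps[2:]):
        idx = take(n_de)
        up, down = idx[:n_up], idx[n_up:]
        later = [sb_cols[float(t)] for t in tps if t >= t2]
        means[np.ix_(up, later)] *= fold
        means[np.ix_(down, later)] /= fold

    # wound-only DE genes (wounded vs fresh leaf)
    idx = take(n_de)
    wl = cond_index[(Tissue.LEAF_WOUNDED, 2.0)]
    means[idx[:n_up], wl] *= fold
    means[idx[n_up:], wl] /= fold

    # wound-shared: a fraction of early stem-base pulse genes are also
    # regulated by leaf wounding, in the same direction
    early = [t for t in tps[1:3]]
    for t in early:
        for arr, mult in ((pulse_up.get(float(t)), fold), (pulse_down.get(float(t)), 1 / fold)):
            if arr is None or len(arr) == 0:
                continue
            k = int(round(config.frac_wound_shared * len(arr)))
            means[arr[:k], wl] *= mult

    # root-vs-stem DE genes
    idx = take(n_de)
    means[idx[:n_up], root_col] *= fold
    means[idx[n_up:], root_col] /= fold

    truth_de = _derive_truth(gene_ids, means, cond_index, config)
    annotation_table, enriched = _assign_categories(gene_ids, truth_de, config, rng)

    # replicate sampling: multiplicative log-normal noise, unbiased in the mean
    sigma2 = math.log(1.0 + config.noise_cv**2)
    sigma = math.sqrt(sigma2)
    design: list[SampleCondition] = []
    columns: list[np.ndarray] = []
    for tissue, hpe in conds:
        for r in range(1, config.replicates + 1):
            design.append(SampleCondition(tissue, hpe, r))
            m = means[:, cond_index[(tissue, hpe)]]
            if sigma == 0:
                columns.append(m.copy())
            else:
                columns.append(m * np.exp(rng.normal(-sigma2 / 2, sigma, n)))
    values = np.column_stack(columns)

    dataset = ExpressionDataset(gene_ids, values, design)
    annotation = GeneAnnotation(annotation_table)
    truth = SyntheticTruth(
        de_genes=truth_de,
        wound_genes=truth_de["leafw_vs_leaff"][0] | truth_de["leafw_vs_leaff"][1],
        stem_identity_genes=frozenset(stem_switch),
        root_identity_genes=frozenset(root_rise),
        stem_switch_hpe=stem_switch,
        root_rise_hpe=root_rise,
        enriched_categories=enriched,
    )
    return dataset, annotation, truth


def generate_null_dataset(
    n_genes: int,
    replicates: int = 4,
    noise_cv: float = 0.3,
    seed: int = 0,
    baseline_log_mean: float = 6.2,
    baseline_log_sd: float = 1.0,
    timepoints: tuple[float, ...] = (0.0, 24.0),
) -> ExpressionDataset:
    """Two-condition (or more) stem-base dataset with no planted effects.

    Every condition shares the same per-gene mean, so the true M-value of
    every gene is 0 in every comparison; used to calibrate the permutation
    test's type-I error.
    """
    rng = np.random.default_rng(seed)
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, n_genes))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sigma2 = math.log(1.0 + noise_cv**2)
    sigma = math.sqrt(sigma2)
    design: list[SampleCondition] = []
    columns: list[np.ndarray] = []
    for t in timepoints:
        for r in range(1, replicates + 1):
            design.append(SampleCondition(Tissue.STEM_BASE, float(t), r))
            if sigma == 0:
                columns.append(baseline.copy())
            else:
                columns.append(baseline * np.exp(rng.normal(-sigma2 / 2, sigma, n_genes)))
    return ExpressionDataset(gene_ids, np.column_stack(columns), design)
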