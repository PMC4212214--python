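"""End-to-end orchestration: data -> rank product -> DE -> identity -> representation.

A pipeline run is driven by a single config (either a simulation section or
paths to an expression matrix, design and annotation), writes every stage's
output as tab-separated text under one output directory, and records a JSON
manifest with the config snapshot, per-file SHA-256 checksums, stage wall
times and — when the data were simulated — recovery scores against the
planted truth.  One global seed is split deterministically into per-stage
substreams, so a rerun with the same config and seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import Comparison, DEThresholds, compare_conditions, standard_comparisons, write_de_table
from .identity import (
    IdentityConfig,
    identity_shift_table,
    largest_shift_interval,
    organ_specific_genes,
    subtract_wound,
    wound_regulated_genes,
    write_shift_table,
)
from .io import (
    ExpressionDataset,
    GeneAnnotation,
    Tissue,
    read_annotation,
    read_expression,
    write_annotation,
    write_expression,
    write_gene_set,
)
from .rankprod import DEFAULT_FLOOR, RPConfig, rank_product_test
from .representation import (
    DEFAULT_FOLD_CRITERION,
    DEFAULT_MIN_CATEGORY_SIZE,
    category_profile,
    hormone_timecourse,
    write_representation,
)
from .simulate import CategorySpec, SimulationConfig, SyntheticTruth, generate_dataset

logger = logging.getLogger("rootshift")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; exactly one data source."""

    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    n_permutations: int = 1000
    floor: float = DEFAULT_FLOOR
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    identity: IdentityConfig = field(default_factory=IdentityConfig)
    min_category_size: int = DEFAULT_MIN_CATEGORY_SIZE
    fold_criterion: float = DEFAULT_FOLD_CRITERION
    representation_comparison: str | None = None  # default: 72-vs-24-style window
    seed: int = 0

    def validate(self) -> None:
        has_paths = self.expression_path is not None or self.design_path is not None
        has_sim = self.simulation is not None
        if has_paths and has_sim:
            raise ValueError("config must provide either input paths or a simulation, not both")
        if not has_paths and not has_sim:
            raise ValueError("config must provide input paths or a simulation section")
        if has_paths and (self.expression_path is None or self.design_path is None):
            raise ValueError("both expression_path and design_path are required")

    # -- (de)serialisation --------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "category_plan" in sim and sim["category_plan"] is not None:
                sim["category_plan"] = tuple(CategorySpec(**c) for c in sim["category_plan"])
            for key in ("timepoints_hpe", "stem_decay_schedule", "root_rise_schedule"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x for x in sim[key])
            cfg.simulation = SimulationConfig(**sim)
        inputs = raw.get("inputs") or {}
        cfg.expression_path = inputs.get("expression")
        cfg.design_path = inputs.get("design")
        cfg.annotation_path = inputs.get("annotation")
        rp = raw.get("rank_product") or {}
        cfg.n_permutations = int(rp.get("n_permutations", cfg.n_permutations))
        cfg.floor = float(rp.get("floor", cfg.floor))
        thr = raw.get("thresholds") or {}
        cfg.thresholds = DEThresholds(
            m_cut=float(thr.get("m_cut", 1.0)),
            p_cut=float(thr.get("p_cut", 0.01)),
            threshold_on=str(thr.get("threshold_on", "p")),
        )
        ident = raw.get("identity") or {}
        cfg.identity = IdentityConfig(
            expression_cutoff=float(ident.get("expression_cutoff", 500.0)),
            thresholds=cfg.thresholds,
        )
        rep = raw.get("representation") or {}
        cfg.min_category_size = int(rep.get("min_category_size", cfg.min_category_size))
        cfg.fold_criterion = float(rep.get("fold_criterion", cfg.fold_criterion))
        cfg.representation_comparison = rep.get("comparison")
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out: dict = {
            "rank_product": {"n_permutations": self.n_permutations, "floor": self.floor},
            "thresholds": {
                "m_cut": self.thresholds.m_cut,
                "p_cut": self.thresholds.p_cut,
                "threshold_on": self.thresholds.threshold_on,
            },
            "identity": {"expression_cutoff": self.identity.expression_cutoff},
            "representation": {
                "min_category_size": self.min_category_size,
                "fold_criterion": self.fold_criterion,
                "comparison": self.representation_comparison,
            },
            "seed": self.seed,
        }
        if self.simulation is not None:
            sim = asdict(self.simulation)
            if sim.get("category_plan") is not None:
                sim["category_plan"] = [asdict(c) for c in self.simulation.category_plan]
            out["simulation"] = sim
        else:
            out["inputs"] = {
                "expression": self.expression_path,
                "design": self.design_path,
                "annotation": self.annotation_path,
            }
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, labels: list[str]) -> dict[str, int]:
    """Deterministic per-stage integer seeds (< 2**31) from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(labels))
    return {
        lbl: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for lbl, child in zip(labels, children)
    }


def _score_calls(de: pd.DataFrame, truth: SyntheticTruth, label: str) -> dict:
    called = set(de.loc[de["call"] != "ns", "gene_id"])
    true = set(truth.regulated(label))
    tp = len(called & true)
    return {
        "comparison": label,
        "n_called": len(called),
        "n_true": len(true),
        "sensitivity": tp / len(true) if true else float("nan"),
        "fdp": (len(called) - tp) / len(called) if called else 0.0,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage in dependency order and return the manifest dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "outputs": {},
    }
    files: dict[str, Path] = {}

    def finish_stage(name: str, t0: float, written: dict[str, Path], info: dict | None = None) -> None:
        files.update(written)
        manifest["stages"].append(
            {
                "name": name,
                "seconds": round(time.time() - t0, 3),
                "outputs": sorted(str(p.name) for p in written.values()),
                **(info or {}),
            }
        )
        logger.info("stage %s done in %.2fs (%d outputs)", name, time.time() - t0, len(written))

    # ---- stage: data ------------------------------------------------------
    t0 = time.time()
    truth: SyntheticTruth | None = None
    if config.simulation is not None:
        sim = replace(config.simulation, seed=_stage_seeds(config.seed, ["simulate"])["simulate"])
        ds, annotation, truth = generate_dataset(sim)
        write_expression(ds, out / "expression.tsv", out / "design.tsv")
        write_annotation(annotation, out / "annotation.tsv")
        written = {
            "expression": out / "expression.tsv",
            "design": out / "design.tsv",
            "annotation": out / "annotation.tsv",
        }
    else:
        ds = read_expression(config.expression_path, config.design_path)
        annotation = (
            read_annotation(config.annotation_path) if config.annotation_path else None
        )
        written = {}
    finish_stage("data", t0, written, {"n_genes": ds.n_genes, "n_samples": len(ds.design)})

    # ---- stage: rank product + DE calls -----------------------------------
    t0 = time.time()
    comparisons = standard_comparisons(ds)
    seeds = _stage_seeds(config.seed, ["simulate"] + [c.label for c in comparisons] + ["organs"])
    de_tables: dict[str, pd.DataFrame] = {}
    written = {}
    for comp in comparisons:
        rp_cfg = RPConfig(config.n_permutations, seeds[comp.label], config.floor)
        de = compare_conditions(ds, comp, rp_cfg, config.thresholds)
        de_tables[comp.label] = de
        path = out / f"de_{comp.label}.tsv"
        write_de_table(de, path)
        written[f"de_{comp.label}"] = path
    finish_stage("differential_expression", t0, written, {"n_comparisons": len(comparisons)})

    # ---- stage: wound + organ identity sets -------------------------------
    t0 = time.time()
    written = {}
    wound = wound_regulated_genes(de_tables["leafw_vs_leaff"], config.thresholds)
    organ_rp = RPConfig(config.n_permutations, seeds["organs"], config.floor)
    stem_set = organ_specific_genes(
        ds, Tissue.STEM_BASE, config.thresholds, config.identity.expression_cutoff, organ_rp
    )
    root_set = organ_specific_genes(
        ds, Tissue.ROOT, config.thresholds, config.identity.expression_cutoff, organ_rp
    )
    for gs, fname in ((wound, "wound_regulated.tsv"), (stem_set, "stem_identity.tsv"),
                      (root_set, "root_identity.tsv")):
        write_gene_set(gs, out / fname)
        written[fname] = out / fname
    finish_stage(
        "gene_sets", t0, written,
        {"n_wound": len(wound), "n_stem_identity": len(stem_set), "n_root_identity": len(root_set)},
    )

    # ---- stage: identity shift table --------------------------------------
    t0 = time.time()
    de_by_tp = {
        float(c.hpe_a): de_tables[c.label]
        for c in comparisons
        if c.tissue_a is Tissue.STEM_BASE and c.tissue_b is Tissue.STEM_BASE and c.hpe_b == 0.0
    }
    shift = identity_shift_table(ds, stem_set, root_set, wound, de_by_tp, config.identity)
    write_shift_table(shift, out / "identity_shift.tsv")
    interval = largest_shift_interval(shift) if len(shift) >= 2 else None
    finish_stage(
        "identity_shift", t0, {"identity_shift": out / "identity_shift.tsv"},
        {"largest_shift_interval": list(interval) if interval else None},
    )

    # ---- stage: representation --------------------------------------------
    t0 = time.time()
    written = {}
    if annotation is not None:
        rep_label = config.representation_comparison
        if rep_label is None:
            cons = [c.label for c in comparisons if c.tissue_b is Tissue.STEM_BASE and c.hpe_b != 0.0]
            rep_label = "sb72_vs_sb24" if "sb72_vs_sb24" in de_tables else (
                cons[-1] if cons else comparisons[0].label
            )
        profile = category_profile(
            de_tables[rep_label], annotation, config.min_category_size, config.fold_criterion
        )
        write_representation(profile, out / f"representation_{rep_label}.tsv")
        written[f"representation_{rep_label}"] = out / f"representation_{rep_label}.tsv"
        hormone_labels = {
            c.label: de_tables[c.label]
            for c in comparisons
            if (c.tissue_b is Tissue.STEM_BASE and c.hpe_b == 0.0)
        }
        hormones = hormone_timecourse(
            hormone_labels, annotation, config.min_category_size, config.fold_criterion
        )
        write_representation(hormones, out / "hormone_timecourse.tsv")
        written["hormone_timecourse"] = out / "hormone_timecourse.tsv"
    finish_stage("representation", t0, written, {"comparison": rep_label if annotation else None})

    # ---- manifest ----------------------------------------------------------
    if truth is not None:
        scores = [
            _score_calls(de_tables[lbl], truth, lbl) for lbl in de_tables if lbl in truth.de_genes
        ]
        manifest["recovery"] = scores
    manifest["outputs"] = {name: {"path": str(p), "sha256": _sha256(p)} for name, p in files.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
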