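"""End-to-end orchestration: simulate/load -> ingest -> cluster -> assign
-> overlap -> enrich, under a single config with derived per-stage seeds.

Each stochastic stage receives a seed derived deterministically from the
global seed and the stage name, so stages are reproducible independently
and never share a random stream. Re-running with the same config and
inputs reproduces byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.metrics import balanced_accuracy_score

from .design import StudyDesign, granule_ip_design
from .granule_clustering import (
    assign_membership,
    estimate_fuzzifier,
    select_cluster_count,
)
from .quant_ingest import QuantTable, ingest_pipeline, read_quant_table
from .set_analysis import GeneSet, hypergeom_enrich, set_overlap
from .synthetic_data import ProteomeSimSpec, TruthLabels, generate_quant_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "cluster", "assign", "overlap", "enrich")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_CLUSTER_DEFAULTS = {
    "c_min": 2,
    "c_max": 25,
    "n_starts": 10,
    "tol": 1e-6,
    "max_iter": 1000,
    "tau": 0.001,
    "condition": "glucose_depleted",
    "marker_a": "seed_A",
    "marker_b": "seed_B",
}
_INGEST_DEFAULTS = {"impute": "qrilc", "quantile_cut": 0.01, "width": 0.3, "shift": 1.8}
_SIMULATE_DEFAULTS = {"noise_sd": 0.3, "missing_rate": 0.10, "dual_weight": 0.5}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    quant: str | None = None  # external table; None -> simulate
    dialect: str = "generic_tsv"
    design: StudyDesign | None = None
    simulate: dict = field(default_factory=dict)
    ingest: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, given, known in (
            ("simulate", self.simulate, _SIMULATE_DEFAULTS),
            ("ingest", self.ingest, _INGEST_DEFAULTS),
            ("cluster", self.cluster, _CLUSTER_DEFAULTS),
        ):
            unknown = set(given) - set(known)
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
            merged = dict(known)
            merged.update(given)
            setattr(self, name, merged)
        if self.design is None:
            self.design = granule_ip_design()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {"seed", "quant", "dialect", "design", "simulate", "ingest", "cluster"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "design" in d and d["design"] is not None:
            d["design"] = StudyDesign.from_dict(d["design"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(str(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    stages: list[dict] = field(default_factory=list)
    attrition: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def record(self, stage: str, n_in: int | None, n_out: int | None, t0: float,
               **extra) -> None:
        entry = {
            "stage": stage,
            "n_in": n_in,
            "n_out": n_out,
            "wall_clock_s": round(time.monotonic() - t0, 3),
        }
        entry.update(extra)
        self.stages.append(entry)
        logger.info("stage %s: %s -> %s rows", stage, n_in, n_out)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "attrition": self.attrition,
            "parameters": self.parameters,
        }

    def write_json(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")


def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.parameters = {
        "seed": config.seed,
        "simulate": config.simulate,
        "ingest": config.ingest,
        "cluster": {k: v for k, v in config.cluster.items()},
    }
    design = config.design
    assert design is not None

    # --- simulate / load -------------------------------------------------
    t0 = time.monotonic()
    truth: TruthLabels | None = None
    try:
        if config.quant is None:
            sim = config.simulate
            from .synthetic_data import NoiseSpec

            spec = ProteomeSimSpec(
                noise=NoiseSpec(sd=sim["noise_sd"]),
                dual_weight=sim["dual_weight"],
                target_missing_rate=sim["missing_rate"],
            )
            quant, truth = generate_quant_dataset(
                design=design, spec=spec, seed=stage_seed(config.seed, "simulate")
            )
            quant.write_tsv(out / "quant.tsv")
            truth.write_tsv(out / "truth.tsv")
        else:
            quant = read_quant_table(config.quant, config.dialect, design)  # type: ignore[arg-type]
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise StageError("simulate", exc) from exc
    report.record("simulate", None, quant.n_features, t0)
    report.attrition["simulated"] = quant.n_features

    # --- ingest ----------------------------------------------------------
    t0 = time.monotonic()
    try:
        ing = config.ingest
        profiles, ingest_report = ingest_pipeline(
            quant,
            design,
            seed=stage_seed(config.seed, "ingest"),
            impute=ing["impute"],
            quantile_cut=ing["quantile_cut"],
            width=ing["width"],
            shift=ing["shift"],
        )
        for pm in profiles:
            pm.write_tsv(out / f"profiles_{pm.condition}.tsv")
        with open(out / "ingest_report.json", "w") as fh:
            json.dump(ingest_report.to_dict(), fh, indent=2)
    except Exception as exc:  # noqa: BLE001
        raise StageError("ingest", exc) from exc
    report.record("ingest", quant.n_features, profiles[0].n_proteins, t0)
    for stage, n in ingest_report.stages:
        report.attrition[stage] = n

    # --- cluster + assign -------------------------------------------------
    clu = config.cluster
    markers = (clu["marker_a"], clu["marker_b"])
    assignments = {}
    for pm in profiles:
        t0 = time.monotonic()
        try:
            m = estimate_fuzzifier(pm.n_proteins, pm.dimensionality)
            selection, model = select_cluster_count(
                pm,
                marker_ids=markers,
                m=m,
                seed=stage_seed(config.seed, f"cluster:{pm.condition}"),
                c_min=clu["c_min"],
                c_max=min(clu["c_max"], pm.n_proteins - 1),
                n_starts=clu["n_starts"],
                max_iter=clu["max_iter"],
                tol=clu["tol"],
            )
            model.membership.to_csv(
                out / f"membership_{pm.condition}.tsv", sep="\t"
            )
            with open(out / f"selection_{pm.condition}.json", "w") as fh:
                json.dump({"fuzzifier": m, **selection.to_dict()}, fh, indent=2)
        except Exception as exc:  # noqa: BLE001
            raise StageError("cluster", exc) from exc
        report.record(
            "cluster", pm.n_proteins, model.c, t0,
            condition=pm.condition, fuzzifier=round(m, 4), selected_c=model.c,
        )

        t0 = time.monotonic()
        try:
            assignment = assign_membership(model, markers, tau=clu["tau"])
            assignment.write_tsv(out / f"assignment_{pm.condition}.tsv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("assign", exc) from exc
        assignments[pm.condition] = assignment
        counts = assignment.table["label"].value_counts().to_dict()
        report.record(
            "assign", pm.n_proteins, len(assignment.table), t0,
            condition=pm.condition, label_counts=counts,
        )

    # --- overlap ----------------------------------------------------------
    eval_condition = clu["condition"]
    if eval_condition not in assignments:
        raise StageError(
            "overlap", KeyError(f"no assignment for condition {eval_condition!r}")
        )
    t0 = time.monotonic()
    try:
        asg = assignments[eval_condition]
        set_a = GeneSet.from_ids("granule_A", asg.members("granule_A"))
        set_b = GeneSet.from_ids("granule_B", asg.members("granule_B"))
        overlap = set_overlap(set_a, set_b)
        with open(out / "overlap.json", "w") as fh:
            json.dump(overlap.to_dict(), fh, indent=2)
    except Exception as exc:  # noqa: BLE001
        raise StageError("overlap", exc) from exc
    report.record(
        "overlap", len(set_a) + len(set_b), overlap.n_intersection, t0,
        condition=eval_condition,
    )

    # --- enrich -----------------------------------------------------------
    t0 = time.monotonic()
    try:
        universe = GeneSet.from_ids("assigned", asg.table.index)
        if truth is not None:
            terms = [
                GeneSet.from_ids(cls, truth.protein_class.index[
                    truth.protein_class.isin(members)
                ])
                for cls, members in (
                    ("planted_A", {"seed_A", "granule_A", "dual"}),
                    ("planted_B", {"seed_B", "granule_B", "dual"}),
                )
            ]
        else:
            terms = [set_a, set_b]
        results = []
        for query in (set_a, set_b):
            for r in hypergeom_enrich(query, terms, universe):
                results.append({"query": query.name, **r.__dict__})
        pd.DataFrame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", exc) from exc
    report.record("enrich", len(terms), len(results), t0)

    report.write_json(out / "run_report.json")
    return report


def recovery_metrics(
    assignment, truth: TruthLabels
) -> dict[str, float]:
    """Balanced accuracy of recovered granule labels against planted truth,
    plus the fraction of planted dual proteins labelled 'both'."""
    table = assignment.table
    expected = truth.expected_granule_label().reindex(table.index)
    predicted = table["label"]
    ba = balanced_accuracy_score(expected.to_numpy(), predicted.to_numpy())
    planted_dual = truth.protein_class.reindex(table.index) == "dual"
    dual_rate = (
        float((predicted[planted_dual] == "both").mean())
        if planted_dual.any()
        else float("nan")
    )
    return {
        "balanced_accuracy": float(ba),
        "dual_both_rate": dual_rate,
        "n_evaluated": int(len(table)),
    }
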