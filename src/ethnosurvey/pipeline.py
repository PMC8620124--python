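"""End-to-end survey analysis pipeline.

``run_pipeline`` executes the stages (simulate-or-load, validate, indices,
kmto, associations, drivers) in dependency order, writes each stage's
artifacts as JSON/CSV under the output directory, and finishes with a
manifest listing every emitted file with a checksum, the configuration hash
and the seed.  All randomness flows from the one root seed, split per stage
by stable labels, so rerunning an identical configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import drivers as drv
from . import indices as idx
from . import kmto as km
from .association import fit_count_model
from .survey_data import SurveyDataset, read_dataset, validate_dataset, write_dataset
from .synthetic import GeneratorConfig, generate_dataset

log = logging.getLogger("ethnosurvey")

ALL_STAGES = ("simulate", "validate", "indices", "kmto", "associations", "drivers")


@dataclass
class RunConfig:
    """Exactly one of ``input_dir`` (existing survey CSVs) or ``generator``
    must be set; ``seed`` overrides the generator's."""

    out_dir: str
    input_dir: str | None = None
    generator: GeneratorConfig | None = None
    seed: int | None = None
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError("exactly one input source (input_dir or generator) "
                             "must be configured")
        if self.input_dir is not None and \
                Path(self.input_dir).resolve() == Path(self.out_dir).resolve():
            raise ValueError("output directory must differ from the input directory")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunReport:
    manifest: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def _write_json(path: Path, payload) -> Path:
    path.write_text(json.dumps(_jsonable(payload), sort_keys=True, indent=1,
                               allow_nan=True) + "\n", encoding="utf-8")
    return path


def tree_as_dict(node: drv.TreeNode) -> dict:
    out = {
        "prediction": _jsonable(node.prediction),
        "probability": node.probability,
        "n": node.n,
        "n_share": node.n_share,
        "impurity": node.impurity,
    }
    if node.class_counts is not None:
        out["class_counts"] = _jsonable(node.class_counts)
    if not node.is_leaf:
        out["split"] = {
            "feature": node.split.feature,
            "kind": node.split.kind,
            "threshold": node.split.threshold,
            "left_levels": sorted(node.split.left_levels),
        }
        out["children"] = [tree_as_dict(c) for c in node.children]
    return out


_TREE_FEATURES = ("group", "gender", "age_category", "schooling", "activity",
                  "religion", "migratory_status", "owns_trees",
                  "perceived_growth", "perceived_time_to_fruiting_years",
                  "perceived_availability", "knows_taboo",
                  "knows_superstition", "perceives_market")


def _tree_frame(ds: SurveyDataset):
    df = ds.respondents_frame()
    out = df[list(_TREE_FEATURES)].copy()
    for col in ("owns_trees", "knows_taboo", "knows_superstition",
                "perceives_market"):
        out[col] = out[col].map({True: "yes", False: "no"})
    return out, df


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run the configured stages and return the manifest."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(manifest={"stages_completed": [], "files": {}})
    artifacts = report.artifacts

    # --- input ------------------------------------------------------------
    if cfg.generator is not None:
        gen = cfg.generator
        if cfg.seed is not None:
            gen = dataclasses.replace(gen, seed=cfg.seed)
        ds = generate_dataset(gen)
        report.manifest["seed"] = gen.seed
        report.manifest["config_hash"] = gen.config_hash()
        if "simulate" in cfg.stages:
            data_dir = out_dir / "data"
            r_path, u_path = write_dataset(ds, data_dir)
            artifacts["respondents"] = r_path
            artifacts["use_reports"] = u_path
            report.manifest["stages_completed"].append("simulate")
    else:
        in_dir = Path(cfg.input_dir)
        ds = read_dataset(in_dir / "respondents.csv", in_dir / "use_reports.csv")
        report.manifest["seed"] = cfg.seed

    seed = report.manifest.get("seed") or 0

    # --- validate ----------------------------------------------------------
    if "validate" in cfg.stages:
        violations = validate_dataset(ds)
        path = out_dir / "validation.jsonl"
        path.write_text("".join(json.dumps(_jsonable(v), sort_keys=True) + "\n"
                                for v in violations), encoding="utf-8")
        artifacts["validation"] = path
        report.manifest["n_violations"] = len(violations)
        report.manifest["stages_completed"].append("validate")
        log.info("validate: %d violations", len(violations))

    # --- indices -----------------------------------------------------------
    if "indices" in cfg.stages:
        payload = {
            "overall_uv": idx.total_use_value(ds),
            "uv_by_category": idx.use_value_by(ds, "category"),
            "uv_by_plant_part": idx.use_value_by(ds, "plant_part"),
            "uv_by_group": idx.use_value_by(ds, "group"),
            "iar_by_category": [
                {**dataclasses.asdict(r), "iar_display": r.iar_display()}
                for r in idx.iar_table(ds, "category")],
            "iar_by_body_system": [
                {**dataclasses.asdict(r), "iar_display": r.iar_display()}
                for r in idx.iar_table(ds, "body_system")],
        }
        artifacts["indices"] = _write_json(out_dir / "indices.json", payload)
        report.manifest["stages_completed"].append("indices")

    # --- kmto ---------------------------------------------------------------
    if "kmto" in cfg.stages:
        tallies = km.path_frequencies(ds)
        by_cat = km.path_frequencies(ds, by_category=True)
        payload = {
            "paths": [{"path": t.path.label(), "count": t.count,
                       "proportion": t.proportion} for t in tallies],
            "paths_by_category": {
                cat: [{"path": t.path.label(), "count": t.count,
                       "proportion": t.proportion} for t in ts]
                for cat, ts in by_cat.items()},
            "attribute_state_tests": km.attribute_state_tests(ds),
            "category_independence_tests": km.kmto_category_tests(ds, seed=seed),
        }
        artifacts["kmto"] = _write_json(out_dir / "kmto.json", payload)
        report.manifest["stages_completed"].append("kmto")

    # --- associations -------------------------------------------------------
    if "associations" in cfg.stages:
        import pandas as pd

        from .association import equal_proportions_test, independence_test

        df = ds.respondents_frame()
        owners = df[df["owns_trees"]]
        payload = {}
        if not owners.empty:
            mode_counts = owners["ownership_mode"].value_counts().sort_index()
            payload["ownership_mode_proportions"] = equal_proportions_test(
                mode_counts.to_numpy())
            habitat_tab = pd.crosstab(owners["habitat"], owners["group"])
            if habitat_tab.shape[0] >= 2 and habitat_tab.shape[1] >= 2:
                payload["habitat_by_group"] = independence_test(
                    habitat_tab.to_numpy(), seed=seed)
            fit = fit_count_model(owners["n_trees"].to_numpy(),
                                  owners[["group"]])
            payload["trees_by_group_glm"] = {
                "coefficients": fit.coefficients,
                "std_errors": fit.std_errors,
                "dispersion": fit.dispersion,
                "family_used": fit.family_used,
            }
        avail_counts = df["perceived_availability"].value_counts().sort_index()
        if len(avail_counts) >= 2:
            payload["availability_proportions"] = equal_proportions_test(
                avail_counts.to_numpy())
        artifacts["associations"] = _write_json(out_dir / "associations.json",
                                                payload)
        report.manifest["stages_completed"].append("associations")

    # --- drivers ------------------------------------------------------------
    if "drivers" in cfg.stages:
        params = drv.TreeParams(seed=seed)
        X, df = _tree_frame(ds)
        labels = np.where(df["willing_to_cultivate"], "yes", "no")
        payload = {}
        if len(set(labels)) > 1 and len(labels) >= params.min_split:
            ctree = drv.fit_classification_tree(X, labels, params)
            ctree = drv.prune_tree(ctree, X, labels, params)
            payload["willingness"] = {"tree": tree_as_dict(ctree),
                                      "text": drv.tree_to_text(ctree)}
        willing = df["willing_to_cultivate"].to_numpy()
        Xw = X[willing]
        for target, col in (("acreage", "max_acreage_ha"),
                            ("price", "max_price_usd")):
            y = df.loc[willing, col].to_numpy(dtype=float)
            if len(y) >= params.min_split and np.ptp(y) > 0:
                rtree = drv.fit_regression_tree(Xw, y, params)
                rtree = drv.prune_tree(rtree, Xw, y, params)
                payload[target] = {"tree": tree_as_dict(rtree),
                                   "text": drv.tree_to_text(rtree)}
        artifacts["drivers"] = _write_json(out_dir / "drivers.json", payload)
        report.manifest["stages_completed"].append("drivers")

    # --- manifest -----------------------------------------------------------
    for name, path in artifacts.items():
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        report.manifest["files"][name] = {"path": str(path.relative_to(out_dir)),
                                          "sha256": digest}
    _write_json(out_dir / "manifest.json", report.manifest)
    return report
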