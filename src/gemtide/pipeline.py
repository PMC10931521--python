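"""End-to-end pipeline orchestration with a config file and manifests.

A :class:`RunConfig` collects every input path, numeric threshold and
seed; :func:`run_pipeline` executes the stages in order (simulate or
load inputs, metabolomics classification, model tailoring, TIDEs
scoring per condition, condition-specific pruning + flux sampling,
cross-condition comparison) and writes each stage's tables plus a JSON
manifest of input hashes, seeds and versions.  Re-running with an
identical config reproduces identical result tables; seeds are
mandatory (no wall-clock seeding).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .integration import (
    bray_curtis_matrix,
    ordinate_2d,
    prune_to_condition,
    rank_distinguishing_reactions,
    sample_condition,
    shared_reactions,
)
from .metabolomics import (
    AbundanceMatrix,
    classify_metabolites,
    filter_missing,
    impute_half_min,
    normalize,
    results_to_frame,
)
from .network import load_tasks, read_model
from .synth import make_bundle
from .tailoring import ConditionConstraints, add_exchanges_for_measured, apply_condition_constraints
from .tides import run_tides

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """All pipeline inputs, thresholds and seeds (YAML round-trippable)."""

    bundle_dir: str = "bundle"
    out_dir: str = "run"
    simulate: bool = True
    conditions: list[str] = field(default_factory=lambda: ["control", "treat"])
    condition_pairs: list[list[str]] = field(default_factory=lambda: [["treat", "control"]])
    fdr_threshold: float = 0.01
    task_alpha: float = 0.1
    metabolite_alpha: float = 0.1
    missing_fraction: float = 0.6
    objective_fraction: float = 0.9
    n_perm: int = 1000
    n_samples: int = 50
    thinning: int = 100
    seed: int = 1
    consumed_from_metabolomics: bool = True

    def __post_init__(self):
        for name, value, lo, hi in (
            ("fdr_threshold", self.fdr_threshold, 0, 1),
            ("task_alpha", self.task_alpha, 0, 1),
            ("metabolite_alpha", self.metabolite_alpha, 0, 1),
            ("missing_fraction", self.missing_fraction, 0, 1),
            ("objective_fraction", self.objective_fraction, 0, 1),
        ):
            if not lo <= value <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")
        if self.n_perm < 1 or self.n_samples < 1:
            raise ValueError("n_perm and n_samples must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls(**yaml.safe_load(handle))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(path)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _load_abundances(bundle: Path) -> AbundanceMatrix:
    values = pd.read_csv(bundle / "abundances.tsv", sep="\t", index_col="metabolite")
    meta = pd.read_csv(bundle / "samples.tsv", sep="\t")
    kegg = pd.read_csv(bundle / "kegg_ids.tsv", sep="\t")
    blank_rows = meta.loc[meta["is_blank"], "group"].unique()
    return AbundanceMatrix(
        values=values,
        sample_groups=dict(zip(meta["sample"], meta["group"])),
        blank_group=str(blank_rows[0]),
        kegg_ids=dict(zip(kegg["metabolite"], kegg["kegg_id"])),
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = Path(config.bundle_dir)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if config.simulate:
        make_bundle(bundle, seed=config.seed)
    model = read_model(bundle / "model.xml")
    tasks = load_tasks(bundle / "tasks.yaml")
    manifest["inputs"] = {
        name: _sha256(bundle / name)
        for name in sorted(p.name for p in bundle.iterdir() if p.is_file())
    }

    # --- metabolomics chain
    matrix = _load_abundances(bundle)
    matrix = filter_missing(matrix, config.missing_fraction)
    matrix = impute_half_min(matrix)
    matrix = normalize(matrix)
    pairs = [tuple(p) for p in config.condition_pairs]
    change_calls = classify_metabolites(matrix, pairs, alpha=config.metabolite_alpha)
    results_to_frame(change_calls).to_csv(out / "metabolite_classes.tsv", sep="\t", index=False)
    manifest["stages"]["metabolomics"] = {"n_metabolites": len(change_calls)}

    # --- tailoring: exchanges for measured metabolites, then constraints
    measured = {res.kegg_id for res in change_calls if res.kegg_id}
    tailored, ledger, counts = add_exchanges_for_measured(model, model, measured, change_calls)
    ledger.to_frame().to_csv(out / "curation_ledger.tsv", sep="\t", index=False)
    consumed: set[str] = set()
    if config.consumed_from_metabolomics:
        by_kegg = {
            res.kegg_id: res for res in change_calls if res.kegg_id is not None
        }
        for met in tailored.metabolites:
            kegg = met.annotation.get("kegg.compound")
            kegg = kegg[0] if isinstance(kegg, list) else kegg
            if met.compartment != "e" or kegg not in by_kegg:
                continue
            calls = [c for c, _ in by_kegg[kegg].vs_blank.values()]
            if "consumed" in calls:
                consumed.add(met.id)
    constraints = ConditionConstraints(consumed_metabolites=consumed)
    constrained, report = apply_condition_constraints(tailored, constraints)
    manifest["stages"]["tailoring"] = {
        "exchange_counts": counts,
        "consumed": sorted(consumed),
        "feasible": report.feasible,
        "objective_value": report.objective_value,
    }
    if not report.feasible:
        raise RuntimeError(
            f"condition constraints infeasible; blocking demands {report.blocking_demands}"
        )

    # --- TIDEs per condition
    tides_tables = []
    for i, condition in enumerate(sorted(config.conditions)):
        de_path = bundle / f"de_{condition}.tsv"
        if not de_path.exists():
            logger.warning("no DE table for condition %s; skipping TIDEs", condition)
            continue
        de = pd.read_csv(de_path, sep="\t")
        table = run_tides(
            model,
            tasks,
            de,
            fdr_threshold=config.fdr_threshold,
            n_perm=config.n_perm,
            seed=config.seed + i,
            alpha=config.task_alpha,
        )
        table.insert(0, "condition", condition)
        tides_tables.append(table)
    if tides_tables:
        pd.concat(tides_tables).to_csv(out / "tides_scores.tsv", sep="\t", index=False)
        manifest["stages"]["tides"] = {"n_rows": int(sum(len(t) for t in tides_tables))}

    # --- condition-specific models + sampling
    sample_sets = []
    for i, condition in enumerate(sorted(config.conditions)):
        tpm_path = bundle / f"tpm_{condition}.tsv"
        if not tpm_path.exists():
            continue
        tpm_table = pd.read_csv(tpm_path, sep="\t")
        tpm = dict(zip(tpm_table["gene"], tpm_table["tpm"]))
        condition_model, model_report = prune_to_condition(
            constrained,
            tpm,
            objective_fraction=config.objective_fraction,
            condition_label=condition,
        )
        samples = sample_condition(
            condition_model,
            n=config.n_samples,
            seed=config.seed + 100 + i,
            objective_fraction=config.objective_fraction,
            thinning=config.thinning,
            condition_label=condition,
        )
        samples.to_tsv(out / f"flux_samples_{condition}.tsv")
        sample_sets.append(samples)
        manifest["stages"][f"model_{condition}"] = {
            "kept": len(model_report.kept_reactions),
            "pruned": len(model_report.pruned_reactions),
            "objective_retained_fraction": model_report.objective_retained_fraction,
            "correlation_p": model_report.correlation_p,
        }

    # --- comparison
    if len(sample_sets) >= 2:
        shared = shared_reactions(sample_sets)
        distances, labels = bray_curtis_matrix(sample_sets, shared)
        coords, stress = ordinate_2d(distances, seed=config.seed)
        pd.DataFrame(
            {"sample": range(len(labels)), "condition": labels,
             "nmds1": coords[:, 0], "nmds2": coords[:, 1]}
        ).to_csv(out / "ordination.tsv", sep="\t", index=False)
        ranking = rank_distinguishing_reactions(sample_sets, seed=config.seed)
        ranking.to_frame().to_csv(out / "reaction_ranking.tsv", sep="\t", index=False)
        manifest["stages"]["comparison"] = {
            "n_shared_reactions": len(shared),
            "stress": stress,
            "top_reaction": ranking.top,
        }

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return out
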