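"""Synthetic study generator: toy network, DE tables, abundances, TPM.

Everything the pipeline consumes can be generated here with known
ground truth, emulating a paired transcriptomics + metabolomics study
of cultured cells against blank (cell-free) media:

* a toy genome-scale-style network (~45 reactions, two compartments)
  with glycolysis, two redundant respiration routes, nucleotide, lipid
  and ROS-detoxification pathways, AND/OR GPR rules throughout, and
  KEGG-annotated extracellular metabolites with exchanges;
* a catalogue of feasible metabolic tasks (ATP production, nucleotide
  synthesis, lipid synthesis, ROS detoxification);
* per-condition differential-expression tables with planted
  task-localized log fold changes and a configurable background DEG
  rate;
* metabolite x sample raw-area-count matrices (n=3 per group) with
  planted produced/consumed metabolites, engineered high-missingness
  rows, and optional missing-at-random gaps;
* per-condition TPM profiles with a planted suppressed pathway.

Defaults mirror a small in-vitro study design: 3 replicates per group,
|log2FC| = 2 planted effects, 5% background DEG rate, 90% depletion of
consumed metabolites and 5-fold accumulation of produced ones.
Regeneration with the same parameters and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import cobra
import numpy as np
import pandas as pd

from .metabolomics import AbundanceMatrix
from .network import MetabolicTask, save_tasks, write_model

__all__ = [
    "SyntheticTruth",
    "make_toy_model",
    "toy_pathways",
    "simulate_de",
    "simulate_abundances",
    "simulate_tpm",
    "make_bundle",
]

BASE_TASKS = ("atp_production", "nucleotide_synthesis", "lipid_synthesis", "ros_detoxification")


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated bundle."""

    planted_tasks: dict[str, str] = field(default_factory=dict)  # task -> increased|decreased
    planted_metabolites: dict[str, dict[str, str]] = field(default_factory=dict)
    # metabolite -> {group: produced|consumed}
    planted_pathway_per_condition: dict[str, str | None] = field(default_factory=dict)
    background_deg_rate: float = 0.05
    effect_size: float = 2.0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


# ---------------------------------------------------------------------------
# toy network


def _met(mid: str, name: str, compartment: str, kegg: str | None = None) -> cobra.Metabolite:
    met = cobra.Metabolite(mid, name=name, compartment=compartment)
    if kegg:
        met.annotation["kegg.compound"] = kegg
    return met


def _rxn(
    rid: str,
    stoich: dict[cobra.Metabolite, float],
    bounds: tuple[float, float],
    gpr: str = "",
    subsystem: str = "",
) -> cobra.Reaction:
    rxn = cobra.Reaction(rid, lower_bound=bounds[0], upper_bound=bounds[1])
    rxn.add_metabolites(stoich)
    if gpr:
        rxn.gene_reaction_rule = gpr
    if subsystem:
        rxn.subsystem = subsystem
    return rxn


def toy_pathways(n_pathways: int = 4) -> dict[str, list[str]]:
    """Gene membership of each pathway in the toy model."""
    pathways = {
        "glycolysis": ["gGLY1", "gGLY2", "gGLY3", "gGLY4", "gALA1", "gALA2", "gSER1"],
        "oxphos_a": ["gPDH1", "gPDH2", "gOXA1", "gOXA2", "gOXA3"],
        "oxphos_b": ["gOXB1", "gOXB2", "gOXB3"],
        "nucleotide": ["gNUC1", "gNUC2", "gNUC3", "gNUC4", "gNUC5", "gNUC6", "gNUC7"],
        "lipid": ["gLIP1", "gLIP2", "gLIP3", "gLIP4", "gTRlip"],
        "ros_detox": ["gROS1", "gROS2", "gROS3"],
    }
    for i in range(5, n_pathways + 1):
        pathways[f"aux_{i}"] = [f"gAUX{i}a", f"gAUX{i}b", f"gAUX{i}t"]
    return pathways


def make_toy_model(n_pathways: int = 4, seed: int = 0) -> tuple[cobra.Model, list[MetabolicTask]]:
    """Build the deterministic toy network and its task catalogue.

    ``n_pathways`` >= 2 counts the tasked pathway families beyond the
    always-present core (glycolysis + dual respiration); values above 4
    append auxiliary linear degradation pathways with their own tasks.
    The structure does not depend on ``seed`` (generation is fully
    deterministic); the argument is accepted for interface symmetry.
    """
    if n_pathways < 2:
        raise ValueError("n_pathways must be >= 2")
    model = cobra.Model("toy_heart")

    e, c = "e", "c"
    mets = {
        "glc_e": _met("glc_e", "glucose", e, "C00031"),
        "glc_c": _met("glc_c", "glucose", c, "C00031"),
        "o2_e": _met("o2_e", "oxygen", e, "C00007"),
        "o2_c": _met("o2_c", "oxygen", c, "C00007"),
        "co2_e": _met("co2_e", "carbon dioxide", e, "C00011"),
        "co2_c": _met("co2_c", "carbon dioxide", c, "C00011"),
        "lac_e": _met("lac_e", "lactate", e, "C00186"),
        "lac_c": _met("lac_c", "lactate", c, "C00186"),
        "gln_e": _met("gln_e", "glutamine", e, "C00064"),
        "gln_c": _met("gln_c", "glutamine", c, "C00064"),
        "pi_e": _met("pi_e", "phosphate", e, "C00009"),
        "pi_c": _met("pi_c", "phosphate", c, "C00009"),
        "ala_e": _met("ala_e", "alanine", e, "C00041"),
        "ala_c": _met("ala_c", "alanine", c, "C00041"),
        "ser_e": _met("ser_e", "serine", e, "C00065"),
        "ser_c": _met("ser_c", "serine", c, "C00065"),
        "fa_e": _met("fa_e", "hexadecanoate", e, "C00249"),
        "fa_c": _met("fa_c", "hexadecanoate", c, "C00249"),
        "nuc_e": _met("nuc_e", "nucleotide", e, "C00144"),
        "nuc_c": _met("nuc_c", "nucleotide", c, "C00144"),
        "lipid_e": _met("lipid_e", "lipid", e, "C00422"),
        "lipid_c": _met("lipid_c", "lipid", c, "C00422"),
        "h2o_e": _met("h2o_e", "water", e, "C00001"),
        "h2o_c": _met("h2o_c", "water", c, "C00001"),
        "ros_e": _met("ros_e", "hydrogen peroxide", e, "C00027"),
        "ros_c": _met("ros_c", "hydrogen peroxide", c, "C00027"),
        "atp_c": _met("atp_c", "ATP", c, "C00002"),
        "adp_c": _met("adp_c", "ADP", c, "C00008"),
        "pyr_c": _met("pyr_c", "pyruvate", c, "C00022"),
        "accoa_c": _met("accoa_c", "acetyl-CoA", c, "C00024"),
        "ribose_c": _met("ribose_c", "ribose-5-phosphate", c, "C00117"),
        "rna_c": _met("rna_c", "RNA (lumped)", c),
        "dna_c": _met("dna_c", "DNA (lumped)", c),
        "gsh_c": _met("gsh_c", "glutathione", c, "C00051"),
        "gssg_c": _met("gssg_c", "glutathione disulfide", c, "C00127"),
    }
    m = mets
    media = {"glc_e", "o2_e", "gln_e", "pi_e", "ala_e", "ser_e", "fa_e", "ros_e"}

    reactions: list[cobra.Reaction] = []
    # exchanges: uptake allowed only for media components
    for mid in sorted(k for k in m if k.endswith("_e")):
        lb = -10.0 if mid in media else 0.0
        reactions.append(_rxn(f"EX_{mid}", {m[mid]: -1.0}, (lb, 1000.0), subsystem="exchange"))

    transports = [
        ("GLCt", "glc_e", "glc_c", "gTRglc1 or gTRglc2", False),
        ("O2t", "o2_e", "o2_c", "gTRo2", True),
        ("CO2t", "co2_c", "co2_e", "gTRco2", True),
        ("LACt", "lac_c", "lac_e", "gTRlac", True),
        ("GLNt", "gln_e", "gln_c", "gTRgln", False),
        ("PIt", "pi_e", "pi_c", "gTRpi", True),
        ("ALAt", "ala_e", "ala_c", "gTRala", False),
        ("SERt", "ser_e", "ser_c", "gTRser", False),
        ("FAt", "fa_e", "fa_c", "gTRfa", False),
        ("NUCt", "nuc_c", "nuc_e", "gTRnuc", False),
        ("LIPIDt", "lipid_c", "lipid_e", "gTRlip", False),
        ("H2Ot", "h2o_c", "h2o_e", "gTRh2o", True),
        ("ROSt", "ros_e", "ros_c", "", False),  # diffusion, no GPR
    ]
    for rid, src, dst, gpr, reversible in transports:
        lb = -1000.0 if reversible else 0.0
        reactions.append(
            _rxn(rid, {m[src]: -1.0, m[dst]: 1.0}, (lb, 1000.0), gpr, "transport")
        )

    reactions += [
        _rxn(
            "GLYC",
            {
                m["glc_c"]: -1, m["adp_c"]: -2, m["pi_c"]: -2,
                m["pyr_c"]: 2, m["atp_c"]: 2, m["h2o_c"]: 2,
            },
            (0, 1000), "(gGLY1 and gGLY2) or gGLY3", "glycolysis",
        ),
        _rxn("LDH", {m["pyr_c"]: -1, m["lac_c"]: 1}, (0, 1000), "gGLY4", "glycolysis"),
        _rxn("ALADEG", {m["ala_c"]: -1, m["pyr_c"]: 1}, (0, 1000), "gALA1 and gALA2", "glycolysis"),
        _rxn("SERDEG", {m["ser_c"]: -1, m["pyr_c"]: 1}, (0, 1000), "gSER1", "glycolysis"),
        _rxn(
            "PDH",
            {m["pyr_c"]: -1, m["accoa_c"]: 1, m["co2_c"]: 1},
            (0, 1000), "gPDH1 and gPDH2", "respiration",
        ),
        _rxn(
            "OXPHOS_A",
            {
                m["accoa_c"]: -1, m["o2_c"]: -2, m["adp_c"]: -14, m["pi_c"]: -14,
                m["co2_c"]: 2, m["atp_c"]: 14, m["h2o_c"]: 2,
            },
            (0, 1000), "gOXA1 and (gOXA2 or gOXA3)", "respiration",
        ),
        _rxn(
            "OXPHOS_B",
            {
                m["accoa_c"]: -1, m["o2_c"]: -2, m["adp_c"]: -14, m["pi_c"]: -14,
                m["co2_c"]: 2, m["atp_c"]: 14, m["h2o_c"]: 2,
            },
            (0, 1000), "gOXB1 and (gOXB2 or gOXB3)", "respiration",
        ),
        _rxn(
            "ATPM",
            {m["atp_c"]: -1, m["adp_c"]: 1, m["pi_c"]: 1},
            (0, 1000), "", "maintenance",
        ),
        _rxn(
            "PRPP",
            {m["glc_c"]: -1, m["atp_c"]: -1, m["ribose_c"]: 1, m["adp_c"]: 1, m["pi_c"]: 1},
            (0, 1000), "gNUC1", "nucleotide",
        ),
        _rxn(
            "NUCSYN",
            {
                m["ribose_c"]: -1, m["gln_c"]: -1, m["atp_c"]: -2,
                m["nuc_c"]: 1, m["adp_c"]: 2, m["pi_c"]: 2,
            },
            (0, 1000), "(gNUC2 and gNUC3) or gNUC4", "nucleotide",
        ),
        _rxn(
            "RNASYN",
            {m["nuc_c"]: -2, m["atp_c"]: -1, m["rna_c"]: 1, m["adp_c"]: 1, m["pi_c"]: 1},
            (0, 1000), "gNUC5", "nucleotide",
        ),
        _rxn(
            "DNASYN",
            {m["nuc_c"]: -2, m["atp_c"]: -2, m["dna_c"]: 1, m["adp_c"]: 2, m["pi_c"]: 2},
            (0, 1000), "gNUC6 and gNUC7", "nucleotide",
        ),
        _rxn("DM_rna_c", {m["rna_c"]: -1}, (0, 1000), "", "maintenance"),
        _rxn("DM_dna_c", {m["dna_c"]: -1}, (0, 1000), "", "maintenance"),
        _rxn(
            "FASYN",
            {
                m["accoa_c"]: -4, m["atp_c"]: -8,
                m["fa_c"]: 1, m["adp_c"]: 8, m["pi_c"]: 8,
            },
            (0, 1000), "gLIP1 and gLIP2", "lipid",
        ),
        _rxn(
            "LIPSYN",
            {m["fa_c"]: -1, m["atp_c"]: -1, m["lipid_c"]: 1, m["adp_c"]: 1, m["pi_c"]: 1},
            (0, 1000), "gLIP3 or gLIP4", "lipid",
        ),
        _rxn(
            "ROSDETOX",
            {m["ros_c"]: -1, m["gsh_c"]: -2, m["gssg_c"]: 1, m["h2o_c"]: 2},
            (0, 1000), "gROS1", "ros_detox",
        ),
        _rxn(
            "GSHREGEN",
            {m["gssg_c"]: -1, m["atp_c"]: -1, m["gsh_c"]: 2, m["adp_c"]: 1, m["pi_c"]: 1},
            (0, 1000), "gROS2 or gROS3", "ros_detox",
        ),
    ]

    tasks = [
        MetabolicTask(
            "atp_production",
            "aerobic ATP production from glucose",
            required_inputs={"glc_e": (0, 10), "o2_e": (0, 1000)},
            required_outputs={
                "co2_e": (0, 1000), "lac_e": (0, 1000), "h2o_e": (0, 1000), "pi_e": (0, 1000),
            },
            additional_bounds={"ATPM": (1, 1000)},
            curated_reactions=["GLYC", "LDH", "PDH", "OXPHOS_A", "OXPHOS_B"],
        ),
        MetabolicTask(
            "nucleotide_synthesis",
            "nucleotide synthesis and secretion from glucose and glutamine",
            required_inputs={"glc_e": (0, 10), "gln_e": (0, 10), "o2_e": (0, 1000)},
            required_outputs={
                "nuc_e": (1, 1000), "co2_e": (0, 1000), "lac_e": (0, 1000),
                "h2o_e": (0, 1000), "pi_e": (0, 1000),
            },
            curated_reactions=["PRPP", "NUCSYN", "RNASYN", "DNASYN", "NUCt"],
        ),
        MetabolicTask(
            "lipid_synthesis",
            "lipid synthesis and secretion from glucose",
            required_inputs={"glc_e": (0, 10), "o2_e": (0, 1000)},
            required_outputs={
                "lipid_e": (1, 1000), "co2_e": (0, 1000), "lac_e": (0, 1000),
                "h2o_e": (0, 1000), "pi_e": (0, 1000),
            },
            curated_reactions=["FASYN", "LIPSYN", "LIPIDt"],
        ),
        MetabolicTask(
            "ros_detoxification",
            "detoxification of imported hydrogen peroxide",
            required_inputs={"ros_e": (1, 10), "glc_e": (0, 10), "o2_e": (0, 1000)},
            required_outputs={
                "h2o_e": (0, 1000), "co2_e": (0, 1000), "lac_e": (0, 1000), "pi_e": (0, 1000),
            },
            curated_reactions=["ROSDETOX", "GSHREGEN"],
        ),
    ]

    if n_pathways == 2:
        drop_rxns = {"FASYN", "LIPSYN", "LIPIDt", "EX_lipid_e", "EX_fa_e", "FAt",
                     "ROSDETOX", "GSHREGEN", "ROSt", "EX_ros_e"}
        reactions = [r for r in reactions if r.id not in drop_rxns]
        tasks = [t for t in tasks if t.id in ("atp_production", "nucleotide_synthesis")]
    elif n_pathways == 3:
        drop_rxns = {"ROSDETOX", "GSHREGEN", "ROSt", "EX_ros_e"}
        reactions = [r for r in reactions if r.id not in drop_rxns]
        tasks = [t for t in tasks if t.id != "ros_detoxification"]

    for i in range(5, n_pathways + 1):
        aux_e = _met(f"aux{i}_e", f"auxiliary substrate {i}", e, f"C9{i:04d}")
        aux_c = _met(f"aux{i}_c", f"auxiliary substrate {i}", c, f"C9{i:04d}")
        reactions += [
            _rxn(f"EX_aux{i}_e", {aux_e: -1.0}, (-10, 1000), subsystem="exchange"),
            _rxn(f"AUXt{i}", {aux_e: -1.0, aux_c: 1.0}, (0, 1000), f"gAUX{i}t", "transport"),
            _rxn(
                f"AUXDEG{i}",
                {aux_c: -1, m["atp_c"]: -1, m["co2_c"]: 1, m["adp_c"]: 1, m["pi_c"]: 1},
                (0, 1000), f"gAUX{i}a and gAUX{i}b", f"aux_{i}",
            ),
        ]
        tasks.append(
            MetabolicTask(
                f"aux_{i}_degradation",
                f"degradation of auxiliary substrate {i}",
                required_inputs={f"aux{i}_e": (1, 10), "glc_e": (0, 10), "o2_e": (0, 1000)},
                required_outputs={
                    "co2_e": (0, 1000), "lac_e": (0, 1000), "h2o_e": (0, 1000),
                    "pi_e": (0, 1000),
                },
                curated_reactions=[f"AUXt{i}", f"AUXDEG{i}"],
            )
        )

    model.add_reactions(reactions)
    model.objective = "ATPM"
    return model, tasks


# ---------------------------------------------------------------------------
# differential expression


def simulate_de(
    model: cobra.Model,
    planted_genes: dict[str, set[str]] | None,
    truth: SyntheticTruth,
    seed: int | None = None,
    effect_sd: float = 0.25,
    n_nonmodel_genes: int = 20,
) -> pd.DataFrame:
    """Simulate a DE table (gene, lfc, fdr) with planted task effects.

    ``planted_genes`` maps each planted task id (directions taken from
    ``truth.planted_tasks``) to its gene set; planted genes draw lfc ~
    Normal(direction x effect, ``effect_sd``) with fdr ~ U(0, 0.005).
    Background model genes become DEGs (fdr < 0.01, lfc ~ Normal(0, 1))
    at rate ``truth.background_deg_rate`` and are otherwise
    non-significant (fdr ~ U(0.2, 1)).  Non-model genes are appended to
    exercise the model-mapping filter downstream.
    """
    planted_genes = planted_genes or {}
    for task_id in planted_genes:
        if task_id not in truth.planted_tasks:
            raise ValueError(f"planted gene set for untracked task {task_id!r}")
        if truth.effect_size == 0:
            raise ValueError("planted direction requires a nonzero effect size")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    direction_sign = {"increased": 1.0, "decreased": -1.0}

    planted_lookup: dict[str, float] = {}
    for task_id, genes in planted_genes.items():
        sign = direction_sign[truth.planted_tasks[task_id]]
        for gene in genes:
            planted_lookup[gene] = sign

    rows = []
    for gene in sorted(g.id for g in model.genes):
        if gene in planted_lookup:
            lfc = rng.normal(planted_lookup[gene] * truth.effect_size, effect_sd)
            fdr = rng.uniform(0, 0.005)
        elif rng.random() < truth.background_deg_rate:
            lfc = rng.normal(0, 1)
            fdr = rng.uniform(0, 0.01)
        else:
            lfc = rng.normal(0, 0.25)
            fdr = rng.uniform(0.2, 1)
        rows.append({"gene": gene, "lfc": lfc, "fdr": fdr})
    for i in range(n_nonmodel_genes):
        rows.append(
            {"gene": f"nonmodel_{i}", "lfc": rng.normal(0, 1), "fdr": rng.uniform(0, 1)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metabolomics abundances

# measured panel: (name, kegg id or None, role)
# roles: consumed_all, produced_all, consumed_treat, produced_treat,
#        differential_only (S3C exemplar), neutral, high_missing
PANEL = [
    ("glucose", "C00031", "consumed_all"),
    ("glutamine", "C00064", "consumed_all"),
    ("alanine", "C00041", "consumed_all"),
    ("serine", "C00065", "consumed_all"),
    ("hexadecanoate", "C00249", "consumed_all"),
    ("lactate", "C00186", "produced_all"),
    ("phosphate", "C00009", "produced_all"),
    ("uracil", "C00106", "consumed_treat"),
    ("2-deoxyuridine", "C00526", "produced_treat"),
    ("erythritol", "C00503", "differential_only"),
    ("pyruvate", "C00022", "neutral"),
    ("guanosine-5-monophosphate", "C00144", "neutral"),
    ("triacylglycerol", "C00422", "neutral"),
    ("ethylmalonate", "C02441", "neutral"),
    ("xanthosine", "C01762", "high_missing"),
    ("orotate", "C00295", "high_missing"),
]


def simulate_abundances(
    groups: tuple[str, ...] = ("blank", "control", "treat"),
    n_per_group: int = 3,
    seed: int = 0,
    depletion: float = 0.9,
    production_fold: float = 4.0,
    extra_treat_depletion: float = 0.5,
    noise_sd: float = 0.2,
    missing_rate: float = 0.0,
    blank_group: str = "blank",
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Simulate a raw-area-count panel with planted metabolite changes.

    Baselines are log-normal around 1e6 area counts.  Consumed
    metabolites are scaled by (1 - depletion) relative to blank in the
    designated groups (consumed_treat roles deplete in treatment only,
    and consumed_all metabolites deplete somewhat further in treatment
    than control so treatment-vs-control contrasts exist); produced
    metabolites scale by (1 + production_fold).  The S3C exemplar
    (differential between treatment and control but overlapping a noisy
    blank baseline) gets an inflated blank variance.  Two panel rows are
    engineered above the 60% missingness threshold; additional
    missing-at-random gaps are controlled by ``missing_rate`` (default
    0: platform missingness is represented by the engineered
    low-abundance rows, see docs/methods.md).
    """
    if blank_group not in groups:
        raise ValueError("blank group must be part of the design")
    rng = np.random.default_rng(seed)
    samples = [f"{g}_{i + 1}" for g in groups for i in range(n_per_group)]
    sample_groups = {s: s.rsplit("_", 1)[0] for s in samples}
    non_blank = [g for g in groups if g != blank_group]
    treat_groups = [g for g in non_blank if g != "control"]

    truth = SyntheticTruth(seed=seed)
    values = {}
    for name, _, role in PANEL:
        baseline = float(np.exp(rng.normal(np.log(1e6), 0.5)))
        row = {}
        planted: dict[str, str] = {}
        for group in groups:
            scale = 1.0
            if group != blank_group:
                if role == "consumed_all":
                    depth = depletion
                    if group in treat_groups:
                        depth = depletion + (1 - depletion) * extra_treat_depletion
                    scale = 1 - depth
                    planted[group] = "consumed"
                elif role == "produced_all":
                    scale = 1 + production_fold
                    planted[group] = "produced"
                elif role == "consumed_treat" and group in treat_groups:
                    scale = 1 - depletion
                    planted[group] = "consumed"
                elif role == "produced_treat" and group in treat_groups:
                    scale = 1 + production_fold
                    planted[group] = "produced"
                elif role == "differential_only":
                    scale = 2.0 if group in treat_groups else 0.5
            sd = noise_sd
            if role == "differential_only" and group == blank_group:
                sd = 1.0  # wide cell-free baseline: blank contrast stays null
            for i in range(n_per_group):
                sample = f"{group}_{i + 1}"
                row[sample] = baseline * scale * float(np.exp(rng.normal(0, sd)))
        if planted:
            truth.planted_metabolites[name] = planted
        values[name] = row

    frame = pd.DataFrame.from_dict(values, orient="index")[samples]

    # engineered high-missingness rows (strictly above the 60% rule)
    n_samples = len(samples)
    n_missing = int(np.floor(0.6 * n_samples)) + 1
    for name, _, role in PANEL:
        if role == "high_missing":
            hide = rng.choice(n_samples, size=n_missing, replace=False)
            frame.loc[name, frame.columns[hide]] = np.nan
    if missing_rate > 0:
        eligible = [name for name, _, role in PANEL if role != "high_missing"]
        mask = rng.random((len(eligible), n_samples)) < missing_rate
        block = frame.loc[eligible].to_numpy(float)
        block[mask] = np.nan
        frame.loc[eligible] = block

    matrix = AbundanceMatrix(
        values=frame,
        sample_groups=sample_groups,
        blank_group=blank_group,
        kegg_ids={name: kegg for name, kegg, _ in PANEL if kegg},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# transcript abundances


def simulate_tpm(
    model: cobra.Model,
    suppressed_pathway: str | None,
    seed: int = 0,
    base_log_tpm: float = np.log(100.0),
    sigma: float = 1.0,
    suppression: float = 0.05,
    n_pathways: int = 4,
) -> pd.DataFrame:
    """Simulate a per-condition TPM table with a suppressed pathway.

    Baseline TPM ~ LogNormal(``base_log_tpm``, ``sigma``); every gene of
    the suppressed pathway is scaled by ``suppression`` (default 20-fold
    knock-down).
    """
    pathways = toy_pathways(n_pathways)
    if suppressed_pathway is not None and suppressed_pathway not in pathways:
        raise KeyError(f"unknown pathway {suppressed_pathway!r}")
    suppressed_genes = set(pathways.get(suppressed_pathway, []))
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(g.id for g in model.genes):
        tpm = float(np.exp(rng.normal(base_log_tpm, sigma)))
        if gene in suppressed_genes:
            tpm *= suppression
        rows.append({"gene": gene, "tpm": tpm})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle


def make_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_pathways: int = 4,
    conditions: dict[str, str | None] | None = None,
    planted_task: str = "nucleotide_synthesis",
    planted_direction: str = "increased",
    background_deg_rate: float = 0.05,
    effect_size: float = 2.0,
) -> SyntheticTruth:
    """Write a complete synthetic input bundle to ``out_dir``.

    Contents: model (SBML + JSON), tasks.yaml, de_<condition>.tsv,
    abundances.tsv + samples.tsv, tpm_<condition>.tsv, truth.json.
    ``conditions`` maps condition labels to the pathway suppressed in
    that condition's transcriptome (None for no suppression).
    """
    from .tides import task_reaction_set  # deferred: avoids import cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = conditions if conditions is not None else {"control": None, "treat": "oxphos_b"}

    model, tasks = make_toy_model(n_pathways=n_pathways, seed=seed)
    write_model(model, out / "model.xml")
    write_model(model, out / "model.json")
    save_tasks(tasks, out / "tasks.yaml")

    truth = SyntheticTruth(
        planted_tasks={planted_task: planted_direction},
        planted_pathway_per_condition=dict(conditions),
        background_deg_rate=background_deg_rate,
        effect_size=effect_size,
        seed=seed,
    )

    task = next(t for t in tasks if t.id == planted_task)
    planted_genes = {
        planted_task: {
            g
            for rid in task_reaction_set(model, task)
            for g in (gg.id for gg in model.reactions.get_by_id(rid).genes)
        }
    }
    rng = np.random.default_rng(seed)
    for i, condition in enumerate(sorted(conditions)):
        is_treat = condition != "control"
        de = simulate_de(
            model,
            planted_genes if is_treat else {},
            truth,
            seed=int(rng.integers(2**31)),
        )
        de.to_csv(out / f"de_{condition}.tsv", sep="\t", index=False)
        tpm = simulate_tpm(
            model,
            conditions[condition],
            seed=int(rng.integers(2**31)),
            n_pathways=n_pathways,
        )
        tpm.to_csv(out / f"tpm_{condition}.tsv", sep="\t", index=False)

    matrix, met_truth = simulate_abundances(seed=seed)
    truth.planted_metabolites = met_truth.planted_metabolites
    matrix.values.rename_axis("metabolite").to_csv(out / "abundances.tsv", sep="\t")
    meta = pd.DataFrame(
        {
            "sample": list(matrix.values.columns),
            "group": [matrix.sample_groups[s] for s in matrix.values.columns],
            "is_blank": [
                matrix.sample_groups[s] == matrix.blank_group for s in matrix.values.columns
            ],
        }
    )
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)
    kegg = pd.DataFrame(
        sorted(matrix.kegg_ids.items()), columns=["metabolite", "kegg_id"]
    )
    kegg.to_csv(out / "kegg_ids.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    return truth
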