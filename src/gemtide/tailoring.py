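"""Tissue- and condition-specific model tailoring.

Builds a tissue model from a general (species-level) model by mapping a
reference reaction list through shared identifiers, adds user-curated
species-specific reactions, adds exchange reactions for metabolites the
metabolomics data shows to be produced or consumed (KEGG-id matched),
and applies the condition constraint recipe: consumed-metabolite
exchanges opened to a lower bound of -10 (a theoretical overabundance),
an ATP-hydrolysis objective capped at 100 flux units, DNA and RNA
maintenance demands fixed at 1 unit, and internal reaction upper bounds
lifted to 1e6 so internal capacity never constrains the solution space.

Every structural change is recorded in a :class:`CurationLedger` so the
difference between input and output models is fully auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .metabolomics import MetaboliteChangeResult

logger = logging.getLogger(__name__)

__all__ = [
    "CurationEntry",
    "CurationLedger",
    "ConditionConstraints",
    "TailoringReport",
    "AmbiguousMappingError",
    "map_reference_reactions",
    "add_exchanges_for_measured",
    "apply_condition_constraints",
]


@dataclass
class CurationEntry:
    reaction_id: str
    action: str  # mapped | added_species_specific | added_exchange | bound_change |
    # unmappable | present
    reason: str
    source: str  # reference_model | general_model | metabolomics | config


@dataclass
class CurationLedger:
    entries: list[CurationEntry] = field(default_factory=list)

    def add(self, reaction_id: str, action: str, reason: str, source: str) -> None:
        self.entries.append(CurationEntry(reaction_id, action, reason, source))

    def by_action(self, action: str) -> list[CurationEntry]:
        return [e for e in self.entries if e.action == action]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reaction": e.reaction_id,
                    "action": e.action,
                    "reason": e.reason,
                    "source": e.source,
                }
                for e in self.entries
            ]
        )


@dataclass
class ConditionConstraints:
    """The condition-specific constraint recipe.

    Units are model flux units; the DNA/RNA maintenance unit is
    model-relative (1 unit of the lumped DNA/RNA pseudo-metabolite
    demand).
    """

    consumed_metabolites: set[str] = field(default_factory=set)  # extracellular met ids
    uptake_bound: float = -10.0
    objective_reaction: str = "ATPM"
    objective_upper_bound: float = 100.0
    maintenance_outputs: dict[str, float] = field(
        default_factory=lambda: {"DM_dna_c": 1.0, "DM_rna_c": 1.0}
    )
    internal_upper_bound: float = 1e6

    def __post_init__(self):
        if self.uptake_bound >= 0:
            raise ValueError("uptake_bound must be negative (uptake flux is negative)")
        for value in (self.objective_upper_bound, self.internal_upper_bound):
            if not np.isfinite(value):
                raise ValueError("bounds must be finite")


@dataclass
class TailoringReport:
    feasible: bool
    objective_value: float
    blocking_demands: list[str] = field(default_factory=list)


class AmbiguousMappingError(ValueError):
    pass


# ---------------------------------------------------------------------------


def map_reference_reactions(
    general_model: cobra.Model,
    reference_reaction_ids: set[str],
    extra_reactions: set[str] = frozenset(),
) -> tuple[cobra.Model, CurationLedger]:
    """Subset a general model to a reference reaction list plus extras.

    Reference ids absent from the general model are reported in the
    ledger as ``unmappable`` (not silently dropped); unknown extra
    reaction ids are an error.  Metabolites participating in no kept
    reaction are excluded.
    """
    general_ids = {r.id for r in general_model.reactions}
    unknown_extras = sorted(set(extra_reactions) - general_ids)
    if unknown_extras:
        raise KeyError(f"extra reactions absent from general model: {unknown_extras}")

    ledger = CurationLedger()
    tissue = cobra.Model(f"{general_model.id}_tissue")
    tissue.compartments = dict(general_model.compartments)

    for rid in sorted(reference_reaction_ids):
        if rid not in general_ids:
            ledger.add(rid, "unmappable", "reference id absent from general model", "reference_model")
            continue
        tissue.add_reactions([general_model.reactions.get_by_id(rid).copy()])
        ledger.add(rid, "mapped", "shared reaction identifier", "reference_model")
    for rid in sorted(set(extra_reactions) - set(reference_reaction_ids)):
        tissue.add_reactions([general_model.reactions.get_by_id(rid).copy()])
        ledger.add(rid, "added_species_specific", "curated species-specific addition", "config")

    # carry the objective over when its reactions survived the subsetting
    objective = {
        r.id: c
        for r, c in cobra.util.solver.linear_reaction_coefficients(general_model).items()
        if r.id in tissue.reactions
    }
    if objective:
        tissue.objective = {
            tissue.reactions.get_by_id(rid): coef for rid, coef in objective.items()
        }
    return tissue, ledger


def _kegg_of(met: cobra.Metabolite) -> str | None:
    value = met.annotation.get("kegg.compound")
    if isinstance(value, list):
        return value[0] if value else None
    return value


def _extracellular_by_kegg(model: cobra.Model, kegg_id: str) -> list[cobra.Metabolite]:
    # exchanges live on extracellular species; restrict matching there
    return [
        m
        for m in model.metabolites
        if _kegg_of(m) == kegg_id and m.compartment in ("e", "extracellular")
    ]


def _any_by_kegg(model: cobra.Model, kegg_id: str) -> list[cobra.Metabolite]:
    return [m for m in model.metabolites if _kegg_of(m) == kegg_id]


def add_exchanges_for_measured(
    model: cobra.Model,
    general_model: cobra.Model,
    measured: set[str],
    change_calls: list[MetaboliteChangeResult] | None = None,
) -> tuple[cobra.Model, CurationLedger, dict[str, int]]:
    """Add exchanges from the general model for measured metabolites.

    ``measured`` holds KEGG compound ids.  When ``change_calls`` is
    given, only metabolites with a significant produced-or-consumed call
    against blank media qualify for addition.  For each qualifying
    metabolite whose exchange exists in the general model but not in the
    tissue model, the exchange is copied over; if the tissue model has
    no reaction consuming or producing the extracellular species, the
    lexicographically first transport reaction from the general model is
    co-added so the new exchange is not dead-ended.

    Returns the extended model, a ledger, and counts: ``matched``
    (measured ids mapping to any general-model metabolite),
    ``with_exchange`` (matched ids with a general-model exchange) and
    ``added`` (exchanges newly added to the tissue model).
    """
    significant: set[str] | None = None
    if change_calls is not None:
        significant = {
            res.kegg_id
            for res in change_calls
            if res.kegg_id is not None and res.significant_vs_blank
        }

    extended = model.copy()
    ledger = CurationLedger()
    counts = {"matched": 0, "with_exchange": 0, "added": 0}

    for kegg_id in sorted(measured):
        any_match = _any_by_kegg(general_model, kegg_id)
        if not any_match:
            continue
        counts["matched"] += 1
        candidates = _extracellular_by_kegg(general_model, kegg_id)
        if len(candidates) > 1:
            raise AmbiguousMappingError(
                f"KEGG id {kegg_id} maps to several extracellular metabolites: "
                f"{sorted(m.id for m in candidates)}"
            )
        if not candidates:
            continue  # matched an internal metabolite only: no exchange possible
        met = candidates[0]
        exchange = next((r for r in met.reactions if r.boundary), None)
        if exchange is None:
            continue
        counts["with_exchange"] += 1
        if significant is not None and kegg_id not in significant:
            continue
        if exchange.id in extended.reactions:
            ledger.add(exchange.id, "present", f"exchange for {kegg_id} already present", "metabolomics")
            continue
        extended.add_reactions([exchange.copy()])
        counts["added"] += 1
        ledger.add(
            exchange.id,
            "added_exchange",
            f"measured metabolite {kegg_id} produced/consumed vs blank",
            "metabolomics",
        )
        ext_met = extended.metabolites.get_by_id(met.id)
        has_transport = any(not r.boundary for r in ext_met.reactions)
        if not has_transport:
            transports = sorted(
                (r for r in met.reactions if not r.boundary), key=lambda r: r.id
            )
            if transports:
                extended.add_reactions([transports[0].copy()])
                ledger.add(
                    transports[0].id,
                    "added_exchange",
                    f"transport chain completion for {kegg_id}",
                    "general_model",
                )
    return extended, ledger, counts


def apply_condition_constraints(
    model: cobra.Model,
    cc: ConditionConstraints,
    auto_create_demands: bool = False,
) -> tuple[cobra.Model, TailoringReport]:
    """Apply the condition constraint recipe; returns (model, report).

    The report flags infeasibility and names the maintenance demands
    whose individual relaxation restores feasibility.
    """
    out = model.copy()

    # internal reaction capacity: lift upper bounds so that internal
    # fluxes never constrain the solution space (objective and
    # maintenance demands keep their dedicated bounds)
    protected = {cc.objective_reaction, *cc.maintenance_outputs}
    for rxn in out.reactions:
        if rxn.boundary or rxn.id in protected:
            continue
        rxn.upper_bound = cc.internal_upper_bound

    for met_id in sorted(cc.consumed_metabolites):
        if met_id not in out.metabolites:
            raise KeyError(f"consumed metabolite {met_id!r} not in model")
        met = out.metabolites.get_by_id(met_id)
        exchange = next((r for r in met.reactions if r.boundary), None)
        if exchange is None:
            raise KeyError(f"consumed metabolite {met_id!r} has no exchange reaction")
        exchange.lower_bound = cc.uptake_bound

    if cc.objective_reaction not in out.reactions:
        raise KeyError(f"objective reaction {cc.objective_reaction!r} not in model")
    objective_rxn = out.reactions.get_by_id(cc.objective_reaction)
    objective_rxn.upper_bound = cc.objective_upper_bound
    out.objective = objective_rxn

    for rxn_id, units in cc.maintenance_outputs.items():
        if rxn_id not in out.reactions:
            if not auto_create_demands:
                raise KeyError(
                    f"maintenance demand {rxn_id!r} missing and auto-creation disabled"
                )
            met_id = rxn_id.removeprefix("DM_")
            demand = out.add_boundary(out.metabolites.get_by_id(met_id), type="demand")
            demand.id = rxn_id
            out.repair()
        out.reactions.get_by_id(rxn_id).bounds = (units, units)

    value = out.slim_optimize(error_value=float("nan"))
    if value is not None and not np.isnan(value):
        return out, TailoringReport(feasible=True, objective_value=float(value))

    blocking = []
    for rxn_id in cc.maintenance_outputs:
        with out:
            out.reactions.get_by_id(rxn_id).bounds = (0.0, cc.maintenance_outputs[rxn_id])
            relaxed = out.slim_optimize(error_value=float("nan"))
        if relaxed is not None and not np.isnan(relaxed):
            blocking.append(rxn_id)
    logger.warning(
        "condition constraints leave the model infeasible; blocking demands: %s", blocking
    )
    return out, TailoringReport(
        feasible=False, objective_value=float("nan"), blocking_demands=blocking
    )
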