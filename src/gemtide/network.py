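"""Genome-scale metabolic network handling: IO, FBA/pFBA, tasks, sampling.

The in-memory network container is :class:`cobra.Model`; this module
adds the thin result types and operations the rest of the pipeline is
written against.  Flux balance analysis (FBA) maximizes a linear
objective c'v subject to steady state S.v = 0 and reaction bounds;
parsimonious FBA (pFBA) additionally minimizes total absolute flux at a
fraction of that optimum.  Metabolic tasks are input/output requirements
(minimum uptakes and secretions with all other boundary reactions
closed) whose feasibility a model must satisfy.  Flux sampling draws
feasible flux vectors from the constraint polytope with a seeded
hit-and-run sampler (ACHR).

Sign convention: exchange flux < 0 is uptake, > 0 is secretion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import numpy as np
import pandas as pd
import yaml
from cobra.flux_analysis import pfba as _cobra_pfba
from cobra.sampling import ACHRSampler
from cobra.util.array import create_stoichiometric_matrix
from cobra.util.solver import linear_reaction_coefficients

logger = logging.getLogger(__name__)

STEADY_STATE_TOL = 1e-6
BOUND_TOL = 1e-9
ACTIVE_FLUX_TOL = 1e-9

__all__ = [
    "MetabolicTask",
    "FluxDistribution",
    "FluxSampleSet",
    "ModelValidationError",
    "read_model",
    "write_model",
    "validate_model",
    "fba",
    "pfba",
    "check_task",
    "flux_sample",
    "load_tasks",
    "save_tasks",
]


class ModelValidationError(ValueError):
    pass


@dataclass
class MetabolicTask:
    """A required metabolic capability, e.g. ATP production from glucose.

    ``required_inputs``/``required_outputs`` map extracellular metabolite
    ids to (min, max) uptake/secretion ranges, in flux units.  All
    boundary reactions not named by the task are closed while checking
    it.  ``additional_bounds`` may override internal reaction bounds
    (e.g. force flux through an ATP-hydrolysis demand).
    """

    id: str
    description: str = ""
    required_inputs: dict[str, tuple[float, float]] = field(default_factory=dict)
    required_outputs: dict[str, tuple[float, float]] = field(default_factory=dict)
    additional_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    curated_reactions: list[str] | None = None

    def __post_init__(self):
        for name, table in (
            ("required_inputs", self.required_inputs),
            ("required_outputs", self.required_outputs),
            ("additional_bounds", self.additional_bounds),
        ):
            for key, (lo, hi) in table.items():
                if lo > hi:
                    raise ValueError(f"{self.id}: {name}[{key}] has min > max")


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def validate(self, model: cobra.Model) -> None:
        """Assert steady state and bound feasibility against ``model``."""
        if self.status != "optimal":
            return
        v = np.array([self.fluxes[r.id] for r in model.reactions])
        S = create_stoichiometric_matrix(model)
        imbalance = np.max(np.abs(S @ v)) if v.size else 0.0
        if imbalance > STEADY_STATE_TOL:
            raise ModelValidationError(f"steady-state violation: {imbalance:.3g}")
        for rxn in model.reactions:
            flux = self.fluxes[rxn.id]
            if flux < rxn.lower_bound - BOUND_TOL or flux > rxn.upper_bound + BOUND_TOL:
                raise ModelValidationError(
                    f"{rxn.id}: flux {flux:.6g} outside [{rxn.lower_bound}, {rxn.upper_bound}]"
                )


@dataclass
class FluxSampleSet:
    """Reaction-by-sample flux matrix for one condition model."""

    condition_label: str
    reaction_ids: list[str]
    samples: np.ndarray  # n_samples x n_reactions
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, condition_label: str = "", seed: int | None = None):
        frame = pd.read_csv(path, sep="\t")
        return cls(condition_label, list(frame.columns), frame.to_numpy(float), seed)

    def validate(self, model: cobra.Model) -> None:
        S = create_stoichiometric_matrix(model)
        order = [self.reaction_ids.index(r.id) for r in model.reactions]
        lbs = np.array([r.lower_bound for r in model.reactions])
        ubs = np.array([r.upper_bound for r in model.reactions])
        for i, row in enumerate(self.samples):
            v = row[order]
            imbalance = np.max(np.abs(S @ v))
            if imbalance > STEADY_STATE_TOL:
                raise ModelValidationError(f"sample {i}: steady-state violation {imbalance:.3g}")
            if np.any(v < lbs - 1e-6) or np.any(v > ubs + 1e-6):
                raise ModelValidationError(f"sample {i}: bound violation")


# ---------------------------------------------------------------------------
# IO


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Read an SBML (level 3 / FBC) or JSON model and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        model = cobra.io.read_sbml_model(str(path))
    elif fmt == "json":
        model = cobra.io.load_json_model(str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    validate_model(model)
    return model


def write_model(model: cobra.Model, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif fmt == "json":
        cobra.io.save_json_model(model, str(path), pretty=True)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def validate_model(model: cobra.Model) -> None:
    """Check structural invariants (bounds ordered, non-empty stoichiometry)."""
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(f"{rxn.id}: lower bound exceeds upper bound")
        if len(rxn.metabolites) == 0:
            raise ModelValidationError(f"{rxn.id}: empty stoichiometry")


# ---------------------------------------------------------------------------
# LP operations


def _solution_status(value: float | None, model: cobra.Model) -> str:
    if value is None or np.isnan(value):
        status = model.solver.status
        return "unbounded" if status == "unbounded" else "infeasible"
    return "optimal"


def fba(model: cobra.Model) -> FluxDistribution:
    """Solve the flux balance LP for the model's current objective."""
    if not linear_reaction_coefficients(model):
        raise ValueError("model has an empty objective")
    with model:
        value = model.slim_optimize(error_value=float("nan"))
        status = "optimal"
        if value is None:
            status = _solution_status(None, model)
            return FluxDistribution({}, float("nan"), status)
        solution = model.optimize()
        return FluxDistribution(dict(solution.fluxes), float(solution.objective_value), "optimal")


def pfba(model: cobra.Model, objective_fraction: float = 1.0) -> FluxDistribution:
    """Minimize total |flux| subject to objective >= fraction * optimum."""
    if not 0 < objective_fraction <= 1:
        raise ValueError("objective_fraction must be in (0, 1]")
    coeffs = linear_reaction_coefficients(model)
    with model:
        try:
            solution = _cobra_pfba(model, fraction_of_optimum=objective_fraction)
        except cobra.exceptions.Infeasible:
            return FluxDistribution({}, float("nan"), "infeasible")
        objective_value = sum(c * solution.fluxes[r.id] for r, c in coeffs.items())
        return FluxDistribution(dict(solution.fluxes), float(objective_value), "optimal")


def _exchange_for(model: cobra.Model, metabolite_id: str) -> cobra.Reaction | None:
    met = model.metabolites.get_by_id(metabolite_id)
    for rxn in met.reactions:
        if rxn.boundary:
            return rxn
    return None


def _apply_task(model: cobra.Model, task: MetabolicTask) -> list[cobra.Reaction]:
    """Impose a task inside an active model context; returns output exchanges."""
    for rxn in model.boundary:
        rxn.bounds = (0.0, 0.0)
    outputs = []
    for met_id, (lo, hi) in task.required_inputs.items():
        if met_id not in model.metabolites:
            raise KeyError(f"task {task.id}: unknown metabolite {met_id!r}")
        rxn = _exchange_for(model, met_id)
        if rxn is None:
            rxn = model.add_boundary(model.metabolites.get_by_id(met_id), type="exchange")
        rxn.bounds = (-hi, -lo)  # uptake is negative flux
    for met_id, (lo, hi) in task.required_outputs.items():
        if met_id not in model.metabolites:
            raise KeyError(f"task {task.id}: unknown metabolite {met_id!r}")
        rxn = _exchange_for(model, met_id)
        if rxn is None:
            rxn = model.add_boundary(model.metabolites.get_by_id(met_id), type="exchange")
        rxn.bounds = (lo, hi)
        outputs.append(rxn)
    for rxn_id, bounds in task.additional_bounds.items():
        model.reactions.get_by_id(rxn_id).bounds = bounds
    return outputs


def check_task(
    model: cobra.Model, task: MetabolicTask, objective_fraction: float = 1.0
) -> tuple[bool, set[str]]:
    """Test whether the model can complete a metabolic task.

    All boundary reactions outside the task are closed; required uptake
    and secretion ranges are imposed (exchanges are added temporarily if
    missing).  Feasibility is an LP feasibility check; the active
    reaction set comes from the parsimonious (minimum total flux)
    solution of the task LP, maximizing total required secretion.
    """
    with model:
        outputs = _apply_task(model, task)
        # objective: total secretion of required outputs, plus any forced
        # internal demand; a pure feasibility problem otherwise
        if outputs:
            model.objective = sum(r.flux_expression for r in outputs)
        value = model.slim_optimize(error_value=float("nan"))
        if value is None or np.isnan(value):
            return False, set()
        solution = _cobra_pfba(model, fraction_of_optimum=objective_fraction)
        active = {
            rid for rid, flux in solution.fluxes.items() if abs(flux) > ACTIVE_FLUX_TOL
        }
        return True, active


def flux_sample(
    model: cobra.Model,
    n: int = 50,
    seed: int | None = None,
    thinning: int = 100,
    condition_label: str = "",
) -> FluxSampleSet:
    """Draw ``n`` feasible flux vectors by seeded hit-and-run (ACHR).

    Identical model + seed yields an identical matrix.  Raises if the
    model is infeasible before any sampling is attempted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    with model:
        model.objective = model.problem.Objective(0)
        feasible = model.slim_optimize(error_value=float("nan"))
    if feasible is None or np.isnan(feasible):
        raise ModelValidationError("model is infeasible; cannot sample")
    try:
        sampler = ACHRSampler(model, thinning=thinning, seed=seed)
    except ValueError as err:
        if "single point" not in str(err):
            raise
        # fully determined network: the polytope is one vertex, so every
        # sample is that unique flux distribution
        with model:
            model.objective = model.problem.Objective(0)
            solution = model.optimize()
        row = np.array([solution.fluxes[r.id] for r in model.reactions])
        return FluxSampleSet(
            condition_label, [r.id for r in model.reactions], np.tile(row, (n, 1)), seed
        )
    frame = sampler.sample(n)
    return FluxSampleSet(condition_label, list(frame.columns), frame.to_numpy(float), seed)


# ---------------------------------------------------------------------------
# Task catalogue IO (YAML)


def load_tasks(path: str | Path) -> list[MetabolicTask]:
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    tasks = []
    for entry in raw["tasks"]:
        tasks.append(
            MetabolicTask(
                id=entry["id"],
                description=entry.get("description", ""),
                required_inputs={k: tuple(v) for k, v in entry.get("inputs", {}).items()},
                required_outputs={k: tuple(v) for k, v in entry.get("outputs", {}).items()},
                additional_bounds={
                    k: tuple(v) for k, v in entry.get("additional_bounds", {}).items()
                },
                curated_reactions=entry.get("curated_reactions"),
            )
        )
    return tasks


def save_tasks(tasks: Iterable[MetabolicTask], path: str | Path) -> None:
    payload = {
        "tasks": [
            {
                "id": t.id,
                "description": t.description,
                "inputs": {k: list(v) for k, v in t.required_inputs.items()},
                "outputs": {k: list(v) for k, v in t.required_outputs.items()},
                "additional_bounds": {k: list(v) for k, v in t.additional_bounds.items()},
                **(
                    {"curated_reactions": list(t.curated_reactions)}
                    if t.curated_reactions
                    else {}
                ),
            }
            for t in tasks
        ]
    }
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)
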