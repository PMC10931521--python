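"""Task scores Inferred by Differential Expression (TIDEs).

TIDEs overlays differential-expression evidence on a genome-scale
metabolic network at the level of metabolic tasks.  Genes with FDR below
a threshold (default 0.01) carry their log2 fold change as a weight and
all other genes carry 0; weights propagate through GPR rules to
reactions (see :mod:`gemtide.gpr`); a task's score is the arithmetic
mean reaction weight over the reactions required to complete it.
Significance comes from a permutation null in which the multiset of
gene weights is reshuffled uniformly across the model's genes (default
1000 shuffles), recomputing reaction and task scores each time.

Two one-sided empirical p-values (add-one corrected) are reported; the
combined significance call doubles the smaller one (a two-sided-style
correction), so that under a structureless null the flagged fraction at
alpha matches alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import cobra
import numpy as np
import pandas as pd

from .gpr import GPRExpression, parse_gpr, reaction_weight_matrix
from .network import MetabolicTask, check_task

logger = logging.getLogger(__name__)

__all__ = [
    "TaskScoreResult",
    "gene_weights_from_de",
    "task_reaction_set",
    "task_score",
    "permutation_test",
    "run_tides",
]


@dataclass
class TaskScoreResult:
    task_id: str
    observed_score: float
    null_scores: np.ndarray
    p_up: float
    p_down: float
    p_value: float  # two-sided-style combined p = min(1, 2*min(p_up, p_down))
    direction: str  # increased | decreased | none
    n_reactions_scored: int

    @property
    def significant(self) -> bool:
        return self.direction != "none"


def gene_weights_from_de(
    de: pd.DataFrame,
    model: cobra.Model,
    fdr_threshold: float = 0.01,
) -> dict[str, float]:
    """Convert a DE table (gene, lfc, fdr columns) to gene weights.

    A gene with FDR < threshold is assigned its log fold change as a
    weight and 0 otherwise; only genes present in the model are kept.
    """
    required = {"gene", "lfc", "fdr"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    if de["gene"].duplicated().any():
        dupes = sorted(de.loc[de["gene"].duplicated(), "gene"].unique())
        raise ValueError(f"duplicate gene rows in DE table: {dupes[:5]}")
    if ((de["fdr"] < 0) | (de["fdr"] > 1)).any():
        raise ValueError("FDR values must lie in [0, 1]")
    model_genes = {g.id for g in model.genes}
    kept = de[de["gene"].isin(model_genes)]
    dropped = len(de) - len(kept)
    if dropped:
        logger.info("dropped %d DE genes absent from the model", dropped)
    return {
        row.gene: (float(row.lfc) if row.fdr < fdr_threshold else 0.0)
        for row in kept.itertuples()
    }


def _gpr_of(model: cobra.Model, rxn_id: str) -> GPRExpression | None:
    return parse_gpr(model.reactions.get_by_id(rxn_id).gene_reaction_rule)


def task_reaction_set(
    model: cobra.Model,
    task: MetabolicTask,
    curated: list[str] | None = None,
) -> list[str]:
    """Reactions over which a task is scored, in deterministic order.

    Default: the GPR-bearing reactions active in the parsimonious
    solution of the task LP.  A curated per-task reaction list (from the
    task itself or the ``curated`` argument) overrides that.
    """
    curated = curated if curated is not None else task.curated_reactions
    if curated is not None:
        unknown = [r for r in curated if r not in model.reactions]
        if unknown:
            raise KeyError(f"task {task.id}: unknown curated reactions {unknown}")
        return list(curated)
    feasible, active = check_task(model, task)
    if not feasible:
        raise ValueError(f"task {task.id!r} is infeasible in this model")
    with_gpr = [
        rid for rid in sorted(active) if model.reactions.get_by_id(rid).gene_reaction_rule
    ]
    return with_gpr


def task_score(
    reaction_ids: list[str],
    model: cobra.Model,
    weights: dict[str, float],
    strategy: str = "magnitude",
) -> float:
    """Mean propagated weight over a task's reactions (zeros included)."""
    if not reaction_ids:
        raise ValueError("cannot score a task with an empty reaction set")
    genes = sorted({g.id for g in model.genes})
    gene_index = {g: i for i, g in enumerate(genes)}
    row = np.array([[weights.get(g, 0.0) for g in genes]])
    values = [
        reaction_weight_matrix(_gpr_of(model, rid), row, gene_index, strategy=strategy)[0]
        for rid in reaction_ids
    ]
    return float(np.mean(values))


def permutation_test(
    task: MetabolicTask,
    model: cobra.Model,
    weights: dict[str, float],
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.1,
    reaction_ids: list[str] | None = None,
    strategy: str = "magnitude",
) -> TaskScoreResult:
    """Permutation significance for one task score.

    Each permutation reassigns the multiset of gene weights uniformly at
    random across the model's gene set and recomputes the task score.
    p_up = (1 + #{null >= observed}) / (n_perm + 1); p_down analogous
    with <=.  The direction call uses the doubled smaller p against
    ``alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if reaction_ids is None:
        reaction_ids = task_reaction_set(model, task)
    if not reaction_ids:
        raise ValueError(f"task {task.id!r} has no GPR-bearing reactions to score")

    genes = sorted({g.id for g in model.genes})
    gene_index = {g: i for i, g in enumerate(genes)}
    base = np.array([weights.get(g, 0.0) for g in genes], float)
    exprs = [_gpr_of(model, rid) for rid in reaction_ids]

    rng = np.random.default_rng(seed)
    perm_rows = np.empty((n_perm + 1, len(genes)))
    perm_rows[0] = base  # row 0 = observed assignment
    for i in range(1, n_perm + 1):
        perm_rows[i] = base[rng.permutation(len(genes))]

    reaction_values = np.stack(
        [reaction_weight_matrix(e, perm_rows, gene_index, strategy=strategy) for e in exprs]
    )  # n_reactions x (n_perm + 1)
    scores = reaction_values.mean(axis=0)
    observed, null = float(scores[0]), scores[1:]

    p_up = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    p_down = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    p_value = min(1.0, 2 * min(p_up, p_down))
    if p_value < alpha:
        direction = "increased" if p_up <= p_down else "decreased"
    else:
        direction = "none"
    return TaskScoreResult(
        task_id=task.id,
        observed_score=observed,
        null_scores=null,
        p_up=p_up,
        p_down=p_down,
        p_value=p_value,
        direction=direction,
        n_reactions_scored=len(reaction_ids),
    )


def run_tides(
    model: cobra.Model,
    tasks: list[MetabolicTask],
    de: pd.DataFrame,
    fdr_threshold: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.1,
    strategy: str = "magnitude",
) -> pd.DataFrame:
    """Score every task in the catalogue against one DE table.

    Returns one row per task (infeasible or GPR-free tasks are skipped
    with a logged reason).  Significance at ``alpha`` appears as a flag
    column; no rows are filtered.
    """
    weights = gene_weights_from_de(de, model, fdr_threshold)
    rows = []
    rng = np.random.default_rng(seed)
    for task in tasks:
        try:
            reaction_ids = task_reaction_set(model, task)
        except (ValueError, KeyError) as err:
            logger.warning("skipping task %s: %s", task.id, err)
            continue
        if not reaction_ids:
            logger.warning("skipping task %s: no GPR-bearing reactions", task.id)
            continue
        result = permutation_test(
            task,
            model,
            weights,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
            alpha=alpha,
            reaction_ids=reaction_ids,
            strategy=strategy,
        )
        rows.append(
            {
                "task": task.id,
                "score": result.observed_score,
                "p_up": result.p_up,
                "p_down": result.p_down,
                "p_value": result.p_value,
                "direction": result.direction,
                "significant": result.significant,
                "n_reactions": result.n_reactions_scored,
            }
        )
    return pd.DataFrame(rows)
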