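"""Metabolomics preprocessing and produced/consumed classification.

The chain mirrors common practice for untargeted raw-area-count panels
measured in spent media against cell-free (blank) media controls:

1. remove metabolites with more than 60% missing values (strictly
   greater; a metabolite missing in exactly 60% of samples is kept);
2. impute remaining missing values as half the metabolite's minimum
   observed raw area count;
3. log-scale and center within each metabolite (mean-centering by
   default; median optional);
4. Mann-Whitney U tests of each condition group against the blank
   group (produced/consumed) and of each treatment against its control;
5. Benjamini-Hochberg correction within each contrast family, calls at
   FDR < 0.1.

A metabolite significantly above blank is *produced*, below blank
*consumed*.  A metabolite never significant against blank but shifted
between treatment and control is *differential without blank
significance* — its direction (production vs consumption) cannot be
determined.

Note on small samples: with 3 vs 3 samples and no ties the smallest
attainable exact two-sided Mann-Whitney p is 0.1, so blank-media calls
at BH-FDR < 0.1 are unattainable in exact mode; the classification
chain therefore defaults to the normal approximation without continuity
correction (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "MetaboliteChangeResult",
    "filter_missing",
    "impute_half_min",
    "normalize",
    "mann_whitney",
    "bh_adjust",
    "classify_metabolites",
    "results_to_frame",
]


@dataclass
class AbundanceMatrix:
    """Metabolite x sample raw area counts with group labels.

    ``values`` rows are metabolites, columns samples; NaN marks a
    missing measurement.  ``sample_groups`` maps every sample to a group
    label; ``blank_group`` names the cell-free control group.  ``stage``
    tracks the preprocessing state (raw -> filtered -> imputed ->
    normalized) so stages cannot be applied out of order or twice.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    blank_group: str = "blank"
    kegg_ids: dict[str, str] = field(default_factory=dict)
    stage: str = "raw"

    def __post_init__(self):
        missing_labels = [s for s in self.values.columns if s not in self.sample_groups]
        if missing_labels:
            raise ValueError(f"samples without group labels: {missing_labels}")
        if self.blank_group not in set(self.sample_groups.values()):
            raise ValueError(f"no samples in blank group {self.blank_group!r}")
        if self.stage != "normalized" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw area counts must be nonnegative")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for sample in self.values.columns:
            seen.setdefault(self.sample_groups[sample], None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.sample_groups.values()):
            raise KeyError(f"unknown group label {group!r}")
        return [s for s in self.values.columns if self.sample_groups[s] == group]


@dataclass
class MetaboliteChangeResult:
    """Per-metabolite classification against blank media and controls."""

    metabolite: str
    kegg_id: str | None
    vs_blank: dict[str, tuple[str, float]]  # group -> (produced|consumed|unchanged, fdr)
    treatment_vs_control: dict[tuple[str, str], tuple[str, float]]
    # (treatment, control) -> (higher|lower|unchanged, fdr)
    class_label: str
    # consumed_only | produced_or_consumed |
    # differential_without_blank_significance | unchanged

    @property
    def significant_vs_blank(self) -> bool:
        return any(call != "unchanged" for call, _ in self.vs_blank.values())


# ---------------------------------------------------------------------------
# preprocessing stages


def filter_missing(matrix: AbundanceMatrix, max_missing_fraction: float = 0.6) -> AbundanceMatrix:
    """Drop metabolites with missing fraction strictly greater than the cap."""
    if matrix.stage != "raw":
        raise ValueError(f"filter_missing expects a raw matrix, got stage {matrix.stage!r}")
    frac = matrix.values.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "removed %d metabolites with > %.0f%% missing values",
            removed,
            100 * max_missing_fraction,
        )
    return replace(matrix, values=matrix.values.loc[keep].copy(), stage="filtered")


def impute_half_min(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Impute each missing value as half the metabolite's observed minimum."""
    if matrix.stage != "filtered":
        raise ValueError(f"impute_half_min expects a filtered matrix, got {matrix.stage!r}")
    values = matrix.values.copy()
    row_min = values.min(axis=1, skipna=True)
    if row_min.isna().any():
        offenders = list(values.index[row_min.isna()])
        raise ValueError(f"metabolites with no observed values: {offenders}")
    for met in values.index:
        row = values.loc[met]
        values.loc[met] = row.fillna(0.5 * row_min[met])
    return replace(matrix, values=values, stage="imputed")


def normalize(
    matrix: AbundanceMatrix, log_base: float = 2.0, center: str = "mean"
) -> AbundanceMatrix:
    """Log-scale and center within each metabolite.

    Not idempotent; guarded by the stage flag so it can only follow
    imputation (or a complete, missing-free filtered matrix).
    """
    if matrix.stage == "normalized":
        raise ValueError("matrix is already normalized")
    if matrix.stage not in ("imputed", "filtered"):
        raise ValueError(f"normalize expects an imputed matrix, got {matrix.stage!r}")
    if matrix.values.isna().any().any():
        raise ValueError("missing values present; impute before normalizing")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    values = matrix.values.to_numpy(float)
    if (values <= 0).any():
        raise ValueError("all values must be positive before log-scaling")
    logged = np.log(values) / np.log(log_base)
    centers = logged.mean(axis=1) if center == "mean" else np.median(logged, axis=1)
    out = pd.DataFrame(
        logged - centers[:, None], index=matrix.values.index, columns=matrix.values.columns
    )
    return replace(matrix, values=out, stage="normalized")


# ---------------------------------------------------------------------------
# statistics


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (midranks under ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return r_x - len(x) * (len(x) + 1) / 2


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by full enumeration of group labelings.

    Handles ties through midranks; the two-sided p doubles the smaller
    tail (capped at 1), the convention under which x=[1,2,3] vs
    y=[4,5,6] gives p = 2 * (1/20) = 0.1.
    """
    n_x = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    observed = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    null = np.array(
        [
            ranks[list(combo)].sum() - n_x * (n_x + 1) / 2
            for combo in itertools.combinations(range(len(pooled)), n_x)
        ]
    )
    tol = 1e-9
    p_low = np.mean(null <= observed + tol)
    p_high = np.mean(null >= observed - tol)
    return float(observed), float(min(1.0, 2 * min(p_low, p_high)))


def mann_whitney(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "auto",
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    ``mode='exact'`` enumerates the full permutation distribution of U
    (midranks for ties); ``'asymptotic'`` uses the normal approximation
    with tie correction (and continuity correction when ``continuity``).
    ``'auto'`` picks exact when min(n) <= 8.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both sample vectors must be non-empty")
    if mode == "auto":
        mode = "exact" if min(x.size, y.size) <= 8 else "asymptotic"
    if mode == "exact":
        return _exact_mwu(x, y)
    if mode != "asymptotic":
        raise ValueError(f"unknown mode {mode!r}")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return _u_statistic(x, y), 1.0  # degenerate: all values tied
    result = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=continuity
    )
    return float(result.statistic), float(result.pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving output)."""
    pvalues = np.asarray(pvalues, float)
    if pvalues.size == 0:
        return pvalues.copy()
    if np.any((pvalues < 0) | (pvalues > 1)) or np.any(np.isnan(pvalues)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# classification


def classify_metabolites(
    matrix: AbundanceMatrix,
    condition_pairs: list[tuple[str, str]],
    alpha: float = 0.1,
    test_mode: str = "asymptotic",
    continuity: bool = False,
) -> list[MetaboliteChangeResult]:
    """Classify every metabolite from a *normalized* matrix.

    ``condition_pairs`` lists (treatment, control) group pairs.  Tests
    run for every non-blank group against blank and for every listed
    pair; BH correction is applied within each contrast family (all
    metabolites x one contrast); calls use strict FDR < ``alpha``.

    The default test is the tie-corrected normal approximation without
    continuity correction: with n=3 per group neither the exact
    enumeration (p floor 0.1) nor the continuity-corrected normal
    approximation can clear BH-FDR < 0.1 (see module docstring).
    """
    if matrix.stage != "normalized":
        raise ValueError("classification requires a normalized matrix")
    for treatment, control in condition_pairs:
        for group in (treatment, control):
            if group not in matrix.groups:
                raise KeyError(f"unknown condition label {group!r}")

    mets = list(matrix.values.index)
    blank = matrix.values[matrix.samples_in(matrix.blank_group)].to_numpy(float)
    groups = [g for g in matrix.groups if g != matrix.blank_group]

    # vs-blank contrasts, one BH family per group
    blank_calls: dict[str, dict[str, tuple[str, float]]] = {m: {} for m in mets}
    for group in groups:
        data = matrix.values[matrix.samples_in(group)].to_numpy(float)
        pvals = np.array(
            [
                mann_whitney(data[i], blank[i], mode=test_mode, continuity=continuity)[1]
                for i in range(len(mets))
            ]
        )
        fdrs = bh_adjust(pvals)
        for i, met in enumerate(mets):
            if fdrs[i] < alpha:
                call = "produced" if data[i].mean() > blank[i].mean() else "consumed"
            else:
                call = "unchanged"
            blank_calls[met][group] = (call, float(fdrs[i]))

    # treatment-vs-control contrasts, one BH family per pair
    pair_calls: dict[str, dict[tuple[str, str], tuple[str, float]]] = {m: {} for m in mets}
    for treatment, control in condition_pairs:
        t_data = matrix.values[matrix.samples_in(treatment)].to_numpy(float)
        c_data = matrix.values[matrix.samples_in(control)].to_numpy(float)
        pvals = np.array(
            [
                mann_whitney(t_data[i], c_data[i], mode=test_mode, continuity=continuity)[1]
                for i in range(len(mets))
            ]
        )
        fdrs = bh_adjust(pvals)
        for i, met in enumerate(mets):
            if fdrs[i] < alpha:
                call = "higher" if t_data[i].mean() > c_data[i].mean() else "lower"
            else:
                call = "unchanged"
            pair_calls[met][(treatment, control)] = (call, float(fdrs[i]))

    results = []
    for met in mets:
        significant_blank = [c for c, _ in blank_calls[met].values() if c != "unchanged"]
        significant_pair = [c for c, _ in pair_calls[met].values() if c != "unchanged"]
        if significant_blank:
            if all(c == "consumed" for c in significant_blank):
                label = "consumed_only"
            else:
                label = "produced_or_consumed"
        elif significant_pair:
            label = "differential_without_blank_significance"
        else:
            label = "unchanged"
        results.append(
            MetaboliteChangeResult(
                metabolite=met,
                kegg_id=matrix.kegg_ids.get(met),
                vs_blank=blank_calls[met],
                treatment_vs_control=pair_calls[met],
                class_label=label,
            )
        )
    return results


def results_to_frame(results: list[MetaboliteChangeResult]) -> pd.DataFrame:
    """Tidy TSV-ready table: one row per metabolite x contrast."""
    rows = []
    for res in results:
        for group, (call, fdr) in res.vs_blank.items():
            rows.append(
                {
                    "metabolite": res.metabolite,
                    "kegg_id": res.kegg_id,
                    "contrast": f"{group}_vs_blank",
                    "call": call,
                    "fdr": fdr,
                    "class": res.class_label,
                }
            )
        for (treatment, control), (call, fdr) in res.treatment_vs_control.items():
            rows.append(
                {
                    "metabolite": res.metabolite,
                    "kegg_id": res.kegg_id,
                    "contrast": f"{treatment}_vs_{control}",
                    "call": call,
                    "fdr": fdr,
                    "class": res.class_label,
                }
            )
    return pd.DataFrame(rows)
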