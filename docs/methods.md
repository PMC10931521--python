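# Methods

`gemtide` implements a joint analysis of paired transcriptomics and
metabolomics data on a genome-scale metabolic network (GEM): metabolic-task
scoring of differential expression with a permutation null, classification of
measured metabolites as produced or consumed against blank media,
metabolite-driven model tailoring, and transcript-guided condition-specific
flux sampling with reaction-level comparison. This note records the models,
the tunable parameters, and the design choices made where the design was
genuinely open.

## Network layer

Networks are handled as `cobra.Model` objects; SBML level 3 (with the FBC
package for bounds, gene associations and objectives) is the interchange
format and cobrapy's JSON dialect the convenient alternative. Flux balance
analysis (FBA) maximizes a linear objective c'v subject to steady state
S·v = 0 and reaction bounds; parsimonious FBA (pFBA) additionally minimizes
Σ|v| subject to retaining a fraction of the FBA optimum. Solutions are
checked against a steady-state tolerance of 1e-6 (infinity norm of S·v) and a
bound tolerance of 1e-9, matching common solver defaults. The LP backend is
GLPK via optlang. Exchange fluxes are negative for uptake and positive for
secretion.

A *metabolic task* is a required capability — e.g. ATP production from
glucose — expressed as minimum/maximum uptake and secretion ranges on
extracellular metabolites, optionally with internal bound overrides (the ATP
task forces flux through the ATP-hydrolysis demand). While a task is checked,
every boundary reaction it does not name is closed; missing exchanges are
added temporarily. Feasibility is an LP feasibility check; the task's active
reaction set is read from the parsimonious solution of the task LP.

Flux sampling uses the seeded ACHR hit-and-run sampler from cobrapy
(default thinning 100); identical model and seed give a bit-identical sample
matrix. A fully determined network (single-vertex polytope) cannot seed a
hit-and-run chain, so sampling returns n copies of the unique flux
distribution in that case.

## GPR propagation

GPR rules parse into explicit AND/OR trees (AND binds tighter than OR;
operators case-insensitive; malformed rules fail with a character position).
Two propagation semantics are implemented:

* **Signed DE weights** (task scoring): a leaf carries its gene's weight; an
  AND node takes the child value of minimum absolute magnitude (a complex is
  limited by its weakest subunit's evidence); an OR node the child of maximum
  absolute magnitude (any isozyme's change can change the reaction). Exact
  magnitude ties resolve toward the positive value, then the leftmost child,
  making the result deterministic. Signs are carried through. A plain-mean
  strategy is available as a configuration option; the min/max-magnitude rule
  is the default because it is sign-aware and penalizes incomplete complexes.
* **Transcript abundances** (model pruning): AND = min (scarcest subunit),
  OR = sum (isozymes contribute additively). A reaction without a GPR is
  *unassessed* rather than zero.

Genes missing from a weight or TPM table contribute 0 and are counted in the
log — a gene absent from the differential-expression table is
indistinguishable from a non-significant one.

## Task scoring (TIDEs)

Genes with FDR < 0.01 carry their log2 fold change as a weight, all others 0;
only genes present in the model are used. A task's score is the arithmetic
mean propagated weight over its reaction set, zero-weight reactions included;
reactions without GPRs are excluded from the set because weights are defined
only through genes. The reaction set is either a curated per-task list (the
toy catalogue ships one per task, listing the pathway reactions distinctive
of the task) or, by default, the GPR-bearing reactions active in the task's
parsimonious solution. Curated lists are preferred where available: active
sets of different tasks share the core ATP machinery, so scoring active sets
lets a strong planted signal bleed into every task that respires.

Significance comes from shuffling the multiset of gene weights uniformly
across the model's genes (default 1000 shuffles) and recomputing reaction and
task scores each time. Two one-sided empirical p-values with add-one
correction are reported: p_up = (1 + #{null ≥ observed}) / (n_perm + 1) and
the analogue with ≤. The combined significance call doubles the smaller one
(p = min(1, 2·min(p_up, p_down)), a two-sided-style correction) and compares
it with alpha = 0.1; the direction is the smaller tail. The doubling is what
makes the procedure calibrated: without it a structureless null is flagged at
about 2·alpha, because either tail can fire. No multiple-task correction is
applied by default, matching the task-level 0.1 threshold convention; a BH
option exists downstream of the returned p-values.

The permutation-null width grows with the number and size of nonzero weights
in the multiset. This is the mechanism by which a condition with a massive
transcriptional response produces a sparse task grid: the same observed score
must beat a wider null.

## Metabolomics chain

Stages run strictly in order — missingness filter, half-minimum imputation,
log-scaling and centering — and each stage is guarded by a state flag
(normalization in particular is not idempotent). A metabolite is removed when
its missing fraction is strictly greater than 0.6; missing values impute as
half the metabolite's observed minimum; values are then log2-scaled and
mean-centered within each metabolite (log base and a median-centering option
are configurable; mean is the default, and the choice does not affect the
rank-based tests).

Group comparisons use the Mann-Whitney U test. The standalone test defaults
to exact enumeration of the permutation distribution of U (midranks under
ties) whenever min(n) ≤ 8, and the exact implementation is verified against a
brute-force enumeration oracle. The two-sided p doubles the smaller tail.
With 3 vs 3 samples and no ties the smallest attainable exact two-sided p is
2/20 = 0.1: *no* blank-media call can clear a BH-corrected threshold of 0.1
in exact mode at this design size. The continuity-corrected normal
approximation (minimum p ≈ 0.081) cannot clear it either once several tests
share a BH family. The classification chain therefore defaults to the
tie-corrected normal approximation without continuity correction (minimum
p ≈ 0.0497 at 3 vs 3), the variant under which an n=3 study can report
FDR < 0.1 discoveries at all. This small-sample floor is a real limitation of
the design being emulated, not of the implementation; it is surfaced here
deliberately.

Benjamini-Hochberg correction is applied within each contrast family (all
metabolites × one contrast). A metabolite significantly above the blank mean
is *produced*, below it *consumed*. The classes are: `consumed_only` (every
significant blank call is consumption), `produced_or_consumed` (at least one
significant production call), `differential_without_blank_significance`
(nothing significant against blank but a treatment-control shift exists — the
direction of exchange cannot be determined), and `unchanged`.

## Model tailoring

A tissue model is the subnetwork of a general model on a reference reaction
id list plus curated species-specific additions; unmappable reference ids are
reported, never silently dropped, and every structural change lands in a
curation ledger. Measured metabolites map to model species by exact KEGG
compound id (name-based fallback is deliberately off — too ambiguous). For
each measured metabolite with a significant produced-or-consumed call whose
exchange exists in the general model but not the tissue model, the exchange
is copied over; if the tissue model has no reaction touching the
extracellular species, the lexicographically first transport reaction from
the general model is co-added, because an exchange without a transporter is
dead weight. The operation is idempotent.

The condition constraint recipe: exchanges of consumed metabolites open to a
lower bound of −10 (a theoretical overabundance relative to demand); the
objective is an ATP-hydrolysis demand capped at 100 flux units; DNA and RNA
maintenance demands are fixed at exactly 1 unit (the unit is model-relative —
one unit of the lumped pseudo-metabolite demand); all other internal upper
bounds are lifted to 1e6 so internal capacity never shapes the solution
space. If the constrained model is infeasible, each maintenance demand is
relaxed in turn and the ones whose relaxation restores feasibility are named
in the report.

## Condition-specific models and comparison

Transcript-guided extraction is a deliberately simple cost-weighted pruning
with the standard knobs (TPM input, 90% objective fraction, 50 samples):
reaction abundances are min-max rescaled to [0, 1] over assessed reactions;
cost = 1 − scaled + 0.01 (the floor keeps every cost positive so the LP is
bounded and uniform transcriptomes reduce exactly to pFBA); unassessed
reactions get the median assessed cost. The LP minimizes Σ cost·|v| subject
to objective ≥ 0.9 × optimum; reactions with |flux| < 1e-9 are pruned. The
solution itself witnesses that the pruned model retains the objective
fraction. The report carries the Spearman association between kept |flux| and
reaction abundance. Parity with any published extraction tool is a non-goal;
the contract is internal consistency and planted-truth recovery.

Sampling keeps the objective-fraction constraint active. Cross-condition
comparison restricts to reactions shared by all conditions (lexicographic
order), takes |flux| (Bray-Curtis requires nonnegative profiles; a pair of
all-zero profiles has distance 0 by convention), embeds with non-metric MDS
(seeded restarts, normalized stress), and ranks reactions by a seeded
random-forest classifier with permutation importance. A model-free fallback —
absolute standardized mean difference, max over label pairs — must agree on
the top feature for a cleanly separated planting, and a label-permutation
null bounds what importance identical distributions can produce.

## Synthetic study generator

The generator emulates a small in-vitro toxicology-style study: treated and
control cells in culture, blank (cell-free) media controls, 3 replicates per
group. The toy network (~44 reactions, cytosol + extracellular) has
glycolysis with a lactate sink, two redundant respiration routes (the planted
alternative for pruning experiments), nucleotide/lipid/ROS-detoxification
pathways, DNA/RNA maintenance demands, AND/OR GPR rules throughout, and
KEGG-annotated exchanges so the metabolomics mapping path is exercised for
real. All four catalogued tasks are feasible by construction and each has a
designed cut reaction.

DE tables plant |log2FC| = 2 (sd 0.25) with FDR ~ U(0, 0.005) on a task's
genes over a 5% background DEG rate; non-model genes are included to exercise
the mapping filter. The metabolite panel (16 named metabolites) plants
consumption (90% depletion, slightly deeper in treatment), production
(5-fold), treatment-only changes, one blank-ambiguous differential metabolite
(wide cell-free baseline), and two rows engineered above the 60% missingness
threshold. Diffuse missing-at-random gaps default to 0: on this platform
missingness is predominantly detection-limit censoring concentrated in
low-abundance metabolites, which the engineered rows represent; a `missing_rate`
parameter adds diffuse gaps when imputation behaviour is the object of study.
TPM profiles are log-normal (median ≈ 100) with the condition's suppressed
pathway scaled ×0.05 (a 20-fold knock-down).

What the generator does *not* emulate: compositionality and batch effects in
TPM, metabolite annotation uncertainty, correlated missingness, intensity-
dependent variance in area counts, and any real tissue biology. Passing tests
demonstrate that the pipeline recovers plantings under its own stated model
of the data, not that it would recover biology from a real study.

## Problem sizes and determinism

Defaults mirror the emulated study design: 1000 permutations per task, 50
flux samples per condition, 3 metabolomics replicates per group, 90%
objective fraction. Recovery and calibration properties are measured over
100-seed sweeps (500 task evaluations for calibration). Every stochastic
step — permutations, sampling, forests, ordination restarts — takes an
explicit seed, and the pipeline config makes seeds mandatory; rerunning a
config reproduces byte-identical result tables. A full synthetic pipeline run
takes a few seconds on one CPU.

## Known limitations

* The AND/OR weight-combination rule is a documented convention; published
  task-scoring implementations do not all print theirs, and the strategy
  option exists because conventions differ.
* The exact-test floor at n=3 means blank-media discoveries at FDR < 0.1
  exist only under the uncorrected normal approximation; single-metabolite
  conclusions at this design size are fragile by construction.
* The transcript-cost pruning is a contract-defined simplification; it shares
  the knobs but not the internals of published extraction algorithms.
* Bray-Curtis on |flux| discards flux direction; a reaction that reverses
  between conditions with equal magnitude is invisible to the ordination
  (the random-forest ranking sees it only through magnitude differences).
* No thermodynamic or loopless constraints; sampled distributions may contain
  thermodynamically infeasible cycles within the lifted internal bounds.
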