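# Methods

This note documents the models, algorithms and design choices behind
`rgem`, in the package's own words. The pipeline integrates kidney-style
transcriptomic presence/absence calls and plasma metabolomic fold changes
with a constraint-based metabolic model, extracts wildtype (WT) and
knockout (KO) context-specific models, and compares their reaction content
and sampled flux states, ending in a metabolite-connectivity ranking that
exposes redox-cofactor involvement.

## Constraint-based core

A model is a stoichiometric matrix `S ∈ R^{m×n}` with flux bounds
`vl ≤ v ≤ vu` (mmol/gDW/h) and steady-state mass balance `S·v = 0`.
Flux balance analysis (FBA) maximizes one reaction's flux — here ATP
demand — over that polytope; flux variability analysis (FVA) minimizes and
maximizes each reaction's flux, optionally under an objective floor.
All linear programs run through SciPy's HiGHS interface with feasibility
tolerances of 1e-9, so optima are deterministic polytope vertices.
Unbounded model bounds are capped at ±1000 mmol/gDW/h (the usual COBRA
convention); the split-variable reformulation below requires finite
bounds, and callers are told to cap rather than having it done silently.

Degenerate optima are a fact of FBA; the package's contracts therefore
promise objective values and flux *ranges*, never one particular optimal
flux vector.

## GIMME extraction

Expression enters as Affymetrix-style P/A calls with at least three
replicates per condition; a gene is present iff called present in at
least 2 of 3 replicates. An optional many-to-one ortholog table projects
source genes onto model genes (target present iff any mapped source is
present). Reaction presence follows GPR logic (OR = any, AND = all);
reactions without a GPR carry no evidence and are never penalized —
absence of evidence is not evidence of absence.

With binary evidence `x ∈ {0,1}` and cutoff `x_cutoff = 0.5`, the GIMME
weight is `c = max(x_cutoff − x, 0)`, i.e. a constant 0.5 on absent
reactions. The extraction solves

    min Σ_j c_j |v_j|   s.t.  S·v = 0,  vl ≤ v ≤ vu,
                               v_obj ≥ f · v_obj*

linearized by the nonnegative split `v = v+ − v−` with `0 ≤ v+ ≤ vu`,
`0 ≤ v− ≤ −vl`. Because every `c_j ≥ 0`, any optimum has `v+·v− = 0` on
penalized columns, so the LP optimum equals the true minimum of
`Σ c|v|`; the test suite verifies this against exhaustive enumeration of
arrangement vertices (the polytope facets plus the coordinate hyperplanes
`v_j = 0`, where a piecewise-linear convex function attains its minimum).
The optimal value is the model's *inconsistency score* (0 = expression
and required functionality fully compatible); the active set is the
unpenalized reactions plus penalized reactions carrying `|v| > 1e-6`.
The required objective fraction `f` defaults to 0.9 of maximal ATP
production and is exposed as configuration — the appropriate fraction is
a modelling choice, and ATP demand is used as the objective because the
expression data are organ-level rather than cell-type-resolved.

Reaction (column) order can affect which of several equivalent penalized
alternatives a vertex solution retains. The ensemble procedure therefore
reruns GIMME on 10 seeded random reaction reorderings per condition and
reports only reactions present in all 10 active sets (strict
intersection); union and per-run sets are kept for diagnostics.

## Metabolomic exchange constraints

Per-metabolite fold changes (KO/WT) and p-values come from a two-way
additive ANOVA (condition + batch, no interaction) on log intensities;
the fold change is the ratio of geometric means. The ANOVA is a
vectorized partial-F test (full model vs batch-only model), identical to
a type-II ANOVA for this design; a unit test pins it to statsmodels'
`anova_lm`. Metabolites pass at p < 0.05 by default (0.10 exposed for
sensitivity analysis; relaxing the cutoff can only add constraints).

Exchange reactions are single-metabolite boundary reactions (positive
flux = secretion, negative = uptake). FVA at fraction 0 (pure
feasibility, since classification precedes the objective) classifies each
exchange as secretion-only, uptake-only, bidirectional or blocked. The
four bound rules for a significant measurement are:

| rule | direction | class          | new bound                           |
|------|-----------|----------------|-------------------------------------|
| R1   | up        | secretion-only | lb := 0.10 × FVA max (force)        |
| R2   | up        | uptake-only    | lb := 0.10 × FVA min (cap uptake)   |
| R3   | down      | secretion-only | ub := 0.10 × FVA max (cap secretion)|
| R4   | down      | uptake-only    | ub := 0.90 × FVA min (force uptake) |

R1 and R4 use the canonical 10%/90% fractions; R2/R3 are only constrained
in sign by the method's definition, and this package fixes both at the
symmetric 10% mark (configurable). Bidirectional and blocked exchanges
are never constrained, only logged. Because the measurements describe the
KO plasma state relative to WT, the rules are applied to the KO model
only; the WT model receives the same reference environment but no
fold-change constraints. Measured substrates get a reference uptake
bound of −0.25 mmol/gDW/h, and oxygen, sodium, potassium, iron,
magnesium, bicarbonate, protons and water exchange freely (±1000).
Every modified bound is recorded in an append-only ledger (old bounds,
new bounds, rule), and the constrained model's objective feasibility is
re-verified.

## Flux sampling and comparison statistics

Each consensus submodel's flux polytope is sampled with
artificial-centering hit-and-run (ACHR): warmup points are the FVA
extreme-point solutions, directions are differences between a stored
point and the running center (automatically in the null space of S), the
step is uniform over the feasible chord, one point is kept every
`thinning = 100` steps and re-projected onto the null space to suppress
numerical drift (residual ‖S·v‖∞ well under 1e-6). The default sample
count is 2n for n reactions. Samples are normalized per flux state by
total absolute flux (L1), making WT/KO comparisons scale-free; the
normalization itself is a documented choice (alternatives: none,
per-reaction z-scores) since only "normalized flux states" is specified
by the method this reimplements.

Differentially active reactions are two-sample Kolmogorov–Smirnov tests
per shared reaction at p < 0.001 with *no* multiple-testing correction
(deliberately mirroring the method's fixed threshold). Correlated
reaction sets (co-sets) are connected components (single linkage) of the
graph with edges |Pearson r| ≥ 0.95 over sampled fluxes,
constant-flux reactions excluded.

## Comparison layer and connectivity

WT and KO consensus sets are partitioned into shared / WT-unique /
KO-unique reactions; induced metabolite sets give per-compartment counts
and KO/WT ratios (0/0 → 1, x/0 flagged infinite). Per subsystem, unique
counts are reported together with the fraction of the subsystem affected,
to counter subsystem-size bias. Metabolite connectivity over a reaction
subset (typically the KO-unique set) is `cm = diag(Sb·SbT)` after
zeroing all non-subset columns of the binarized stoichiometric matrix
`Sb`; this equals, exactly, the number of subset reactions involving each
metabolite. Ranking ties break lexicographically for determinism.

## The synthetic study

The toy redox network (~86 metabolites, ~87 reactions, 8 compartment
codes) is a designed test harness. Its skeleton: lumped glycolysis
(2 ATP + 2 NADH per glucose), lumped pyruvate oxidation (4 NADH + 1
FADH2), complex I/II into a Q10 pool, a lumped III–V step (6 ATP per
2 QH2), malate–aspartate shuttle, carbonic anhydrase, and an ATP demand
objective. All internal reactions are elementally and charge balanced
(checked by `validate_mass_charge_balance` in the test suite). The ROS
branch hard-codes the published superoxide-dismutase isoforms in five
compartments and the ascorbate cycle (ASCBOX_1, DASCBR_1, DHAOX_c)
verbatim, plus catalase, peroxiredoxin/thioredoxin, glutathione
peroxidase/reductase, NADPH oxidase, transhydrogenase, a cytosolic
FAD couple, a complex-III electron leak, and xanthine oxidase /
dehydrogenase feeding urate oxidase. Metabolite ids use `__` where the
printed names contain a hyphen (`ascb__L_c`), keeping identifiers
SBML-compatible.

The simulated knockout of the urate reabsorption transporter has three
coordinated facets: the `EX_urate_e` exchange is blocked ([0, 0]), the
transporter gene `g_urat1` is planted absent in KO expression, and the
20-gene ROS/redox response program is absent at baseline in WT but
induced in KO. Expression calls: planted-absent genes are called absent
with probability 0.9 per replicate (so the 2-of-3 consensus is absent
with probability 0.972); all other genes are called present with
probability 1 − dropout (dropout 0.02, a small spurious-absent rate that
exercises the consensus logic without overwhelming the planted signal).
Metabolomics: 6 samples per condition balanced over 2 batches,
log-normal intensities with σ_log = 0.25, a batch offset (σ = 0.15), and
planted fold changes of 2.0 on six metabolites (urate, allantoin, H2O2,
lactate, glutathione, CO2) and 0.5 on two (glucose, ascorbate), the rest
unchanged — a minority-altered pattern with mostly elevated KO/WT
ratios. At these settings the p < 0.05 filter recovers planted
directions with sensitivity ≥ 0.9 and FDR ≤ 0.1.

What the generator does *not* emulate: probe-level microarray artifacts,
peak identification ambiguity, correlated metabolite panels, growth/
biomass objectives, thermodynamic (loopless) constraints, and
genome-scale degeneracy. Passing tests therefore demonstrate that the
algorithms are implemented correctly and that the integration logic
recovers a planted multi-omics signal — not that the biological
conclusions would replicate on a genome-scale reconstruction.

## Numerical choices

- zero tolerance 1e-12 for coefficient pruning/binarization (below LP
  precision); LP feasibility tolerances 1e-9; active-set flux threshold
  1e-6 (above solver noise, below meaningful flux).
- FVA sign tolerance 1e-9 for exchange classification; "blocked" means
  both extremes within 1e-9 of zero.
- ACHR: directions shorter than 1e-9 are redrawn; chords narrower than
  1e-9 are skipped; a fully flat polytope returns a single point with a
  warning rather than an error.
- KS tests require ≥ 8 samples per side; smaller sets are skipped with a
  warning.
- Co-set variance floor 1e-12 for excluding constant reactions.
- All stochastic components take explicit seeds; derived seeds are
  arithmetic offsets of the master seed, and identical seeds give
  bit-identical samples and byte-identical reports.

## Problem sizes used in the shipped studies

The test suite and the acceptance script run: 50 random ≤8-reaction
networks for the GIMME-vs-enumeration check; 200 random networks for the
connectivity identity; 10,000 draws for consensus arithmetic; 1000
points for the 1-D sampler calibration and 200 replicate pairs for the
null differential-detection rate; 20 seeded end-to-end studies for
knockout-signal recovery. Monte-Carlo property tests inside the unit
suite use 60–300 replicates per property to keep the default run fast.

## Known limitations

- The ensemble's reorder sensitivity is exercised through LP column
  permutation only; genome-scale GIMME implementations can also differ in
  pre/post-processing order.
- The uniform sampler is exact on the toy scale but makes no mixing-time
  guarantee for high-dimensional genome-scale polytopes.
- R2/R3 fractions and the L1 normalization are documented defaults for
  under-specified steps, not uniquely determined by the method.
- `compute_fold_changes` assumes a (near-)balanced two-factor design;
  heavily unbalanced designs get the same partial-F treatment but no
  type-III machinery.
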