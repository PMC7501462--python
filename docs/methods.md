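# Methods

This note documents the models, estimators and design choices behind
`ecswitch`, and what the synthetic system does and does not show about
real data.

## Constraint-based core

A metabolic model is a stoichiometric matrix S with per-reaction flux
bounds, boolean gene rules (AND = complex, OR = isozymes), subsystem
and pathway labels. Flux balance analysis (FBA) solves
max/min c·v s.t. S·v = 0, lb ≤ v ≤ ub; flux variability analysis (FVA)
solves one max-LP and one min-LP per reaction, optionally under
v_obj ≥ fraction·optimum. All LPs use the HiGHS dual simplex through
`scipy.optimize.linprog` with a primal/dual feasibility tolerance of
1e-9, so every optimum is a basic solution — a vertex of the flux
polytope. This matters for the sampler (below). Infeasibility and
unboundedness are reported as distinct statuses, never conflated.

Degenerate optima are not resolved: any optimal vertex is a valid FBA
answer, and tests assert objective values and feasibility, not
individual fluxes of degenerate reactions. Flux units are
mmol·gDW⁻¹·h⁻¹; biomass flux is h⁻¹; the "infinite" bound is ±1000.
Exchange reactions are recognized structurally (single-metabolite
stoichiometry), not by id prefix.

Serialization: SBML Level 3 with the fbc package goes through
cobrapy/libsbml; a flat tabular dialect (metabolites.tsv +
reactions.tsv with equation strings) covers spreadsheet-style editing.
Round-trips preserve ids, stoichiometry, bounds, gene rules and
subsystems. cobrapy is also used in the test suite as an independent
FBA/FVA oracle against the scipy implementation; the two routes are
never collapsed.

### Biomass prosthetic groups

`update_biomass_prosthetics` sets the biomass coefficients of
prosthetic-group metabolites proportional to abundance-weighted sums
over annotated proteins, scales them so the groups' total mass per
unit biomass equals a configured fraction (default 0.03 g/gDW), and
rescales the remaining consumed coefficients by (1 − fraction) to keep
1 g biomass per unit flux. Metabolites without a formula are assigned
1 g/mmol. The proportional-allocation rule is a declared
simplification; it is invariant to rescaling all abundances.

## Thermodynamic directionality curation

Reactions with a standard transformed Gibbs energy estimate are
classified with a lenient ±30 kJ/mol threshold: ΔG' ≤ −30 →
forward-irreversible, ΔG' ≥ +30 → backward-irreversible, otherwise
reversible. The backward side is the symmetric application of the same
threshold. ΔG' uncertainty is carried through but not used for
classification. Reversible ATP-consuming reactions without a positive
ΔG' are additionally proposed forward-irreversible unless excepted
(nucleoside-diphosphate-kinase/ATP-synthase analogs); when both rules
could fire, the thermodynamic proposal wins and the ATP rule only
covers reactions it left untouched.

Proposals are arbitrated against growth/knockout phenotype data. All
proposals are applied at once, then each is singly reverted in
ascending reaction-id order and the reversion kept iff it strictly
improves the Matthews correlation coefficient (MCC) of the FBA
phenotype predictions, recomputing after every kept reversion. When
MCC is undefined (an empty predicted or observed class), accuracy
breaks the tie. Growth is the positive class; predicted growth means
FBA optimum > 1e-6 h⁻¹; an infeasible test model counts as predicted
no-growth. The deterministic reversion order and strict-improvement
criterion avoid churn on ties; the procedure can never end below the
all-applied MCC, and a monotone-safety test checks it never ends below
the pre-proposal model on small systems.

`recover_confusion` is the package's oracle for printed confusion
summaries: it enumerates all integer (tp, fn, tn, fp) on n tests whose
accuracy/sensitivity/specificity fall within half an ulp of the
printed values (ties included, so 0.475 matches a printed 0.48) and
returns every match. Rounding windows prune the search to well under a
second at n = 241.

## Enzyme constraints (GECKO formalism)

Reversible reactions are split into forward/backward irreversible
copies; OR-branches of gene rules become one reaction copy per
isozyme; each copy consumes its enzyme pseudo-metabolites at 1/kcat
(complex subunits all at 1/kcat, subunit stoichiometry fixed at 1 — no
subunit stoichiometry data is in scope). Enzymatic reactions without a
kcat match receive the model-median kcat and are flagged;
gene-rule-free reactions stay uncoupled. Enzymes are supplied either
by a usage reaction bounded by measured abundance (mmol·gDW⁻¹) or by a
shared pool weighted by molecular weight. The pool exchange is capped
at sigma·f·P_total with defaults P_total = 0.45 g/gDW, f = 0.4,
sigma = 0.5 (standard GECKO conventions); after proteome integration
the cap becomes sigma·(f·P_total − measured mass), floored at zero, so
the pool feeds only unmeasured enzymes.

Proteome flexibilization: if a required growth rate is unreachable,
the most limiting measured bound — identified by probing each active
usage bound with a doubling and keeping the largest objective gain —
is doubled, at most 20 times, with every relaxation logged. This is
the package's declared reconciliation policy; the tolerance policy for
condition models (below) keeps it rarely needed.

Condition-specific models pin measured exchange rates to
rate ± tolerance·|rate| bands and bound growth below by
(1 − tolerance)·measured μ. The default tolerance is 0.25, reflecting
the uncertainty of interval rate estimates from noisy batch data.
Infeasible rate sets are diagnosed with an elastic relaxation LP
(slack on every imposed bound, minimize total slack) and reported as a
named list of violated constraints.

Net-flux FVA for split pairs optimizes the linear combination
v_fwd − v_bwd directly; because the optimizer zeroes the opposing copy
this is equivalent to the auxiliary-variable formulation and immune to
futile-cycle inflation of individual copies.

## Cultivation-rate analysis

μ is the least-squares slope of ln(CDW) versus time. The automatic
window is the longest prefix of at least 4 points, ending no later
than the earliest depletion event, that maximizes R² (growth is still
exponential at the depletion time itself; ties go to the longest
prefix). Interval-specific rates use q = ΔC/(Δt·X̄) with the
logarithmic-mean biomass X̄ = (X₂−X₁)/ln(X₂/X₁), exact for exponential
segments; consumption is negative. Depletion times come from linear
interpolation of the first downward threshold crossing; chatter
triggers a warning and the first crossing wins.

Cross-strain production is compared on biomass-normalized titers
(concentration/CDW) evaluated at equal time after each strain's own
phosphate depletion — the physiological alignment that also motivates
the regulon-based time pairing. The reduction is 100·(1 − alt/ref).
A rate-based variant can be built from `specific_rates`, but the
aligned-titer comparison is the default.

## Vertex sampling and pathway statistics

Each draw maximizes an objective with i.i.d. standard-normal
coefficients over all reactions; the simplex optimum is stored. Sign
symmetry makes maximization alone unbiased over polytope vertices.
Identical seeds give identical sample matrices. Mean fluxes summarize
each condition; for enzyme-constrained models they are projected onto
the original reactions (forward minus backward copies, isozyme copies
summed).

Pathway activity is Σ|mean flux| over member reactions — a
direction-free activity measure; a signed variant exists behind a
flag. Activities are divided by the condition's measured specific CO₂
evolution rate (volume-corrected respiration / CDW), then Z-scored per
pathway across the standardization set — both strains jointly by
default so cross-strain levels stay comparable. Zero-variance rows are
emitted as 0 with an explicit flag, never NaN. Rows are ranked by
variance of the normalized values; named pathways can be
force-included. Row ordering/clustering is presentation-only.

Metabolite budgets partition coefficient × mean flux into producers
and consumers; steady state guarantees the totals balance, and the
balance holds for every sampled vertex, not only means.

## Omics comparison

Time-point alignment: each strain's regulon genes are Z-scored over
its own time axis and averaged into one profile; dynamic programming
over monotone pairings (steps advance one or both series, diagonal
preferred on ties) minimizes total squared profile distance. Monotone
DP was chosen over nearest-neighbor matching because the pairing must
not reverse time. PCA centers features and unit-scales them by
default; components are sign-fixed by making each component's
largest-magnitude loading positive, and variance percentages are
reported. Per-gene Z-scoring optionally applies log2(x + 1) first;
zero-variance genes come out flat and flagged.

## The synthetic system

The toy network (51 reactions in the BGC-carrying variant, 43 in the
deletion mutants) covers glycolysis, pentose phosphate pathway, TCA
cycle, oxidative phosphorylation (two branches plus transhydrogenase),
anaplerosis (PEP carboxylase/carboxykinase), glutamate assimilation,
acetate overflow (phosphotransacetylase and pyruvate oxidase),
fatty-acid synthesis from malonyl-CoA, a germicidin-analog pathway in
all strains, and four BGC-analog pathways that drain malonyl-CoA.
Growth strictly requires phosphate, and on the reference medium the
phosphate uptake bound makes μ_max = 0.15/0.5 = 0.3 h⁻¹ by hand.

Strain presets are the study conditions: μ = 0.21/0.21/0.15 h⁻¹ and
phosphate depletion at 35/38/47 h for the wild-type-like, four-BGC
deletion and deletion + RNA-polymerase-mutation presets; the mutant
presets draw a smaller share of biomass carbon from glucose (0.60 /
0.55 / 0.45). Germicidin-analog scale factors 0.73/0.75 and 0.08/0.18
are back-calculated from the planted 27/25 % and 92/82 % reductions.
Time series place the depletion time exactly on the 8-point sampling
grid (3 pre-depletion points at 30/60/85 % of t_dep, the depletion
time, 4 post points), so threshold interpolation recovers it exactly
at zero noise; biomass is exponential then arrested; substrate
consumption is yield-consistent during growth (so interval rates times
yields recover μ) with a slow maintenance drain afterwards; germicidin
analogs accumulate after depletion proportionally to the biomass at
arrest, making the depletion-aligned normalized titer ratio equal the
preset scale factor exactly. Measurement noise is multiplicative
Gaussian (default sd 2 %).

Thermodynamic tables plant ΔG' means of ∓45 kJ/mol around the true
direction (0 for truly reversible reactions) with Normal(0, 5) noise;
two ATP-driven reactions get no estimate so the ATP rule has work to
do. kcats are log-normal with median 3600 h⁻¹ (σ_ln 0.5); molecular
weights are uniform in 15–35 g/mmol; one protein per gene.

Proteome samples are allocated from a reference flux state: the
minimal-total-flux solution of the strain's own GEM with uptakes
pinned at the top of the condition band and growth at the preset μ.
Abundance = 1.15 × reference flux / kcat makes every condition-specific
model feasible by construction. Secondary-metabolite enzymes instead
get calibrated capacities — each BGC pathway's malonyl-CoA drain
capacity is 0.0055 mmol·gDW⁻¹·h⁻¹ and acetyl-CoA
carboxylase/fatty-acid synthase are capped at 0.085/0.06 — which
places the fatty-acid : BGC drain ratio mid-way in the planted 3–6×
band under vertex sampling. After the switch, oxidative-phosphorylation
abundances rise ×1.6, fatty-acid enzymes fall to ×0.2, BGC enzymes
rise ×4, and a six-member phosphate-starvation regulon of
pseudo-proteins rises ×6 (the alignment marker). The least-abundant
~10 % of central proteins are withheld from measurement and draw from
the shared pool. For the toy, the modeled-proteome fraction is
f = 0.8 — the network covers most of what the pseudo-organism
expresses — and total measured mass is kept within f·P_total.
Pre-depletion condition rates are estimated from the pooled
exponential phase (q = μ̂·ΔC/ΔX) rather than single intervals, whose
concentration differences are noise-dominated early in the run.

Phenotype tests combine media grids (carbon-source levels, phosphate
levels, no-phosphate and no-carbon media) with all single-gene
knockouts, FBA-simulated on the ground-truth model; 197
predicted-growth and 44 predicted-no-growth tests are kept and a
seeded subset of observed labels is flipped (42 of the positives, 6 of
the negatives) so that evaluating the suite against the generating
model reproduces the confusion matrix (tp, fp, tn, fn) =
(155, 42, 38, 6) — accuracy 0.80, sensitivity 0.96, specificity 0.48,
MCC 0.53 — exactly.

### What the synthetic system does not show

Switch behavior is imposed piecewise, not emergent from regulation;
passing tests demonstrate that the estimators recover planted
parameters and contrasts, not that the biology of the switch is
modeled mechanistically. Proteome allocation is flux-proportional by
construction, which is tidier than real proteomics (no isoform
ambiguity, no missing-value structure beyond the withheld fraction,
no batch effects). The toy's kcats are a single log-normal family;
real kcat catalogs are sparse, biased toward model organisms and span
more orders of magnitude. Rate tolerances, pool parameters and the
acceptance policy for directionality proposals are declared defaults
where the original study is silent.

## Problem sizes and determinism

Default analyses use 8 conditions per strain, 200 vertex samples per
condition and 241 phenotype tests; the full pipeline runs in about
half a minute on one CPU. Every random draw flows from a single seed
through `numpy.random.default_rng` with fixed stream offsets, so
reruns are bitwise identical; the pipeline manifest records the config
hash and library versions.
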