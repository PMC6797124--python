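# Methods

## Constraint-based model and growth LP

A model is a set of metabolites (with compartment codes such as `c`
cytoplasm, `m` mitochondria, `e` extracellular), reactions with signed
stoichiometry and flux bounds in mmol/(gDW·h), optional GPR rules, and one
objective reaction. A reaction touching exactly one metabolite is an
exchange; uptake is negative flux internally, and only presentation tables
flip uptake positive. The growth LP (max c·v, S·v = 0, lb ≤ v ≤ ub) is
solved with HiGHS via `scipy.optimize.linprog`. Feasibility tolerance is
the solver's (≈1e-9); every optimal solution is checked against
max|S·v| ≤ 1e-6 before it is returned.

Alternate optima are endemic in genome-scale models, so a single optimal
flux vector is solver-arbitrary. Everything that must be reproducible
(saturation screening, summaries, diagnosis) consumes FVA ranges or the
objective value; single vectors appear only where explicitly chosen
(`use_fva_max=False` restores literal one-solution screening). FVA holds
the objective at `fraction_of_optimum` × optimum with a 1e-9 slack so the
optimal face itself stays feasible at fraction 1. Phase planes pin the
exchange flux to each uptake level exactly; levels the network cannot
absorb are infeasible and recorded as absent (default grid: 20 even levels
from 0 to the exchange's current maximal uptake).

An exhaustive vertex-enumeration solver (`toxflux.bruteforce`) provides an
independent reference for networks of ≤6 reactions: it enumerates every
candidate vertex (all subsets of n − rank(S) variables pinned to either
bound) and maximizes over the feasible ones. It shares no code with the
simplex path and exists purely as a cross-check.

## Expression integration

Per-condition profiles are arithmetic means over that condition's samples;
the fallback mean for genes absent from the matrix is the mean of the
per-gene means of measured genes. A measured expression of exactly 0 is a
value (capacity 0), not a missing entry. GPR capacity is min over `and`
children and sum over `or` children; a gene shared between two `or`
branches is counted in each branch's minimum, so it can contribute twice
to the sum — this is the stated rule applied literally, kept deliberately.

Capacities are rescaled linearly to [0, scale] (scale defaults to 1000,
the conventional default bound in genome-scale models). The normalizing
maximum is taken jointly over both conditions by default: joint scaling is
the only choice under which cross-condition growth ratios are meaningful,
and it preserves each reaction's treated/control capacity ratio exactly.
Per-condition scaling is available as a flag. Only upper bounds are set
from expression; lower bounds stay at model defaults unless
`mirror_reversible=True`, which mirrors −bound onto reversible reactions'
lower bounds (classic E-Flux behaviour). Raw counts should be library-size
normalized first; a median-of-ratios helper is provided.

## Limiting-reaction and limiting-gene diagnosis

Saturation screening reports reactions whose FVA maximum lies within a
tolerance (default 0.1 flux units) of their upper bound, sorted by slack;
reactions still at the global default bound are excluded because their
bound carries no expression information. The diagnosis loop:

1. solve both condition models; if the objectives already agree within
   `recovery_tol` (default 1e-3), the diagnosis is empty;
2. screen the (working) treated model for saturated reactions whose
   control bound is strictly looser;
3. rank by (near-saturation in control, slack, id) — the primary candidate
   is a reaction pressed against its bound in *both* conditions;
4. for the first candidate, also solve the reverse transplant (treated
   bound installed in control) as confirmation that this single bound
   reproduces the treated growth;
5. transplant the candidate's control bound into the working model,
   re-solve, accept the step if the objective improves, and repeat until
   the control objective is recovered or `max_depth` (default 5) is hit.

The loop formalizes a narrative procedure: the original study relaxed
second-tier bounds to an arbitrary large value (10) rather than the
control bound; those manual experiments are available separately through
`test_limiting` (edit bounds, re-solve, record objective and edited
fluxes) rather than inside the loop, because control-bound transplantation
is the variant with an exact termination guarantee (transplanting all
bounds reproduces the control objective identically).

`limiting_gene` reports, per complex configuration (or-branch) and
condition, the minimum-expression subunit; ties are listed jointly, and
the per-condition verdict is the intersection of the branch argmins.

## Metabolomics preprocessing and analyses

Fixed pipeline order: impute → near-constant filter → normalize →
Pareto scale. Choices:

* **Imputation** replaces missing entries by half of the global minimum
  positive intensity (a per-feature variant is a flag). Imputation
  precedes filtering so variability scores are computable.
* **Near-constant filter** removes exactly ⌊fraction·n⌋ features (default
  fraction 0.05, "up to 5%"), scored by interquartile range with variance
  and input order as tie-breaks. A `protect` set exempts features — the
  internal standard is near-constant by design but must survive to the
  normalization stage that consumes it.
* **Normalization**: total-sum to percentages (each sample sums to 100)
  for direct-injection ESI-MS; division by the internal-standard intensity
  (standard dropped afterwards) for GC-MS.
* **Pareto scaling**: per feature (x − mean)/√sd with sd the sample
  standard deviation; zero-sd features are centered, not scaled.

The t-test (Welch by default; pooled-variance flag available) runs on
log2-transformed normalized intensities — MS intensities are approximately
log-normal, so the log scale is where replicate noise is near-normal — with
Benjamini–Hochberg adjustment across features and log2 fold change
reported as the difference of group means of log2 intensities. PCA runs on
the Pareto-scaled matrix; loadings are the unit-norm principal axes and a
feature is called at |loading| > 0.1 on the selected components (PC1 for
ESI, PC1 or PC2 for GC). PLS-DA fits the scaled matrix against 0/1 group
membership (NIPALS, via scikit-learn); VIP uses the standard weighted
sum-of-squares definition cumulatively over the first k components, so
mean squared VIP is exactly 1, and a feature is called at VIP > 1 on any
selected component count. The permutation validation compares the
between/within sum-of-squares ratio of the first latent-variable scores
against label permutations, p = (1 + #{null ≥ observed})/(1 + n_perm);
permutations reproducing the original partition (identical or swapped
labels) are redrawn so a perfectly separated data set can reach the
attainable floor 1/(1 + n_perm).

The majority vote combines three native call columns with six external 0/1
indicator columns (sPLS-DA, OPLS-DA, EBAM, SAM, Random Forest, SVM — their
internal re-implementation is out of scope). Compounds absent from one
source cast no vote there (0). Relevance threshold defaults to 5 of 9.
Cross-platform union normalizes compound names by trim/case-fold/collapse
whitespace only; no synonym resolution.

## Synthetic data

`make_network_scenario` builds exchange → chain → biomass networks (2+
internal reactions, optional parallel branches, GPRs drawn as single
genes, AND complexes of 2–3 subunits, or OR pairs of complexes, optionally
sharing a gene across branches). One chain reaction is planted as the
bottleneck: its chosen gene has the lowest mean in both conditions, and
its treated mean is `bottleneck_fraction` × control. Under joint
normalization the treated/control growth ratio equals that fraction
exactly, and the planted reaction is the unique binding constraint — so
closed-form growth, the limiting reaction and the limiting gene are all
known ground truth. Expression replicates (default 3 per condition) are
log-normal around the condition means and rescaled so the realized
arithmetic mean equals the planted mean exactly; this keeps
condition-mean recovery and the analytic growth exact rather than
asymptotic, at the cost of replicate means carrying no sampling error.

`make_omics_scenario` draws log2 intensities ~ Normal(baseline +
group·effect, noise_sd) with baselines uniform on [10, 20] (a realistic
three-decade dynamic range), default six replicates per group, optional
uniform missingness, and an internal-standard feature with zero effect and
no missingness. Both generators are pure functions of their parameters and
seed.

What the generators do *not* emulate: correlated features (co-regulated
metabolites), intensity-dependent missingness (censoring at the detection
limit), batch effects, drift, or peak-integration artifacts. Passing tests
therefore demonstrate correctness of the algorithms under the stated
noise model, not robustness to real-data pathologies.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen as
the smallest that exercise every code path convincingly: 100–120 random
≤6-reaction networks for the LP oracle, 50 planted network scenarios, 200
null tables of 100 features for type-I calibration, 60 simulations for the
power comparison against the closed-form noncentral-t oracle. LP
feasibility is 1e-9, steady-state and reporting tolerances 1e-6,
saturation tolerance 0.1 flux units, diagnosis recovery tolerance 1e-3 —
all configurable.

## Known limitations

* The SBML adapter reads Level 3 + FBC (bounds, objective, gene-product
  associations) and does not write SBML; the JSON dialect is the
  round-trip format.
* The diagnosis assumes the growth gap is expressible through upper
  bounds of expression-constrained reactions; gaps caused by lower bounds
  or by combinations of non-saturated bounds end with an explanatory
  empty tier rather than a forced answer.
* The permutation test refits the PLS model per permutation; at 1000
  permutations on large tables this is the slowest step of the
  metabolomics path.
* GC two-component PCA/PLS-DA criteria require rank ≥ 2; rank-deficient
  inputs raise an error rather than silently downgrading to one
  component.
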