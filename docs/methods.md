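# Methods

## Scope and model

`contextflux` implements constraint-based analysis of compartmentalised
metabolic networks under the steady-state assumption: fluxes **v** satisfy
*S***v** = 0 with per-reaction bounds, where *S* is the m × n stoichiometric
matrix.  Metabolite ids carry their compartment as a bracket suffix
(`gsh[m]`); the id minus the suffix is the *species key*, the unit over
which cross-compartment quantities (production capacity) are aggregated.
Exchange reactions touch exactly one metabolite; positive flux is secretion,
negative is uptake, and importers normalise dialects with the opposite sign.
Flux units are arbitrary (conventionally mmol·gDW⁻¹·h⁻¹); unbounded
reactions default to ±1000 (reversible) or [0, 1000] (irreversible).

All optimisation runs through a single thin layer over scipy's HiGHS
interface (`scipy.optimize.milp`, which also handles pure LPs).  Solves are
stateless and deterministic: the model matrix is rebuilt per solve with a
fixed variable ordering, so identical inputs give identical solutions and
FVA results are independent of scan order.

## Context construction

**Expression discretisation.** Continuous expression is mapped to
LOW/MODERATE/HIGH by quantile thresholds (defaults: 0.25 and 0.75, the
common choice for tri-level integration; exposed in config).  Values tied
with a threshold are MODERATE — conservative and deterministic.  Gene
categories reach reactions through GPR rules: AND-nodes (complexes) take
the minimum category, OR-nodes (isoenzymes) the maximum; reactions without
a rule, and genes missing from the profile, are MODERATE.

**Stage 1 — expression fit.** A MILP maximises the count of
highly-expressed reactions with |vᵢ| ≥ ε_act plus lowly-expressed reactions
with vᵢ = 0, using per-direction boolean indicators linked to fluxes
through the reaction's own bounds (an infinite bound falls back to the
big-M config value, default 1000).  ε_act defaults to 1.0 flux unit.  These
are conventions, not measured values; both are configurable.

**Stage 2 — measured-flux fit.** With the stage-1 objective held at its
optimum, the LP minimises Σ(yᵢ⁺ + yᵢ⁻) subject to vᵢ − fᵢ = yᵢ⁺ − yᵢ⁻,
y ≥ 0 over the measured exchange set — the exact split-variable
linearisation of the L1 deviation, so at any optimum Σ(y⁺+y⁻) = Σ|vᵢ − fᵢ|.
Measurements naming reactions absent from the network are a hard error:
data/model mismatches must surface, not vanish.

**Locking.** The expression optimum is locked exactly (it is an integer
count) and the deviation optimum D\* with a small slack,
Σ ≤ D\*(1+10⁻⁶)+10⁻⁶, for floating-point safety.  The boolean indicators
remain in the locked system, so downstream analyses explore the union of
all co-optimal activity patterns — the space of alternative optima — not
one solver-chosen solution.  Consequences used as test invariants:
locked FVA intervals are always subsets of unlocked ones, and D\* = 0
exactly when the measurements are simultaneously attainable.

## Capacity analyses

**FVA** solves two optimisations per reaction over the locked space.  With
binary indicators present each solve is a MILP; at the network sizes this
package targets (≤ 200 reactions) this is well inside interactive runtimes.

**Production capacity** of a species adds one transient irreversible drain
`met[x] → ∅` per compartment containing it and maximises the *sum* of drain
fluxes in a single joint LP.  Per-compartment independent maxima are not
summed: they can be jointly infeasible, so the joint optimum is the
well-defined reading of "summed over compartments".  For the redox
cofactors NADH and NADPH the drain instead converts the reduced form back
to its oxidised partner (`nadph[x] → nadp[x]`): cofactor pools are
conserved moieties, so a plain sink could never carry flux, and capacity
here means regeneration rate, not pool size.

**Pathway fold-changes** are medians over member species of capacity
ratios.  Denominators below the floor ε_cap = 10⁻⁹ are floored and
flagged; species with both capacities below the floor are excluded;
pathways left empty are reported as undefined rather than raising.

**Essentiality**: a reaction is essential for an objective if forcing
v = 0 (overriding its bounds — a knockout removes the reaction, including
any constitutive lower bound) drops the objective maximum below
`viability_fraction` (default 0.01) of its unconstrained value.

**Coupling scan**: each reaction in turn is forced active, |v| ≥ ε,
implemented as two LPs (forward, reverse) keeping the better objective —
a disjunction needs no MILP here.  The scan reports the target capacity
under each forcing.  When a reference reaction is given (the succinicGSH
sink), its capacity *decrease* is summarised two ways: an empirical rank
p-value among all scanned reactions, and a rank-sum test of the singleton
reference decrease against the others.  A single reference value does not
determine a unique two-sample construction, so both summaries are reported
and neither is privileged.

## Succination perturbation and dependency scan

GSH succination is grafted as one irreversible `gsh[x] + fum[x] → succgsh`
reaction per compartment holding both substrates plus a secretion sink for
the adduct, which is modelled as a single pooled species without a
compartment tag.  In the FH-deficient variant the sink carries a forced
minimum flux ε_sec (default 0.01 flux units — small enough not to dominate
the flux distribution, large enough to make the coupling visible; the
biological statement is only that secretion is non-zero).  Forcing the sink
can only shrink the feasible space, so redox capacity is monotonically
non-increasing under it — an invariant the tests assert across seeds.
When a perturbed network is re-analysed in a measured context, both optima
are re-fit and re-locked on the perturbed network (the grafted reactions
change what is attainable).

The dependency scan takes each exchange in turn, computes its FVA range
[lo, hi], steps the exchange flux through n_points (default 20) evenly
spaced values spanning the range — the flux is pinned at each step, with
both bounds set to the grid value — and records the maximal production of
the target species at each step.  The Spearman correlation between grid
values and production maxima summarises the dependence: negative for
metabolites whose uptake feeds the target (cystine-like), positive where
higher exchange flux (less uptake or more secretion) frees production
(arginine-like).  Pinning, rather than capping only the upper bound, is
what makes an uptake dependence detectable at all: with the lower bound
left at the FVA minimum, maximal uptake would remain available at every
step and the production maximum could never decrease along the grid.
Degenerate ranges and flat production profiles yield flags, never
exceptions, so a scan over many exchanges always completes.

## Validation statistics

Leave-one-out cross-validation rebuilds the context from the expression
data and all-but-one measurements (the expression stage depends only on
expression, so its optimum is computed once), then predicts the held-out
exchange flux as its FVA range over the rebuilt locked space.  The point
prediction is the range midpoint — symmetric and parameter-free; the full
range is reported so other point rules can be evaluated.  Overall agreement
is the Pearson correlation between point predictions and measurements
(Spearman is reported alongside); infeasible folds are flagged and excluded
with a warning rather than aborting the validation.

Correlations use exact permutation p-values when the permutation space is
enumerable (n ≤ 8 by default; the dependency sweep uses n ≤ 10) and
scipy's asymptotic approximations beyond; the rank-sum test enumerates all
group assignments up to 2·10⁵ combinations with midranks throughout.
Zero-variance inputs yield a flagged undefined result, not an exception.
Hypergeometric enrichment reports the upper-tail probability P(X ≥ k)
summed in log-space; no multiple-testing correction is applied inside the
enrichment call itself.

## Synthetic scenarios

`make_toy_network` emulates the structure the analyses rely on: a
glucose-like input feeding a pentose-phosphate-like NADPH source (2 NADPH
per carbon unit), cystine uptake reduced to two cysteines per NADPH,
glutathione synthesis consuming cysteine and glutamine and co-exporting an
arginine-like byproduct, glutamine-driven mitochondrial fumarate production
with NADH yield, an FH reaction (fumarate → malate) and downstream
NADH-yielding malate oxidation, plus seed-varying decoy chains.  Planted
fluxes are assembled chain-by-chain and asserted steady-state and
bound-feasible at generation; expression truth is assigned so HIGH genes
sit only on reactions carrying at least ε_act and LOW genes only on
zero-flux reactions.  Design choices worth stating explicitly:

* The wild-type twin's FH reaction carries a small constitutive lower
  bound (default 1 flux unit), standing in for measured FH activity, so
  the knockout/wild-type fumarate contrast is structural at the network
  level rather than depending on a particular context fit.
* The methionine-to-cysteine salvage route is present only in the
  wild-type twin.  The FH-deficient scenario encodes the cystine-dependent
  glutathione phenotype — glutathione synthesis drawing cysteine
  exclusively from NADPH-consuming cystine reduction — which is precisely
  the structural dependence the dependency scan and redox-coupling
  analyses are designed to detect; with a free methionine bypass that
  dependence would not exist in the toy at all.
* Measurement noise is multiplicative Gaussian, fᵢ = vᵢ\*(1+εᵢ),
  εᵢ ~ N(0, σ): consumption-release errors scale with magnitude.
  Expression truth is categorical; a continuous mode samples the three
  categories from shifted log-normals so quantile discretisation can be
  exercised end-to-end.
* The cross-validation fixture (`make_conservation_network`) partitions
  its exchanges over several independently balanced pools.  Each held-out
  flux is exactly determined by the rest of its pool; using several pools
  (rather than one) prevents the leave-one-out predictions from being a
  single affine function of the measurements, which would make the
  validation trivially perfect under any noise level.

What the toys do **not** emulate: genome-scale size (they stay ≤ 200
reactions against ~2,000-reaction human reconstructions), elemental
stoichiometric fidelity, thermodynamic (ΔG) constraints, flux loops and
loop-law corrections, transcript-level GPR weighting, or biological
measurement error structure beyond multiplicative Gaussian noise.  Passing
tests therefore certify the correctness and the qualitative sign behaviour
of the algorithms, not quantitative predictions for real cell lines.

## Problem sizes and numerical choices

Default analyses and the reproduction script use toy networks of roughly
25–45 reactions, 8-to-20-point sweep grids, 10-exchange cross-validation
fixtures over 20 seeds, and oracle comparisons on ≤ 8-reaction networks —
sizes chosen so the full suite and the reproduction script each run in a
few tens of seconds on one CPU while still exercising every code path.
Steady-state and bound tolerances are 10⁻⁶ (matching double-precision LP
solver defaults); FVA endpoint inversions below solver tolerance are
midpoint-collapsed; capacities are clipped at zero.  Solver stdout is
parked during solves (HiGHS occasionally emits C-level diagnostics);
results go only to files and logs to stderr.

## Known limitations

* Objective-only locking of the expression fit follows the
  space-of-alternative-optima reading; locking one concrete activity
  pattern would shrink downstream ranges and is not offered.
* The coupling comparison's two-sample construction is underdetermined
  (see above); the reported p-values characterise the scan distribution,
  not a canonical published statistic.
* FVA over a space with binary indicators reports the union over discrete
  activity patterns; pinned sweep levels inside an FVA range can then be
  infeasible (the projection need not be convex).  Such grid points are
  skipped and flagged.
* SBML support is read-only and limited to the FBC flavour via cobrapy;
  anything else is rejected loudly rather than partially parsed.
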