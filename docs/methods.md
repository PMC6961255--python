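# Methods

## The model

A constraint-based metabolic model is the polytope
{v : **S**v = 0, α ≤ v ≤ β}.  The enzyme-constrained form adds a single
linear protein-allocation constraint Σ vᵢ·cᵢ ≤ P_eff with enzyme cost
cᵢ = MWᵢ/k_cat,ᵢ (g·h/mmol), embedded as one pseudo-metabolite row
(coefficient −cᵢ in every catalyzed column) and one pool-delivery
pseudo-reaction with upper bound P_eff.  This is an exact reformulation
of the explicit program with per-enzyme concentration variables
(vᵢ ≤ k_cat·gᵢ, Σ gᵢ·MWᵢ ≤ P): substituting gᵢ at its lower limit loses
nothing, and for multi-enzyme reactions using the *minimal* cost
min_E MW_E/k_cat,E keeps the flux space identical, because any optimum in
which the pool binds routes the flux through the cheapest enzyme.  The
test suite verifies this equivalence numerically against an independent
LP oracle that keeps all gᵢ variables explicit (one (reaction, enzyme)
pair each, flux shares summing to the column flux), built on
scipy/HiGHS so the two routes share no solver code.

Assumptions inherited from the formulation: costs are linear in flux
(no substrate-saturation kinetics inside the LP), the pool covers
metabolic enzymes only, and exchange, biomass and gene-less reactions are
pool-exempt (cost 0).

### Preprocessing

Reversible catalyzed reactions must be split before augmentation, since a
single column cannot carry a direction-specific cost.  A reaction with
bounds (α<0, β) becomes a forward copy [0, β] and a reversed-stoichiometry
copy [0, −α], suffixed `_fwd`/`_rev`; a direction map is always returned
so no downstream code parses identifiers.  The default scope splits only
enzymatic reactions (all that the pool row needs); flux-variability
comparisons use `scope="all"` so both models being compared have the same
column semantics.

### Enzymes from gene rules

Gene-protein-reaction rules are normalized to OR-of-ANDs: each AND
conjunct is one enzyme (a complex whose MW is the copy-number-weighted
sum of subunit masses, default copy number 1), each OR alternative an
isozyme.  Enzymes with a subunit missing from the molecular-weight table
are dropped with a warning; a reaction losing all its enzymes becomes
enzyme-free rather than failing the build.  Cost ties between isozymes
are broken by lexicographic enzyme id, so reports are reproducible.

### Units

k_cat is stored in 1/h (database entries in 1/s are converted by ×3600),
MW in g/mmol, fluxes in mmol/gDW/h, pool in g/gDW.  With these choices
every pool-row coefficient is dimensionally consistent and no conversion
happens at solve time.

## Turnover-number assignment

For each catalyzed reaction direction, candidate values are drawn from an
EC-keyed local database snapshot (value in 1/s, substrate ids, source
organism).  Selection order:

1. entries matching any of the reaction's EC numbers (field-wise
   comparison; `-`/`*` and missing trailing fields are wildcards);
2. filter to entries sharing at least one substrate with the direction's
   consumed metabolites (namespace ids, compartment tags stripped);
3. among those, take the taxonomically nearest entries, relaxing the
   distance one lineage level at a time while fewer than `min_count = 10`
   values have been collected;
4. only if *no* entry matches the substrates at any distance is the
   substrate filter dropped and step 3 repeated over all entries.  The
   ordering "substrate filter first, relax taxonomy within it, drop the
   filter only when empty" is a design choice of this package; when the
   filter had to be dropped but the opposite direction found
   substrate-matched data, the opposite value is mirrored instead, which
   keeps directional evidence ahead of substrate-less evidence.

The arithmetic mean of the collected values (pooled with any custom
per-enzyme overrides) is the assigned value — a deliberate raw-scale mean,
no log transform.  Directions with nothing at all mirror their opposite
direction; whatever remains receives the default, the median of all
directly assigned values, computed once after all selections.  The median
is taken over reaction-*direction* values (the finer granularity; the
coarser per-reaction median differs only when many reversibles are
one-sided, and the direction level is what the cost table consumes).
Taxonomic distance is the index, within the query organism's ancestor
lineage, of the first ancestor shared with the subject; unknown taxa count
as maximally distant.  Congeneric species therefore need a
species-distinguishing first lineage element to resolve at distance 1 —
the bundled toy taxonomy does this.

Invariants checked by tests: determinism, monotone growth of the
candidate set under relaxation, and scale equivariance (scaling the
database scales every assignment and the default).

## Calibration

The fit objective is the weighted symmetric relative error
Σⱼ Σᵢ w·max(vᵐ/vᵖ, vᵖ/vᵐ), which is ≥ Σ w with equality exactly at
perfect prediction.  Zero-valued measurements are rejected outright (the
ratio is undefined; silent ε-substitution would hide the problem).
Failed or non-positive predictions take a large finite penalty (10⁶ per
unit weight) so scalar searches remain stable across infeasible regions.

Fitting is deliberately derivative-free and deterministic:

- **Pool:** P_eff is fitted to growth-rate terms only, by a 25-point grid
  scan over the search interval refined with a bounded scalar
  minimization (tolerance 10⁻⁴ g/gDW).  When no interior point beats the
  interval endpoints the better endpoint is returned with a warning.
- **Preselection:** a reaction's k_cat is fit-safe when perturbing it
  2-fold up and down changes the predicted growth of exactly one scenario
  (by more than 10⁻⁶) and no other — fitting it cannot silently degrade
  the remaining scenarios.  The perturbation factor δ=2 and the fitting
  band below are package choices, exposed as parameters.
- **k_cat fit:** coordinate descent over the preselected reactions in
  model order, each reaction's directions scaled jointly on a log axis
  confined to [k/100, k·100], grid-plus-refinement per coordinate, sweeps
  until a full sweep improves by < 10⁻⁶.  Only improving moves are
  accepted, so the final objective provably never exceeds the initial
  one.

Because the augmented matrix stores costs, not k_cat values, refitting a
k_cat is implemented as an exact multiplicative rescaling of the matching
pool-row coefficient; the chosen enzyme never changes (all enzymes of a
direction share the assigned k_cat, so the argmin is fixed by MW).

## Analyses

Flux variability runs paired LPs per reaction (via cobrapy), flags
blocked reactions (|min|, |max| < 10⁻⁶) and "practically unbounded" ones
(|bound| ≥ the model's artificial bound, 1000 by convention).  Uptake
scans fix the substrate exchange at each grid value between the minimal
feasible uptake (set by maintenance demands) and the maximal attainable
uptake (both LP results), maximize growth, and report product exchange
fluxes from a secondary parsimonious LP at fixed optimal growth — the
tie-break that makes the reported exchange fluxes unique and hence
assertable.  Range-shrinkage summaries compare width tables over the
shared reaction set and verify containment (the pool row can only remove
flux vectors).

## Enzyme-concentration integration

A measured concentration [E] (mmol/gDW) bounds Σ v/k_cat over the
reactions E catalyzes, encoded as one pseudo-metabolite consumed with
coefficient 1/k_cat by every E-exclusive column and one delivery reaction
bounded by [E].  Where E shares a reaction with other enzymes, the column
is split: a new E-exclusive copy (suffix `_enz_<id>`, cost MW_E/k_cat)
and the original column re-minimized over the remaining enzymes.  If the
shared reaction carried a finite bound, a linking "arm" pseudo-metabolite
(produced 1:1 by every copy, drained by a reaction bounded at the
original β) enforces the bound on the *sum* of the copies — one
admissible encoding of a constraint whose internal representation is not
standardized.  Supplying a non-limiting concentration (10⁹ mmol/gDW) for
every enzyme yields the fully expanded GECKO-analogous model; tests
verify it leaves every LP optimum and FVA range unchanged.

## Synthetic fixtures — what they do and do not show

The toy generator emits a seeded linear pathway (uptake, n 1:1
conversion steps, biomass drain) covering every structural case the
pipeline must handle: a reversible enzymatic reaction, an isozyme pair, a
complex with subunit stoichiometry 2, enzyme-free boundary reactions and
an optional maintenance demand.  Kinetic parameters are seeded draws in
realistic ranges (k_cat 10–100 /s, subunit masses 20–100 g/mmol ≈ 20–100
kDa); the accompanying database holds ten same-organism substrate-matched
entries per direction at the true value plus sister-taxon decoys at 7×,
so assignments are only correct if the substrate/taxonomy logic is.
Measurements are produced by solving the generated model itself, noise
off by default so calibration has a known optimum (optional seeded
lognormal noise is available).  The overflow fixture is a two-pathway
energy model whose critical uptake, maximal uptake and minimal uptake are
closed forms of the chosen costs.

These fixtures exercise correctness of the transformations, not realism:
they contain no promiscuous-enzyme webs at genome scale, no thermodynamic
infeasibilities, no measurement bias, and their databases are consistent
by construction.  Passing tests therefore demonstrate that the machinery
is exact and deterministic, not that database-derived k_cat values are
accurate for any real organism — that is precisely what the calibration
layer exists to absorb.

Problem sizes throughout (4-step pathways, 20-seed oracle sweeps, 3-seed
calibration recoveries) were chosen as the smallest sizes that exercise
every structural case; the whole suite and the acceptance script each run
in a few seconds on one CPU.

## Known limitations

- The compact formulation cannot report *which* isozyme carries flux when
  several could (it always books the cheapest); use the GECKO expansion
  when per-enzyme usage matters.
- Calibration is a sequence of 1-D searches, not a joint optimization;
  with strongly coupled parameters it finds a good, reproducible
  objective value rather than a certified global minimum.
- The k_cat database format is a local snapshot; live retrieval from
  public kinetic databases is out of scope by design, so results are only
  as current as the snapshot provided.
- SBML round-trips preserve values to printed double precision, not
  bit-exactly.
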