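# Methods

This note documents the models, numerical choices, and deliberate limitations
behind `mfa2s`, in the order data flows through the pipeline.

## Network model and the core/non-core split

A `NetworkModel` is ordinary constraint-based fare: metabolites with BIGG-style
ids (compartment suffixes `c`, `m`, `x`, `e`), reactions with signed
stoichiometry and flux bounds in mmol/gDW/h, and the steady-state constraint
`S·v = 0` over all metabolites (exchange reactions open the boundary).  SBML
Level 3/FBC is the on-disk format (Level 2 accepted); carbon counts come from
chemical formulas, and species without a formula get `n_carbons = 0`, which
excludes them from labeling but not from stoichiometry.  That rule is also
used deliberately: cofactors (ATP/ADP/Pi/CoA/H₂O) in the toy network carry no
carbon and are buffered by reversible sink reactions, because the package
models carbon flow, not energy or redox balance.  The acetyl-CoA-handling
reactions still carry their full cofactor stoichiometry (ATP citrate lyase is
`cit_c + atp + coa + h2o → oaa_c + accoa_c + adp + pi`).

The *core* is the subset of reactions carrying carbon-atom maps; the split is
valid only if every core reaction is mapped and every mapped reaction is core.
Atom maps live in a three-column TSV (`reaction_id`, reactant slots, product
slots; slots are `metabolite=letters` tokens, letters conserved across sides).
Symmetric metabolites are declared in the same file (`#! symmetric:`
directive) because plain SBML has no slot for that fact.

The two-scale validity assumption is that carbon flows from the core to
peripheral metabolism and not back.  The simulation therefore ignores unmapped
influx into core pools; ELVA (below) quantifies what that ignoring could cost.

## Labeling simulation (EMU)

Mass distribution vectors are simulated with the elementary-metabolite-unit
decomposition: the fragments to be predicted are traced backward through the
atom maps, and one dense linear system is solved per EMU size, smallest size
first, with condensation reactions entering as convolutions of smaller EMUs.
Core networks here are small (tens of EMUs per size), so dense LU solves are
the right tool; no sparse machinery.

Choices that matter:

* **Reversibility.** Reversible core reactions are decomposed into forward and
  backward fluxes; the net flux is their difference and the bidirectional
  (exchange) flux `min(fwd, bwd)` is capped (default 300 mmol/gDW/h, ~100× the
  default glucose uptake).  Labeling sees only the non-negative directed
  fluxes.
* **Symmetry.** Reactions consuming a symmetric metabolite (succinate,
  fumarate) are expanded into orientation variants of weight ½; a measured
  fragment on a symmetric metabolite is read out as the average of the
  fragment and its mirror.
* **Steady state.** Both metabolic and isotopic steady state are assumed — the
  study design samples labeling deep in exponential growth (15 h); there is no
  isotopically non-stationary mode.
* **Degenerate fluxes.** An EMU whose metabolite has (numerically) zero influx
  is parked at M0 when nothing consumes the pool at that flux vector — this
  happens legitimately when the optimizer pushes a branch to zero — but a pool
  with zero influx and real outflux demand, or a subnetwork carrying
  circulating flux with no external input, raises a diagnostic error naming
  the offender.  During fitting those diagnostics are converted into a large
  flat objective so the line search backs off.
* **Feed.** The tracer mixture is positional patterns with molar fractions
  (default 80% [1-¹³C] + 20% [U-¹³C] glucose); nominally labeled positions can
  be diluted by an isotopic-purity parameter (default 1.0, since certificates
  state ≥99% enrichment).  Natural-abundance correction of measured MDVs is
  provided (standard correction-matrix inversion over the non-carbon elements
  of the fragment formula, small negatives clipped and logged) but optional —
  the synthetic data are tracer-only.

The analytic Jacobian of every simulated MDV with respect to the directed
fluxes is propagated size-by-size through the same LU factorizations (the
balance matrices are linear in flux, so their derivatives are constant index
patterns), which is what makes the fit and the variability analysis cheap.

An independent brute-force oracle solves the full positional-isotopomer
balance (2ⁿ states per metabolite, Gauss–Seidel fixed point, pool-level
symmetrization) for networks up to 24 total core carbons.  It shares no
machinery with the EMU path and pins it down to ~1e-13 per channel on the
shipped fixtures.

## Measurements

Amino-acid MDVs are whole-molecule (no fragmentation).  Each amino acid is
tied to central metabolism by a curated recipe — a convolution of cytosolic
precursor EMUs (e.g. Val = pyr{1,2,3} ⊗ pyr{2,3}; Phe = pep{1,2,3} ⊗ pep{2,3}
⊗ e4p{1–4}; Arg includes a CO₂ carbon) — shipped as an editable TSV.  All
amino-acid pools are treated as cytosolic; mitochondrial amino-acid synthesis
is deliberately not modeled.

MDV tables are renormalized when their row sum is within ±0.02 of 1 and
rejected (with line numbers) otherwise; per-channel standard deviations are
floored at 0.005 mole fraction so a single lucky channel cannot dominate the
SSR.  Exchange fluxes come either directly (TSV of `reaction_id, rate, sd`,
uptake negative) or from timecourses: growth rate μ from a log-linear OD fit,
yield Y from a linear fit of concentration against biomass (0.835 gDW/L per
OD unit), rate = Y·μ; standard errors are propagated from the fits, and
two-point fits (the minimal HPLC design) fall back to a 5% default relative
sd because residual-based errors need ≥3 points.

## Flux fitting

The estimator works in null-space coordinates: directed fluxes are
`d = v_p + N·α` with `N` a basis of the null space of the steady-state system
(bounds pinned to a single value are moved into the equality system, so
knockouts keep the polytope full-dimensional in α).  Mass balance then holds
identically and only bound inequalities remain.  SSR is minimized by SLSQP
with the analytic gradient, restarted from the Chebyshev center and seeded
hit-and-run samples of the polytope interior (default 10 starts) — the SSR
landscape is nonconvex and the multistart is the global-reliability device.
The best feasible iterate ever seen is kept, so reported SSR never exceeds
any evaluated iterate.  Growth enters as a residual on the biomass reaction;
measured uptake is a soft residual by default (pin the exchange bounds to make
it hard).  Fits are bit-reproducible for a fixed seed.

Goodness of fit is judged against a two-sided 95% χ² band with
dof = n_residuals − rank of the residual Jacobian at the optimum; the rank is
the honest count of identifiable parameter combinations and is computed by
SVD rather than assumed.

## Confidence intervals and ELVA

¹³C flux variability analysis minimizes and maximizes each net flux subject to
the bounds and a profile-likelihood ceiling `SSR ≤ SSR_opt + χ²(α, 1)` (a
global `χ²(α, dof)` ceiling is available as an option).  Each direction is
warm-started from the optimum and from a bisection point where the SSR along
the flux direction crosses the ceiling, so flat (structurally unidentifiable)
directions reach the polytope boundary even if the local solver stalls; inner
failures flag the interval as unreliable rather than tighten it.  If an inner
optimization terminates short of the best fit, the interval is widened to
contain it and a warning is logged — an interval that excludes its own point
estimate is treated as an inconsistency, not a result.  Intervals print in the
field's notation, `best [lo–hi]`.

ELVA bounds, per measured fragment, the worst-case probability τ that a
fragment molecule carries any carbon that entered the core through an unmapped
reaction, at the fitted flux magnitudes: unmapped influx counts as fully
tainted, the feed as clean, flux-weighted averaging propagates τ, and
condensations combine independently (`1 − Π(1 − τᵢ)`).  No MDV channel can
move by more than τ whatever labeling that carbon carries, so fragments with
τ below the threshold (default 0.01 mole fraction) certify the core set; the
minimum achievable perturbation is 0.  The bound is conservative (worst case
over labeling), which is the right direction for a validity check.

## Synthetic data: what it emulates and what it does not

The toy yeast network (~50 reactions; cytosol, mitochondrion, extracellular;
the peroxisome is omitted because no reported balance needs it) covers
glycolysis, the oxidative and non-oxidative pentose phosphate pathway,
pyruvate decarboxylase/dehydrogenase, ethanol/acetate/glycerol secretion,
acetyl-CoA synthetase, optional ATP citrate lyase, pyruvate carboxylase, the
TCA cycle with citrate/malate/oxaloacetate shuttling, the glyoxylate-shunt
malate synthase, GPD1, and an acetyl-CoA carboxylase gateway into a lumped
fatty-acid drain.  Six variants mirror an engineering series: ACL present or
absent, malate synthase downregulated (upper bound 0.3 mmol/gDW/h), GPD1
knocked out (bounds 0).  Biomass drains canonical precursor demands
(~30 mmol carbon per gDW).

Ground truths are seeded hit-and-run samples of the variant's flux polytope
with glucose uptake pinned at 3.0 mmol/gDW/h — a fixture parameter at the
order of magnitude of glucose-limited shake flasks, not a claim about any
measured culture.  Noise is additive Gaussian on MDV channels (default sd
0.01 mole fraction, the conventional LC-MS assumption), clipped at zero and
renormalized, plus 5% relative noise on exchange fluxes and growth rate;
`noise_sd = 0` reproduces the truth exactly.  What passing tests on these
fixtures shows: the estimator, intervals, and reports are correct and
calibrated *under this error model and network*.  What they do not show:
robustness to correlated instrument error, natural-abundance residuals,
compartment-pool mixing, or model misspecification in a real genome-scale
reconstruction.

Problem sizes used by the test suite and the acceptance script (noiseless fit
plus 10–20 noisy replicates, intervals profiled for the handful of reactions
the balance tables report) were chosen so the whole analysis reruns from
scratch in minutes on one CPU; they are fixture parameters, not statistical
claims.

## Known limitations

* Carbon-only accounting: no energy/redox constraints, so flux modes that are
  thermodynamically implausible are excluded only by bounds.
* Local optimization with multistart carries no global-optimality certificate.
* Profile-likelihood intervals are asymptotic; no bootstrap alternative.
* The ELVA bound is worst-case and can flag a core set that is in fact
  adequate; it cannot miss one that is inadequate by more than the threshold.
* Amino-acid recipes assume cytosolic precursor pools; organisms with strong
  mitochondrial amino-acid synthesis need edited recipes and a larger core.
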