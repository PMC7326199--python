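# Methods

## Scope and model

`grnode` treats a gene regulatory network at two levels: a signed directed
graph `([n], E, b)` with `b_ij ∈ {+1, −1}`, and a module-based ODE model
over mRNA abundances `x` (observed) and protein concentrations `y`
(hidden). The ODE level follows the generative scheme popularized by the
GeneNetWeaver simulator: transcription factors act on a target through
*cis*-regulatory modules; the input sets of a target's modules partition
its regulator set, so each TF influences a given target through exactly
one module. Modules are enhancers (`c = +1`) or silencers (`c = −1`), bind
independently (mode `r = 0`, Shea–Ackers Type 1) or as a complex (`r = 1`;
Type 2 if all inputs activate, Type 3 if some deactivate), and contribute
`c·β·M` to the target's production rate on top of the basal rate
`α_basal`, with `M` the module's activation probability built from Hill
terms `ν_ij = (y_i/k_ij)^{h_ij}`. Dynamics are first order:
`ẋ_j = f_j(y) − δ_j x_j`, `ẏ_i = ρ_i (x_i − y_i)` (protein units chosen so
translation and protein degradation rates coincide).

A module whose formula is forced into the Type-3 shape while it has no
deactivators is rejected rather than silently reduced to Type 2: with the
empty product over deactivators read as 1 instead of 0, the Type-3
denominator corrupts Type-2 modules, a mistake subtle enough to have
shipped in early simulator code. The constructor therefore derives the
type from `(r, D)` and refuses the inconsistent combination.

### Production-rate conventions

Three conventions for combining modules are implemented and named
explicitly, because they differ in exactly the regime that matters for
sign analysis:

* `linear` — `f_j = α_basal + Σ_K c_K β_K M_K`. This equals the expectation
  of per-configuration promoter activities under independent Bernoulli(M)
  module states when activities combine linearly. Globally sign-stable.
* `truncated` — every per-configuration activity is clipped to `[0, 1]`
  and the expectation is taken explicitly over the `2^{|S_j|}` on/off
  configurations (the behaviour of the simulator source). Monotonicity in
  a single module activation is no longer guaranteed.
* `clip` — a single outer `max(·, 0)` on the linear rate. This is the
  convention the five-gene case-study equations use, and it is the one the
  case-study classes are built with. `clip` and `truncated` genuinely
  differ (the outer clip acts on the mean, the truncated form on each
  configuration), so both are kept.

### Nondimensionalization

`δ_j = α_basal,j + Σ_K β_K` makes the maximal production rate equal the
degradation rate, so steady states lie in `[0, 1]` and trajectories
started in the unit box stay there (up to solver tolerance). The operation
is idempotent and is applied by the random sampler and the case-study
builder.

## Random model generation

The sampler draws, per regulated gene: a uniform partition of the
regulator set into module input blocks (partitions are enumerated
exhaustively, which is exact for in-degree ≤ 10 and covers every network
this package targets); per block, a type drawn uniformly among the
sign-consistent options and a mode `r ~ Bernoulli(1/2)` for multi-input
blocks (single-input modules are always independent single-activator, the
only consistent form). Sign consistency `b_ij = c·(1{i∈A} − 1{i∈D})`
determines the activator/deactivator roles once `c` is chosen, and is
validated on every constructed model.

Continuous parameters are uniform draws with documented default ranges:
`k ~ U(0.01, 1)` (protein-concentration units, spanning weak to strong
binding on the nondimensional scale), `h ∈ {1, 2, 3, 4}` uniformly
(cooperativities beyond 4 are rare in practice), `β ~ U(0.2, 1)` (module
effects comparable to basal rates so no edge is cosmetic),
`ρ ~ U(0.5, 2)` (protein time scales within a factor 2 of the mRNA scale),
and `α_basal ~ U(0, 0.2)` offset by the summed silencer effects for genes
with silencer modules — without the offset a silencer could never lower
expression below zero production and its edge would be invisible. These
ranges are knobs (`ParamRanges`), not claims about any organism; what the
tests rely on is only the structural constraints above.

## Constant-sign analysis

Two per-pair sign notions over a state–parameter condition `(x, λ)`:

* **Sum–product** (`b_sum`): the molecular graph connects internal classes
  `k → l` where `f_l` actually depends on component `k` (declared
  sparsity; "actually depends on" is not decidable from point samples, so
  the pattern is declared, with a sampling-based warning for declared but
  never-active pairs). An *unobserved path* from regulator `i` to target
  `j` passes only through unobservables in its interior; degradation
  self-loops are never traversed (they carry no regulator-to-target
  influence, and skipping them is what makes a translation/production
  two-layer model's molecular graph effectively bipartite, with all
  regulator–target pairs at molecular distance 2). The statistic
  `Δ = Σ_paths Π_steps ∂f` over shortest paths is classified by sign.
* **Infinitesimal** (`b_inf`): integrate the *clamped* system — every
  observable except the target and every signal frozen — from the given
  state with the regulator offset by `±h`, and classify the sign of the
  difference quotient of the target across a probe grid
  (`h ∈ {±10⁻³, ±10⁻²}`, `t ∈ {10⁻³, 10⁻², 10⁻¹}`). The exact definition
  quantifies over all sufficiently small `t` and `h`; the finite grid is a
  numeric surrogate. Grid points whose difference is below a noise floor
  (10⁻¹², solver-accuracy territory at DOP853 tolerances rtol 10⁻¹¹ /
  atol 10⁻¹³) are uninformative; all-uninformative probes return the empty
  verdict.

Per-pair verdicts are unioned over a sample of conditions; the constant
sign property holds when no pair accumulates `{1, −1}`, in which case the
induced graph collapses to a signed digraph. For module models with
`linear` production the induced graph equals the generating graph — the
test suite verifies this exactly on 100 random graphs (n ≤ 8, 20 states
each) and verifies probe/sum-product agreement on 50 random models × 10
states. No such recovery is asserted for `truncated`/`clip` production,
whose clipping can destroy monotonicity; the recovery claim is an
untruncated-regime property.

### Numerical sign classification

The zero case of the sum–product sign is classified with a *relative*
band: `|Δ| ≤ 10⁻⁹ · Σ_paths |Π ∂f|` → indeterminate. A single path keeps
its exact sign however small its magnitude (saturated Hill terms routinely
push `Δ` to 10⁻¹⁵ while its sign remains provably fixed); only deep
relative cancellation between paths, or an exact zero, is indeterminate.
With finite-difference partials (the fallback when no analytic partials
are supplied; central differences, step `10⁻⁶·(1+|x|)`), values near a
true sign-switch boundary inherit truncation noise — supply analytic
partials when behaviour *at* such boundaries matters, as the test fixtures
do.

Self-effects (`i = j`) are out of scope for all sign notions: a self-loop
conflates autoregulation with degradation and the clamped construction
cannot separate them.

## Synthetic datasets

Datasets are multi-shot: `S` trajectory sets share dynamics parameters and
differ only in initial conditions `x(0), y(0) ~ U(0,1)^{2n}`; only the
mRNA variables are recorded, at `t = 0, 1, …, 6` by default (so one set of
a five-gene model contributes 35 observations). A one-shot design (each
observation from a distinct individual, as in destructive sampling) is
provided for contrast but unused by the case study. Reference
integration uses LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ — integration error must
sit far below the ~10⁻³ loss scales the fitting experiment resolves.

The null generator produces reflected Brownian motion per set and gene:
increments of variance `0.05·Δt` (the "covariance 0.05" is read as
variance rate per unit time, with Δt = 1 between samples), folded into
`[0, 1]`, started uniformly. Pre-reflection paths can be returned so
increment statistics are testable.

What the generator does *not* emulate: measurement noise on `x`,
perturbation/knockout designs, external signals, slow protein–protein
interactions, or stochastic (Langevin) transcription. Tests passing on
these datasets therefore demonstrate correctness of the machinery under
the model's own assumptions, not robustness to real-data nuisance
structure.

## The case study

Gene order `(E1, COL1a, FT4, FT2a, AP1a)`; the flowering graph has 7
signed edges, its variant flips the COL1a→E1 sign, and a five-gene
repressilator serves as an unrelated control. With the canonical
enumeration order (fewer module blocks first, independent before
synergistic, enhancer before silencer), gene 3 admits 3 configurations and
gene 5 admits 5, giving 15 ODE classes per flowering graph, indexed
`F[i,j]±`; the repressilator class `R` is unique.

Free continuous parameters of a class: per-gene `α_basal` and `ρ`,
per-edge `k`, per-module `β` (22 for configuration `[1,1]`, 24 for
`[3,5]`, 20 for `R`), plus `2n` initial conditions per trajectory set;
`δ` is derived by nondimensionalization and Hill constants are fixed known
integers (default 2) — the time scale is treated as known, which acts as a
regularizer. A separate accounting convention
(`2·genes + 2·edges + extra-module increments + 10·S`) counts `k` and `β`
per *edge* rather than per module and is what the conventional parameter
table for these classes reports (34/36/30 at S = 1); both counts are
exposed, the fitted vector uses the per-module one that matches the
printed equations.

The canonical data-generating model is a single documented draw of the
sampler restricted to configuration `[1,1]` with `h = 2` (seed 7), shipped
as a JSON fixture (`grnode/data/f11p_true_model.json`) so every experiment
reuses identical dynamics.

## Fitting

Loss is the root-mean-square difference over all `S·T·n` tensor entries;
the coefficient of determination is pooled, `1 − SS_res/SS_tot` with
`SS_tot` about the grand mean of all entries (a per-gene diagnostic is
available). Pooling was chosen because each experiment cell reports a
single scalar; per-trajectory averaging would weight short excursions
oddly.

Global optimization is basin hopping: bounded least-squares local solves
(`scipy.optimize.least_squares`, trf) alternating with random kicks —
multiplicative log-normal (σ = 0.5) on dynamics parameters, which respects
positivity, and uniform resampling of initial-condition parameters within
`[0, 1]`. Every third hop restarts from a fresh random point instead of
kicking the incumbent, so a deep but wrong basin cannot trap the whole
run. Starting points draw dynamics parameters log-uniformly (floored at
10⁻²) and initial conditions uniformly. All randomness flows through
one seeded generator; identical seeds give identical results, and the
best-so-far loss is monotone nonincreasing in the hop budget. Objective
evaluations that raise or return non-finite values score a large finite
residual instead of aborting the run. Bounds: dynamics parameters
`(10⁻⁶, 10]`, initial conditions `[0, 1]`.

The fitting objective integrates trajectories with fixed-step classical
RK4 (step 0.02, all sets stacked into one system), compiled with numba
when available and bit-identical to a pure-numpy fallback; global error
~step⁴ ≈ 10⁻⁷ sits orders below the loss scales compared, and the
fixed-step scheme avoids adaptive-solver overhead across the ~10⁵
objective evaluations of a fit. Starting a self-fit at the true parameters
reproduces the data to < 10⁻⁶ loss, confirming the fitting-time and
data-generation-time integrators agree.

### Experiment sizes

The cross-model experiment in the test suite runs at sizes chosen to keep
the full suite comfortably under half an hour on one core: the
correct-model self-fit uses S = 1 with 4 hops; the correct-vs-wrong-graph
ranking uses S = 5, three data seeds, 2 hops with capped local iterations
(the ranking gap — roughly 0.003 vs 0.02 RMS — is far wider than
optimizer noise at these settings); the Brownian control uses S = 1 with
2 hops, since its loss plateaus near 0.1 almost immediately. The
acceptance script reruns the S = 1 self-fit from scratch at 8 hops.

## Known limitations

* The infinitesimal probe is a finite surrogate for an ε-quantified
  definition; pathological systems whose sign flips below the smallest
  probe scale would be misclassified.
* Shortest-path dominance is a short-time statement: over longer horizons
  slightly longer paths of opposite sign can take over, and no alternative
  longer-horizon sign notion is implemented.
* Graph recovery is guaranteed (and asserted) only for `linear`
  production; the clipped case-study models can in principle lose
  monotonicity where the clip is active.
* The uniform-partition sampler enumerates set partitions and therefore
  requires regulator in-degree ≤ 10.
* Parameter-level identifiability is out of scope: the fitting experiment
  measures class-level distinguishability (trajectory loss), not recovery
  of individual rate constants.
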