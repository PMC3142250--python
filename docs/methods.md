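# Methods

This note documents the models implemented in `palmdiv`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the package's known limitations.

## Chronograms and branching times

A chronogram is a rooted, binary, ultrametric tree with branch lengths in
Ma; node ages are measured backward from the present (tips at 0, root age =
crown age).  Ultrametricity is checked on root-to-tip depths with a
*relative* tolerance (default 1e-6), because chronograms exported from
Bayesian samplers carry floating-point noise.  Polytomies are rejected by
default — every likelihood below assumes binary trees — but can be resolved
randomly into zero-length bifurcations with a seeded RNG.

All diversification machinery consumes `BranchingTimes`: the descending
internal-node ages `u_1 > … > u_{n−1}` plus a `window_end` marking where
the observation window closes (0 for complete trees; the threshold age for
truncated data).  With `u_n := window_end`, the interval during which
exactly `j` lineages exist is `g_j = u_{j−1} − u_j` for `j = 2..n`.

### Truncation convention

When nodes younger than a threshold `w` are deleted, the default convention
is that *observation ends at `w`*: the final no-event interval runs from
the youngest retained node to `w`, and `n` is the retained lineage count.
For the birth–death likelihood, ages are measured from the window end.  A
flag (`extend_to_present`) instead stretches the final interval to age 0 —
the naive reading of "delete the young nodes" — and is kept only for
comparison, since it adds lineage-time during which speciation demonstrably
did occur (in the deleted part of the tree) without any observed events.
Null trees for the Monte Carlo tests are matched to the retained lineage
count and analysed through the same convention.

## Missing-species curve and threshold

With one sampled representative per genus, speciation inside a genus can
only postdate the genus's stem node, so the species missing from genus `g`
(total `N_g` minus sampled `n_g`) start counting against the LTT plot at
`stem_age(g)`.  The curve `missing(t) = Σ_{g: stem_age(g) ≥ t} (N_g − n_g)`
(reported also as a percentage of the family total) is monotone
non-decreasing toward the present; genera whose stem age equals `t` exactly
are counted as present (the conservative choice).  Two threshold rules are
offered and always reported together:

* **tolerance** (default 15%): the oldest age at which the missing
  percentage exceeds the tolerance.  The default sits deliberately between
  a low plateau (~12%) and the steep jump (~24–28%) that a single
  hyperdiverse genus typically produces; if the tolerance is never
  exceeded, age 0 is returned with a warning flag.
* **max-jump**: the age of the single largest increment, reporting the
  genus responsible — the diagnostic for a *Calamus*-style hyperdiverse
  genus whose stem age dominates the curve.

## Diversification likelihoods

All five models are likelihoods of branching times conditioned on the
crown, and all drop the data-constant combinatorial factor `Σ ln j`
identically, so it cancels from every AIC comparison.  Rates are
per-lineage, per-Ma.

* **Pure birth**: `logL = (n−2)·ln λ − λ·S`, `S = Σ_j j·g_j`; the MLE is
  closed-form, `λ̂ = (n−2)/S`.
* **Birth–death** (net rate `r = λ−μ`, relative extinction `a = μ/λ ∈
  [0,1)`), conditioned on the crown age with both crown lineages surviving:
  `logL = (n−2)·ln r + r·Σ_{i≥2} u_i + n·ln(1−a) − 2·Σ_i ln(e^{r·u_i} − a)`.
  At `a = 0` this reduces algebraically to pure birth.
* **Two-rate pure birth**: rate `λ1` applies to tree portions older than
  the shift age `t_s`, `λ2` to younger portions; an event exactly at `t_s`
  belongs to the older regime.  For fixed `t_s` both rates have closed-form
  MLEs (events/exposure per regime), so the fit profiles `t_s` over the
  observed branching times and interval midpoints — the likelihood is
  piecewise in `t_s` — and then refines locally.
* **DDX** (exponential density dependence): `λ_j = r₁·j^{−x}`.
* **DDL** (logistic density dependence): `λ_j = r₁·(1 − j/K)`, requiring
  `K > n`; `K → ∞` recovers pure birth.

Fitting uses a derivative-free Nelder–Mead simplex on log-transformed rates
with three starting points and a 1e-8 function tolerance; every nested
model is additionally seeded at the pure-birth optimum, which guarantees
the nesting inequalities (`logL_model ≥ logL_pure_birth`) hold exactly and
makes boundary estimates (`â = 0`, `K` at its bound) explicit rather than
silent.  Non-convergence is flagged on the result, never raised.

`ΔAIC_RC` is the best rate-constant AIC minus the best rate-variable AIC;
negative values favour constancy.  Note that its *sign* is not a calibrated
test under the null: the minimum over three rate-variable models frequently
beats pure birth by chance (in our null simulations at n = 100 only ~40% of
pure-birth datasets give a negative value), which is exactly why the
parametric bootstrap exists.  The bootstrap simulates pure-birth trees at
the observed pure-birth MLE with the observed lineage count and reports the
add-one upper-tail p-value `(#{null ≥ obs} + 1)/(R + 1)`.

The γ statistic uses
`γ = [mean(T_2..T_{n−1}) − T/2] / [T·√(1/(12(n−2)))]` with
`T_i = Σ_{k≤i} k·g_k`, `T = T_n`; it is approximately standard normal under
pure birth and invariant to time rescaling, so its Monte Carlo null is
simulated at unit rate.  Both the two-sided and lower-tail p-values are
reported, the lower tail because the museum-versus-cradle contrast is
directional (rootward node crowding gives γ < 0).

## Mk1 ancestral biomes

The biome character takes k = 3 states with a single symmetric rate `q`;
the transition probabilities are closed-form
(`P_ii = 1/k + (k−1)/k·e^{−kqt}`).  The likelihood is Felsenstein pruning
with a uniform root prior (1/k per state); ambiguous tips contribute a
partial likelihood of 1 to each admissible state.  Genera spanning TRF and
non-TRF biomes are coded `{0, 2}` — mangrove is *not* an admissible
resolution of that ambiguity, since the ambiguity rule concerns TRF
occupancy; this is configurable.  The rate is fitted by bounded 1-D
maximization on the log scale (bounds 1e-8 to 1e3 per Ma); a likelihood
flat out to a bound (invariant characters; saturating two-tip data) is
reported as a boundary estimate.  Marginal "proportional likelihoods" per
node come from a single outside–inside pass and sum to 1 at every node.

Phylogenetic signal is tested by shuffling the tip-to-state assignment
(1,000 permutations by default) and comparing the observed Fitch parsimony
step count (set-valued Fitch, handling ambiguity exactly) against the
permutation null; signal is declared when the observed count falls below
the null's 0.5th percentile, and the add-one lower-tail p-value is
reported.

## Time-stratified DEC

Ranges are subsets of 7 areas with at most 2 areas (the areas are
continent-scale, so wider ancestral ranges are not meaningful; tips coded
with more than 2 areas are rejected with a recoding hint, the policy
applied to widespread genera like *Cocos*).  The anagenetic generator adds
area `b` to range `R` at rate `d·Σ_{a∈R} m(a,b)` and removes each area at
rate `e`; the null range is an absorbing state of the generator but is
excluded from cladogenesis and from the root summation.  Extirpation is
area- and epoch-independent (the time-stratification concerns dispersal
opportunity, not persistence).  Branch propagation multiplies per-epoch
matrix exponentials over the sub-intervals a branch crosses, oldest first;
the exponentials come from one eigendecomposition per epoch per rate pair
(with an `expm` fallback if the spectral reconstruction error exceeds
1e-9), and all single-epoch branches are batched through one broadcast
matrix product.  Cladogenesis enumerates the standard DEC scenarios —
identical inheritance for singletons; vicariance (one area vs the rest) and
subset sympatry (one area vs the full range), both orders — with uniform
weights summing to 1.

The root likelihood is the unweighted sum over non-null root ranges (the
Lagrange convention); a uniform-prior variant sits behind a flag and both
are recorded in the output.  `fit_dec` maximizes over `(ln d, ln e)` by
multi-start Nelder–Mead and then computes per-node marginal range
probabilities and ranked split scenarios by an outside–inside pass at the
optimum.  Because the published five-epoch multiplier matrices are not
available in machine-readable form, the package ships an *illustrative*
five-epoch M1 configuration (`example_m1_epochs`) built from the same
multiplier levels {0.01, 0.25, 0.5, 0.75, 1} and a plausible
Laurasia-centred connectivity history; it exercises the time-stratified
machinery and is clearly labelled synthetic.

## Synthetic data: what it emulates, and what it does not

The generators encode the study conditions: ~100–200 tip chronograms; a
family of 183 genera and 2,400 species with one sampled species per genus
(7.6% sampling); geometric (heavy-right-tail) genus richness, mimicking
hyperdiverse genera alongside many monotypic ones; three-state Mk biome
characters, optionally rooted in TRF; and DEC histories over 7 areas.
Specific conventions:

* Yule/birth–death/two-rate simulators condition on the *tip count*, not
  the age, because Monte Carlo nulls must match the observed tree's size.
  A final `Exp(n·λ)` interval separates the last node from the present;
  this makes the interval durations exactly the independent exponentials
  the likelihoods assume and gives the γ statistic its ~N(0,1) null
  (verified: mean within ±0.1, sd within [0.9, 1.1] over 1,000 trees).
  Under this convention the expected crown age is `Σ_{j=2}^{n} 1/(jλ)`
  (≈ 41.9 Ma for n = 100, λ = 0.1).
* The two-rate simulator draws node ages tip-rootward from the
  piecewise-exponential hazard `j·λ(t)`, which matches the two-rate
  likelihood exactly; topologies are uniform random joins (the Yule
  topology distribution).  Default shift conditions for power analyses:
  λ = 0.1 → 0.5 (five-fold) at 5 Ma with n = 200, which leaves roughly 16
  lineages in the old regime — enough signal on both sides of the shift.
* The DEC simulator resamples a branch (conditioning that lineage on
  survival) when it hits the null range, since all tips in the study
  design are extant; it does not model observed extinction.
* Posterior tree sets are emulated as independent simulations — the
  generators do not reproduce the topological correlation of a real
  Bayesian posterior sample, so ensemble credible bands on synthetic data
  are wider than those of a true posterior.

Passing tests on these generators demonstrate internal correctness and
statistical calibration (type-I error, power, estimator consistency); they
do not validate the biological assumptions — genus monophyly, biome
conservatism, the area scheme — that a real analysis inherits.

## Numerical choices and problem sizes

* Monte Carlo p-values always use the add-one estimator, so they are never
  exactly zero.
* The rate-constancy type-I error check exploits the time-rescaling
  invariance of ΔAIC_RC: one 999-draw null sample at the common tip count
  serves all 1,000 pure-birth test datasets.  Calibration lands at ~0.044
  at a nominal 0.05.
* Recovery studies run at: Mk rate, 200 trees of 200 tips (median `q̂`
  within a few percent of truth); DEC dispersal, 100 trees of 100 tips
  over the full 29-range state space (median `d̂` well within a factor of
  two).  These sizes were chosen as the smallest at which the medians are
  stable.
* Optimizer tolerances: 1e-8 on the objective, 1e-5 (diversification) /
  1e-4 (DEC) on log-scale parameters; looser x-tolerances cost nothing
  statistically because sampling noise dominates far above those scales.
* Degenerate inputs are handled explicitly: trees with < 2 tips, thresholds
  at or beyond the crown age, carrying capacities `K ≤ n`, empty tip
  ranges, and tips missing from coding tables all raise informative errors;
  invariant characters and saturated two-tip data yield flagged boundary
  estimates.

## Limitations

* No sampling-fraction-corrected diversification likelihoods: the approach
  to incomplete sampling is truncation, by design.
* No per-clade shift placement (MEDUSA-style), coalescent-based fitting,
  asymmetric or covarion Mk models, stochastic character mapping, or
  founder-event (DEC+J) cladogenesis.
* Molecular dating is out of scope; chronograms are consumed as input.
* The shipped M1 epoch configuration is illustrative, not the published
  model; real constrained analyses should supply their own epoch JSON.
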