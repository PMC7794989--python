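# Methods

## Model and scope

`emstem` simulates signed gene-regulatory circuits as deterministic ODE
systems.  Node `i` with expression level `p_i` obeys

    dp_i/dt = g_i · ∏_{j→i} HS(p_j; μ_ji, λ_ji, n_ji) − k_i p_i ,

with the shifted Hill factor `HS(p; μ, λ, n) = (μⁿ + λpⁿ)/(μⁿ + pⁿ)`:
bounded between `min(1, λ)` and `max(1, λ)`, equal to 1 with no regulator,
`(1+λ)/2` at `p = μ`, and λ at saturation.  `λ > 1` encodes activation,
`0 < λ < 1` inhibition.  The *maximal* production rate `G = g·∏λ⁺` (product
over incoming activating edges) is the sampled quantity; the basal rate `g`
is derived, so `G` is the level reached with all activators saturated and
all inhibitors off.  There is no stochastic dynamics, no explicit time
delay, and no limit-cycle analysis: trajectories that fail the steady-state
criterion are logged and excluded.

Family-level regulators (miR-200, let-7, ZEB, LIN28) are collapsed to
single nodes, as is conventional for this circuit.  OCT4 is not modeled
explicitly; LIN28, its direct upstream regulator, serves as the stemness
readout.

## The ensemble is the synthetic-data generator

No external data enter the pipeline.  The object of study is the *ensemble*
of random parameterizations of a fixed topology — a model of cell-to-cell
kinetic variability within a population.  Defaults (one "model" = one
parameter set):

| parameter | distribution | default |
| --- | --- | --- |
| maximal production `G` | uniform | [1, 100] (rate units) |
| degradation `k` | uniform | [0.1, 1] (1/time) |
| Hill coefficient `n` | uniform integer | {1, …, 6} |
| activation fold `λ⁺` | uniform | [1, 100] |
| inhibition fold `λ⁻` | reciprocal of uniform [1, 100] | median 0.02 |
| threshold `μ` of edge `s→t` | uniform | [0.02·M_s, 1.98·M_s] |
| initial conditions | log-uniform per node | [L, U] (below) |

These are the published defaults of the random-circuit-perturbation
(RACIPE) family of methods; ranges were originally motivated by surveyed
kinetic constants.  All are overridable via `SamplingRanges` / YAML config.

**Threshold calibration (half-functional rule).**  `M_s` estimates the
median level of the *source* node across the ensemble, so that an outgoing
link is functional (its threshold crossed) with roughly even odds.  A node's
level distribution depends on its own regulators: a strongly repressed node
(e.g. a microRNA inside a toggle) typically sits far below its free level
`G/k`.  `threshold_medians` therefore estimates `M_s` by Monte Carlo, one
regulatory level deep: sample `G/k` for the source, multiply by the shifted
Hill factor of each incoming edge with the regulator's level drawn from its
*unregulated* `G/k` distribution (and inner thresholds around the
regulator's unregulated median), take the median.  The Monte Carlo uses a
fixed internal seed (20 000 samples), making the calibration a pure function
of topology and ranges.  The cruder alternative `threshold_rule =
"unregulated"` (`M = mid(G range)/mid(k range)`) is retained for comparison;
it under-activates links into repressed nodes and collapses the circuit's
multistability (a plain toggle switch drops from ~21% to ~7% bistable), so
it is not the default.

**Perturbations.**  Over-/down-expression by `fold` multiplies both ends of
the node's `G` sampling range (oe10 = ×10, de10 = ×0.1).  Thresholds always
use the unperturbed reference ranges, so a perturbation shifts production
only — matching how the perturbation is defined in the method this package
follows.

**Initial conditions.**  Per node, `U = G/k` (activators saturated,
inhibitors off) and `L = (G/∏λ⁺)·∏λ⁻/k` (the opposite extreme); `count`
initial states are drawn log-uniformly on `[L, U]`.  Input-less nodes get
`G/k` exactly.  Defaults: 100 initial conditions at paper scale, 50 at desk
scale (state counts are insensitive between 50 and 200 on the base circuit;
states reachable only from minute basins may still be missed — a limitation
shared with the method itself).

**Randomness.**  Each parameter set uses an independent substream
`default_rng([seed, replicate, index])`; ensembles are bit-reproducible
given `(seed, replicate)` and statistically independent across replicates.

## Steady-state enumeration

Per parameter set each initial condition is integrated with an exponential
(production–decay) Euler scheme compiled with numba: production is frozen
over a step and the decay integrated exactly, which preserves positivity
and is unconditionally stable in the linear part.  Two safeguards handle
the steep Hill regions (λ spans two orders of magnitude, so the dynamics
are locally stiff): the step is capped so no node changes by more than 20%
per step, and the cap is damped (×0.7) whenever the scale-free residual
grows — the frozen-production map can otherwise 2-cycle around a steep
nullcline instead of converging.  Convergence is declared at
`max_i |dp_i/dt|/(k_i p_i) < 1e-6`, within a horizon `t_max = 200/min(k)`
and 30 000 steps.

Converged endpoints are merged in log2 space, and each representative is
then re-solved by Newton iteration (`scipy.optimize.root`, analytic
Jacobian, log-space variables) and accepted only if the polished residual
is below 1e-8 and the Jacobian's eigenvalues all have negative real part
(endpoints that settled onto saddles by numerical accident are discarded).
Two states are identical when every node agrees within 0.05 log2 units —
well below the ≳1 log2-unit separation of Hill branches.  The integrator
only needs to deliver basins of attraction; precision comes from the Newton
polish.  On 1- and 2-node circuits the enumeration is verified in the test
suite against exhaustive grid-seeded root finding, and it was spot-checked
against high-tolerance LSODA integration on random 6-node parameter sets
during development.

A parameter set's number of distinct stable states classifies it
(monostable / bistable / tristable / ≥4-stable); sets where no trajectory
converges are excluded from fractions and logged (≈0–1% on the 7-node
circuits, 0% observed on the base circuit at desk scale).

## Normalization, phenotypes, phases

All solutions of a replicate are pooled with equal weight regardless of
their parameter set's state count.  Levels are log2-transformed and
normalized gene-wise against the *unperturbed* circuit of the same
replicate: `z = (log2 p − mean(log2 p_ref))/sd(log2 p_ref)`.  Perturbed
ensembles reuse the reference statistics, so all folds live on one scale.

Phenotypes come from k-means (best of 10 seeded restarts) on the four core
nodes only — miR-200, ZEB, LIN28, let-7; SNAIL, NF-kB and PSF nodes are
excluded because the core toggles do not feed back onto them.  At k = 4
clusters are named e < he < hm < m by ascending median ZEB (ties broken by
descending median miR-200 — our choice; ties are essentially impossible on
real ensembles).  Each replicate is normalized and clustered separately;
cross-replicate quantities are reported mean ± SD.  The multiset of labels
of one parameter set's coexisting states is its phase (e.g. `{e,m}`);
phase frequencies are tabulated per multistability class.  Cluster-count
diagnostics (silhouette, Calinski–Harabasz, Davies–Bouldin, inertia; Ward
dendrogram cross-check) are computed per replicate, silhouette on a seeded
subsample above 20 000 rows.

## Stemness window and enrichment

Per replicate, the median `m` and interquartile range `q` of the pooled
LIN28 z-scores are computed, then averaged across replicates.  The
*biological range* is `[m − q, m + q]`; the *stemness window* is its middle
fraction `f`, i.e. `[m − f·q, m + f·q]`, closed at both ends, with
`f = 0.30` by default ("middle 30% centered on the median" — interpreted as
30% of the full 2q width, the only reading consistent with symmetry about
the median; `f` is a config knob).  Enrichment is quantified per replicate
by `p1(c) = P(in window | phenotype c)` and `p2(c) = P(c | in window)`;
`Σ_c p2 = 1` whenever the window is occupied.  The width-sensitivity sweep
reports pooled window composition for a list of `f` values (pooled across
replicates for stability at small `f`).  IQRs use all pooled solutions, not
monostable-only.

## Link metrics

For edge `s→t`, `l = λ_eff · (G_s/k_s)/μ` with `λ_eff = λ` (activation) or
`1/λ` (inhibition): an expression-free potency normalized by the source's
maximal level, so a neutral link (`λ_eff = 1`, `μ = G_s/k_s`) has `l = 1`.
The source node supplies the `G/k` normalizer because μ thresholds the
source's level; this is the only dimensionally coherent choice and is
switchable (`normalize_by="target"`).  For a feedback pair, asymmetry
`log2(l₁/l₂)` and coupling `log2 l₁ + log2 l₂` jointly invert to the
individual log-strengths.  Being parameter-level quantities, they attach to
every solution of their parameter set when grouped by phenotype.

## Significance testing

Within-replicate distribution comparisons use the two-sided Mann–Whitney U
test; cross-replicate proportion comparisons use Welch's unequal-variance
t-test; each emitted table is Holm–Bonferroni-adjusted as one family.
Because within-replicate n is large, medians' ratio and difference are
reported alongside p-values as effect-size surrogates.  Degenerate inputs
are flagged, not raised: all-tied rank-sum samples and zero-variance
equal-mean Welch inputs report p = 1.

## Problem sizes

Three presets: `paper` (5 replicates × 10 000 models × 100 initial
conditions), `desk` (5 × 1000 × 50, the default for the acceptance script
and heavy tests; ensemble fractions are stable at this scale to within a
couple of percentage points), and `mini` (2 × 600 × 30, used for the
perturbation-sweep and geometry tests where only orderings are asserted).

## What passing tests do and do not show

The generator emulates kinetic heterogeneity across cells with *uniform,
independent* parameter draws and a deterministic steady-state readout.  It
does not emulate correlated parameter variation, extrinsic/intrinsic noise,
transcriptional bursting, cell division, or any measurement model — so
agreement of the pipeline's statistics with expectations demonstrates
properties of the circuit topology under the stated sampling assumptions,
not properties of any real transcriptomic data set.

## Known limitations

* The exact sampling ranges and run parameters of the original study's
  appendix were not available; the defaults above are the method's published
  defaults plus our Monte-Carlo instantiation of the half-functional
  threshold rule.  Headline ensemble statistics (multistability fractions,
  PC1/PC2 variance, enrichment orderings, perturbation responses) reproduce
  the expected values under these defaults.
* One diagnostic does not: the *global* maximum of the average silhouette
  width over k ∈ 2..8 falls at k = 2 (~0.44) rather than k = 4 (~0.42) on
  our ensembles — k = 4 is a clear local peak (it beats k = 3 and k = 5 in
  every replicate, which the suite asserts), but the two-supercluster split
  along the EMT axis scores slightly higher.  This ordering is stable across
  desk and paper scale, Ward vs k-means labels, and distance variants, so it
  reflects the ensemble geometry under our defaults rather than estimator
  noise.
* Limit cycles, if any, are not detected; non-converging trajectories are
  dropped.  States reachable only from very small basins can be missed at
  finite initial-condition counts.
* The NRF2 circuit wiring (balanced activation by miR-200 and ZEB, NRF2 ⊣
  SNAIL) follows the published NRF2 PSF model; conclusions specific to NRF2
  should be re-checked under alternative wirings via a user `.topo` file.
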