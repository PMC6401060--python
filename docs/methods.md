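# Methods

## Model

`stratodec` implements the dispersal–extinction–cladogenesis (DEC) model
of geographic range evolution on a rooted, ultrametric, dated phylogeny,
with time-stratified paleogeography. A range is a non-empty subset of N
discrete areas, encoded as a bitmask; the empty set is the absorbing
"null" state representing global extinction of a lineage. The state space
is ordered null-first, then by occupancy count and mask value, and may be
capped at a maximum range size to bound its 2^N growth (no cap by default
at N = 5, i.e. 32 states).

### Anagenesis

Within one time slice, range evolution is a continuous-time Markov chain
with generator entries

- gain of area k: `d * sum_{i in R} m[i][k]` for k not in R,
- loss of area i in R: `e` (independently per occupied area; a
  single-area range that loses its area enters null).

`d` (dispersal) and `e` (extinction) are in events per million years; the
multiplier matrix `m` is a property of the time slice and the dispersal
hypothesis. States containing currently unavailable areas are *not*
purged from the state space mid-slice; unavailability acts purely through
zero multipliers into those areas. Only entries *into* unavailable areas
are zeroed, not entries out of them — a lineage stranded on a sinking
landmass can still be lost through `e`.

### Time stratification

Dated geological events cut `[0, root_age]` into half-open slices
`[young, old)` (the oldest slice closed at the root age). Events older
than the root are outside the analysis window and dropped by default
(`strict=True` turns them into errors). Branch transition probabilities
are old-to-young ordered products of segment matrix exponentials across
every slice boundary the branch crosses. When all slices share one
multiplier matrix this reduces exactly (by the semigroup property) to the
unstratified likelihood, which the tests assert to 1e-10.

### Cladogenesis

At each internal node the parental range divides by the classic DEC
scenario set: identity for single-area parents; for widespread parents,
vicariance (single area vs remainder) and subset sympatry (single area vs
full parental range), uniform over the distinct ordered daughter pairs.
This yields 1, 6, 12, 16, 20 scenarios for range sizes 1–5. No jump
dispersal and no widespread-sympatry duplication are included.

### Likelihood and root treatment

Felsenstein pruning with per-node rescaling (accumulated log scalers)
guards against underflow; data that are structurally impossible under a
model raise an explicit zero-likelihood signal rather than returning
−inf. The root prior is uniform over non-null states: the reported
likelihood is the mean of the root partials over non-null ranges. This
choice (the original Lagrange default is not documented) is configurable
in principle via the engine's `root_prior` vector and is asserted in the
tests through the root-renormalization identity.

## The six hypotheses

`MODEL_SPECS` maps A–F onto (corridor flag × dispersal mode):
A/B distance-dependent without/with the GAARlandia corridor, C/D uniform,
E/F minimal. Distance dependence uses ordinal distance classes
(0 = same/adjacent landmass, 1 = near overwater, 2 = far overwater) with
default tier multipliers 1.0 / 0.5 / 0.1. The published analyses this
design follows do not print their distance matrices, so the shipped
class assignments for the Caribbean presets are this package's own
documented defaults, fully overridable in the geography config.
"Minimal dispersal" is a uniform multiplier ε = 0.01 rather than literal
zero, so a dispersal rate remains identifiable under E/F (their fitted
`d` absorbs 1/ε, which is why Table-style outputs show E/F dispersal
estimates an order of magnitude larger). The corridor raises the South
America ↔ Greater Antilles multipliers to 1.0 (both directions) in
slices contained in [33, 35) mya, and is active only under B/D/F.

Two named presets ship: the five-area likelihood scheme (SA incl.
Aruba/Curaçao/Bonaire; North+Central America; Greater Antilles incl.
Bahamian Bank; northern and southern Lesser Antilles) with the six dated
events (3, 5, 12, 33, 35, 55 mya), and a six-area reconstruction scheme
(adds Australasia, splits Central from North America, merges the Lesser
Antilles). The engine itself is N-area generic.

## Fitting

`DECModel.fit()` maximizes ln L over (log d, log e) with L-BFGS-B inside
box bounds [1e-9, 10] per rate, from a fixed four-point start grid
(d, e) ∈ {(0.005, 0.002), (0.05, 0.02), (0.001, 0.01), (0.1, 0.001)};
the best optimum wins, with a derivative-free Nelder–Mead polish if the
quasi-Newton run reports abnormal termination. Everything is
deterministic: refitting identical inputs reproduces the identical
result. Standard errors for (log d, log e) come from the numerical
Hessian at the optimum; on extant-only trees `e` is weakly identified
and frequently sits at its lower bound with an enormous standard error —
this is a property of DEC on such data, not a fitting failure. Model
comparison fits each hypothesis independently and reports the Table-style
columns (model, −ln L, dispersal, extinction) plus pairwise Δ(−ln L);
per-model failures are recorded without aborting the remaining rows.

## Ancestral reconstruction

*Marginal (empirical Bayes)*: inside/outside passes consistent with the
cladogenesis distribution give, for every internal node, the posterior
probability of each parental range given all tips, with rates fixed at
their ML estimates. The root marginals equal the prior-weighted
normalized root partials (asserted to 1e-10). This stands in for
MCMC-based Bayesian reconstructions: it conditions on one tree and on
point estimates of the rates, so it understates uncertainty relative to
methods that average over trees and parameters.

*Parsimony*: Sankoff dynamic programming over non-null ranges with a
symmetric step-cost matrix, default = size of the symmetric difference of
the two area sets (one unit per area gained or lost; swapping two
disjoint singletons costs 2). The full most-parsimonious-reconstruction
set per node is recovered by an outside pass; asymmetric costs are
rejected unless explicitly allowed, since the total cost then depends on
the rooting.

A node summary calls a node resolved when the top range carries ≥ 0.5
posterior mass (threshold configurable; "unresolved" has no standard
numeric definition) or, in parsimony mode, when the MPR set is a
singleton.

## Synthetic data

The forward simulator mirrors the inference model exactly: Yule
(pure-birth) trees conditioned on a tip count and rescaled to an exact
root age (emulating a Yule tree prior; no fossilized birth–death), a
root range from the uniform non-null prior, Gillespie simulation of
gains/losses with slice-appropriate rates along each branch, and a
scenario draw at each node. Datasets with any null tip are rejected and
redrawn from the same seeded stream (cap 1,000 retries, count reported) —
the simplest unbiased way to condition on the non-null tips the
likelihood assumes. The packaged study fixture uses 74 tips, a 55 My
root, birth rate 0.1/My (a realistic pace for ~74 extant species in
55 My), the five-area geography, the corridor model B, and rate
magnitudes d = 0.004, e = 0.002 per My.

What the simulator does *not* emulate: phylogenetic and dating error
(node ages are exact), extinct/unsampled lineages, within-area
population structure, or distance matrices estimated from real
geography. Passing tests therefore demonstrate internal correctness and
recoverability under the model's own assumptions, not robustness to
their violation on real data.

## Numerical choices

- Rate matrices are diagonalized once per slice per likelihood
  evaluation; branch segments then cost two small matrix products. If the
  eigenbasis inverse has residual > 1e-9 the slice falls back to
  `scipy.linalg.expm`. Tiny negative probabilities from the
  eigen-reconstruction are clamped to zero.
- Pruning rescales partials at every node; branch row sums are accurate
  to ~1e-12 in practice (asserted at 1e-9).
- Optimizer tolerances 1e-8 (ftol) on the negative log-likelihood;
  zero-likelihood regions during optimisation are penalized with a large
  finite value instead of raising.
- Ultrametricity is validated at 1e-6 relative to the root age, then tip
  ages are clamped to exactly 0 so slice arithmetic is exact.
- Ages increase into the past; tips at age 0; slices half-open
  [young, old), oldest closed.

## Problem sizes used in the checks

Exhaustive-enumeration oracles run at ≤ 4 tips / ≤ 3 areas (likelihood),
3 tips / 2 areas (marginal posteriors) and ≤ 6 tips (parsimony), where
enumeration over all joint assignments is exact and fast. Calibration
and recovery studies use 10,000 single-branch draws, 20 replicates of
150-tip datasets for rate recovery, and 20 replicates of 74-tip datasets
for the model-ordering study — the scale of the motivating study system.
The ordering study simulates at d = 0.02 per My (dispersal-rich): at the
fixture's d = 0.004 a 55 My tree carries too few dispersal events for
distance structure to separate the hypotheses reliably, which is itself
informative — model choice in this design is powered by dispersal
events, not by the corridor.

## Known limitations

- No DEC+J (founder-event jump dispersal); no per-area extinction rates;
  no Bayesian sampling over (d, e); single fixed tree (no posterior
  tree-set averaging).
- Extinction is weakly identifiable from extant-only data (see above).
- The distance-class defaults are plausible stand-ins, not estimates;
  conclusions about distance dependence on real data should re-specify
  them from actual geography.
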