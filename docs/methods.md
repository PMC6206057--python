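# Methods

This note documents the statistical machinery behind `morbinet`, the
design of the synthetic cohort generator, and the numerical choices made
where the method leaves them open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Input model and the relative-risk engine

The pipeline's epidemiological input is one co-occurrence summary per
age-band × gender stratum: the population size `N`, per-disease
prevalence counts `N_i`, and pairwise Jaccard indices
`J_ij = C_ij / (N_i + N_j − C_ij)`. One fixed population `N` per stratum
is assumed (every disease shares the same denominator).

Because `J` is a deterministic invertible function of the integer
co-occurrence count, `C = J (N_i + N_j) / (1 + J)` recovers `C` exactly
(the inversion is algebraically exact; floating-point rounding is
corrected by rounding to the nearest integer, and a deviation larger than
`1e-6 · (N_i + N_j)` raises a consistency warning). The relative risk is
the observed/expected ratio `RR = C·N / (N_i·N_j)`. All entries of the
2×2 table (`a = C`, `b = N_j − C`, `c = N_i − C`, `d = N − N_i − N_j + C`)
are therefore available exactly, which the test suite verifies
integer-exactly against raw diagnosis matrices.

**Confidence intervals.** The Katz log-normal interval is computed for the
*conditional* risk ratio `[a/(a+b)] / [c/(c+d)]` with
`SE(ln RR) = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))`; the P value is the
two-sided normal tail of `ln RR / SE`. The interval is attached to the
observed/expected point estimate. These are two different estimands: at
low prevalence (a few percent) they nearly coincide and the interval
brackets the point estimate, but at high prevalence the conditional ratio
is systematically larger (the worked example in the README shows a case
at ~7% prevalence where RR = 1.84 sits just below a CI of [1.74, 2.23]).
Tables with an empty `a` or `c` cell have no defined interval and are
flagged with `(nan, nan, p = 1)`.

**Filters.** Pairs where either disease is below 1% prevalence are
dropped first. Network edges are then restricted to the bottom/top
vigintile (5th/95th percentile, linear interpolation between order
statistics) of the stratum's RR distribution; the percentiles are
computed per stratum. A stratum with fewer than 20 records falls back to
fixed bounds (0.8, 1.6) — the values these vigintiles correspond to in
large primary-care cohorts — with a warning. Records with `C = 0`
(`RR = 0`) have no finite signed weight and never become edges.

## Signed networks and small-world-ness

Edges carry the signed transform `w~ = RR` (RR > 1) or `−1/RR` (RR < 1),
which makes mutual exclusivity a negative interaction of comparable
magnitude. Small-world-ness treats all weights as 1:
`S = (C_G/C_rand) / (L_G/L_rand)`, where `C` is the mean local
clustering coefficient (nodes of degree < 2 contribute 0) and `L` the
mean shortest path length, with baselines averaged over `n_random`
G(n, m) graphs with matched node and edge counts. A disconnected random
sample has `L` computed on its largest component (the G(n, m) ensemble
occasionally disconnects; the reference does not prescribe a rule).
`S > 1` indicates the small-world regime.

## Centrality

Signed PageRank has no stochastic interpretation, so the two signed
layers are ranked separately: PR⁺ on the positive subnetwork, PR⁻ on the
absolute weights of the negative subnetwork, each restricted to the nodes
incident to that layer and normalised to sum 1 there (each PR vector is a
probability distribution over the nodes it can rank; nodes outside a
layer score 0 in it). `MPR = PR⁺ − PR⁻`. The Google matrix
`G = αWD⁻¹ + ((1−α)/n)J` uses a uniform teleport column for dangling
nodes (required for column-stochasticity) and damping α = 0.5 — lower
than the conventional 0.85 because nodes aggregate whole blocks of
diagnoses; the top-ranked nodes are stable across α. Power iteration runs
to an L1 tolerance of 1e-10 and is verified against dense
dominant-eigenvector computation to 1e-8 on hundreds of random graphs.

Because each layer is separately normalised, a node's MPR is sensitive to
*membership* in the negative layer: in sparse negative subnetworks the
difference between zero and one incident negative edge shifts MPR by
roughly `1/n`. This is a real property of the estimator, and it is why
central diseases are defined by *persistence* (≥ 4 appearances in the
per-stratum top-10) rather than by any single stratum's ranking.

Deletion impact removes a node set from the chosen-sign subnetwork and
compares the resulting component count with equally many uniformly drawn
deletions (add-one empirical P). The uniform null is this package's
construction.

## Communities

Signed modularity with per-layer resolution parameters,

    Q = 1/(2w⁺+2w⁻) Σ_ij [ W_ij − (γ⁺ w_i⁺w_j⁺/2w⁺ − γ⁻ w_i⁻w_j⁻/2w⁻) ] δ(σ_i, σ_j),

is minimised via the spin-glass Hamiltonian `H = −Σ_ij [...] δ`
(`Q = −H/(2w⁺+2w⁻)`, an identity the fuzz suite asserts to 1e-10; with
γ⁺ = 1 on an all-positive graph Q reduces exactly to Newman–Girvan
modularity). The double sums run over ordered pairs and include the
`i = j` null terms. Layers with no weight contribute nothing to the null
(0/0 → 0).

**Annealer.** Classical simulated annealing over single-node spin moves,
`min(1, exp(−ΔH/T))` acceptance. Defaults: T from 1.0 down to 0.01,
cooling 0.99, 50 sweeps per temperature, 25 initial spin states, 3
restarts keeping the best (lowest-H) assignment ever visited. A move
costs O(1) to evaluate via an incremental node × community interaction
table (numba-compiled) and O(n) to commit. The schedule was chosen so
that exhaustive enumeration over all set partitions of ≤ 8-node signed
graphs is matched in ≥ 99% of seeded runs. Labels are relabelled
contiguously; an edgeless network returns singletons. Deterministic given
the seed.

**Resolution estimation.** γ per layer is iterated to a fixed point:
partition at the current γ; compute the layer's within- and
between-community weight *relative to the configuration-null expectation*
`s_i s_j / 2w` (so an unstructured layer gives ω_in ≈ ω_out ≈ 1); update
`γ = (ω_in − ω_out)/(ln ω_in − ln ω_out)`, the planted-partition
equivalence value, clamped to [0.2, 5]. Guards: a layer with
ω_in ≤ ω_out keeps γ = 1 (no assortative structure; for the negative
layer this is the expected outcome, since exclusivity edges run *between*
communities); ω_in = ω_out exactly yields the analytic limit γ = ω;
ω_out = 0 yields the γ → 0 limit, i.e. the clamp floor. Relative (not
raw) densities matter: raw within/between densities shrink with network
size and drive γ below 1, which merges communities.

**Independence and roots.** `I(σ_k) = (1/n_k) Σ_{i∈k, j∉k} −W_ij`
(negative boundary edges add, positive subtract; isolated communities
score 0). Per stratum the top-3 most independent communities are
eligible for tracking; a community chains to the next stratum's
community sharing ≥ 2 nodes, ambiguity resolved by larger overlap then
higher independence, each successor used at most once (greedy, larger
current communities matched first — deterministic). A track's *root* is
the intersection of all its snapshots; tracks must span ≥ 2 consecutive
strata and keep roots of ≥ 2 nodes. Chains never pass through
non-top-3 communities.

## Degree leaps and the randomisation null

Connectivity trajectories count, per disease and stratum, incident edges
with RR > 1.6. Strata where a disease has no network presence are
*missing*, not zero; the leap is max − min over present strata. Burst
seeds need a sustained leap ≥ 10: flat records are dropped, and so are
*spurious* ones, operationalised as a single-stratum excursion — one
stratum holds the unique extreme, the next value (if any) returns to the
range seen before the excursion, and without that stratum the leap
disappears.

The null model randomises each stratum's strong-edge subnetwork while
preserving *both* the exact per-node degrees (connected double-edge
swaps, rolled back on disconnection; the number of accepted swaps equals
the node count) *and* the disease labelling only up to a uniform
permutation of the network's nodes. The second ingredient matters:
degree-preserving rewiring alone cannot change any node's degree, so
trajectories rebuilt from rewired networks would reproduce the observed
trajectories verbatim and the null would be vacuous. With the
relabelling, the null asks: if each stratum's degree sequence were dealt
out at random (over a topology with the same degrees and connectedness),
how many diseases would show sustained leaps ≥ 10? Because rewiring
leaves the degree map untouched, `leap_null_distribution` draws each
replicate directly as per-stratum permutations of the observed degree
maps — distributionally identical to rewire-then-relabel and ~1000×
cheaper. The structural rewiring operation itself is exposed and
contract-tested separately (1000 replicates of a 50-node network all
preserve per-node degrees and connectedness). Empirical P uses the
add-one rule `(1 + #{null ≥ obs})/(R + 1)` throughout, so P is never
exactly zero.

## Cumulative risk trends

`risk_sums` works on *all* prevalence-filtered pairs, deliberately
independent of the network edge thresholds: per disease and stratum,
Σ RR over partners with RR > 1 and Σ 1/RR over partners with
0 < RR < 1 (zero-RR records have no finite inverse and are skipped).
Variants: raw sum, per-partner average (undefined, hence NaN, for
strata with no qualifying partner), and sum normalised by the number of
strata in which the disease appears.

Smoothing fits a cubic B-spline basis (two interior knots at age
quantiles; band midpoints as the age coordinate, 92.5 for the open 90+
band) by ordinary least squares; the pointwise band is
`fit ± t_{df} · SE` from the coefficient covariance. The t quantile with
the fit's residual df is used rather than z, which at 15 support points
undercovers (~92% instead of the nominal 95% in the coverage
Monte-Carlo). Fewer than 4 points fall back to a linear fit with a
warning.

Group trend comparison is a permutation analogue of the classical
parallelism/coincidence tests: the statistic is the summed squared
difference between the two group mean curves over the shared stratum
grid, and the null permutes the disease → group labels. The join-point /
annual-percent-change machinery used for trend slopes in the
epidemiological literature is an external program; the permutation
coincidence test covers the group-difference question this package needs,
and spline slope CIs cover trend shape. The Spearman correlation between
average (per-network min-max normalised) centrality and the min–max range
of a disease's risk sum is reported with its asymptotic P.

## Molecular coherence

Disease pairs are scored by the mean shortest-path length between their
causal gene sets in an undirected interactome (shared genes contribute 0;
unreachable pairs are excluded from the mean and counted, or, behind a
flag, penalised as diameter + 1). The null keeps one disease's gene set
fixed and replaces the other by an equal-size uniform sample of network
genes; smaller distance = more coherent, with the add-one empirical P.
The fraction of mapped diseases with at least one coherent incident
association (P < 0.05) summarises a network. Gene–disease maps and
interactomes are file-based (two-column TSVs); a synthetic
planted-module interactome generator ships for testing and is labelled
synthetic throughout.

## The synthetic cohort generator

The generator simulates binary diagnosis matrices per stratum so that
`N`, `N_i` and `J_ij` are mutually consistent by construction (the RR
engine's 2×2 reconstruction must be exact). Latent-factor model per
individual: independent community activations (probability 0.10)
multiply member probabilities by φ; hubs are additionally boosted when a
target community is active; burst factors exist only at/after the onset
age band; exclusion pairs lose one member (uniformly chosen) with
probability equal to the exclusivity strength; individuals with < 2
diagnoses are dropped, matching the multimorbidity inclusion rule (this
raises marginal prevalences slightly and induces a weak negative
dependence between diseases — negligible at the default diagnosis
counts of ~6 per individual). Configurations whose combined boosts could
exceed probability 1 are rejected outright. Burst onset acts through the
stratum sequence; there is no within-stratum ageing.

### Reference cohort design

15 age bands × 2 genders, 20,000 individuals per stratum, 179 diseases,
baselines log-uniform in (0.02, 0.025). The planted classes are designed
so that each class is the *only* carrier of its own signature:

* **29 communities of 6 diseases** (φ = 6 → within-community RR ≈ 2.0)
  cover almost all diseases. This gives every disease a stable floor of
  ~5 strong edges, which keeps the strong-edge degree distribution
  homogeneous — the property that makes the leap null informative: with
  homogeneous non-seed degrees, permutation replicates almost never
  assemble a sustained leap ≥ 10, while each planted seed always does.
* **10 hubs** (first member of communities 0–9, coupling 4 to one
  distinct target community each) gain ~6 cross-community strong edges:
  about twice a member's weighted degree — reliably in the MPR top-10 —
  while their raw strong-edge degree (~11) stays safely below the leap
  threshold relative to the degree floor.
* **5 burst seeds** live outside the communities but are *anchored*
  (coupling 4) to one community each, so they are present in every
  stratum with ~5 edges; from age band 80–84 a burst factor (activation
  0.15) boosts the seed ×10 and its 18 partners ×2.7, creating ~14 new
  strong edges at once (seed–partner RR ≈ 1.7) while partner–partner
  co-occurrence stays below the edge threshold (partners spread one per
  community, so no partner inherits a leap).
* **4 exclusion pairs** (strength 0.6 → RR ≈ 0.4) provide negative
  edges with known ground truth.

A further constraint shaped these numbers: planted strong edges must not
crowd the vigintile budget (5% of all pairs per tail), or the upper
threshold climbs into the planted RR range and burst-partner edges drop
out of the networks. With 179 diseases the planted positives occupy
roughly 70% of the budget, leaving the threshold in the noise tail
(≈ 1.45).

The `null_config` variant (no planted structure, a *uniform* baseline for
every disease) exists for null calibration: permutation P values are
exactly exchangeable — hence uniform on their achievable grid — only when
diseases are i.i.d.; heterogeneous baselines make label-permutation nulls
conservative. Calibration tests therefore use the uniform-baseline
configuration, and their KS checks tolerate the residual super-uniformity
that discrete test statistics (tied permutation values) produce.

### What the generator does not emulate

* Couplings are age-constant except for burst onsets. Real cohorts show
  cumulative risk sums rising substantially with age and their range
  correlating with centrality; here central diseases have flat risk-sum
  trajectories, so the centrality-vs-range correlation is ≈ 0 and the
  central-vs-other coincidence test separates only weakly. Passing
  recovery tests therefore demonstrate *structural* recovery (hubs,
  communities, exclusions, bursts), not age-trend recovery.
* No care-seeking process, no missing data, no longitudinal patient
  trajectories, no real ICD semantics (codes are block-like labels;
  chapters are aligned with planted communities so the clinical
  coherence test has a planted positive control).
* One fixed population per stratum; no overlap of individuals between
  strata.

## Problem sizes and determinism

The test suite runs the full reference cohort once (session fixture) and
scales Monte-Carlo sizes to what the checks need: 500 random graphs for
the PageRank oracle, 1000 fuzz cases for the Q/H identity, 100 seeded
annealing runs per enumeration graph, 1000 leap-null replicates, 200
replicates per null-calibration check, 1000 rewirings for the structural
contract, 1000 simulated tables for CI coverage. `scripts/acceptance.py`
re-runs the pipeline end to end (about two minutes on one CPU) and
derives every stage seed from the single `--seed` via `SeedSequence`
spawning; reruns of the orchestrated pipeline with the same config and
seed are byte-identical, which the suite asserts by comparing CSVs.

## Known limitations

* The Katz interval is attached to a different estimand than the point
  estimate (documented above); at prevalences above ~5% the mismatch
  becomes visible.
* MPR rankings in sparse negative layers are sensitive to single
  negative edges; selection by persistence mitigates but does not remove
  this.
* The γ fixed-point iteration can stall in a coarse (merged) fixed point
  when communities are small and bridged; the annealer restarts and the
  null-relative ω parametrisation make this rare on the reference
  cohort, but γ estimation on arbitrary networks should be sanity-checked
  against the partition it induces.
* The leap null conditions on the observed per-stratum degree sequences;
  it does not model sampling noise in the RR estimates themselves.
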