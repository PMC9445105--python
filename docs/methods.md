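# Methods

## Problem

A deterministic system of coupled oscillators on a finite connected graph
either synchronizes (reaches a constant phase configuration) or settles
into a non-synchronizing limit cycle.  `l2psync` treats the question *will
this system synchronize?* as binary classification: given a graph `G`, an
initial configuration `X_0`, and the first `r` iterations of the dynamics,
predict the indicator `1(X_T concentrated)` at a far horizon `T >> r`.
Everything the pipeline consumes is generated internally: random graphs,
random initial configurations, and simulated trajectories.

## Oscillator models

All three couplings act on a graph `G = (V, E)` with node set `0..n-1`.

**Kuramoto model (KM).**  Continuous phases `theta_i` on the circle
`R/2piZ` with identical intrinsic frequency `omega`.  One iteration is one
explicit-Euler step

    theta_i <- theta_i + h * (omega + K * sum_{j in N(i)} sin(theta_j - theta_i))   (mod 2pi)

Defaults `omega = 0` (rotating frame), `K = 1`, `h = 0.1`; all
configurable.  A stability precondition `h * (|omega| + K * d_max) < pi`
is checked at simulation start — it bounds the per-step phase increment by
half a circle.  The effective product `h*K` is the only free scale in the
rotating frame; `h*K = 0.1` places the baseline concentration fraction
x(5) near 0.07 on 15-node small-world graphs, matching the regime in which
roughly one in ten synchronizing systems is already concentrated after
five iterations.

**Firefly cellular automaton (FCA).**  `kappa` cyclic colours with
blinking colour `b = floor(kappa/2)`.  A node with colour greater than `b`
holds for one step if some neighbour is exactly at `b`; every other node
advances by one modulo `kappa`.  Defaults `kappa = 5`.

**Greenberg–Hastings model (GHM).**  Excitable medium: state 0 is rest,
1 excited, `2..kappa-1` refractory.  A resting node becomes excited iff
some neighbour is excited; all other states advance modulo `kappa`
(`kappa-1 -> 0`).  The all-rest configuration is absorbing.

## Concentration, synchronization, labels

A continuous configuration is *concentrated* when all phases lie in an
open arc shorter than `pi` (computed as: largest circular gap between
sorted phases exceeds `pi`); a discrete configuration when all occupied
colours fit in a cyclic window of fewer than `kappa/2` consecutive
integers (brute force over the `kappa` windows).  For KM with identical
frequencies and for FCA, concentration at any time guarantees eventual
synchronization (the classical half-circle principle); GHM admits no such
principle, so for GHM "concentrated" is defined as synchronized.

Labels use exactly these predicates at the horizon `T`: KM/FCA label
`= 1(X_T concentrated)`, GHM label `= 1(X_T constant)`.  Synchrony of a
continuous configuration is separately diagnosed as all phases within
`1e-6` radians (circular) of the circular mean; labels never use this
tolerance.

## Baseline predictor

Predict synchronization if `X_t` is concentrated for any `1 <= t <= r`
(note: `t = 0` excluded); otherwise flip a fair coin.  On a dataset with
synchronizing fraction `alpha` in which a fraction `x(r)` of synchronizing
samples concentrate by iteration `r`, the expected accuracy is
`0.5 + x(r) * alpha / 2`.  For KM/FCA the rule has no false positives by
the half-circle principle.  The ensemble variant pools all phases observed
across the sampled subgraphs at each `t` and applies the same test to the
pooled multiset — local concentration on a subgraph alone proves nothing
about the full system.  Coins draw from a dedicated generator so baseline
randomness never perturbs classifier seeds.

## Random graphs

The workhorse is a Newman–Watts–Strogatz variant with an extra round
count `M`: start from the ring lattice where each node joins its `k_nws`
nearest neighbours, then in each of `M` independent rounds offer every
initial non-edge with probability `p / (n - k_nws - 1)`.  The embedded
cycle keeps every sample connected.  The exact expected edge count is

    nk/2 + [C(n,2) - nk/2] * (1 - (1 - p/(n-k-1))^M)

with the leading-order form `nk/2 + n^2 p M / (2(n-k-1))` also exposed.
Defaults for the 15/30-node datasets: `k_nws = 2`, `M = 1`, `p = 0.85`
for KM and `0.65` for FCA/GHM.  With these settings the graphs are
somewhat sparser (mean edges ~40 at n = 30, p = 0.65) than the densities
reported for comparable studies (~47), which weakens how much the five
graph statistics alone separate the classes for the discrete models; the
initial degree and round count are deliberately left at their simplest
values and exposed in config rather than fitted to match edge-count
tables.  Large-graph datasets draw `n ~ U{n_min..n_max}`,
`p ~ N(mu, 0.04)` with `mu ~ U(0.32, 0.62)` clipped to `[0, 1]`, and
`M ~ U{1..20}`.

Special topologies (ring, path, complete, bounded-degree random tree
grown by uniform attachment with rejection on the degree cap) support the
topology-contrast experiments, each class backed by a rigorous result:
complete-graph KM synchronizes, path GHM synchronizes by iteration
`n + kappa`, and 5-colour FCA synchronizes on trees of maximum degree at
most four.

## Datasets

Rejection sampling builds balanced sets: draw a graph, deduplicate by
Weisfeiler–Leman hash (3 refinement rounds — not a complete isomorphism
invariant, but collisions are vanishingly rare at n <= 600), draw
`X_0` i.i.d. uniform per node, simulate to `T`, label, and keep the
sample only while its class quota is unfilled.  An attempt cap of 50x the
total quota turns pathological imbalance into an explicit error carrying
the achieved counts.  Samples retain rows `0..r` only (a flag stores full
trajectories for diagnostics).  Serialization is plain text: a JSON
manifest, one edge-list file and one CSV trajectory per sample
(`%.17g` floats round-trip exactly), and a labels CSV.

## Features and classifiers

A feature vector concatenates, in fixed order: five graph statistics
(edges, min/max degree, diameter, nodes), the three quartiles of `X_0`
(linear-interpolation sample quantiles; a five-number-summary option
exists), and rows `0..r_used` of the trajectory flattened row-major in
creation node order.  Phases enter as raw radians (an optional sin/cos
encoding is off by default); node order is never canonicalized.

Classifier kinds: random forest (500 trees), gradient boosting
(500 rounds, rate 0.1, depth 3), a feed-forward net (two hidden layers of
128, ReLU, Adam 1e-3, early stopping, standardized inputs), and
GraphLRCN.  Probability threshold 0.5 with ties positive, everywhere —
including the ensemble vote.

**GraphLRCN.**  Frame `t` is the adjacency matrix with off-diagonal entry
`A_ij * s(X_t(i), X_t(j))` for an agreement kernel `s` in `[0, 1]`
(continuous `(1 + cos dphi)/2`; discrete `1 - d_circ/floor(kappa/2)`) and
diagonal `X_t(i)` normalized to `[0, 1]`; smaller graphs pad with zero
rows.  The network — implemented from scratch in numpy with
backpropagation through time and verified against numeric gradients — is
a shared frame encoder (3x3 conv, 2x2 max-pool, 3x3 conv, max-pool,
affine+ReLU projection to 64), an LSTM of width 64 over the frame
sequence, and a logistic head; Adam with early stopping on a 10%
validation split, float32 arithmetic.  Convolution earns its keep here
because the generators number nodes in ring order, so travelling waves
appear as local motifs near the adjacency diagonal; a dense encoder
(`encoder="dense"`, for order-free graphs) trains faster but plateaus
several accuracy points lower on 30-node GHM.

## Ensemble prediction for large graphs

Train: for each training graph sample `k_sub` connected induced subgraphs
of `n0` nodes by random BFS growth (uniform seed, then uniform choice
among neighbours of the current set), restrict the first `r` iterations
to each subgraph, attach the parent's *global* label, optionally append
the subgraph's own graph statistics, and fit one base classifier on the
pooled subgraph samples.  Predict: mean base-classifier probability over
the `k_sub` observed subgraphs, thresholded at 0.5 — equivalent to
majority vote for hard votes and deterministic on even-`k` ties; strict
majority is available in config.  Subgraphs are sampled fresh per graph
and per evaluation.

## Numerical choices

* Batched simulators advance many systems in lockstep; the Kuramoto
  coupling uses `sum_j A_ij sin(th_j - th_i) = cos th_i (A sin th)_i -
  sin th_i (A cos th)_i`, two matrix products instead of an `n x n` sine.
* Past the recorded horizon, Kuramoto systems whose phases agree to
  within `1e-9` (circular) are frozen: with `omega = 0` a constant
  configuration is a fixed point, so the frozen state stands in for `X_T`
  exactly up to rounding.  The check runs every 64 steps.
* Degenerate metric denominators (no positive predictions, no positive
  labels) yield `None`, never a silent zero.
* Dataset splits and cross-validation are stratified; every stochastic
  step keys off an explicit seed, and identical seeds give bit-identical
  datasets, fits, and reports.

## Problem sizes

The reference studies train on 4 x 10^4 to 10^5 examples per class; this
package's default experiment scales, its test suite, and
`scripts/acceptance.py` run desk-sized replicas chosen to finish on one
CPU in minutes: 2-5 x 10^3 per class for the 15-node sets, 4.5 x 10^3 per
class for 30-node GHM, 8 x 10^2 per class for the full-horizon 30-node
sets, and ~3 x 10^2 graphs of 300-600 nodes for the ensemble study (with
the shortcut-round count capped at 12 so the densest draws respect the
Euler stability bound).  Subgraph coverage matters for the ensemble
comparison: when the k_sub subgraphs cover most of a small graph, the
pooled-concentration baseline effectively observes the whole system and
the ensemble's advantage vanishes, so the study keeps coverage near 20%.
The full scales remain reachable through configuration.

## What the synthetic data does and does not show

The generator reproduces the study conditions exactly as stated (graph
law, uniform initial configurations, labelling horizons), so passing
tests certify the pipeline's behaviour under those conditions.  They do
not certify behaviour on real oscillator networks — degree-correlated or
clustered topologies, heterogeneous frequencies, noisy or partially
observed dynamics are all outside the generator's scope (heterogeneous
frequencies and noise are explicit non-goals).  Accuracy figures at desk
scale sit below the full-scale figures wherever the learning curve has
not saturated; the Kuramoto 15-node dynamics-only task is the clearest
case (roughly 0.61-0.65 at 5 x 10^3 examples versus ~0.77 reported at
2 x 10^5), and scaled accuracy bands in the tests allow for this where
the underlying claim is a bound rather than a point value.

## Known limitations

* The Kuramoto iteration scale is pinned only through the baseline
  concentration fraction; if the reference discretization differs, the
  information content of "five iterations" differs with it.
* WL hashing can in principle admit isomorphic duplicates; at these sizes
  the probability is negligible.
* The GraphLRCN architecture (channel widths, LSTM width) follows the
  published architecture family, not exact layer dimensions, which are
  not available; hyperparameters are exposed in config.
* Gradient boosting with 500 rounds dominates training cost at larger
  scales; the forest and the feed-forward net are the fast paths.
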