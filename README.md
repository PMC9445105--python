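# l2psync — learning to predict synchronization of coupled oscillators

Whether a system of coupled oscillators on a graph eventually
synchronizes is, in general, analytically intractable: sufficient
conditions exist (complete graphs, trees, phases concentrated in an open
half-circle), but most systems of interest satisfy none of them.
`l2psync` treats the question as a binary classification problem.  For a
coupling `F` (Kuramoto, Firefly Cellular Automaton, or Greenberg–Hastings),
a graph `G`, and an initial configuration `X_0`, the target is

    f(X_T) = 1(X_T is concentrated),        T >> r > 0,

predicted from the initial trajectory `(X_t)_{0 <= t <= r}` and,
optionally, five basic graph statistics (edges, min/max degree, diameter,
nodes).  "Concentrated" means confined to an open half-circle — an arc
shorter than `pi`, or fewer than `kappa/2` consecutive colours — which for
Kuramoto (identical frequencies) and FCA guarantees synchronization; for
GHM it means synchronized outright.

The package is aimed at researchers in network dynamics who want to
reproduce, probe, or extend this classification approach: it generates
the random graphs (a Newman–Watts–Strogatz variant with `M` shortcut
rounds), simulates the three couplings, builds balanced non-isomorphic
labelled datasets, trains four classifier families (random forest,
gradient boosting, feed-forward net, and GraphLRCN — a recurrent
convolutional net fed dynamics encoded onto the adjacency matrix), scores
everything against the concentration-principle baseline
(`accuracy = 0.5 + x(r)·alpha/2`), and scales to large graphs by an
ensemble vote over small connected subgraphs observed in isolation.

## Worked example

Build a balanced 5-colour FCA dataset on 15-node small-world graphs,
score the baseline, and train a random forest on the first three
iterations of dynamics alone:

```python
from l2psync.data import DatasetSpec, build_balanced_dataset, split
from l2psync.graphs import NwsParams
from l2psync.features import feature_matrix
from l2psync.classifiers import train_classifier, predict, evaluate
from l2psync.baseline import concentration_fraction, baseline_expected_accuracy

spec = DatasetSpec(
    model="fca", graph=NwsParams(n=15, k_nws=2, p=0.65, M=1),
    r=25, T=70, quota=500, kappa=5, seed=42,
)
ds = build_balanced_dataset(spec)
print(f"dataset: {len(ds)} samples, class counts {ds.class_counts}")

stats = concentration_fraction(ds, r=3)
print(f"baseline at r=3: alpha={stats.alpha:.2f}, x(3)={stats.x_of_r:.3f}, "
      f"expected accuracy {baseline_expected_accuracy(stats):.3f}")

train, test = split(ds, test_fraction=0.2, rng=0)
Xtr, ytr, _, _ = feature_matrix(train, r_used=3, include_graph=False, include_quartiles=False)
Xte, yte, _, _ = feature_matrix(test, r_used=3, include_graph=False, include_quartiles=False)
model = train_classifier("rf", Xtr, ytr, seed=0)
pred, _ = predict(model, Xte)
rep = evaluate(pred, yte)
print(f"random forest on 4 iterations of dynamics alone: "
      f"accuracy {rep.accuracy:.3f}, precision {rep.precision:.3f}, recall {rep.recall:.3f}")
```

Output:

```
dataset: 1000 samples, class counts (500, 500)
baseline at r=3: alpha=0.50, x(3)=0.026, expected accuracy 0.506
random forest on 4 iterations of dynamics alone: accuracy 0.610, precision 0.628, recall 0.540
```

Read: the dataset is balanced by construction (`alpha = 0.5`), and by
iteration 3 only 2.6% of the synchronizing samples are already
half-circle concentrated, so classical theory predicts essentially at
chance (50.6%).  The forest, seeing exactly the same three iterations,
reaches 61% — the gap over the baseline is the learnable signal in the
early dynamics, and it widens with more training examples and larger `r`.

## Command line

```
l2psync generate --config cfg.yaml --seed 1 out_dir     # build + save a dataset
l2psync baseline out_dir                                # closed-form baseline accuracy
l2psync train --kind rf --no-graph-features out_dir     # cross-validated metrics
l2psync experiment curves --seed 1 --outdir results     # accuracy-vs-r curves
l2psync experiment ensemble --seed 1                    # subgraph-ensemble study
l2psync experiment gini --seed 1                        # feature-importance boxplots
```

Experiment configs are YAML overrides of desk-scale defaults; every
report embeds the resolved config and seed.

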