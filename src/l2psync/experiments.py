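"""Config-driven experiments chaining the library modules.

Four named experiments, all runnable at configurable scale:

* ``contrast`` — topology-contrast classification (classes live on different
  topologies); graph-features-only FFNN plus dynamics-only accuracy
  versus training iteration, against the concentration baseline.
* ``curves`` — same-random-graph-model datasets; accuracy of the four
  classifiers versus training iteration r, with and without graph
  features, against the closed-form baseline curve.
* ``ensemble`` — subgraph-ensemble prediction on large mixed-size NWS
  graphs versus the pooled-concentration baseline, over a schedule of
  subgraph counts.
* ``gini`` — distribution of gradient-boosting Gini importances of the
  graph-statistic and initial-quartile features over repeated splits.

Every report embeds the fully resolved configuration and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .baseline import BaselineStats, baseline_expected_accuracy, concentration_fraction
from .classifiers import cross_validate, evaluate, gini_importance_experiment
from .data import (
    Dataset,
    DatasetSpec,
    NwsMixture,
    TopologySpec,
    build_balanced_dataset,
    build_topology_contrast_dataset,
    split,
)
from .ensemble import EnsembleSpec, ensemble_train, evaluate_ensemble
from .graphs import NwsParams

__all__ = ["EXPERIMENTS", "default_config", "run_experiment"]

# Desk-scale defaults; the headline studies' scales are reachable by
# raising the quotas in config.
_DEFAULTS: dict[str, dict] = {
    "contrast": {
        "quota": 200,
        "kappa": 5,
        "r_schedule": [1, 3, 5, 10],
        "contrasts": {
            "km": {"sync": ["complete", 30], "nonsync": ["ring", 30], "T": 1758, "r": 25},
            "ghm": {"sync": ["path", 30], "nonsync": ["complete", 30], "T": 70, "r": 25},
            "fca": {"sync": ["random_tree", 30, 4], "nonsync": ["ring", 30], "T": 70, "r": 25},
        },
    },
    "curves": {
        "model": "fca",
        "n": 15,
        "p": 0.65,
        "k_nws": 2,
        "M": 1,
        "quota": 500,
        "kappa": 5,
        "r": 25,
        "T": 70,
        "r_schedule": [0, 3, 5, 10, 25],
        "kinds": ["rf", "gb", "ffnn"],
        "folds": 5,
    },
    # Subgraph coverage should stay well below the full graph, else the
    # pooled-concentration baseline effectively sees the whole system.
    "ensemble": {
        "model": "km",
        "n_min": 300,
        "n_max": 600,
        "mu_min": 0.32,
        "mu_max": 0.62,
        "sigma": 0.04,
        "M_min": 1,
        "M_max": 12,
        "quota": 120,
        "kappa": 5,
        "r": 160,
        "T": 1758,
        "n0": 30,
        "k_schedule": [1, 2, 4, 8],
        "kind": "ffnn",
        "include_graph_features": False,
        "test_fraction": 0.2,
    },
    "gini": {
        "model": "fca",
        "n": 30,
        "p": 0.65,
        "k_nws": 2,
        "M": 1,
        "quota": 300,
        "kappa": 5,
        "r": 25,
        "T": 70,
        "n_splits": 50,
    },
}

EXPERIMENTS = tuple(_DEFAULTS)


def default_config(experiment: str) -> dict:
    if experiment not in _DEFAULTS:
        raise ValueError(f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}")
    return json.loads(json.dumps(_DEFAULTS[experiment]))


def _resolve(experiment: str, config: dict | None, seed: int) -> dict:
    cfg = default_config(experiment)
    cfg.update(config or {})
    cfg["experiment"] = experiment
    cfg["seed"] = int(seed)
    return cfg


def _nws_dataset(cfg: dict, seed: int, quota: int | None = None) -> Dataset:
    spec = DatasetSpec(
        model=cfg["model"],
        graph=NwsParams(cfg["n"], cfg["k_nws"], cfg["p"], cfg["M"]),
        r=cfg["r"],
        T=cfg["T"],
        quota=quota or cfg["quota"],
        kappa=cfg.get("kappa"),
        seed=seed,
    )
    return build_balanced_dataset(spec)


def _write_report(outdir: Path, name: str, report: dict) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return path


def _plot_curves(outdir: Path, name: str, xlabel: str, curves: dict, x: list) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, ys in curves.items():
        ax.plot(x, ys, marker="o", label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("accuracy")
    ax.set_ylim(0.4, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / f"{name}.png", dpi=120)
    plt.close(fig)


def _topology_spec(entry: list) -> TopologySpec:
    kind, n = entry[0], entry[1]
    max_degree = entry[2] if len(entry) > 2 else None
    return TopologySpec(kind, n, max_degree)


def run_contrast(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    results = {}
    for model, c in cfg["contrasts"].items():
        ds = build_topology_contrast_dataset(
            model,
            _topology_spec(c["sync"]),
            _topology_spec(c["nonsync"]),
            r=c["r"],
            T=c["T"],
            quota=cfg["quota"],
            kappa=cfg["kappa"],
            seed=seed,
        )
        feats = cross_validate(
            "ffnn", ds, r_used=0, include_quartiles=False, include_dynamics=False, seed=seed
        )
        dyn_curve, base_curve = [], []
        for r_used in cfg["r_schedule"]:
            cv = cross_validate(
                "ffnn", ds, r_used=r_used, include_graph=False,
                include_quartiles=False, seed=seed,
            )
            dyn_curve.append(cv["accuracy"]["mean"])
            base_curve.append(
                baseline_expected_accuracy(concentration_fraction(ds, max(1, r_used)))
            )
        results[model] = {
            "ffnn_features_accuracy": feats["accuracy"]["mean"],
            "r_schedule": cfg["r_schedule"],
            "ffnn_dynamics_accuracy": dyn_curve,
            "baseline_accuracy": base_curve,
        }
        _plot_curves(
            outdir, f"contrast_{model}", "training iteration r",
            {"FFNN (dynamics)": dyn_curve, "baseline": base_curve},
            cfg["r_schedule"],
        )
    return results


def run_curves(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    ds = _nws_dataset(cfg, seed)
    report: dict = {"r_schedule": cfg["r_schedule"], "with_features": {}, "dynamics_only": {}}
    for with_features in (True, False):
        key = "with_features" if with_features else "dynamics_only"
        for kind in cfg["kinds"]:
            curve = []
            for r_used in cfg["r_schedule"]:
                if kind == "graphlrcn" and r_used == 0:
                    curve.append(None)
                    continue
                cv = cross_validate(
                    kind, ds, folds=cfg["folds"], r_used=r_used,
                    include_graph=with_features, include_quartiles=with_features,
                    seed=seed,
                )
                curve.append(cv["accuracy"]["mean"])
            report[key][kind] = curve
    report["baseline"] = [
        baseline_expected_accuracy(concentration_fraction(ds, max(1, r_used)))
        for r_used in cfg["r_schedule"]
    ]
    curves = {f"{k} (dyn)": v for k, v in report["dynamics_only"].items()}
    curves["baseline"] = report["baseline"]
    _plot_curves(
        outdir, f"curves_{cfg['model']}{cfg['n']}", "training iteration r",
        {k: v for k, v in curves.items() if None not in v}, cfg["r_schedule"],
    )
    return report


def run_ensemble(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    spec = DatasetSpec(
        model=cfg["model"],
        graph=NwsMixture(
            cfg["n_min"], cfg["n_max"], mu_min=cfg["mu_min"], mu_max=cfg["mu_max"],
            sigma=cfg["sigma"], M_min=cfg["M_min"], M_max=cfg["M_max"],
        ),
        r=cfg["r"],
        T=cfg["T"],
        quota=cfg["quota"],
        kappa=cfg.get("kappa"),
        seed=seed,
    )
    ds = build_balanced_dataset(spec)
    train, test = split(ds, cfg["test_fraction"], rng=seed)
    report: dict = {"k_schedule": cfg["k_schedule"], "ensemble": {}, "baseline": {}}
    for k_sub in cfg["k_schedule"]:
        espec = EnsembleSpec(
            n0=cfg["n0"], k_sub=k_sub, kind=cfg["kind"],
            include_graph_features=cfg["include_graph_features"], r_used=cfg["r"],
        )
        model = ensemble_train(train, espec, rng=seed + 1, seed=seed)
        out = evaluate_ensemble(model, test, rng=seed + 2, coin_rng=seed + 3)
        ens = evaluate(out["y_ensemble"], out["y_true"])
        base = evaluate(out["y_baseline"], out["y_true"])
        for name, rep in (("ensemble", ens), ("baseline", base)):
            report[name][str(k_sub)] = {
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
            }
    _plot_curves(
        outdir, f"ensemble_{cfg['model']}", "number of subgraphs k",
        {
            "ensemble": [report["ensemble"][str(k)]["accuracy"] for k in cfg["k_schedule"]],
            "baseline": [report["baseline"][str(k)]["accuracy"] for k in cfg["k_schedule"]],
        },
        cfg["k_schedule"],
    )
    return report


def run_gini(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    ds = _nws_dataset(cfg, seed)
    table = gini_importance_experiment(ds, n_splits=cfg["n_splits"], seed=seed)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / f"gini_{cfg['model']}{cfg['n']}.csv", index=False)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.boxplot([table[c] for c in table.columns], tick_labels=list(table.columns))
    ax.set_ylabel("Gini importance")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / f"gini_{cfg['model']}{cfg['n']}.png", dpi=120)
    plt.close(fig)
    return {"median_importance": {c: float(table[c].median()) for c in table.columns}}


_RUNNERS = {
    "contrast": run_contrast,
    "curves": run_curves,
    "ensemble": run_ensemble,
    "gini": run_gini,
}


def run_experiment(
    experiment: str, config: dict | None = None, seed: int = 0, outdir="results"
) -> dict:
    """Run one named experiment; returns the report written to <outdir>."""
    cfg = _resolve(experiment, config, seed)
    outdir = Path(outdir)
    results = _RUNNERS[experiment](cfg, outdir)
    report = {"config": cfg, "results": results}
    _write_report(outdir, experiment, report)
    return report
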