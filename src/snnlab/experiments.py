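"""Scripted experiments: rheobase sweep, noise-mean accuracy sweep, growth
comparison — each returning tidy tables plus a manifest that makes every
reported number regenerable from a (config, seed) pair.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import generate_digits
from .encoding import EncodingParams
from .growth import GrowthRule, run_growth_experiment
from .lif import LIFParams, simulate_constant_current
from .network import build_two_layer, evaluate, train
from .noise import NoiseParams
from .stdp import STDPParams

__all__ = [
    "ExperimentManifest",
    "sweep_rheobase",
    "sweep_noise_mean",
    "growth_comparison",
]


@dataclass
class ExperimentManifest:
    """Full provenance of one experiment: id, config snapshot, seeds and the
    per-run metrics derived from them."""

    experiment: str
    config: dict
    seeds: list
    metrics: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)
    version: str = __version__
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = time.strftime("%Y-%m-%dT%H:%M:%S")

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=_jsonify))
        return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def sweep_rheobase(mu_range, sigma: float = 0.0, duration: float = 200.0,
                   dt: float = 0.1, lif: LIFParams | None = None,
                   ) -> pd.DataFrame:
    """Single-neuron constant-current sweep locating the firing boundary.

    Each row reports whether the neuron fired within ``duration`` ms and the
    first spike time.  Only the deterministic ``sigma = 0`` case is
    supported (the boundary is then exact).
    """
    if sigma != 0.0:
        raise ValueError("the rheobase sweep is defined for sigma = 0")
    lif = lif or LIFParams()
    rows = []
    for mu in mu_range:
        spikes, _ = simulate_constant_current(lif, float(mu), duration, dt)
        rows.append({
            "mu": float(mu),
            "fired": bool(spikes.size),
            "first_spike_time": float(spikes[0]) if spikes.size else np.nan,
        })
    return pd.DataFrame(rows)


def _run_classification(mu: float, sigma: float, iterations: int, seed: int,
                        n_train: int, n_test: int, I_syn: float,
                        dt: float) -> list[dict]:
    """Train the two-layer network once; per-iteration accuracy rows."""
    dataset = generate_digits(n_train + n_test, seed=seed)
    train_set, test_set = dataset.split(n_train)
    noise = (NoiseParams(mu=mu, sigma=sigma, refresh_dt=dt, seed=seed)
             if (mu or sigma) else None)
    # desk-scale training config: ~10^3 presentations total, so the STDP
    # amplitude is raised above the asymptotic pair-based default
    stdp = STDPParams(A_plus=0.02, A_minus=1.05 * 0.02)
    net = build_two_layer(noise=noise, seed=seed, dt=dt, I_syn=I_syn,
                          stdp=stdp)
    _, log = train(net, train_set, iterations, test_set=test_set)
    return log


def sweep_noise_mean(mu_grid=None, sigma: float = 0.0, iterations: int = 5,
                     seeds=range(5), n_train: int = 200, n_test: int = 100,
                     I_syn: float = 1200.0, dt: float = 0.1,
                     ) -> tuple[pd.DataFrame, ExperimentManifest]:
    """Accuracy versus noise mean on the synthetic-digit task.

    Runs the two-layer training at every grid point in (0, 30] pA plus the
    mu = 0 baseline, at matched seeds; ``delta_vs_baseline`` is
    ``test_acc(mu) - test_acc(0)`` at the same (seed, iteration).
    """
    mu_grid = np.arange(2.0, 31.0, 2.0) if mu_grid is None else np.asarray(
        mu_grid, dtype=float)
    if mu_grid.size and not ((mu_grid > 0) & (mu_grid <= 30)).all():
        raise ValueError("mu grid must lie in (0, 30] pA")
    seeds = list(seeds)
    rows = []
    for seed in seeds:
        baseline = _run_classification(0.0, 0.0, iterations, seed,
                                       n_train, n_test, I_syn, dt)
        for entry in baseline:
            rows.append({"mu": 0.0, "seed": seed, **entry,
                         "delta_vs_baseline": 0.0})
        for mu in mu_grid:
            log = _run_classification(float(mu), sigma, iterations, seed,
                                      n_train, n_test, I_syn, dt)
            for entry, base in zip(log, baseline):
                rows.append({"mu": float(mu), "seed": seed, **entry,
                             "delta_vs_baseline":
                                 entry["test_acc"] - base["test_acc"]})
    table = pd.DataFrame(rows)
    final = table[table.iteration == iterations]
    manifest = ExperimentManifest(
        experiment="sweep_noise_mean",
        config={"mu_grid": mu_grid.tolist(), "sigma": sigma,
                "iterations": iterations, "n_train": n_train,
                "n_test": n_test, "I_syn": I_syn, "dt": dt},
        seeds=seeds,
        metrics={"max_mean_test_acc_over_grid": float(
            final[final.mu > 0].groupby("mu").test_acc.mean().max())
            if mu_grid.size else np.nan,
            "baseline_mean_test_acc": float(
                final[final.mu == 0].test_acc.mean())},
    )
    return table, manifest


def growth_comparison(n_presentations: int = 30, seeds=range(10),
                      mu: float = 400.0, sigma: float = 0.0,
                      n_images: int = 20, n_noise: int = 120,
                      rule: GrowthRule | None = None,
                      ) -> tuple[dict, pd.DataFrame, ExperimentManifest]:
    """Run the three growth conditions at matched seeds.

    Returns per-condition lists of :class:`GrowthReport`, a tidy count
    table, and a manifest carrying the median counts and the c-vs-a ratio.
    """
    seeds = list(seeds)
    noise = NoiseParams(mu=mu, sigma=sigma)
    reports = {"a": [], "b": [], "c": []}
    rows = []
    for seed in seeds:
        dataset = generate_digits(n_images, seed=seed)
        for condition in ("a", "b", "c"):
            rep = run_growth_experiment(
                condition, dataset if condition != "b" else None,
                noise=noise, n_presentations=n_presentations, seed=seed,
                rule=rule, n_noise=n_noise)
            reports[condition].append(rep)
            rows.append({"seed": seed, "condition": condition,
                         "n_synapses": rep.n_synapses})
    table = pd.DataFrame(rows)
    med = table.groupby("condition").n_synapses.median()
    manifest = ExperimentManifest(
        experiment="growth_comparison",
        config={"n_presentations": n_presentations, "mu": mu, "sigma": sigma,
                "n_images": n_images, "n_noise": n_noise,
                "rule": dataclasses.asdict(rule or GrowthRule())},
        seeds=seeds,
        metrics={"median_counts": med.to_dict(),
                 "c_over_a_ratio": float(med["c"] / med["a"]) if med["a"] else np.inf},
    )
    return reports, table, manifest
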