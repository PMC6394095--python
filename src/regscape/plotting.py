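"""Figure helpers for walk ensembles and connectivity scans."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_trajectories",
    "plot_fraction_vs_k",
    "plot_steps_vs_start",
    "plot_speed",
    "plot_variance",
]


def plot_trajectories(result, ax=None):
    """Replicate fitness vs mutational events, plus the ensemble mean."""
    if ax is None:
        _, ax = plt.subplots()
    for row in result.fitness_matrix:
        ax.plot(row, color="steelblue", alpha=0.15, lw=0.8)
    ax.plot(result.mean_fitness_series, color="black", lw=2, label="ensemble mean")
    ax.axhline(result.global_fitness, color="red", ls="--", lw=1, label="global peak")
    ax.set_xlabel("mutational events")
    ax.set_ylabel("fitness")
    ax.set_title(f"K={result.K}, start F≈{result.start_fitness_target}")
    ax.legend()
    return ax


def plot_fraction_vs_k(table: pd.DataFrame, ax=None):
    """Fraction of replicates reaching the global peak vs connectivity."""
    if ax is None:
        _, ax = plt.subplots()
    for f0, sub in table.groupby("start_F"):
        sub = sub.sort_values("K")
        ax.plot(sub["K"], sub["fraction_reached_global"], "o-", label=f"start F={f0}")
    ax.set_xlabel("connectivity K")
    ax.set_ylabel("fraction reaching global peak")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_steps_vs_start(summary: pd.DataFrame, ax=None):
    """Mean mutational events to the global peak vs starting fitness."""
    if ax is None:
        _, ax = plt.subplots()
    for K, sub in summary.groupby("K"):
        sub = sub.sort_values("start_F")
        ax.plot(sub["start_F"], sub["mean_steps"], "o-", label=f"K={K}")
    ax.set_xlabel("starting fitness")
    ax.set_ylabel("mean mutations to global peak")
    ax.legend(fontsize=8)
    return ax


def plot_speed(results: dict, K: int, ax=None):
    """Per-step gain of ensemble-mean fitness for each start at one K."""
    if ax is None:
        _, ax = plt.subplots()
    for (k, f0), res in sorted(results.items()):
        if k != K:
            continue
        ax.plot(res.speed_series, label=f"start F={f0}")
    ax.set_xlabel("mutational events")
    ax.set_ylabel("Δ mean fitness per event")
    ax.set_title(f"speed of evolution, K={K}")
    ax.legend(fontsize=8)
    return ax


def plot_variance(results: dict, K: int, ax=None):
    """Between-replicate fitness variance dynamics for each start at one K."""
    if ax is None:
        _, ax = plt.subplots()
    for (k, f0), res in sorted(results.items()):
        if k != K:
            continue
        ax.plot(res.var_fitness_series, label=f"start F={f0}")
    ax.set_xlabel("mutational events")
    ax.set_ylabel("between-replicate fitness variance")
    ax.set_title(f"trajectory variance, K={K}")
    ax.legend(fontsize=8)
    return ax
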