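"""Plotting hooks: PSTH, raster, period histogram, SAC, to image files."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_psth", "plot_raster", "plot_period_histogram", "plot_sac"]


def plot_psth(trains, binwidth_ms: float = 1.0, path=None, ax=None):
    """Peri-stimulus time histogram (rate in Hz) pooled over trials."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 3))
    allt = np.concatenate([np.asarray(t) for t in trains]) if trains else np.empty(0)
    tmax = allt.max() if len(allt) else 1.0
    bins = np.arange(0.0, tmax + binwidth_ms * 1e-3, binwidth_ms * 1e-3)
    counts, edges = np.histogram(allt, bins=bins)
    rate = counts / (len(trains) * binwidth_ms * 1e-3)
    ax.bar(edges[:-1] * 1e3, rate, width=binwidth_ms, align="edge", color="k")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("rate (Hz)")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_raster(trains, path=None, ax=None):
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 3))
    for k, tr in enumerate(trains):
        tr = np.asarray(tr)
        ax.plot(tr * 1e3, np.full_like(tr, k), "|", ms=3, color="k")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("trial")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_period_histogram(trains, f_mod: float, n_bins: int = 32, path=None, ax=None):
    """Spike-phase histogram on the modulation cycle."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 3))
    allt = np.concatenate([np.asarray(t) for t in trains]) if trains else np.empty(0)
    phases = np.mod(allt * f_mod, 1.0)
    ax.hist(phases, bins=np.linspace(0, 1, n_bins + 1), color="k")
    ax.set_xlabel("phase (cycles)")
    ax.set_ylabel("spikes")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_sac(sac_result, path=None, ax=None):
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 3))
    ax.step(sac_result.lags_ms, sac_result.rate, color="k", where="mid")
    ax.axhline(1.0, color="r", lw=0.5)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("normalized coincidence rate")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
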