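"""Optional figure output for population analyses (matplotlib)."""

from __future__ import annotations

import numpy as np


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_energy_attitude(population, path) -> None:
    """Scatter of baseline energy vs attitude per option, with quadratic fit."""
    from .analysis import quadratic_fit

    plt = _agg_backend()
    fig, axes = plt.subplots(
        1, len(population.topology.option_ids), figsize=(10, 4), squeeze=False
    )
    for ax, o in zip(axes[0], population.topology.option_ids):
        x = population.baselines[f"attitude_{o}"]
        y = population.baselines["energy"]
        fit = quadratic_fit(x, y)
        xs = np.linspace(x.min(), x.max(), 100)
        ax.scatter(x, y, s=8, alpha=0.4)
        ax.plot(xs, fit["c0"] + fit["c1"] * xs + fit["c2"] * xs * xs, "r-")
        ax.set_xlabel(f"attitude ({o})")
        ax.set_ylabel("energy")
        ax.set_title(f"{o}: R$^2$={fit['r_squared']:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pre_post_energy(prepost, path) -> None:
    """Grouped bars of mean energy before/after treatment per condition."""
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(prepost))
    ax.bar(x - 0.2, prepost["mean_pre"], width=0.4, label="pre")
    ax.bar(x + 0.2, prepost["mean_post"], width=0.4, label="post")
    ax.set_xticks(x, prepost["condition"])
    ax.set_ylabel("mean energy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_weight_surface(surface, path) -> None:
    """Heatmaps of mean weight change by (w_r, w_s) bin per condition/type."""
    plt = _agg_backend()
    groups = list(surface.groupby(["condition", "link_type"], observed=True))
    fig, axes = plt.subplots(1, max(len(groups), 1), figsize=(4 * len(groups), 3.5), squeeze=False)
    for ax, ((cond, lt), g) in zip(axes[0], groups):
        pivot = g.pivot_table(index="w_r_bin", columns="w_s_bin", values="mean_dw", observed=True)
        im = ax.imshow(pivot.to_numpy(), cmap="coolwarm", vmin=-2, vmax=2, origin="lower")
        ax.set_title(f"{cond} / {lt}")
        ax.set_xlabel("sender weight bin")
        ax.set_ylabel("prior weight bin")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
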