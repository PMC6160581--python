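"""Basic result plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_outflow_histograms", "plot_sigma_decay", "plot_profiles"]


def plot_outflow_histograms(results, path=None, bins=30):
    """Distal saturation distributions for the three models."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharex=True, sharey=True)
    c = results.model_comparison
    panels = [
        ("moving RBC", results.lagrangian.path_records["S_out"].to_numpy(),
         None, c["cosh_lagrangian"]),
        ("ODE functional", results.ode_functional.outflow_S,
         results.ode_functional.outflow_w, c["cosh_functional"]),
        ("ODE geometric", results.ode_geometric.outflow_S,
         results.ode_geometric.outflow_w, c["cosh_geometric"]),
    ]
    for ax, (title, S, w, cosh) in zip(axes, panels):
        ax.hist(S, bins=bins, range=(0, 1), weights=w, density=True,
                color="#7a1f1f", alpha=0.8)
        ax.set_title(f"{title}\nσ = {cosh:.3f}")
        ax.set_xlabel("outflow S")
    axes[0].set_ylabel("RBC-flow density")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sigma_decay(lagrangian_result, labels=None, path=None):
    """Per-vessel σ_S rate of change against the inlet σ_S (network overview)."""
    st = lagrangian_result.vessel_stats()
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    rates, sig_a = [], []
    for vid, rowdata in st.iterrows():
        tr = lagrangian_result.vessel_transits[vid]
        if len(tr) < 10:
            continue
        sig_a.append(rowdata["sigma_a"])
        rates.append(rowdata["sigma_v"] - rowdata["sigma_a"])
    ax.axhline(0, color="k", lw=0.5)
    ax.plot(sig_a, rates, "o", ms=4, alpha=0.7)
    ax.set_xlabel(r"inlet $\sigma_S$")
    ax.set_ylabel(r"$\Delta\sigma_S$ across vessel")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_profiles(network_saturation, vessel_ids, path=None):
    """Mean ± SD saturation profiles for selected vessels (ODE model)."""
    fig, axes = plt.subplots(1, len(vessel_ids), figsize=(3 * len(vessel_ids), 3),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, vid in zip(axes, vessel_ids):
        prof = network_saturation.profiles[vid]
        m, s = prof.mean, prof.std
        for k in range(prof.S_atoms.shape[0]):
            ax.plot(prof.x, prof.S_atoms[k], color="g", lw=0.5, alpha=0.5)
        ax.plot(prof.x, m, "k", lw=1.5)
        ax.fill_between(prof.x, m - s, m + s, color="k", alpha=0.15)
        ax.set_title(f"vessel {vid}")
        ax.set_xlabel("x (μm)")
    axes[0].set_ylabel("S")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
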