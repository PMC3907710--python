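"""Figure generation from the CSV outputs of :mod:`vtanet.runner`.

Every figure is rebuilt purely from the written CSV files, so plots can be
regenerated (or restyled) without re-running any simulation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["render_outputs", "plot_traces", "plot_acquisition", "plot_sweep"]


def plot_traces(csv_path, out_png) -> None:
    """VTA rate time courses, one panel per (association, trial)."""
    df = pd.read_csv(csv_path)
    vta = df[df["population"] == "VTA"]
    if vta.empty:
        return
    groups = list(vta.groupby(["assoc_id", "trial"]))
    ncols = max(t for (_, t), _ in groups) if groups else 1
    assocs = sorted({a for (a, _), _ in groups})
    trials = sorted({t for (_, t), _ in groups})
    fig, axes = plt.subplots(len(trials), len(assocs),
                             figsize=(4 * len(assocs), 2.2 * len(trials)),
                             sharex=False, sharey=True, squeeze=False)
    for i, trial in enumerate(trials):
        for j, a in enumerate(assocs):
            g = vta[(vta["assoc_id"] == a) & (vta["trial"] == trial)]
            ax = axes[i][j]
            ax.plot(g["time_ms"] / 1000.0, g["rate"], lw=0.6, color="k")
            ax.axhline(0.2, color="grey", lw=0.5, ls=":")
            ax.set_title(f"association {a}, trial {trial}", fontsize=8)
            if i == len(trials) - 1:
                ax.set_xlabel("time (s)")
            if j == 0:
                ax.set_ylabel("VTA rate")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def plot_burst_evolution(csv_path, out_png) -> None:
    """CS- and US-locked VTA maxima across conditioning trials."""
    df = pd.read_csv(csv_path)
    df = df[df["metric"].isin(["cs_burst", "us_burst"])]
    if df.empty:
        return
    assocs = sorted(df["assoc_id"].unique())
    fig, axes = plt.subplots(1, len(assocs), figsize=(4 * len(assocs), 3),
                             sharey=True, squeeze=False)
    for j, a in enumerate(assocs):
        ax = axes[0][j]
        for metric, color in [("cs_burst", "tab:blue"), ("us_burst", "tab:red")]:
            g = df[(df["assoc_id"] == a) & (df["metric"] == metric)]
            ax.plot(g["trial"], g["value"], "o-", color=color, ms=3,
                    label=metric.replace("_", " "))
        ax.axhline(0.2, color="grey", lw=0.5, ls=":")
        ax.set_title(f"association {a}")
        ax.set_xlabel("conditioning trial")
    axes[0][0].set_ylabel("max VTA rate")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def plot_acquisition(csv_path, out_png) -> None:
    """Probe-trial minima of VTA and maxima of NAcc across conditioning."""
    df = pd.read_csv(csv_path)
    assocs = sorted(df[df["trial"] > 0]["assoc_id"].unique())
    if not assocs:
        return
    fig, axes = plt.subplots(1, len(assocs), figsize=(4 * len(assocs), 3),
                             sharey=True, squeeze=False)
    for j, a in enumerate(assocs):
        ax = axes[0][j]
        for metric, color, label in [
                ("probe_min_vta", "tab:red", "min VTA"),
                ("probe_max_nacc", "tab:blue", "max NAcc")]:
            g = df[(df["assoc_id"] == a) & (df["metric"] == metric)]
            ax.plot(g["trial"], g["value"], "o-", color=color, ms=3, label=label)
        ax.set_title(f"association {a}")
        ax.set_xlabel("conditioning trial")
    axes[0][0].set_ylabel("rate at expected reward time")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def plot_sweep(csv_path, out_png) -> None:
    """Mean +- sd of cue/reward responses against reward magnitude."""
    df = pd.read_csv(csv_path)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharex=True)
    panels = [("BLA", "cs_bla", "us_bla"), ("VTA", "cs_vta", "us_vta")]
    for ax, (title, cs_key, us_key) in zip(axes, panels):
        for trial, style in [(1, ":"), (df["trial"].max(), "-")]:
            g = df[df["trial"] == trial]
            for key, color, lbl in [(cs_key, "tab:blue", "CS"),
                                    (us_key, "tab:red", "US")]:
                m, s = g[f"{key}_mean"], g[f"{key}_std"].fillna(0.0)
                ax.plot(g["magnitude"], m, style, color=color,
                        label=f"{lbl} trial {trial}")
                ax.fill_between(g["magnitude"], m - s, m + s, color=color,
                                alpha=0.15)
        ax.set_title(title)
        ax.set_xlabel("reward magnitude")
    axes[0].set_ylabel("max rate in window")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def render_outputs(out_dir) -> None:
    """Render whatever figures the CSVs present in ``out_dir`` support."""
    out = Path(out_dir)
    if (out / "traces.csv").exists():
        plot_traces(out / "traces.csv", out / "vta_traces.png")
    if (out / "metrics.csv").exists():
        plot_burst_evolution(out / "metrics.csv", out / "burst_evolution.png")
    if (out / "probe_metrics.csv").exists():
        plot_acquisition(out / "probe_metrics.csv", out / "acquisition.png")
    if (out / "sweep_summary.csv").exists():
        plot_sweep(out / "sweep_summary.csv", out / "magnitude_sweep.png")
    for variant in ("omission", "early"):
        p = out / f"{variant}_trace.csv"
        if p.exists():
            plot_traces(p, out / f"{variant}_trace.png")
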