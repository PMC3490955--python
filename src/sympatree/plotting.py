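"""Optional diagnostic figures (LTT, ARC scatter, area-age scatter)."""
from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def ltt_plot(bt, path) -> None:
    """Log lineage-through-time step plot, time axis toward the present."""
    from .diversification import ltt_curve

    plt = _pyplot()
    ages = [t for t, _ in ltt_curve(bt)]
    counts = list(range(2, 2 + len(ages)))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.step([-a for a in ages] + [0], counts + [counts[-1]], where="post")
    ax.set_yscale("log")
    ax.set_xlabel("time (Myr, 0 = present)")
    ax.set_ylabel("lineages")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def arc_plot(fit: dict, path, table_path=None) -> None:
    """Node overlap against node age with the fitted ARC line."""
    import pandas as pd

    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if table_path is not None:
        table = pd.read_csv(table_path, sep="\t")
        ax.scatter(table["age_myr"], table["mean_overlap"], zorder=3)
        xs = np.linspace(0, table["age_myr"].max(), 50)
    else:
        xs = np.linspace(0, 10, 50)
    ax.plot(xs, fit["intercept"] + fit["slope"] * xs, "k--")
    ax.set_xlabel("node age (Myr)")
    ax.set_ylabel("mean degree of sympatry")
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def area_age_plot(table, path) -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(table["age_myr"], table["area_km2"])
    ax.set_xlabel("species age (Myr)")
    ax.set_ylabel("range area (km2)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
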