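"""Minimal plotting helpers; every plotted quantity is also emitted as TSV,
so plots are cosmetic and tests never parse images."""

from __future__ import annotations

import pandas as pd


def plot_drift_table(dtab: pd.DataFrame, path) -> None:
    """Per-bin I/D ratio vs donor methylation level."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (dtab["bin_lo"] + dtab["bin_hi"]) / 2
    ax.plot(centers, dtab["id_ratio"], "o-")
    ax.axhline(dtab.attrs.get("reference_ratio", 1.0), ls="--", c="grey")
    ax.set_xlabel("donor fractional methylation")
    ax.set_ylabel("increase/decrease ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_quintiles(qt: pd.DataFrame, path) -> None:
    """Down/up ratio per density quintile."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(qt["median_metric"], qt["di_ratio"], "o-")
    ref = qt.attrs.get("reference")
    if ref and ref[1]:
        ax.axhline(ref[0] / ref[1], ls="--", c="grey")
    ax.set_xlabel("median density per quintile")
    ax.set_ylabel("down/up gene ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
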