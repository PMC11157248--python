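"""Optional GRM / MD diagram plotting (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_grm", "plot_md"]


def plot_grm(histogram: dict[int, int], path: str, title: str = "GRM diagram") -> None:
    """Bar plot of period frequency: a peak at period n marks an n-mer HOR."""
    fig, ax = plt.subplots(figsize=(7, 3.2))
    periods = sorted(histogram)
    ax.bar(periods, [histogram[p] for p in periods], width=0.8, color="navy")
    ax.set_xlabel("period (monomer units)")
    ax.set_ylabel("frequency")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_md(points, path: str, title: str = "MD diagram") -> None:
    """Scatter of (enumeration index, period); dense horizontal runs are
    HOR arrays, co-located lower runs their subfragments."""
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.plot([p.index for p in points], [p.period for p in points],
            ".", ms=2, color="darkred")
    ax.set_xlabel("monomer enumeration")
    ax.set_ylabel("period (monomer units)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
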