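"""Basic summary plots: occurrence counts per period and prevalence
through time colour-coded by host phylum."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .prevalence import PrevalenceValue
from .timescale import Timescale, load_timescale


def occurrence_histogram(records, path, timescale: Timescale | None = None):
    """Counts of analytical parasitized occurrences per period."""
    ts = timescale or load_timescale()
    counts = [sum(r.period == p.name for r in records) for p in ts.periods]
    mids = [p.midpoint_ma for p in ts.periods]
    widths = [p.duration_myr * 0.9 for p in ts.periods]
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.bar(mids, counts, width=widths, color="#4477aa", edgecolor="black")
    ax.set_xlim(560, -5)
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("parasitized occurrences")
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)
    return path


def prevalence_vs_age(values: list[PrevalenceValue], path):
    """Prevalence of each eligible occurrence against its best age."""
    fig, ax = plt.subplots(figsize=(9, 3.6))
    phyla = sorted({v.host_phylum for v in values})
    cmap = plt.get_cmap("tab10")
    for i, ph in enumerate(phyla):
        sub = [v for v in values if v.host_phylum == ph]
        ax.scatter(
            [v.best_age_ma for v in sub],
            [v.p_float for v in sub],
            s=14, alpha=0.7, color=cmap(i % 10), label=ph or "unknown",
        )
    ax.set_xlim(560, -5)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("best age (Ma)")
    ax.set_ylabel("prevalence")
    ax.legend(fontsize=7, ncol=2, frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)
    return path
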