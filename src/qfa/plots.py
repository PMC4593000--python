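"""Static fitness plots: control-vs-query scatter and per-gene profiles."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .interaction import GISRecord, StrainSummary
from .profiles import ProfileSet

logger = logging.getLogger(__name__)

__all__ = ["render_fitness_plot", "render_profile_plot"]


def render_fitness_plot(
    records: Sequence[GISRecord],
    m: float,
    path: str | Path,
    title: str = "",
) -> dict[str, int] | None:
    """Scatter of control vs query mean fitness with interaction calls.

    Grey dots: no significant interaction; red inverted triangles: negative
    interactions; blue upward triangles: positive. The solid grey line is the
    through-origin regression (slope m); the dashed line is equal fitness.
    Class counts are annotated across the top. Returns the plotted counts.
    """
    if not records:
        logger.warning("render_fitness_plot: no records, nothing plotted")
        return None
    x = np.array([r.control_mean for r in records])
    y = np.array([r.query_mean_obs for r in records])
    call = np.array([r.call for r in records])

    counts = {
        "none": int(np.sum(call == "none")),
        "negative": int(np.sum(call == "negative")),
        "positive": int(np.sum(call == "positive")),
    }

    fig, ax = plt.subplots(figsize=(6, 6))
    sel = call == "none"
    ax.plot(x[sel], y[sel], ".", color="0.6", ms=4, label=f"none ({counts['none']})")
    sel = call == "negative"
    ax.plot(x[sel], y[sel], "v", color="crimson", ms=5,
            label=f"negative ({counts['negative']})")
    sel = call == "positive"
    ax.plot(x[sel], y[sel], "^", color="royalblue", ms=5,
            label=f"positive ({counts['positive']})")

    xmax = float(x.max()) * 1.05 if x.size else 1.0
    xs = np.array([0.0, xmax])
    ax.plot(xs, m * xs, "-", color="0.4", lw=1.2)
    ax.plot(xs, xs, "--", color="0.4", lw=1.0)
    ax.annotate(
        f"n={len(records)}   m={m:.3f}   "
        f"neg={counts['negative']}  pos={counts['positive']}",
        xy=(0.02, 1.02), xycoords="axes fraction", fontsize=9,
    )
    ax.set_xlabel("control mean fitness (doublings$^2$/day)")
    ax.set_ylabel("query mean fitness (doublings$^2$/day)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return counts


def render_profile_plot(
    profile_set: ProfileSet,
    genes: Sequence[str],
    path: str | Path,
    replicate_values: Mapping[str, Mapping[str, StrainSummary]] | None = None,
) -> None:
    """Per-gene fitness across screens; strip-plot replicates when provided.

    ``replicate_values`` maps screen name -> per-gene summaries, letting the
    plot show replicate spread behind the per-screen means.
    """
    screens = profile_set.screens
    xs = np.arange(len(screens))
    fig, ax = plt.subplots(figsize=(1.2 * len(screens) + 2, 4))
    for gene in genes:
        prof = profile_set.profile(gene).as_dict()
        ax.plot(xs, [prof[s] for s in screens], "o-", ms=5, label=gene)
        if replicate_values:
            for i, s in enumerate(screens):
                summ = replicate_values.get(s, {}).get(gene)
                if summ is not None:
                    jitter = np.linspace(-0.12, 0.12, summ.n)
                    ax.plot(i + jitter, summ.replicate_fitnesses, ".",
                            color="0.6", ms=3, zorder=0)
    ax.set_xticks(xs, screens, rotation=30, ha="right")
    ax.set_ylabel("fitness (doublings$^2$/day)")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
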