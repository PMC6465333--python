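"""Figure helpers. CSVs are the canonical outputs; figures are optional."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .enrichment import ConditionSummary
from .ripqpcr import EnrichmentRecord


def enrichment_dotplot(summaries: list[ConditionSummary], path=None):
    """Per-cell enrichment ratios per condition: one dot per cell, mean line,
    95% CI band and SD band."""
    fig, ax = plt.subplots(figsize=(1.5 * len(summaries) + 1, 4))
    for i, s in enumerate(summaries):
        x = i + 0.08 * np.random.default_rng(i).standard_normal(len(s.ratios))
        ax.plot(x, s.ratios, "o", ms=4, alpha=0.6, color="0.3")
        ax.fill_between([i - 0.3, i + 0.3], s.mean - s.sd, s.mean + s.sd,
                        color="tab:blue", alpha=0.2)
        ax.fill_between([i - 0.3, i + 0.3], s.ci95[0], s.ci95[1],
                        color="tab:red", alpha=0.3)
        ax.hlines(s.mean, i - 0.3, i + 0.3, color="k")
    ax.set_xticks(range(len(summaries)), [s.label for s in summaries])
    ax.set_ylabel("enrichment ratio")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def bar_with_dots(records: list[EnrichmentRecord], path=None):
    """Replicate-aggregated qPCR statistics: bar = mean, whisker = SD,
    dots = individual biological replicates."""
    fig, ax = plt.subplots(figsize=(1.2 * len(records) + 1, 4))
    for i, r in enumerate(records):
        ax.bar(i, r.value, width=0.6, color="0.8", edgecolor="k",
               yerr=r.sd if r.sd is not None else 0)
        ax.plot([i] * len(r.per_replicate), r.per_replicate, "o", color="0.2", ms=4)
    ax.set_xticks(range(len(records)), [r.gene for r in records])
    ax.set_ylabel(records[0].statistic if records else "")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
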