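"""Minimal plotting helper: per-condition deviation bar plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .scoring import ConditionSummary

__all__ = ["deviation_barplot"]


def deviation_barplot(summaries: list[ConditionSummary], path: str | Path) -> None:
    """Bar plot of mean absolute hitting deviation (+/- SD) per condition."""
    labels = [s.condition for s in summaries]
    means = [s.mean_abs_deviation_pd for s in summaries]
    sds = [s.sd_deviation_pd for s in summaries]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(labels, means, yerr=sds, capsize=4, color="#c44", alpha=0.85)
    ax.set_ylabel("hitting deviation (PD)")
    ax.set_xlabel("condition")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
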