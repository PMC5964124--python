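"""Markdown run summaries and score-distribution plots."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bab import DEFAULT_BAB_CUTOFF, ImbalanceResult


def _quantiles(values: Sequence[float]) -> dict:
    arr = np.array([v for v in values if not math.isnan(v)])
    if arr.size == 0:
        return {}
    q = np.percentile(arr, [5, 25, 50, 75, 95])
    return {"n": int(arr.size), "min": float(arr.min()), "q05": float(q[0]),
            "q25": float(q[1]), "median": float(q[2]), "q75": float(q[3]),
            "q95": float(q[4]), "max": float(arr.max())}


def render_markdown(results: Iterable[ImbalanceResult],
                    mapping_stats: Mapping[str, object] | None = None,
                    cutoff: float = DEFAULT_BAB_CUTOFF) -> str:
    """Human-readable summary: score distribution per condition, selections, QC."""
    results = list(results)
    lines = ["# Allelic-imbalance screen summary", ""]
    by_condition: dict[str, list[ImbalanceResult]] = {}
    for r in results:
        by_condition.setdefault(r.condition, []).append(r)
    for condition in sorted(by_condition):
        rs = by_condition[condition]
        stats = _quantiles([r.score for r in rs])
        n_sig = sum(1 for r in rs if not math.isnan(r.score) and abs(r.score) >= cutoff)
        lines.append(f"## Condition {condition}")
        lines.append("")
        lines.append(f"- results scored: {len(rs)}")
        if stats:
            lines.append(f"- score range: {stats['min']:.2f} .. {stats['max']:.2f} "
                         f"(median {stats['median']:.2f}, IQR {stats['q25']:.2f} .. "
                         f"{stats['q75']:.2f})")
        lines.append(f"- |score| >= {cutoff:.2f}: {n_sig}")
        lines.append("")
    if mapping_stats:
        lines.append("## Mapping QC")
        lines.append("")
        for sample, stats in sorted(mapping_stats.items()):
            frac = getattr(stats, "on_target_fraction", stats)
            lines.append(f"- {sample}: on-target fraction {float(frac):.3f}")
        lines.append("")
    return "\n".join(lines)


def plot_score_distribution(results: Iterable[ImbalanceResult], path,
                            cutoff: float = DEFAULT_BAB_CUTOFF) -> Path:
    """Histogram of scores per condition with the significance cutoffs marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = [r for r in results if not math.isnan(r.score)]
    fig, ax = plt.subplots(figsize=(6, 4))
    by_condition: dict[str, list[float]] = {}
    for r in results:
        by_condition.setdefault(r.condition, []).append(r.score)
    for condition, scores in sorted(by_condition.items()):
        ax.hist(scores, bins=40, alpha=0.6, label=condition)
    for x in (-cutoff, cutoff):
        ax.axvline(x, color="red", linestyle="--", linewidth=1)
    ax.set_xlabel("allelic-imbalance score (log2)")
    ax.set_ylabel("SNP alleles")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
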