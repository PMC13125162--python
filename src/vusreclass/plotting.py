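"""Stacked-bar report of VUS reclassification destinations per predictor."""

from __future__ import annotations

from typing import Mapping, Sequence

from .acmg import Classification
from .pipeline import ReclassificationOutcome


def reclassification_stacked_bar(
    outcomes_by_predictor: Mapping[str, Sequence[ReclassificationOutcome]],
    path: str,
) -> None:
    """Save a per-predictor, per-dataset stacked bar of the percentage of
    baseline VUS reclassified to Likely Pathogenic (dark) vs Likely
    Benign/Benign (light)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, lp_vals, lb_vals = [], [], []
    for pred, outcomes in outcomes_by_predictor.items():
        datasets = sorted({o.dataset for o in outcomes})
        for ds in datasets:
            sub = [
                o
                for o in outcomes
                if o.dataset == ds
                and o.in_denominator
                and o.old_class is Classification.VUS
            ]
            n = len(sub)
            if n == 0:
                continue
            lp = sum(
                1 for o in sub if o.changed and o.new_class > Classification.VUS
            )
            lb = sum(
                1 for o in sub if o.changed and o.new_class < Classification.VUS
            )
            labels.append(f"{ds}\n{pred}")
            lp_vals.append(100.0 * lp / n)
            lb_vals.append(100.0 * lb / n)

    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(labels)), 4))
    x = range(len(labels))
    ax.bar(x, lp_vals, color="#36454f", label="to LP")
    ax.bar(x, lb_vals, bottom=lp_vals, color="#9fc5e8", label="to LB/B")
    ax.set_xticks(list(x))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("% of baseline VUS reclassified")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
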