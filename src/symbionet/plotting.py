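"""Basic plots: functional composition bars and ordination scatter.

Matplotlib is imported lazily so headless pipeline runs never touch a display
backend unless a plot is requested.
"""

from __future__ import annotations

from .diversity import Ordination
from .traits import EXPLORATION_TYPES, FunctionalMatrix, type_proportions

_STATUS_COLORS = {"native": "#2166ac", "alien": "#b2182b"}


def plot_type_composition(fm: FunctionalMatrix, ax=None):
    """Stacked proportion bars of exploration types per plant genus."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.5 * len(fm.row_labels)), 4))
    props = type_proportions(fm)
    bottom = None
    for k, t in enumerate(EXPLORATION_TYPES):
        ax.bar(range(len(fm.row_labels)), props[:, k], bottom=bottom, label=t)
        bottom = props[:, k] if bottom is None else bottom + props[:, k]
    ax.set_xticks(range(len(fm.row_labels)))
    ax.set_xticklabels(fm.row_labels, rotation=90)
    for tick, genus in zip(ax.get_xticklabels(), fm.row_labels):
        tick.set_color(_STATUS_COLORS.get(fm.row_status[genus], "black"))
    ax.set_ylabel("proportion of observations")
    ax.legend(fontsize="small")
    return ax


def plot_ordination(ordination: Ordination, row_status=None, ax=None):
    """PC1/PC2 scatter of genera, coloured by native/alien status."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xs = ordination.scores[:, 0]
    ys = ordination.scores[:, 1] if ordination.scores.shape[1] > 1 else xs * 0
    for label, x, y in zip(ordination.row_labels, xs, ys):
        status = (row_status or {}).get(label, "")
        ax.scatter(x, y, color=_STATUS_COLORS.get(status, "gray"))
        ax.annotate(label, (x, y), fontsize=8)
    ax.set_xlabel(f"PC1 ({ordination.explained[0]:.0%})")
    if ordination.scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({ordination.explained[1]:.0%})")
    return ax
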