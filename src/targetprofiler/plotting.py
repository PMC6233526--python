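"""Optional plot helpers (requires matplotlib; install the ``plots`` extra).

Figures are a convenience layer only — every quantity plotted here is
available as CSV/JSON from the owning modules.
"""

from __future__ import annotations

from typing import Sequence

__all__ = ["plot_calibration_curve", "plot_profile"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_calibration_curve(curve: Sequence[tuple[float, float]], ax=None, label=None):
    """Accuracy vs confidence with the validity diagonal."""
    ax = _axes(ax)
    conf = [c for c, _ in curve]
    acc = [a for _, a in curve]
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.plot(conf, acc, marker="o", label=label)
    ax.set_xlabel("confidence")
    ax.set_ylabel("accuracy")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if label:
        ax.legend()
    return ax


def plot_profile(profile, ax=None):
    """Per-target bar plot: active p-value up (purple), non-active down (green)."""
    ax = _axes(ax)
    rows = profile.to_records()
    targets = [r["target"] for r in rows]
    x = range(len(rows))
    ax.bar(x, [r["p_A"] for r in rows], color="purple", label="p(Active)")
    ax.bar(x, [-r["p_N"] for r in rows], color="green", label="p(Non-active)")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(list(x))
    ax.set_xticklabels(targets, rotation=90)
    ax.set_ylabel("p-value")
    ax.set_ylim(-1.05, 1.05)
    ax.legend()
    return ax
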