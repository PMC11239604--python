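"""Power-curve figures with the standard reference lines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_curves"]


def plot_curves(curves: dict, path, title: str = "",
                xlabel: str = "Effect size (SD of one outcome)") -> None:
    """Plot a family of power curves with reference lines at 0.05 (the
    Type I error rate, a lower limit for power) and 0.9 (a common target
    power for trial design)."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, curve in curves.items():
        ax.plot(curve.grid, curve.powers, label=name)
    for ref in (0.05, 0.9):
        ax.axhline(ref, color="0.6", linewidth=0.8, zorder=0)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("Power")
    ax.set_ylim(0.0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
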