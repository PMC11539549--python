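"""Basic figures: stress-strain curves, rupture counts, gap opening."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .observables import TimeSeries

__all__ = ["plot_stress_strain", "plot_run_overview"]


def plot_stress_strain(curves: Mapping[str, TimeSeries], ax=None,
                       gpa: bool = True):
    """Overlay stress-strain curves of several runs (label -> series)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, ts in curves.items():
        ax.plot(ts.strain, ts.stress_gpa if gpa else ts.stress, label=label)
    ax.set_xlabel("strain")
    ax.set_ylabel("engineering stress [GPa]" if gpa
                  else "stress [kcal/mol/A^3]")
    ax.legend(fontsize=8)
    return ax


def plot_run_overview(ts: TimeSeries, path=None):
    """Stress, broken-bond counts and average gap length vs strain."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    axes[0].plot(ts.strain, ts.stress_gpa)
    axes[0].set_xlabel("strain")
    axes[0].set_ylabel("stress [GPa]")
    axes[1].plot(ts.strain, ts.broken_collagen, label="collagen")
    axes[1].plot(ts.strain, ts.broken_age, label="AGE")
    axes[1].set_xlabel("strain")
    axes[1].set_ylabel("broken bonds")
    axes[1].legend(fontsize=8)
    axes[2].plot(ts.strain, ts.avg_gap_length)
    axes[2].set_xlabel("strain")
    axes[2].set_ylabel("avg gap length [A]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
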