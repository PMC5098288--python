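"""Error-bar plots of the validation designs (optional; needs matplotlib)."""

from __future__ import annotations

from typing import Sequence

from .experiments import PlateauResult, ReplicateSummary, SweepResult

__all__ = ["plot_learning_curve", "plot_ratio_sweep", "plot_plateau"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_learning_curve(summaries: Sequence[ReplicateSummary], sizes: Sequence[int],
                        metric: str = "correlation", ax=None):
    """Mean accuracy vs labelled training-set size with 95% CI error bars."""
    ax = _axes(ax)
    if metric == "correlation":
        means = [s.mean_correlation for s in summaries]
        cis = [s.ci_correlation for s in summaries]
        ax.set_ylabel("test correlation")
    else:
        means = [s.mean_mse for s in summaries]
        cis = [s.ci_mse for s in summaries]
        ax.set_ylabel("test MSE")
    ax.errorbar(list(sizes), means, yerr=cis, fmt="o-", capsize=3)
    ax.set_xlabel("animals with measured phenotypes")
    return ax


def plot_ratio_sweep(result: SweepResult, ax=None):
    """Mean paired gain (R_SSL − R_SL) per cell, one line per labelled size."""
    ax = _axes(ax)
    frame = result.summary_frame()
    for nl, sub in frame.groupby("n_labeled"):
        sub = sub.sort_values("n_unlabeled")
        ax.errorbar(sub["n_unlabeled"], sub["mean_diff"], yerr=sub["ci_diff"],
                    fmt="o-", capsize=3, label=f"n labelled = {nl}")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("animals with self-trained phenotypes")
    ax.set_ylabel("gain in test correlation")
    ax.legend()
    return ax


def plot_plateau(results: dict[int, PlateauResult], ax=None):
    """Mean stopping ratio (pseudo-labelled / labelled) per labelled size."""
    ax = _axes(ax)
    sizes = sorted(results)
    ratios = [results[n].mean_ratio for n in sizes]
    cis = [results[n].ci_ratio for n in sizes]
    ax.errorbar(sizes, ratios, yerr=cis, fmt="o-", capsize=3)
    ax.set_xlabel("animals with measured phenotypes")
    ax.set_ylabel("stopping ratio (self-trained / measured)")
    return ax
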