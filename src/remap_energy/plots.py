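"""Figure helpers: condition bars with 99% CIs and similarity heat maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .controls import _mean_ci


def plot_condition_losses(loss_table, path: str | Path) -> None:
    """Bar chart of mean onset loss per condition, 99% CI whiskers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = loss_table.groupby("condition")["loss"]
    names = sorted(groups.groups, key=lambda c: groups.get_group(c).mean())
    means, errs = [], []
    for c in names:
        v = groups.get_group(c).to_numpy()
        lo, hi = _mean_ci(v)
        means.append(v.mean())
        errs.append((hi - lo) / 2)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(range(len(names)), means, yerr=errs, capsize=3, color="#4878a8")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=30, ha="right")
    ax.set_ylabel("onset loss (mean |preactivation|)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_similarity_matrix(matrix: np.ndarray, path: str | Path,
                           steps_per_fixation: int) -> None:
    """Heat map of the drive-vs-ideal-inhibition correlation matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 5))
    im = ax.imshow(matrix, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xlabel("crop index")
    ax.set_ylabel("model step")
    for f in range(1, matrix.shape[0] // steps_per_fixation):
        ax.axhline(f * steps_per_fixation - 0.5, lw=0.4, color="k")
    fig.colorbar(im, ax=ax, label="r(feedback, ideal inhibition)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
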