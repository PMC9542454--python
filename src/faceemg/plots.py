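"""Summary figures: condition-mean boxplots and the V-shape scatterplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import MODALITIES, CohortResults, quadratic_trend


def condition_boxplots(results: CohortResults, scheme: str, path: Path) -> None:
    means = results.condition_means[scheme]
    conditions = list(dict.fromkeys(means["condition"]))
    fig, axes = plt.subplots(1, len(MODALITIES), figsize=(3 * len(MODALITIES), 4),
                             sharey=True)
    for ax, channel in zip(np.atleast_1d(axes), MODALITIES):
        sub = means[means["channel"] == channel]
        data = [sub.loc[sub["condition"] == c, "value"].to_numpy()
                for c in conditions]
        ax.boxplot(data, tick_labels=conditions)
        ax.set_title(channel, fontsize=9)
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    axes[0].set_ylabel("normalized amplitude")
    fig.suptitle(f"Condition means ({scheme})")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def vshape_scatter(results: CohortResults, path: Path) -> None:
    means = results.condition_means["valence_level"]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharey=True)
    grid = np.linspace(1, 9, 100)
    for ax, channel in zip(axes.ravel(), MODALITIES):
        sub = means[means["channel"] == channel]
        x = sub["condition"].astype(int).to_numpy()
        y = sub["value"].to_numpy()
        ax.scatter(x, y, s=8, alpha=0.5)
        fit = quadratic_trend(x, y)
        ax.plot(grid, fit.predict(grid), color="C1")
        ax.set_title(channel, fontsize=9)
        ax.set_xlabel("valence level")
    axes[0, 0].set_ylabel("normalized amplitude")
    fig.suptitle("Amplitude vs subjective valence (quadratic trend)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def summary_figures(results: CohortResults, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for scheme in results.paired:
        p = out_dir / f"boxplot_{scheme}.png"
        condition_boxplots(results, scheme, p)
        written.append(p)
    p = out_dir / "vshape_valence.png"
    vshape_scatter(results, p)
    written.append(p)
    return written
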