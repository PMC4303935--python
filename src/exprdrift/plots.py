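"""Data-faithful matplotlib views of distance profiles and fits."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .association import SurvivalFit
from .barycentric import TRIANGLE_VERTICES, to_barycentric, ternary_to_cartesian
from .errors import ConfigurationError
from .io import SampleMetadata


def _group_colors(labels):
    cmap = plt.get_cmap("tab10")
    return {lab: cmap(i % 10) for i, lab in enumerate(labels)}


def plot_r1_vs_r2(profiles: pd.DataFrame, metadata: SampleMetadata,
                  path: str | Path, x_label: Optional[str] = None,
                  y_label: Optional[str] = None) -> None:
    """Scatter of the distance to one center against another, by group."""
    cols = list(profiles.columns)
    if len(cols) < 2:
        raise ConfigurationError("need at least two centers for an r1-vs-r2 plot")
    x_label = x_label or cols[0]
    y_label = y_label or cols[1]
    groups = metadata.groups.reindex(profiles.index)
    colors = _group_colors(sorted(groups.unique()))
    fig, ax = plt.subplots(figsize=(5, 5))
    for lab in sorted(groups.unique()):
        sel = groups == lab
        ax.scatter(profiles.loc[sel, x_label], profiles.loc[sel, y_label],
                   s=18, label=lab, color=colors[lab], alpha=0.8)
    ax.set_xlabel(f"distance to {x_label} center")
    ax.set_ylabel(f"distance to {y_label} center")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distance_to_normal(profiles: pd.DataFrame, metadata: SampleMetadata,
                            normal_label: str, path: str | Path) -> None:
    """Strip+box plot of each group's distance to the normal center."""
    groups = metadata.groups.reindex(profiles.index)
    labels = sorted(groups.unique())
    data = [profiles.loc[groups == lab, normal_label].to_numpy() for lab in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, vals in enumerate(data, start=1):
        ax.scatter(i + rng.uniform(-0.12, 0.12, vals.size), vals, s=10, alpha=0.6)
    ax.set_ylabel(f"distance to {normal_label} center")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ternary(profiles: pd.DataFrame, metadata: SampleMetadata,
                 path: str | Path, convention: str = "D") -> None:
    """Ternary scatter of 3-center profiles in the equilateral triangle."""
    if profiles.shape[1] != 3:
        raise ConfigurationError("ternary plot needs exactly 3 centers")
    groups = metadata.groups.reindex(profiles.index)
    colors = _group_colors(sorted(groups.unique()))
    fig, ax = plt.subplots(figsize=(5.5, 5))
    tri = np.vstack([TRIANGLE_VERTICES, TRIANGLE_VERTICES[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="k", lw=1)
    for lab, v in zip(profiles.columns, TRIANGLE_VERTICES):
        ax.annotate(lab, v, textcoords="offset points", xytext=(0, 5),
                    ha="center")
    for lab in sorted(groups.unique()):
        pts = np.array([
            ternary_to_cartesian(to_barycentric(profiles.loc[sid]), convention)
            for sid in profiles.index[groups == lab]
        ])
        ax.scatter(pts[:, 0], pts[:, 1], s=18, label=lab,
                   color=colors[lab], alpha=0.8)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(frameon=False, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_survival(distances: pd.Series, survival: pd.Series,
                  fit: SurvivalFit, path: str | Path) -> None:
    """Survival vs distance scatter with the fitted line."""
    keep = distances.notna() & survival.notna()
    x = distances[keep].to_numpy(dtype=float)
    y = survival[keep].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(x, y, s=14, alpha=0.7)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="crimson",
            label=(f"y = {fit.intercept:.3g} + {fit.slope:.3g} x\n"
                   f"p = {fit.p_value:.2g}, R$^2$ = {fit.r_squared:.2g}"))
    ax.set_xlabel("distance to normal center")
    ax.set_ylabel("survival (days)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
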