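"""Figure exports: KDE-coloured scatter, PC score plots, importance heat maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import Prediction, TrainedClassifier, feature_importance
from .stats import kde_norm

__all__ = ["kde_scatter", "pca_scatter", "importance_heatmap"]


def kde_scatter(events: pd.DataFrame, feature_x: str, feature_y: str,
                path: str | Path, levels: tuple[float, ...] = (0.5, 0.95)) -> None:
    """Scatter of two features coloured by max-normalized kernel density,
    with contour outlines at the requested normalized levels."""
    dens, contours = kde_norm(events, feature_x, feature_y, levels=levels)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    pts = events[[feature_x, feature_y]].to_numpy(dtype=float)
    ok = np.isfinite(pts).all(axis=1)
    ax.scatter(pts[ok, 0], pts[ok, 1], c=dens, s=4, cmap="viridis", lw=0)
    for level, polys in contours.items():
        for poly in polys:
            ax.plot(poly[:, 0], poly[:, 1], color="k",
                    lw=1.5 if level >= 0.9 else 0.8)
    ax.set_xlabel(feature_x)
    ax.set_ylabel(feature_y)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(model: TrainedClassifier, matrix: pd.DataFrame,
                labels: list[str], path: str | Path,
                blind: list[Prediction] | None = None) -> None:
    """Training samples in PC space with the logistic decision regions;
    blind predictions drawn as crosses."""
    scores = model.project(matrix.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(4.5, 4))
    pc1 = np.linspace(scores[:, 0].min() - 0.5, scores[:, 0].max() + 0.5, 200)
    pc2 = np.linspace(scores[:, 1].min() - 0.5, scores[:, 1].max() + 0.5, 200)
    xx, yy = np.meshgrid(pc1, pc2)
    logit = xx * model.lr_coef[0] + yy * model.lr_coef[1] + model.lr_intercept
    ax.contourf(xx, yy, logit >= 0, levels=[-0.5, 0.5, 1.5],
                colors=["#d5c6e8", "#cde8c6"], alpha=0.6)
    colors = {"disease": "#2d8f2d", "healthy": "#7b4fa6"}
    for lbl in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lbl]
        ax.scatter(scores[idx, 0], scores[idx, 1], s=30,
                   color=colors.get(lbl, "gray"), label=lbl, zorder=3)
    if blind:
        ax.scatter([p.pc1 for p in blind], [p.pc2 for p in blind],
                   marker="x", s=60, color="k", label="blind", zorder=4)
    ev = model.explained_variance_ratio * 100
    ax.set_xlabel(f"PC1 ({ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def importance_heatmap(model: TrainedClassifier, path: str | Path) -> None:
    """Colour-coded |loading| of every parameter on PC1 and PC2."""
    imp = feature_importance(model)
    fig, ax = plt.subplots(figsize=(4, max(2.5, 0.18 * len(imp))))
    im = ax.imshow(imp.to_numpy(), aspect="auto", cmap="magma", vmin=0, vmax=1)
    ax.set_xticks([0, 1], labels=imp.columns)
    ax.set_yticks(range(len(imp)), labels=imp.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="|loading| (normalized)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
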