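"""Derived wing metrics and a size-normalised wing ecomorphospace.

Wing loading (weight over area) and aspect ratio (span squared over area)
summarise how a flyer's planform trades speed against glide efficiency.
Projecting log-transformed (mass, span, area) records through a principal
component analysis separates overall size (component 1, on which all three
variables load with the same sign) from shape (the remaining components),
giving a morphospace in which pterosaur reconstructions can be compared with
modern soaring birds.  Region membership in that space — "does this planform
fall inside the albatross hull?" — is a plain point-in-convex-polygon test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .flight_performance import Planform

__all__ = [
    "WingMetrics",
    "EcomorphPoint",
    "wing_metrics",
    "ecomorph_pca",
    "region_membership",
    "plot_ecomorphospace",
]


@dataclass(frozen=True)
class WingMetrics:
    weight: float        # N
    aspect_ratio: float  # dimensionless
    wing_loading: float  # N/m^2


@dataclass(frozen=True)
class EcomorphPoint:
    label: str
    scores: tuple[float, ...]
    group: str | None = None


def wing_metrics(planform: Planform, g: float = 9.81) -> WingMetrics:
    """Weight (N), aspect ratio b^2/S and wing loading W/S for one planform."""
    return WingMetrics(
        weight=planform.weight(g),
        aspect_ratio=planform.aspect_ratio,
        wing_loading=planform.wing_loading(g),
    )


def ecomorph_pca(
    table: pd.DataFrame,
    n_components: int = 3,
    labels: str | None = "label",
    group: str | None = None,
) -> tuple[list[EcomorphPoint], np.ndarray, np.ndarray]:
    """PCA of log10(mass, span, area) wing records.

    Returns (points, loadings, explained_variance).  Component 1 is forced
    to be the size axis: its loadings are sign-fixed to be positive, so that
    larger animals score higher; components 2+ are shape axes.  Scores are
    invariant to record order and, because the transform is logarithmic, to
    any uniform rescaling of measurement units (a pure translation in log
    space removed by centring).
    """
    required = ["mass", "span", "area"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(table) < 3:
        raise ValueError("need at least 3 records for a PCA")
    X = table[required].to_numpy(dtype=float)
    if not np.all(X > 0):
        raise ValueError("mass, span and area must all be positive")
    logX = np.log10(X)
    centred = logX - logX.mean(axis=0)
    # SVD of the centred matrix: rows of Vt are the principal axes
    _, svals, Vt = np.linalg.svd(centred, full_matrices=False)
    n_components = min(n_components, Vt.shape[0])
    loadings = Vt[:n_components]
    # deterministic sign: make each component's largest-magnitude loading
    # positive, so the size axis has all-positive loadings
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = centred @ loadings.T
    explained = svals[:n_components] ** 2 / max(len(table) - 1, 1)
    if labels and labels in table.columns:
        names = table[labels].astype(str).tolist()
    else:
        names = [str(i) for i in range(len(table))]
    groups = (
        table[group].astype(str).tolist()
        if group and group in table.columns
        else [None] * len(table)
    )
    points = [
        EcomorphPoint(label=n, scores=tuple(s), group=g)
        for n, s, g in zip(names, scores, groups)
    ]
    return points, loadings, explained


def region_membership(point: EcomorphPoint | tuple, hull) -> bool:
    """Is a score point inside (or on the boundary of) a convex hull region?

    hull is a sequence of (x, y) vertices; the test uses the first two score
    coordinates.  Boundary points count as inside.
    """
    vertices = list(hull)
    if len(vertices) < 3:
        raise ValueError("hull needs at least 3 vertices")
    poly = Polygon(vertices)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("degenerate hull")
    coords = point.scores[:2] if isinstance(point, EcomorphPoint) else tuple(point)[:2]
    return bool(poly.covers(Point(*coords)))


def plot_ecomorphospace(points, hulls=None, path=None, components=(1, 2)):
    """Optional static scatter of shape-axis scores; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = components
    fig, ax = plt.subplots(figsize=(6, 5))
    for p in points:
        ax.scatter(p.scores[i], p.scores[j], s=20)
        ax.annotate(p.label, (p.scores[i], p.scores[j]), fontsize=7)
    for name, hull in (hulls or {}).items():
        xs, ys = zip(*list(hull) + [hull[0]])
        ax.plot(xs, ys, "--", label=name)
    ax.set_xlabel(f"PC{i + 1}")
    ax.set_ylabel(f"PC{j + 1}")
    if hulls:
        ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
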