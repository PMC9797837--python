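"""Bottleneck latent extraction and class-separability quantification.

The encoder's 4-unit bottleneck gives a low-dimensional latent
representation of every window.  Class separability in that space is
quantified with the mean silhouette coefficient (Euclidean metric) and
visualized as a grid of all C(4,2)=6 dimension-pair scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .models import BackboneModel, CalibratorModel, forward

__all__ = [
    "LatentEmbedding",
    "extract_bottleneck",
    "separability_score",
    "pairwise_latent_plot",
]


@dataclass
class LatentEmbedding:
    """N x d bottleneck activations with their gesture labels."""

    vectors: np.ndarray
    labels: np.ndarray
    scheme: str = ""

    def validate(self, dim: int | None = None) -> None:
        if self.vectors.ndim != 2:
            raise ValueError("embedding must be 2-D")
        if dim is not None and self.vectors.shape[1] != dim:
            raise ValueError(f"embedding width {self.vectors.shape[1]} != {dim}")
        if len(self.labels) != self.vectors.shape[0]:
            raise ValueError("labels/vectors length mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors,
                          columns=[f"z{i + 1}" for i in range(self.vectors.shape[1])])
        df["label"] = self.labels
        return df


def extract_bottleneck(
    backbone: BackboneModel,
    calibrator: CalibratorModel | None,
    windows,
    labels=None,
    scheme: str = "",
    batch: int = 512,
) -> LatentEmbedding:
    """One bottleneck vector per window, order-preserving, inference mode.

    ``windows`` is either an (N, 8, 24) array with ``labels`` given
    separately, or a list of :class:`~emgrecal.dataset.Window` objects.
    """
    if hasattr(windows, "ndim"):
        x = np.asarray(windows, dtype=np.float32)
        labs = np.asarray(labels if labels is not None else [""] * x.shape[0])
    else:
        x = np.stack([w.values for w in windows]).astype(np.float32)
        labs = np.array([w.label for w in windows])
    vecs = []
    for s in range(0, x.shape[0], batch):
        _, bott = forward(backbone, calibrator, x[s:s + batch])
        vecs.append(bott)
    emb = LatentEmbedding(
        vectors=np.concatenate(vecs) if vecs else np.zeros((0, backbone.config.bottleneck_dim)),
        labels=labs,
        scheme=scheme,
    )
    emb.validate(backbone.config.bottleneck_dim)
    return emb


def separability_score(embedding: LatentEmbedding) -> float:
    """Mean silhouette coefficient of the embedding, in [-1, 1]."""
    embedding.validate()
    labs = np.asarray(embedding.labels)
    uniq, counts = np.unique(labs, return_counts=True)
    if uniq.size < 2:
        raise ValueError("undefined separability: need >= 2 classes")
    if counts.min() < 2:
        raise ValueError("undefined separability: need >= 2 points per class")
    return float(silhouette_score(embedding.vectors, labs, metric="euclidean"))


def pairwise_latent_plot(embedding: LatentEmbedding, path) -> Path:
    """Scatter grid of all latent dimension pairs, colored by class."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    embedding.validate()
    n = embedding.vectors.shape[0]
    if n == 0:
        raise ValueError("empty embedding: nothing to plot")
    d = embedding.vectors.shape[1]
    pairs = list(combinations(range(d), 2))
    ncols = 3
    nrows = int(np.ceil(len(pairs) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.2 * nrows))
    axes = np.atleast_1d(axes).ravel()
    labs = np.asarray(embedding.labels)
    uniq = np.unique(labs)
    cmap = plt.colormaps["tab20"]
    for ax, (i, j) in zip(axes, pairs):
        for ci, lab in enumerate(uniq):
            m = labs == lab
            ax.scatter(embedding.vectors[m, i], embedding.vectors[m, j],
                       s=4, alpha=0.6, color=cmap(ci % 20), label=str(lab))
        ax.set_xlabel(f"z{i + 1}")
        ax.set_ylabel(f"z{j + 1}")
    for ax in axes[len(pairs):]:
        ax.axis("off")
    if uniq.size <= 20:
        axes[0].legend(fontsize=6, markerscale=2, loc="best")
    fig.suptitle(f"Bottleneck latent dimensions ({embedding.scheme})")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
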