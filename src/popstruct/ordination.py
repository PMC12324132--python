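"""Principal Coordinate Analysis (classical metric scaling).

Gower double-centering of -0.5 * D^2 followed by eigendecomposition;
coordinates are eigenvectors scaled by the square root of their
(positive) eigenvalues, so Euclidean-embeddable distance matrices are
reproduced exactly.  Negative eigenvalues (non-Euclidean input) are
reported but their axes are dropped; no Cailliez/Lingoes correction is
applied.  Percent variance explained is taken over the positive
eigenvalues only.  Each axis is oriented so that its largest-magnitude
loading is positive, making the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import InputError, LabelledSymmetricMatrix, logger


@dataclass
class PcoaResult:
    """Coordinates (populations x axes), eigenvalues, % variance explained."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray           # all eigenvalues, descending (incl. negative)
    proportion_explained: np.ndarray  # per retained axis, of the positive total

    @property
    def percent_explained(self) -> np.ndarray:
        return 100.0 * self.proportion_explained


def pcoa(
    distance_matrix: LabelledSymmetricMatrix | pd.DataFrame | np.ndarray,
    n_axes: int | None = None,
    labels: list[str] | None = None,
) -> PcoaResult:
    """Classical scaling of a symmetric, zero-diagonal distance matrix."""
    if isinstance(distance_matrix, LabelledSymmetricMatrix):
        labels = distance_matrix.labels
        d = distance_matrix.values
    elif isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        d = distance_matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        if labels is None:
            labels = [f"P{i + 1}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n):
        raise InputError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise InputError("distance matrix must be symmetric")
    if (np.diag(d) != 0).any():
        raise InputError("distance matrix must have a zero diagonal")
    if not np.isfinite(d).all():
        raise InputError("distance matrix contains non-finite entries")
    if (d < 0).any():
        raise InputError("distances must be nonnegative")

    # Gower centering: B = -1/2 J D^2 J with J = I - 11'/n
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d * d) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues; truncating", n_axes, n_pos)
        n_axes = n_pos

    coords = eigvecs[:, :n_axes] * np.sqrt(np.maximum(eigvals[:n_axes], 0.0))
    # deterministic sign: largest-|loading| entry of each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    pos_total = eigvals[eigvals > tol].sum()
    prop = eigvals[:n_axes] / pos_total if pos_total > 0 else np.zeros(n_axes)

    cframe = pd.DataFrame(
        coords, index=pd.Index(labels, name="population"),
        columns=[f"Axis{k + 1}" for k in range(n_axes)],
    )
    return PcoaResult(coordinates=cframe, eigenvalues=eigvals, proportion_explained=np.asarray(prop))


def scatter_png(result: PcoaResult, path, hue: dict[str, str] | None = None) -> None:
    """Optional 2-D ordination scatter (first two axes)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = result.coordinates
    if c.shape[1] < 2:
        raise InputError("need at least two axes to plot")
    fig, ax = plt.subplots(figsize=(6, 5))
    groups: dict[str, list[str]] = {}
    for lab in c.index:
        groups.setdefault(hue.get(lab, "") if hue else "", []).append(lab)
    for g, labs in groups.items():
        sub = c.loc[labs]
        ax.scatter(sub["Axis1"], sub["Axis2"], label=g or None, s=30)
        for lab in labs:
            ax.annotate(lab, (c.loc[lab, "Axis1"], c.loc[lab, "Axis2"]), fontsize=7)
    pct = result.percent_explained
    ax.set_xlabel(f"Axis 1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"Axis 2 ({pct[1]:.1f}%)")
    if hue:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
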