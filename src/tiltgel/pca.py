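"""Principal component analysis of smoothed migration profiles.

Profiles share one unit (molecule counts), so columns are mean-centered
but not variance-scaled: the first component then captures the overall
phosphorylation level, and later components capture migration regions
whose counts co-vary across cells.  The decomposition is a plain SVD of
the centered matrix with a fixed sign convention (the largest-magnitude
loading entry of each component is positive), so results are identical
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ParameterError
from .profiles import ProfileMatrix

__all__ = ["PCAResult", "run_pca", "loading_heatmap_table", "plot_scores", "plot_loading_heatmap"]


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of profile PCA."""

    scores: np.ndarray          # samples x components
    loadings: np.ndarray        # components x bins, unit-norm rows
    explained_variance_ratio: np.ndarray
    bin_centers_um: np.ndarray
    lane_ids: list[str]
    condition_labels: list[str]

    @property
    def component_count(self) -> int:
        return self.scores.shape[1]


def run_pca(matrix: ProfileMatrix, n_components: int = 3) -> PCAResult:
    """PCA of a samples x bins profile matrix.

    Columns are mean-centered (no variance scaling) and decomposed by
    SVD; scores are the centered data projected on the loadings.
    Identical samples therefore map to all-zero scores.
    """
    X = np.asarray(matrix.values, dtype=np.float64)
    n_samples, n_bins = X.shape
    if n_samples < 2:
        raise ParameterError("PCA needs at least 2 samples")
    max_comp = min(n_samples - 1, n_bins)
    if n_components > max_comp:
        raise ParameterError(
            f"n_components={n_components} exceeds min(samples-1, bins)={max_comp}"
        )
    centered = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float((s**2).sum())
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    scores = u * s
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            scores[:, k] = -scores[:, k]
    return PCAResult(
        scores=scores[:, :n_components],
        loadings=vt[:n_components],
        explained_variance_ratio=evr[:n_components],
        bin_centers_um=np.asarray(matrix.bin_centers_um, dtype=float),
        lane_ids=list(matrix.lane_ids),
        condition_labels=list(matrix.condition_labels)
        if matrix.condition_labels
        else [""] * n_samples,
    )


def loading_heatmap_table(result: PCAResult) -> pd.DataFrame:
    """Long-format loadings: one row per (component, migration bin).

    Weights are the loadings, untransformed — the table behind the
    per-migration-position heatmap.
    """
    comps, bins = result.loadings.shape
    return pd.DataFrame(
        {
            "component": np.repeat(np.arange(1, comps + 1), bins),
            "bin_center_um": np.tile(result.bin_centers_um, comps),
            "weight": result.loadings.reshape(-1),
        }
    )


def plot_scores(result: PCAResult, components: tuple[int, int] = (1, 2), ax=None):
    """Score scatter for a pair of components, colored by condition."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    i, j = components[0] - 1, components[1] - 1
    labels = result.condition_labels
    for label in sorted(set(labels)):
        mask = np.array([lab == label for lab in labels])
        ax.scatter(result.scores[mask, i], result.scores[mask, j], label=label or "sample")
    ax.set_xlabel(f"PC{components[0]} ({result.explained_variance_ratio[i]:.0%})")
    ax.set_ylabel(f"PC{components[1]} ({result.explained_variance_ratio[j]:.0%})")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_loading_heatmap(result: PCAResult, ax=None):
    """Heatmap of loading weights per migration position and component."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2))
    vmax = np.abs(result.loadings).max() or 1.0
    im = ax.imshow(
        result.loadings,
        aspect="auto",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        extent=[
            result.bin_centers_um[0],
            result.bin_centers_um[-1],
            result.component_count + 0.5,
            0.5,
        ],
    )
    ax.set_xlabel("migration distance (um)")
    ax.set_ylabel("component")
    ax.figure.colorbar(im, ax=ax, label="loading")
    return ax
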