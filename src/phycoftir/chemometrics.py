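"""PCA of spectrum collections and seasonal group separation.

Spectra conditioned to a common analysis window are decomposed by
mean-centered PCA (no per-wavenumber scaling, the convention for spectral
data). Group separation that published work argues from score plots is
quantified here as the mean silhouette coefficient on the leading score
dimensions, so a visual claim ("the samples group by season") becomes a
scalar with a testable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .errors import ContractError
from .preprocess import PreprocessConfig, condition, resolve_window
from .spectra_io import SpectrumSet


@dataclass(frozen=True)
class PCAModel:
    mean_trace: np.ndarray
    loadings: np.ndarray          # components x grid
    scores: np.ndarray            # samples x components
    explained_pct: np.ndarray
    window: tuple[float, float]
    sample_ids: tuple[str, ...]
    grid: np.ndarray | None = None

    def reconstruct(self) -> np.ndarray:
        """Centered-data reconstruction from all fitted components."""
        return self.scores @ self.loadings

    def project(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.mean_trace) @ self.loadings.T


def _canonicalize_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-|loading| element is positive."""
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0


def pca_fit(sset: SpectrumSet, window: str | tuple[float, float],
            n_components: int = 2,
            preprocess: PreprocessConfig | None = None) -> PCAModel:
    """Mean-centered PCA of a spectrum collection over *window*.

    Every member is conditioned with *preprocess* (crop to the window,
    baseline, normalization) and must end up on one common grid. The sign
    of each component is canonicalized so results are deterministic and
    independent of sample order.
    """
    if len(sset) < 3:
        raise ContractError("pca_fit needs at least 3 spectra")
    lo, hi = resolve_window(window)
    cfg = preprocess or PreprocessConfig()
    cfg = PreprocessConfig(window=(lo, hi), baseline_method=cfg.baseline_method,
                           als_lambda=cfg.als_lambda, als_p=cfg.als_p,
                           als_niter=cfg.als_niter, normalization=cfg.normalization,
                           sg_window_points=cfg.sg_window_points,
                           sg_polyorder=cfg.sg_polyorder)
    conditioned = [condition(s, cfg) for s in sset]
    grid = conditioned[0].wavenumbers
    for s in conditioned[1:]:
        if len(s) != grid.size or not np.allclose(s.wavenumbers, grid, atol=1e-9):
            raise ContractError("spectra are not on a common grid within the window; "
                                "resample the set first")
    X = np.vstack([s.absorbance for s in conditioned])
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_rank:
        raise ContractError(f"n_components must be in 1..{max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    _canonicalize_signs(loadings, scores)
    return PCAModel(
        mean_trace=pca.mean_,
        loadings=loadings,
        scores=scores,
        explained_pct=100.0 * pca.explained_variance_ratio_,
        window=(lo, hi),
        sample_ids=tuple(s.meta.sample_id for s in sset),
        grid=grid,
    )


@dataclass(frozen=True)
class GroupSeparation:
    labels: tuple[str, ...]
    mean_silhouette: float
    per_group_silhouette: Mapping[str, float]
    singleton_groups: tuple[str, ...] = ()


def season_separation(model: PCAModel, labels: Sequence[str],
                      n_components_used: int = 2) -> GroupSeparation:
    """Silhouette of labeled groups in leading-score space.

    Distances are Euclidean on the first ``n_components_used`` score
    columns. A group with a single member gets silhouette 0 and is flagged
    in ``singleton_groups``.
    """
    labels = tuple(str(l) for l in labels)
    if len(labels) != model.scores.shape[0]:
        raise ContractError("labels must align with model.sample_ids")
    if not 1 <= n_components_used <= model.scores.shape[1]:
        raise ContractError("n_components_used exceeds fitted components")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ContractError("need at least 2 distinct groups")
    X = model.scores[:, :n_components_used]
    arr = np.asarray(labels)
    sil = silhouette_samples(X, arr)
    # sklearn already assigns 0 to singleton clusters; just flag them
    singletons = tuple(u for u in uniq if np.sum(arr == u) == 1)
    per_group = {u: float(sil[arr == u].mean()) for u in uniq}
    return GroupSeparation(labels=labels, mean_silhouette=float(sil.mean()),
                           per_group_silhouette=per_group,
                           singleton_groups=singletons)


def plot_scores(model: PCAModel, labels: Sequence[str] | None, path: str) -> None:
    """PC-1 vs PC-2 score plot colored by label (spectroscopy-style figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = list(labels) if labels is not None else ["all"] * len(model.sample_ids)
    pc2 = (model.scores[:, 1] if model.scores.shape[1] > 1
           else np.zeros(model.scores.shape[0]))
    for lab in sorted(set(labels)):
        mask = np.array([l == lab for l in labels])
        ax.scatter(model.scores[mask, 0], pc2[mask], label=str(lab), s=40)
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.axvline(0.0, color="0.8", lw=0.8)
    ax.set_xlabel(f"PC-1 ({model.explained_pct[0]:.1f}%)")
    if model.scores.shape[1] > 1:
        ax.set_ylabel(f"PC-2 ({model.explained_pct[1]:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
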