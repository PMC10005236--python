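"""PCA and UPGMA clustering on second-derivative fingerprint spectra.

Samples are compared in the fingerprint region (800-1800 cm^-1, paraffin
window 1350-1500 cm^-1 excised) after a Savitzky-Golay second derivative,
which sharpens overlapping bands and suppresses residual baseline.
Distances are Euclidean; hierarchical clustering uses average linkage
(UPGMA).  Columns are mean-centered for PCA but never variance-scaled:
all columns share absorbance units, and scaling would inflate flat
spectral regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .preprocess import PreprocessConfig, savgol_derivative
from .spectra import (
    FINGERPRINT,
    PARAFFIN_WINDOW,
    Region,
    SpectrumSet,
    SpectrumError,
    excise_regions,
)


@dataclass
class FeatureMatrix:
    values: np.ndarray        # samples x wavenumbers
    wavenumbers: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise SpectrumError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise SpectrumError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.wavenumbers)


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray   # scipy 4-column merge format
    sample_ids: np.ndarray
    groups: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.linkage_matrix.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return leaves_list(self.linkage_matrix)

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance vector."""
        return cophenet(self.linkage_matrix)


def build_feature_matrix(
    spectrum_set: SpectrumSet,
    config: PreprocessConfig = PreprocessConfig(),
    fingerprint: Region = FINGERPRINT,
    excise: Region | None = PARAFFIN_WINDOW,
) -> FeatureMatrix:
    """Per-sample second-derivative vectors on the excised fingerprint grid."""
    if len(spectrum_set) == 0:
        raise SpectrumError("empty spectrum set")
    rows = []
    wavenumbers = None
    for s in spectrum_set:
        fp = s.slice(fingerprint)
        d2 = savgol_derivative(fp, config, order=2)
        if excise is not None:
            d2 = excise_regions(d2, [excise])
        rows.append(d2.absorbance)
        wavenumbers = d2.wavenumbers
    return FeatureMatrix(
        values=np.vstack(rows),
        wavenumbers=wavenumbers,
        sample_ids=spectrum_set.sample_ids,
        groups=spectrum_set.groups,
    )


def pca(matrix: FeatureMatrix, n_components: int = 2):
    """Mean-centered PCA (no variance scaling).

    Returns ``(scores, loadings, explained_variance_fractions)`` where
    ``scores @ loadings + column_means`` reconstructs the data when all
    components are kept.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise SpectrumError("PCA needs at least 2 samples")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_comp:
        raise SpectrumError(
            f"n_components must be in [1, {max_comp}] for a {X.shape} matrix"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.components_, model.explained_variance_ratio_


def hca_upgma(matrix: FeatureMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) merge tree over pairwise Euclidean distances."""
    if matrix.n_samples < 2:
        raise SpectrumError("clustering needs at least 2 samples")
    Z = linkage(pdist(matrix.values, metric="euclidean"), method="average")
    return Dendrogram(Z, matrix.sample_ids, matrix.groups)


def cut_k(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Flat cluster labels from cutting the tree into exactly k clusters."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise SpectrumError(f"k must be in [1, {n}]")
    labels = fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise SpectrumError(
            f"cannot cut into exactly {k} clusters: tied merge heights collapse "
            f"to {len(np.unique(labels))} clusters"
        )
    return labels


def flag_outliers(dendrogram: Dendrogram) -> list[str]:
    """Samples whose first merge height is extreme (median + 3 IQR rule).

    A leaf joining the rest of the tree far above the bulk of the merge
    heights is spectrally isolated; it is flagged, not removed.
    """
    if dendrogram.n_leaves < 4:
        raise SpectrumError("outlier screening needs at least 4 leaves")
    Z = dendrogram.linkage_matrix
    n = dendrogram.n_leaves
    heights = Z[:, 2]
    q1, med, q3 = np.percentile(heights, [25, 50, 75])
    cutoff = med + 3.0 * (q3 - q1)
    flagged = []
    for leaf in range(n):
        # height of the first merge involving this leaf
        rows = np.nonzero((Z[:, 0] == leaf) | (Z[:, 1] == leaf))[0]
        first = heights[rows[0]] if rows.size else heights[-1]
        if first > cutoff:
            flagged.append(str(dendrogram.sample_ids[leaf]))
    return flagged


def cluster_purity(labels: np.ndarray, groups: np.ndarray):
    """Purity = sum over clusters of the majority-group count, over n.

    Returns ``(purity, contingency)`` with the contingency table as a
    clusters x groups DataFrame.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise SpectrumError("labels and groups must have equal length")
    table = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(groups, name="group"))
    purity = float(table.max(axis=1).sum() / len(labels))
    return purity, table


def merge_groups(groups: np.ndarray, merges: dict[str, str]) -> np.ndarray:
    """Relabel groups (e.g. classic+anaplastic -> one class) for purity checks."""
    return np.array([merges.get(g, g) for g in np.asarray(groups)])
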