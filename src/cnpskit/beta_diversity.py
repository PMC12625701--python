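"""Bray-Curtis distances and ordination of element-specific KO profiles.

Beta-diversity runs on the KO-level submatrix of one element's cycle KOs (the
raw, upstream-TPM-normalized abundances; an optional per-sample relative
toggle is exposed).  Ordination methods: classical PCoA (double-centering +
eigendecomposition, negative eigenvalues reported and dropped), PCA on
centered features, and non-metric MDS (NMDS) with Kruskal stress-1 over
multiple seeded random starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .ontology import CycleMapping, element_ko_order
from .table_io import KOTable


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    method: str  # PCoA | PCA | NMDS
    coordinates: pd.DataFrame  # sample x axis
    explained: Optional[np.ndarray] = None  # per-axis proportion (PCoA/PCA)
    stress: Optional[float] = None  # NMDS only
    seed: Optional[int] = None  # NMDS only
    negative_eigenvalues: Optional[np.ndarray] = None  # PCoA only


def element_ko_matrix(ko: KOTable, mapping: CycleMapping, element: str) -> pd.DataFrame:
    """KO x sample submatrix restricted to the element's cycle KOs.

    Rows keep the KO table's original order and are deduplicated even if the
    mapping lists a KO under two processes of the element.
    """
    wanted = set(element_ko_order(mapping, element))
    rows = [k for k in ko.ko_ids if k in wanted]
    if not rows:
        raise ValueError(f"no {element}-cycle KOs present in the KO table")
    return ko.values.loc[rows]


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    d(i, j) = sum|x_i - x_j| / sum(x_i + x_j); a pair of all-zero samples has
    an undefined ratio and is reported as 0 with a warning.
    """
    x = matrix.to_numpy(dtype=float).T  # samples as rows
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    totals = x.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        condensed = pdist(x, metric="braycurtis")
    if np.isnan(condensed).any():
        warnings.warn(
            "sample pairs with zero total abundance: distance set to 0", stacklevel=2
        )
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(sample_ids=list(matrix.columns), values=squareform(condensed))


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical metric MDS (principal coordinates) of a distance matrix.

    Gower double-centering of -d^2/2, eigendecomposition, axes ordered by
    decreasing eigenvalue.  Axes with non-positive eigenvalues are dropped;
    negative eigenvalues are reported untouched (no Cailliez/Lingoes
    correction).  explained = eigenvalue / sum of positive eigenvalues.
    """
    dm = d.values
    if np.isnan(dm).any():
        raise ValueError("distance matrix contains NaN")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals).max(), 1.0)
    positive = eigvals > tol
    negative = eigvals < -tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    explained = eigvals[positive] / eigvals[positive].sum() if positive.any() else np.array([])
    frame = pd.DataFrame(
        coords,
        index=d.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(
        method="PCoA",
        coordinates=frame,
        explained=explained,
        negative_eigenvalues=eigvals[negative],
    )


def pca(matrix: pd.DataFrame, n_components: Optional[int] = None) -> OrdinationResult:
    """PCA of samples (columns as observations); features centered, not scaled."""
    x = matrix.to_numpy(dtype=float).T
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    from sklearn.decomposition import PCA

    k = n_components or min(x.shape[0] - 1, x.shape[1])
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    frame = pd.DataFrame(
        scores,
        index=list(matrix.columns),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return OrdinationResult(
        method="PCA", coordinates=frame, explained=model.explained_variance_ratio_
    )


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS with Kruskal stress-1, best of ``n_starts`` seeded starts."""
    n = len(d.sample_ids)
    if n <= k + 1:
        raise ValueError(f"NMDS in {k} dimensions needs at least {k + 2} samples")
    from sklearn.manifold import MDS

    kwargs = dict(
        n_components=k,
        n_init=n_starts,
        max_iter=max_iter,
        eps=tol,
        normalized_stress=True,
        random_state=seed,
    )
    try:
        model = MDS(metric_mds=False, metric="precomputed", init="random", **kwargs)
    except TypeError:  # older scikit-learn API
        model = MDS(metric=False, dissimilarity="precomputed", **kwargs)
    coords = model.fit_transform(d.values)
    coords = coords - coords.mean(axis=0)
    frame = pd.DataFrame(
        coords,
        index=d.sample_ids,
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return OrdinationResult(
        method="NMDS", coordinates=frame, stress=float(model.stress_), seed=seed
    )
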