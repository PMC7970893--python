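"""Panel structure: dosage PCA and K-means with a BIC scan over K.

The BIC used is the Gaussian-spherical approximation common in genetic
cluster scans: BIC(K) = n d log(WSS / (n d)) + K d log(n), with n
individuals, d dimensions and WSS the within-cluster sum of squares of the
best of ``n_init`` K-means fits. The selected K is the elbow of the BIC
curve (maximum second difference); the minimum-BIC K is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .panel_io import GenotypeMatrix

_WSS_FLOOR = 1e-12


@dataclass
class PcaResult:
    scores: np.ndarray  # individuals x components
    explained_variance_fraction: np.ndarray
    individual_ids: list[str]
    centered: bool = True
    scaled: bool = False
    mean_filled_missing: bool = False

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.individual_ids, columns=cols)


def pca_dosage(gm: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of the column-centered dosage matrix via SVD.

    Missing cells, if any, are filled with the marker mean (logged on the
    result); explained fraction per component is the squared singular value
    over the total.
    """
    if gm.n_individuals < 2:
        raise ValueError("PCA requires at least 2 individuals")
    X = gm.dosage.copy()
    filled = False
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
        filled = True
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    scores = U * s
    if n_components is not None:
        scores = scores[:, :n_components]
        frac = frac[:n_components]
    return PcaResult(scores, frac, list(gm.individual_ids), mean_filled_missing=filled)


@dataclass
class ClusterScan:
    k_values: list[int]
    bic: list[float]
    wss: list[float]
    assignments: dict[int, np.ndarray]
    selected_k: int  # elbow (max second difference)
    min_bic_k: int

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k_values, "WSS": self.wss, "BIC": self.bic})


def kmeans_bic_scan(
    data: np.ndarray | GenotypeMatrix,
    k_min: int = 1,
    k_max: int = 10,
    n_init: int = 10,
    seed: int | None = None,
    n_pcs: int | None = 50,
) -> ClusterScan:
    """K-means over a range of K with BIC model selection.

    ``data`` is either a score/feature matrix or a GenotypeMatrix; in the
    latter case clustering runs on the top ``n_pcs`` principal-component
    scores (pass n_pcs=None for raw dosages, mean-filled).
    """
    if isinstance(data, GenotypeMatrix):
        if n_pcs is not None:
            data = pca_dosage(data, n_components=min(n_pcs, data.n_individuals - 1)).scores
        else:
            X = data.dosage.copy()
            if np.isnan(X).any():
                col_mean = np.nan_to_num(np.nanmean(X, axis=0), nan=0.0)
                r, c = np.where(np.isnan(X))
                X[r, c] = col_mean[c]
            data = X
    X = np.asarray(data, dtype=float)
    n, d = X.shape
    if n < k_max:
        raise ValueError(f"need at least k_max={k_max} rows, got {n}")
    ks, bics, wsss = [], [], []
    assignments: dict[int, np.ndarray] = {}
    for K in range(k_min, k_max + 1):
        if K == 1:
            centroid = X.mean(axis=0)
            wss = float(((X - centroid) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
            labels = km.fit_predict(X)
            wss = float(km.inertia_)
        wss_f = max(wss, _WSS_FLOOR)  # guard the degenerate WSS=0 fit
        bic = n * d * np.log(wss_f / (n * d)) + K * d * np.log(n)
        ks.append(K)
        wsss.append(wss)
        bics.append(float(bic))
        assignments[K] = labels
    bic_arr = np.asarray(bics)
    if len(ks) >= 3:
        second_diff = bic_arr[:-2] - 2 * bic_arr[1:-1] + bic_arr[2:]
        selected = ks[1 + int(np.argmax(second_diff))]
    else:
        selected = ks[int(np.argmin(bic_arr))]
    min_bic_k = ks[int(np.argmin(bic_arr))]
    return ClusterScan(ks, bics, wsss, assignments, selected, min_bic_k)
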