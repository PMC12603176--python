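"""Principal component analysis of the (optionally subset) panel.

Columns are centered and scaled to unit variance before the decomposition,
so every metabolite contributes equally regardless of its concentration
scale.  Component signs are fixed by the convention that the
largest-magnitude loading of each component is positive, making scores
reproducible across runs and platforms.  Typical use: compare breed
separation before and after metabolite selection via PC1/PC2 scores and
explained-variance fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components (orthonormal columns)
    explained_variance_frac: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(
    matrix: pd.DataFrame,
    metabolite_subset=None,
    n_components: int | None = None,
) -> PCAResult:
    """PCA on unit-variance-scaled columns of ``matrix``.

    NA-bearing and zero-variance metabolites are dropped with a warning
    before scaling.  With ``n_components=None`` all ``min(n-1, m)``
    components are kept, in which case the explained fractions sum to 1
    and scores x loadingsᵀ reconstructs the scaled matrix.
    """
    frame = matrix if metabolite_subset is None else matrix[list(metabolite_subset)]
    if frame.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    na_cols = frame.columns[frame.isna().any()]
    if len(na_cols):
        warnings.warn(f"dropping {len(na_cols)} NA-bearing metabolite(s) before PCA")
        frame = frame.drop(columns=na_cols)
    sd = frame.std(ddof=1)
    flat = sd.index[sd == 0]
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-variance metabolite(s) before PCA")
        frame = frame.drop(columns=flat)
        sd = sd.drop(flat)
    if frame.shape[1] < 1:
        raise ValueError("no usable metabolites remain for PCA")

    scaled = (frame - frame.mean()) / sd
    max_rank = min(frame.shape[0] - 1, frame.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(scaled.to_numpy())
    loadings = pca.components_.T  # metabolites x components

    # sign convention: largest-|loading| entry of each component positive
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1

    # fractions relative to total variance of the scaled data (ddof=1)
    total_var = float(scaled.var(ddof=1).sum())
    frac = pca.explained_variance_ / total_var
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=frame.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=frame.columns, columns=comp_names),
        explained_variance_frac=frac,
    )
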