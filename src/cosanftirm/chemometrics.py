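"""Region-wise principal component analysis of preprocessed spectra.

PCA is fit on mean-centered data (no variance scaling — spectra arrive
normalized from the preprocessing chain) via singular value
decomposition.  The sign of each loading is fixed deterministically by
making its largest-magnitude element positive, so scores and loadings
are reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import apply_recipe
from .spectra import Region, SpectrumSet, extract_region

__all__ = ["PCAResult", "run_pca"]


@dataclass
class PCAResult:
    scores: np.ndarray        # (n_spectra, k)
    loadings: np.ndarray      # (k, n_wavenumbers), rows orthonormal
    explained: np.ndarray     # k fractions of total variance, non-increasing
    mean: np.ndarray          # column means removed before the SVD
    wavenumbers: np.ndarray
    region: Region
    recipe: str

    def reconstruct(self) -> np.ndarray:
        """Data approximation from the retained components plus the mean."""
        return self.scores @ self.loadings + self.mean


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    for j in range(loadings.shape[0]):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0


def run_pca(sset: SpectrumSet, region: Region, recipe: str = "emsc_snv",
            k: int = 3) -> PCAResult:
    """Fit a k-component PCA on a spectral region after preprocessing.

    ``recipe`` is one of the documented chains (``emsc_snv`` for the
    fingerprint/lipids regions, ``emsc_d2_uvn`` for the DNA region, or
    ``raw``); preprocessing runs on the region-restricted set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sset) <= k:
        raise ValueError(f"need more spectra ({len(sset)}) than components ({k})")
    sub = extract_region(sset, region)
    prepped = apply_recipe(sub, recipe)
    X = prepped.absorbance
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float(np.sum(Xc ** 2))
    if total_var <= 1e-24:
        raise ValueError("degenerate set: all spectra identical after preprocessing")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k_eff = min(k, S.size)
    scores = U[:, :k_eff] * S[:k_eff]
    loadings = Vt[:k_eff].copy()
    _fix_signs(scores, loadings)
    explained = (S[:k_eff] ** 2) / total_var
    return PCAResult(scores=scores, loadings=loadings, explained=explained,
                     mean=mean, wavenumbers=prepped.wavenumbers,
                     region=region, recipe=recipe)
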