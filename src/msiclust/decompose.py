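"""PCA decomposition of an ion-image stack.

The stack is a pixels × images matrix: each ion image is one feature column
over pixels, so principal-component scores are themselves spatial images.
Columns are centered and scaled to unit variance (PCA on the correlation
structure); the eigensolver is the deterministic LAPACK SVD, with the sign
of each loading vector fixed by making its largest-magnitude entry positive,
so results are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "run_pca", "contribution"]


@dataclass
class PCAResult:
    """Loadings (images × components), score images (pixels × components),
    per-component variance contributions in %, and the parameter record.

    ``contributions`` is over the full eigenvalue spectrum (sums to 100
    across all possible components); only the first ``n_components`` columns
    of loadings/scores are retained.
    """

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray  # full spectrum, descending
    n_components: int
    scaling: str
    normalisation: str

    @property
    def contributions(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    def score_image(self, k: int, shape: tuple[int, int]) -> np.ndarray:
        """Score map of component ``k`` reshaped to (height, width)."""
        return self.scores[:, k].reshape(shape)


def run_pca(
    stack: np.ndarray,
    n_components: int = 5,
    scaling: str = "unit_variance",
    normalisation: str = "none",
) -> PCAResult:
    """PCA of a pixels × images matrix.

    Parameters mirror the standard MSI software settings: ``scaling``
    ``"unit_variance"`` (divide centered columns by their standard
    deviation) or ``"none"`` (centering only); ``normalisation`` is recorded
    but only ``"none"`` is implemented. A constant (zero-variance) image
    cannot be unit-variance scaled and raises an error naming the offending
    column.
    """
    X = np.asarray(stack, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("stack must be 2-D with at least 2 pixels and 2 images")
    if normalisation != "none":
        raise ValueError(f"unsupported normalisation {normalisation!r}")
    if scaling not in ("unit_variance", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    n_pixels, n_images = X.shape
    n_components = min(n_components, n_images, n_pixels - 1)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = X - X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=1)
        dead = np.nonzero(sd == 0)[0]
        if dead.size:
            raise ValueError(
                f"image column {dead[0]} has zero variance and cannot be scaled"
            )
        X = X / sd
    _u, s, vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / (n_pixels - 1)
    loadings = vt[:n_components].T
    # sign convention: largest-|entry| of each loading vector positive
    for k in range(n_components):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    scores = X @ loadings
    return PCAResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        n_components=n_components,
        scaling=scaling,
        normalisation=normalisation,
    )


def contribution(result: PCAResult, k: int) -> float:
    """Variance contribution of component ``k`` (0-based) in percent:
    eigenvalue_k / Σ eigenvalues × 100."""
    if not 0 <= k < result.n_components:
        raise ValueError(
            f"component index {k} out of range (n_components={result.n_components})"
        )
    return float(result.contributions[k])
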