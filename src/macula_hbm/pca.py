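"""Principal-component decomposition of cross-superpixel matrices.

The 49x49 posterior-mean covariance matrices (random intercepts, slopes,
log residual SDs, residuals) are eigendecomposed; eigenvalue fractions and
cumulative "scree" fractions summarize how much of the across-macula
variation each component explains, and eigenvectors reshaped to the 7x7
grid show the spatial pattern of each component.

The primary analysis decomposes covariance matrices; the correlation-matrix
variant (where the trace equals 49, so fractions are eigenvalues/49) is
selected via ``matrix_type="correlation"``.

Sign convention (decompositions have sign-ambiguous eigenvectors): each
eigenvector is flipped so its loading sum is nonnegative; on a zero sum the
largest-magnitude loading is made positive.  Deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .grid_io import GridMap
from .correlation import EffectCovariance

__all__ = ["PCDecomposition", "eigendecompose", "scree", "pc_gridmaps", "EffectPCA"]


@dataclass
class PCDecomposition:
    """Full eigendecomposition with variance-explained bookkeeping."""

    eigenvalues: np.ndarray  # descending, nonnegative
    eigenvectors: np.ndarray  # columns, orthonormal
    fractions: np.ndarray
    cumulative: np.ndarray
    matrix_type: str = "covariance"
    kind: str = ""


def _fix_signs(V: np.ndarray) -> np.ndarray:
    out = V.copy()
    for j in range(out.shape[1]):
        s = out[:, j].sum()
        if abs(s) < 1e-12:
            lead = np.argmax(np.abs(out[:, j]))
            if out[lead, j] < 0:
                out[:, j] = -out[:, j]
        elif s < 0:
            out[:, j] = -out[:, j]
    return out


def eigendecompose(
    matrix: np.ndarray, matrix_type: str = "covariance", kind: str = ""
) -> PCDecomposition:
    """Eigendecompose a symmetric PSD matrix (tiny negatives clamped to 0)."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    scale = max(1.0, np.abs(M).max())
    if np.abs(M - M.T).max() > 1e-8 * scale:
        raise ValueError("matrix must be symmetric")
    if matrix_type not in ("covariance", "correlation"):
        raise ValueError("matrix_type must be 'covariance' or 'correlation'")
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    trace = max(np.trace(M), np.finfo(float).tiny)
    if w.min() < -1e-6 * trace:
        raise ValueError(f"materially negative eigenvalue: {w.min():g}")
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1]
    w, V = w[order], _fix_signs(V[:, order])
    fractions = w / w.sum()
    return PCDecomposition(
        eigenvalues=w,
        eigenvectors=V,
        fractions=fractions,
        cumulative=np.cumsum(fractions),
        matrix_type=matrix_type,
        kind=kind,
    )


def scree(pc: PCDecomposition) -> list[tuple[int, float]]:
    """(rank, cumulative variance fraction) pairs; the last equals 1."""
    return [(r + 1, float(c)) for r, c in enumerate(pc.cumulative)]


def pc_gridmaps(pc: PCDecomposition, n: int, labels: list[str] | None = None) -> list[GridMap]:
    """First ``n`` eigenvectors as 7x7 grid maps, annotated with % variance."""
    from .grid_io import analysis_labels

    if n > pc.eigenvalues.size:
        raise ValueError("n exceeds the number of components")
    labels = labels or analysis_labels()
    if len(labels) != pc.eigenvectors.shape[0] or len(labels) != 49:
        raise ValueError("grid maps require the 49-superpixel grid")
    maps = []
    for m in range(n):
        name = f"{pc.kind + ' ' if pc.kind else ''}PC{m + 1} ({100 * pc.fractions[m]:.1f}%)"
        maps.append(
            GridMap.from_dict(dict(zip(labels, pc.eigenvectors[:, m])), name=name)
        )
    return maps


class EffectPCA(BaseEstimator):
    """Estimator wrapper: fit on a matrix or :class:`EffectCovariance`.

    Fitted attributes follow scikit-learn decomposition conventions
    (``components_`` rows are eigenvectors, ``explained_variance_ratio_``
    the eigenvalue fractions).
    """

    def __init__(self, matrix_type: str = "covariance") -> None:
        self.matrix_type = matrix_type

    def fit(self, X, y=None) -> "EffectPCA":
        if isinstance(X, EffectCovariance):
            matrix = (
                X.correlation if self.matrix_type == "correlation" else X.covariance
            )
            kind = X.kind
        else:
            matrix, kind = np.asarray(X), ""
        pc = eigendecompose(matrix, matrix_type=self.matrix_type, kind=kind)
        self.decomposition_ = pc
        self.eigenvalues_ = pc.eigenvalues
        self.components_ = pc.eigenvectors.T
        self.explained_variance_ratio_ = pc.fractions
        self.cumulative_ratio_ = pc.cumulative
        return self
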