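"""Model-independent rank analysis of temperature-series spectra.

Singular-value decomposition of the wavelength x temperature ellipticity
matrix counts the spectroscopically distinguishable species contributing to
the melting data, without committing to any mechanism.  Two rank criteria
are provided: a magnitude threshold on the singular values and a smoothness
(lag-1 autocorrelation) criterion on the temperature amplitudes; the
threshold criterion is the headline estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .observables import SpectraMatrix

__all__ = ["SVDResult", "svd_decompose", "estimate_rank"]

logger = logging.getLogger(__name__)


@dataclass
class SVDResult:
    singular_values: np.ndarray   # non-increasing, non-negative
    left_vectors: np.ndarray      # wavelength basis, columns
    right_vectors: np.ndarray     # temperature amplitudes, rows
    rank: int | None = None

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Reconstruction from the first k components (all if None)."""
        k = self.singular_values.size if k is None else k
        return (self.left_vectors[:, :k] * self.singular_values[:k]) @ self.right_vectors[:k]


def svd_decompose(spectra: SpectraMatrix | np.ndarray, center: bool = False) -> SVDResult:
    """Full SVD of the spectra matrix (raw by default, no mean-centering)."""
    m = spectra.values if isinstance(spectra, SpectraMatrix) else np.asarray(spectra, float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("spectra matrix must be 2-D with at least 3 temperature columns")
    if not np.any(m):
        raise ValueError("degenerate all-zero spectra matrix")
    if center:
        m = m - m.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    return SVDResult(singular_values=s, left_vectors=u, right_vectors=vt)


def _lag1_autocorr(v: np.ndarray) -> float:
    v = v - v.mean()
    denom = float(v @ v)
    if denom == 0.0:
        return 0.0
    return float(v[:-1] @ v[1:]) / denom


def estimate_rank(result: SVDResult, method: str = "threshold",
                  threshold_fraction: float = 0.05,
                  autocorr_cutoff: float = 0.8) -> int:
    """Number of significant components.

    ``threshold``: count singular values above ``threshold_fraction`` of the
    largest.  ``autocorrelation``: count components whose temperature
    amplitude has lag-1 autocorrelation above ``autocorr_cutoff`` (smooth
    amplitudes indicate signal, noise amplitudes decorrelate).
    """
    s = result.singular_values
    if method == "threshold":
        rank = int(np.sum(s > threshold_fraction * s[0]))
    elif method == "autocorrelation":
        rank = int(sum(_lag1_autocorr(result.right_vectors[i]) > autocorr_cutoff
                       for i in range(s.size)))
    else:
        raise ValueError(f"unknown rank method {method!r}")
    logger.info("estimated rank %d by %s criterion", rank, method)
    result.rank = rank
    return rank
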