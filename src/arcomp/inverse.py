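"""LORETA-style distributed inverse operator and source spectra.

The inverse operator T (sources x channels) maps common-average
referenced sensor data to source amplitude estimates. LORETA penalizes
the discrete spatial Laplacian of depth-weighted source amplitudes, so
the estimate is maximally smooth; with the Laplacian replaced by the
identity the operator reduces to weighted minimum norm.

Source cross-spectra are the Hermitian congruence T . CSD . T^H, and the
source amplitude spectrum is the square root of its diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .headmodel import LeadFieldModel
from .spectral import CrossSpectrumSet, SpectralTensor, StftTensor

logger = logging.getLogger(__name__)

__all__ = [
    "InverseOperator",
    "loreta_inverse",
    "source_amplitude_spectrum",
    "source_amplitude_spectrum_from_stft",
]


@dataclass
class InverseOperator:
    """Linear inverse T (sources x channels) with its regularization."""

    T: np.ndarray
    regularization: float
    method: str
    leadfield: LeadFieldModel

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if not np.all(np.isfinite(self.T)):
            raise ValueError("inverse operator contains non-finite values")
        if self.T.shape != (self.leadfield.n_sources, self.leadfield.n_channels):
            raise ValueError("inverse operator shape inconsistent with lead field")

    @property
    def n_sources(self) -> int:
        return self.T.shape[0]


def _graph_laplacian(leadfield: LeadFieldModel) -> np.ndarray:
    """Row-normalized graph Laplacian I - D^-1 A of the source grid."""
    n = leadfield.n_sources
    A = np.zeros((n, n))
    for i, j in leadfield.grid.adjacency_pairs:
        A[i, j] = 1.0
        A[j, i] = 1.0
    deg = A.sum(axis=1)
    return np.eye(n) - A / deg[:, None]


def loreta_inverse(
    leadfield: LeadFieldModel,
    alpha: float | None = None,
    method: str = "loreta",
    laplacian_ridge: float = 1e-4,
) -> InverseOperator:
    """Regularized distributed inverse operator.

    T = M K^T (K M K^T + alpha H)^+ with K the common-average gain,
    H the common-average projector, and the source-space metric M the
    inverse of the squared, depth-weighted graph Laplacian
    (M = (Omega L^T L Omega)^-1 with Omega = diag of gain column norms)
    for ``method="loreta"``, or M = Omega^-2 for
    ``method="minimum-norm"``.

    ``alpha=None`` selects the default 0.05 x mean eigenvalue of
    K M K^T. The Laplacian penalty is made invertible by a small ridge
    (``laplacian_ridge`` x mean diagonal of L^T L) that leaves the
    smoothness prior essentially unchanged.
    """
    K = leadfield.gain
    n_ch = leadfield.n_channels
    omega = np.linalg.norm(K, axis=0)
    if method == "loreta":
        L = _graph_laplacian(leadfield)
        P = L.T @ L
        P = P + laplacian_ridge * np.trace(P) / P.shape[0] * np.eye(P.shape[0])
        B = omega[:, None] * P * omega[None, :]
        M = np.linalg.inv(B)
    elif method == "minimum-norm":
        M = np.diag(1.0 / omega**2)
    else:
        raise ValueError(f"unknown method {method!r}")

    KM = K @ M
    KMKt = KM @ K.T
    if alpha is None:
        alpha = 0.05 * float(np.trace(KMKt)) / n_ch
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    H = np.eye(n_ch) - np.ones((n_ch, n_ch)) / n_ch
    G = KMKt + alpha * H
    # the common-average constraint makes the all-ones vector a structural
    # null direction, so a pseudo-inverse is always appropriate here
    rank = np.linalg.matrix_rank(G)
    if rank < n_ch - 1:
        logger.info("gram matrix rank %d < %d: pseudo-inverse regularizing", rank, n_ch - 1)
    T = M @ K.T @ np.linalg.pinv(G, hermitian=True)
    return InverseOperator(T=T, regularization=float(alpha), method=method, leadfield=leadfield)


def source_amplitude_spectrum(
    inverse: InverseOperator,
    csd: CrossSpectrumSet,
) -> SpectralTensor:
    """Source ASD: sqrt(diag(T . CSD . T^H)) per (frequency, window).

    Only the diagonal of the source cross-spectrum is formed
    (sum over channels of (T C) * conj(T), never the full
    n_sources x n_sources matrix).
    """
    if csd.n_channels != inverse.T.shape[1]:
        raise ValueError("channel count mismatch between inverse operator and CSD")
    T = inverse.T
    # diag(T C T^H)_s = sum_n (T C)_{s n} conj(T)_{s n}
    TC = np.einsum("sm,ftmn->ftsn", T, csd.values, optimize=True)
    diag = np.einsum("ftsn,sn->fts", TC, T.conj(), optimize=True)
    if np.abs(diag.imag).max(initial=0.0) > 1e-9 * max(np.abs(diag.real).max(initial=0.0), 1.0):
        raise ValueError("source cross-spectrum diagonal not real: inconsistent input")
    values = np.sqrt(np.clip(diag.real, 0.0, None))
    return SpectralTensor(
        values=np.transpose(values, (2, 0, 1)),
        freqs=csd.freqs.copy(),
        window_centers=csd.window_centers.copy(),
        space_kind="source",
        units="a.u./sqrt(Hz)",
    )


def source_amplitude_spectrum_from_stft(
    inverse: InverseOperator,
    stft_tensor: StftTensor,
) -> SpectralTensor:
    """Source ASD computed from the STFT without materializing CSDs.

    Because CSD_{f,t} = norm * phi phi^H is rank one,
    diag(T CSD T^H) = norm * |T phi|^2, so the source ASD is
    sqrt(norm) * |T phi|. Exactly equal to the CSD route.
    """
    taper = stft_tensor.taper_samples()
    norm = 2.0 / (float(np.mean(taper**2)) * stft_tensor.df)
    psi = np.tensordot(inverse.T, stft_tensor.values, axes=(1, 0))  # sources x f x t
    return SpectralTensor(
        values=np.sqrt(norm) * np.abs(psi),
        freqs=stft_tensor.freqs.copy(),
        window_centers=stft_tensor.window_centers.copy(),
        space_kind="source",
        units="a.u./sqrt(Hz)",
    )
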