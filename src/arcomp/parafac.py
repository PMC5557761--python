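"""Non-negative 3-way PARAFAC (canonical polyadic) decomposition.

The model writes a 3-way tensor X as a sum of K rank-1 terms,

    X[f, m, t] = sum_k A[f, k] B[m, k] C[t, k] + residual,

with all loadings constrained non-negative. Fitting is alternating
least squares: each free mode is updated by exact column-wise
non-negative coordinate descent (HALS) given the other two, which makes
the objective monotonically non-increasing. Any subset of modes can be
held fixed, which is how the source-space fit inherits the frequency
and temporal signatures estimated in sensor space.

Model adequacy is judged by the core consistency diagnostic
(CORCONDIA): the least-squares Tucker core of the fitted loadings is
compared to the K x K x K superdiagonal of ones; 100% means the
trilinear model is appropriate, values near or below zero mean it is
not. The number of components is chosen as the largest K whose core
consistency stays at or above a threshold (90% by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import SpectralTensor

logger = logging.getLogger(__name__)

__all__ = [
    "Parafac",
    "ParafacResults",
    "parafac_als",
    "corcondia",
    "select_num_components",
]

MODE_NAMES = ("frequency", "space", "time")
_DEGENERACY_CONGRUENCE = 0.98


def _congruence(x: np.ndarray, y: np.ndarray) -> float:
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(x @ y / (nx * ny))


def _mttkrp(X: np.ndarray, factors: list[np.ndarray], mode: int) -> np.ndarray:
    """Matricized tensor times Khatri-Rao product for a 3-way array."""
    A, B, C = factors
    if mode == 0:
        return np.einsum("ijk,jr,kr->ir", X, B, C, optimize=True)
    if mode == 1:
        return np.einsum("ijk,ir,kr->jr", X, A, C, optimize=True)
    return np.einsum("ijk,ir,jr->kr", X, A, B, optimize=True)


class Parafac:
    """Non-negative PARAFAC model of a 3-way array.

    Parameters
    ----------
    tensor : ndarray (3-way) or SpectralTensor
        Data to decompose. A :class:`SpectralTensor` (space x frequency
        x time) is rearranged to (frequency, space, time) so that mode
        0 = frequency, mode 1 = space, mode 2 = time, matching the
        loading-matrix convention A (frequency), B (space), C (time).
    rank : int
        Number of components K.
    fixed : dict, optional
        ``{mode_index_or_name: loading matrix}`` of modes to hold fixed
        at the given non-negative values (shape (dim, K)); those modes
        are never updated and are returned bit-identical.
    """

    def __init__(
        self,
        tensor: np.ndarray | SpectralTensor,
        rank: int,
        fixed: dict | None = None,
    ):
        if isinstance(tensor, SpectralTensor):
            self.data = np.transpose(tensor.values, (1, 0, 2)).astype(float)
            self.freqs = tensor.freqs.copy()
            self.window_centers = tensor.window_centers.copy()
            self.space_kind = tensor.space_kind
        else:
            self.data = np.asarray(tensor, dtype=float)
            self.freqs = None
            self.window_centers = None
            self.space_kind = None
        if self.data.ndim != 3:
            raise ValueError("PARAFAC requires a 3-way array")
        if rank < 1:
            raise ValueError("rank must be >= 1")
        if min(self.data.shape) < 1:
            raise ValueError("empty tensor")
        neg = self.data.min()
        if neg < -0.05 * max(abs(self.data).max(), 1e-300):
            raise ValueError(
                "tensor has substantial negative entries; the non-negative "
                "trilinear model expects (approximately) non-negative data"
            )
        self.rank = int(rank)
        self.fixed: dict[int, np.ndarray] = {}
        for key, mat in (fixed or {}).items():
            mode = MODE_NAMES.index(key) if isinstance(key, str) else int(key)
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (self.data.shape[mode], self.rank):
                raise ValueError(
                    f"fixed mode {mode} has shape {mat.shape}, "
                    f"expected {(self.data.shape[mode], self.rank)}"
                )
            if mat.min() < 0:
                raise ValueError("fixed loadings must be non-negative")
            self.fixed[mode] = mat
        if len(self.fixed) == 3:
            raise ValueError("at least one mode must be free")
        self.free_modes = [m for m in range(3) if m not in self.fixed]

    # ------------------------------------------------------------------
    def fit(
        self,
        n_starts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 2000,
        seed: int | np.random.SeedSequence | None = None,
    ) -> "ParafacResults":
        """Multi-start alternating least squares; best fit kept.

        Each start initializes the free modes with uniform random
        non-negative loadings and sweeps HALS updates until the change
        in explained variation drops below ``tol`` or ``max_iter``
        sweeps elapse. The start with the highest explained variation
        wins.
        """
        if n_starts < 1:
            raise ValueError("need at least one start")
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        best: ParafacResults | None = None
        for start_idx, child in enumerate(ss.spawn(n_starts)):
            res = self._fit_single(np.random.default_rng(child), tol, max_iter, start_idx)
            if best is None or res.fit > best.fit:
                best = res
        assert best is not None
        if not best.converged:
            logger.warning(
                "PARAFAC (K=%d) did not converge in %d sweeps (fit %.6f)",
                self.rank,
                max_iter,
                best.fit,
            )
        if best.degenerate:
            logger.warning("PARAFAC (K=%d): degenerate component pair detected", self.rank)
        return best

    def _fit_single(
        self,
        rng: np.random.Generator,
        tol: float,
        max_iter: int,
        start_index: int,
    ) -> "ParafacResults":
        X = self.data
        K = self.rank
        norm_x2 = float(np.sum(X**2))
        factors: list[np.ndarray] = []
        for mode in range(3):
            if mode in self.fixed:
                factors.append(self.fixed[mode].copy())
            else:
                factors.append(rng.uniform(0.1, 1.0, size=(X.shape[mode], K)))
        primary = self.free_modes[0]
        fit_history: list[float] = []
        fit_prev = -np.inf
        converged = False
        n_iter = 0
        eps = np.finfo(float).eps

        for sweep in range(1, max_iter + 1):
            n_iter = sweep
            inner = 0.0
            for mode in self.free_modes:
                W = _mttkrp(X, factors, mode)
                G = np.ones((K, K))
                for other in range(3):
                    if other != mode:
                        F = factors[other]
                        G *= F.T @ F
                U = factors[mode]
                for k in range(K):
                    g = G[k, k]
                    if g <= eps * max(G.max(), 1.0):
                        U[:, k] = 0.0
                        continue
                    u = U[:, k] + (W[:, k] - U @ G[:, k]) / g
                    np.clip(u, 0.0, None, out=u)
                    U[:, k] = u
                # with the other modes unchanged since W and G were formed,
                # <X, X_hat> = tr(U^T W) and ||X_hat||^2 = sum((U^T U) * G)
                inner = float(np.sum(W * U))
                norm_hat2 = float(np.sum((U.T @ U) * G))
            err2 = max(norm_x2 - 2.0 * inner + norm_hat2, 0.0)
            fit = 1.0 - err2 / norm_x2 if norm_x2 > 0 else 1.0
            fit_history.append(fit)
            if abs(fit - fit_prev) < tol:
                converged = True
                break
            fit_prev = fit
            # keep the scale in the first free mode during fitting
            for mode in self.free_modes[1:]:
                scale = np.linalg.norm(factors[mode], axis=0)
                nz = scale > 0
                factors[mode][:, nz] /= scale[nz]
                factors[primary][:, nz] *= scale[nz]

        factors = self._post_normalize(factors)
        residual_norm = float(np.sqrt(max(norm_x2 * (1.0 - fit_history[-1]), 0.0)))
        return ParafacResults(
            model=self,
            factors=factors,
            fit=fit_history[-1],
            fit_history=np.asarray(fit_history),
            n_iterations=n_iter,
            converged=converged,
            residual_norm=residual_norm,
            start_index=start_index,
        )

    def _post_normalize(self, factors: list[np.ndarray]) -> list[np.ndarray]:
        """Unit-maximum columns for free non-primary modes, scale pushed
        into the first free mode; fixed modes untouched; components
        ordered by descending first-free-mode magnitude when nothing is
        fixed (with fixed modes the column correspondence is frozen)."""
        primary = self.free_modes[0]
        out = [f.copy() for f in factors]
        for mode in self.free_modes[1:]:
            m = out[mode].max(axis=0)
            nz = m > 0
            out[mode][:, nz] /= m[nz]
            out[primary][:, nz] *= m[nz]
        if not self.fixed:
            order = np.argsort(-np.linalg.norm(out[primary], axis=0), kind="stable")
            out = [f[:, order] for f in out]
        return out


@dataclass
class ParafacResults:
    """Fitted PARAFAC loadings with diagnostics.

    ``factors`` is [A, B, C] for (frequency, space, time); ``fit`` is
    the explained variation 1 - ||X - X_hat||^2 / ||X||^2.
    """

    model: Parafac
    factors: list[np.ndarray]
    fit: float
    fit_history: np.ndarray
    n_iterations: int
    converged: bool
    residual_norm: float
    start_index: int
    _corcondia: float | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return self.model.rank

    @property
    def A(self) -> np.ndarray:
        """Frequency loadings (N_f x K)."""
        return self.factors[0]

    @property
    def B(self) -> np.ndarray:
        """Spatial loadings (channels or sources x K)."""
        return self.factors[1]

    @property
    def C(self) -> np.ndarray:
        """Temporal loadings (N_t x K)."""
        return self.factors[2]

    @property
    def fixed_modes(self) -> tuple[str, ...]:
        return tuple(MODE_NAMES[m] for m in sorted(self.model.fixed))

    @property
    def corcondia(self) -> float:
        if self._corcondia is None:
            self._corcondia = corcondia(self.model.data, self)
        return self._corcondia

    @property
    def degenerate(self) -> bool:
        """Two-component degeneracy: a pair of components whose loading
        congruence exceeds 0.98 simultaneously in every mode."""
        for i in range(self.K):
            for j in range(i + 1, self.K):
                c = 1.0
                for f in self.factors:
                    c *= _congruence(f[:, i], f[:, j])
                if c > _DEGENERACY_CONGRUENCE:
                    return True
        return False

    def reconstruct(self) -> np.ndarray:
        """Model tensor sum_k a_k (x) b_k (x) c_k."""
        return np.einsum("ir,jr,kr->ijk", *self.factors)

    def subset(self, keep: np.ndarray | list[int]) -> "ParafacResults":
        """Results restricted to a subset of components (re-indexed)."""
        keep = np.asarray(keep, dtype=int)
        sub = ParafacResults(
            model=self.model,
            factors=[f[:, keep] for f in self.factors],
            fit=self.fit,
            fit_history=self.fit_history,
            n_iterations=self.n_iterations,
            converged=self.converged,
            residual_norm=self.residual_norm,
            start_index=self.start_index,
        )
        sub.model = Parafac(self.model.data, rank=len(keep))
        sub.model.freqs = self.model.freqs
        sub.model.window_centers = self.model.window_centers
        sub.model.space_kind = self.model.space_kind
        return sub

    def peak_frequencies(self) -> np.ndarray:
        """Per-component argmax of the frequency loading, in Hz."""
        if self.model.freqs is None:
            raise ValueError("no frequency axis metadata on this model")
        return self.model.freqs[np.argmax(self.A, axis=0)]

    def summary(self) -> str:
        lines = [
            "Non-negative PARAFAC results",
            "=" * 40,
            f"components (K):      {self.K}",
            f"tensor shape:        {self.model.data.shape}",
            f"explained variation: {self.fit:.6f}",
            f"core consistency:    {self.corcondia:.2f}%",
            f"iterations:          {self.n_iterations}"
            + ("" if self.converged else " (NOT converged)"),
            f"fixed modes:         {', '.join(self.fixed_modes) or 'none'}",
            f"degenerate:          {self.degenerate}",
        ]
        if self.model.freqs is not None:
            pf = ", ".join(f"{f:.1f}" for f in self.peak_frequencies())
            lines.append(f"peak frequencies:    {pf} Hz")
        return "\n".join(lines)


def parafac_als(
    tensor: SpectralTensor | np.ndarray,
    K: int,
    fixed: dict | None = None,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | np.random.SeedSequence | None = None,
) -> ParafacResults:
    """Functional wrapper: fit a K-component non-negative PARAFAC."""
    return Parafac(tensor, K, fixed=fixed).fit(
        n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed
    )


def corcondia(tensor: np.ndarray | SpectralTensor, results: ParafacResults) -> float:
    """Core consistency diagnostic, in percent.

    Computes the least-squares Tucker core G of the fitted loadings
    (via mode-wise pseudo-inverses, exact because the pseudo-inverse of
    a Kronecker product is the Kronecker product of pseudo-inverses)
    and returns 100 * (1 - sum((G - T)^2) / sum(T^2)) where T is the
    K x K x K superdiagonal of ones. 100 when G is exactly
    superdiagonal; can be arbitrarily negative. For K = 1 the single
    normalized core element carries no interaction structure and the
    diagnostic is 100 by convention.
    """
    if isinstance(tensor, SpectralTensor):
        X = np.transpose(tensor.values, (1, 0, 2))
    else:
        X = np.asarray(tensor, dtype=float)
    if X.shape != results.model.data.shape:
        raise ValueError("tensor shape does not match the fitted model")
    K = results.K
    if K == 1:
        return 100.0
    pinvs = []
    for f in results.factors:
        if np.linalg.matrix_rank(f) < K:
            logger.info("rank-deficient loading matrix in CORCONDIA; pseudo-inverse used")
        pinvs.append(np.linalg.pinv(f))
    pA, pB, pC = pinvs
    G = np.einsum("ai,bj,ck,ijk->abc", pA, pB, pC, X, optimize=True)
    T = np.zeros((K, K, K))
    idx = np.arange(K)
    T[idx, idx, idx] = 1.0
    return float(100.0 * (1.0 - np.sum((G - T) ** 2) / np.sum(T**2)))


def select_num_components(
    tensor: SpectralTensor | np.ndarray,
    K_max: int = 6,
    threshold: float = 90.0,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | np.random.SeedSequence | None = None,
    return_models: bool = False,
):
    """Model-order selection by core consistency.

    Fits K = 1..K_max and returns the largest K whose core consistency
    is at or above ``threshold`` (percent), together with a per-K
    diagnostics table (fit, core consistency, convergence, degeneracy).
    If no K passes, K = 1 is returned with a warning. With
    ``return_models=True`` the per-K fitted results are returned as a
    third element.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(K_max)
    rows = []
    results: dict[int, ParafacResults] = {}
    for K in range(1, K_max + 1):
        res = parafac_als(
            tensor, K, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=children[K - 1]
        )
        results[K] = res
        rows.append(
            {
                "K": K,
                "fit": res.fit,
                "corcondia": res.corcondia,
                "converged": res.converged,
                "degenerate": res.degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("K")
    passing = table.index[table["corcondia"] >= threshold]
    if len(passing) == 0:
        warnings.warn(
            f"no model order up to K={K_max} reached core consistency {threshold}%; "
            "falling back to K=1",
            stacklevel=2,
        )
        chosen = 1
    else:
        chosen = int(passing.max())
    if return_models:
        return chosen, table, results
    return chosen, table
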