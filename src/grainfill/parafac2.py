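"""PARAFAC2 direct-fit alternating least squares for shifted GC-MS peaks.

PARAFAC2 models a collection of sample slabs ``X_k`` (elution time × m/z)
as::

    X_k ≈ P_k B diag(c_k) Aᵀ

with ``A`` (m/z × R) the shared spectral loadings, ``B`` (R × R) a shared
shape basis, ``P_k`` (time × R) per-sample orthonormal rotations that absorb
retention-time shifts, and ``c_k`` the per-sample component concentrations
(peak areas). Orthonormality of ``P_k`` enforces the constant cross-product
constraint ``(P_k B)ᵀ(P_k B) = BᵀB`` for every sample, which is what makes
the elution mode free to shift while the problem stays identifiable.

The solver is the classical direct-fit ALS: given ``(A, B, C)``, each ``P_k``
is the orthogonal-Procrustes solution; given the ``P_k``, the slabs are
rotated to ``Y_k = P_kᵀ X_k`` and one CP-ALS sweep updates ``B``, ``A`` and
``C``. The loss is monotone non-increasing and iteration stops when its
relative change falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Parafac2", "Parafac2Results"]


def _solve_gram(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``x @ gram = rhs`` rows; fall back to pseudo-inverse if singular."""
    try:
        return np.linalg.solve(gram.T, rhs.T).T
    except np.linalg.LinAlgError:
        return rhs @ np.linalg.pinv(gram)


class Parafac2:
    """Model object: fit a rank-``R`` PARAFAC2 decomposition to sample slabs.

    Parameters
    ----------
    slabs
        Array ``(n_samples, n_time, n_mz)`` or list of equally shaped
        time × m/z matrices (one chromatographic interval of each sample).
    n_components
        Rank ``R`` ≥ 1.
    tol
        Relative loss-change convergence criterion.
    max_iter
        ALS iteration cap; non-convergence is flagged, not raised.

    Notes
    -----
    Initialisation is deterministic (spectral loadings from the eigenvectors
    of ``Σ_k X_kᵀX_k``, ``B = I``, unit concentrations), so identical data
    give identical models. No non-negativity constraints are imposed;
    downstream component validation filters non-physical solutions.
    """

    def __init__(self, slabs, n_components: int, tol: float = 1e-8,
                 max_iter: int = 2000):
        slabs = np.asarray(slabs, dtype=float)
        if slabs.ndim != 3:
            raise ValueError("slabs must be a (sample, time, mz) array")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if n_components > min(slabs.shape[1], slabs.shape[2]):
            raise ValueError("n_components exceeds slab dimensions")
        self.slabs = slabs
        self.n_components = int(n_components)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def fit(self) -> "Parafac2Results":
        X = self.slabs
        K, T, M = X.shape
        R = self.n_components
        total_ssq = float(np.sum(X**2))
        if total_ssq == 0.0:
            raise ValueError("all-zero sub-cube cannot be decomposed")

        # deterministic init: A from the dominant eigenvectors of Σ XᵀX
        gram = np.zeros((M, M))
        for k in range(K):
            gram += X[k].T @ X[k]
        evals, evecs = np.linalg.eigh(gram)
        A = evecs[:, ::-1][:, :R].copy()
        B = np.eye(R)
        C = np.ones((K, R))

        loss_history = []
        prev = np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            # Procrustes step, batched over samples: P_k = UVᵀ of X_k M_kᵀ
            # with M_k = B diag(c_k) Aᵀ, so X_k M_kᵀ = (X_k A) diag(c_k) Bᵀ
            XA = np.einsum("ktm,mr->ktr", X, A)
            Z = (XA * C[:, None, :]) @ B.T  # (K, T, R)
            U, _, Vt = np.linalg.svd(Z, full_matrices=False)
            P = U @ Vt
            # rotate slabs into the common R-dimensional elution space
            Y = np.einsum("ktr,ktm->krm", P, X)  # (K, R, M)

            # one CP-ALS sweep on Y with factors B (mode-1), A (mode-2), C
            AtA = A.T @ A
            CtC = C.T @ C
            YA = np.einsum("krm,ms->krs", Y, A)
            B = _solve_gram(AtA * CtC, np.einsum("krs,ks->rs", YA, C))
            BtB = B.T @ B
            rhs_A = np.einsum("krm,rs,ks->ms", Y, B, C)
            A = _solve_gram(BtB * CtC, rhs_A)
            AtA = A.T @ A
            BYA = np.einsum("rs,krm,ms->ks", B, Y, A)
            C = _solve_gram(BtB * AtA, BYA)

            # loss via the rotated representation:
            # Σ_k ||X_k||² − 2 c_kᵀdiag(BᵀY_kA) + c_kᵀ[(BᵀB)∘(AᵀA)]c_k
            G = (B.T @ B) * (A.T @ A)
            BYA = np.einsum("rs,krm,ms->ks", B, Y, A)
            loss = total_ssq - 2.0 * float(np.sum(C * BYA)) + float(
                np.einsum("kr,rs,ks->", C, G, C)
            )
            loss = max(loss, 0.0)
            loss_history.append(loss)
            if prev < np.inf and prev > 0:
                if abs(prev - loss) / prev < self.tol:
                    converged = True
                    break
            elif loss == 0.0:
                converged = True
                break
            prev = loss

        A, B, C = self._fix_indeterminacy(A, B, C)
        fit_percent = 100.0 * (1.0 - loss_history[-1] / total_ssq)
        fit_percent = float(np.clip(fit_percent, 0.0, 100.0))
        return Parafac2Results(
            model=self,
            A=A,
            B=B,
            projections=P.copy(),
            C=C,
            fit_percent=fit_percent,
            loss_history=np.asarray(loss_history),
            n_iterations=len(loss_history),
            converged=converged,
        )

    @staticmethod
    def _fix_indeterminacy(A, B, C):
        """Unit-norm A and B columns, magnitude into C, sign into C.

        Spectra are flipped so each column of ``A`` sums non-negative (mass
        spectra are non-negative-dominant), the shape basis likewise; both
        flips are absorbed by ``C`` so the fitted slabs are unchanged.
        """
        norm_a = np.linalg.norm(A, axis=0)
        norm_a[norm_a == 0] = 1.0
        A = A / norm_a
        norm_b = np.linalg.norm(B, axis=0)
        norm_b[norm_b == 0] = 1.0
        B = B / norm_b
        C = C * norm_a * norm_b
        sign_a = np.where(A.sum(axis=0) < 0, -1.0, 1.0)
        A = A * sign_a
        C = C * sign_a
        # concentrations are peak areas: make them positive-dominant, with the
        # compensating flip going into the shape basis
        sign_c = np.where(C.mean(axis=0) < 0, -1.0, 1.0)
        C = C * sign_c
        B = B * sign_c
        return A, B, C


@dataclass
class Parafac2Results:
    """Fitted PARAFAC2 decomposition.

    ``A`` is m/z × R (unit-norm spectral profiles), ``B`` is R × R, each
    ``projections[k]`` is time × R orthonormal, and ``C`` (samples × R)
    carries the component magnitudes — the peak-area analogue used downstream
    as the concentration profile.
    """

    model: Parafac2
    A: np.ndarray
    B: np.ndarray
    projections: np.ndarray  # (K, T, R)
    C: np.ndarray
    fit_percent: float
    loss_history: np.ndarray
    n_iterations: int
    converged: bool

    @property
    def n_components(self) -> int:
        return self.A.shape[1]

    def elution_profiles(self, k: int) -> np.ndarray:
        """Time × R elution profiles of sample ``k`` (TIC analogue per unit
        concentration)."""
        return self.projections[k] @ self.B

    def fitted_slab(self, k: int) -> np.ndarray:
        return self.projections[k] @ self.B @ (self.C[k][:, None] * self.A.T)

    def residual_slab(self, k: int) -> np.ndarray:
        return self.model.slabs[k] - self.fitted_slab(k)

    def mean_elution_profile(self) -> np.ndarray:
        """Concentration-weighted mean elution profile per component (T × R)."""
        K = self.C.shape[0]
        prof = np.zeros((self.projections.shape[1], self.n_components))
        for k in range(K):
            prof += self.elution_profiles(k) * self.C[k]
        return prof / K

    def apex_indices(self) -> np.ndarray:
        """Apex (argmax of |mean elution profile|) per component."""
        prof = self.mean_elution_profile()
        return np.argmax(np.abs(prof), axis=0)

    def cross_product_deviation(self) -> float:
        """Max deviation of ``(P_k B)ᵀ(P_k B)`` from ``BᵀB`` over samples."""
        BtB = self.B.T @ self.B
        dev = 0.0
        for k in range(self.projections.shape[0]):
            F = self.projections[k] @ self.B
            dev = max(dev, float(np.max(np.abs(F.T @ F - BtB))))
        return dev
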