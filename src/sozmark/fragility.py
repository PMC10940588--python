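"""Neural fragility: linear system identification plus minimum-norm
destabilizing column perturbations.

Each 250 ms window of the multichannel signal is modelled as a linear
one-step system x(t+1) = A x(t), with A fit by least squares over the
window's transition pairs.  The fragility of channel j is the smallest
Euclidean norm of a rank-one perturbation Delta = d e_j^T (nonzero only in
column j) that moves an eigenvalue of A onto a target point sigma + i*omega
on the unit circle — i.e. how little input at channel j it takes to tip the
network into marginal instability.  Per window the raw norms are inverted
and normalized to [0, 1] as (max - d_hat) / max, so the most fragile channel
scores highest.

The minimum-norm perturbation has a closed form.  Writing
r = e_j^T (A - lambda I)^{-1} (row j of the resolvent), the matrix
determinant lemma makes lambda an eigenvalue of A + d e_j^T exactly when
r . d = -1.  Stacking that complex constraint into B = [Im r; Re r] and
b = (0, -1)^T, the least-norm real solution is d = B^T (B B^T)^{-1} b, and
its norm satisfies ||d||^2 = b^T (B B^T)^{-1} b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowSet
from .spectral_markers import MarkerMatrix

__all__ = [
    "LinearSystem",
    "PerturbationTarget",
    "default_target_grid",
    "fit_linear_system",
    "min_norm_column_perturbation",
    "fragility_map",
]

_IM_TINY = 1e-12


@dataclass
class LinearSystem:
    """One-step state-transition matrix for a single window."""

    A: np.ndarray
    window_index: int = -1
    condition: float = np.nan

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class PerturbationTarget:
    """Target eigenvalue sigma + i*omega for the destabilizing perturbation."""

    sigma: float
    omega: float

    @property
    def value(self) -> complex:
        return complex(self.sigma, self.omega)


def default_target_grid(radius: float = 1.0, n_omega: int = 21) -> list[PerturbationTarget]:
    """Targets on the upper half of the circle |lambda| = radius.

    For a real transition matrix the minimal column-perturbation norm for a
    target and its complex conjugate coincide, so sweeping the closed upper
    semicircle covers both half-planes.
    """
    theta = np.linspace(0.0, np.pi, n_omega)
    return [
        PerturbationTarget(radius * float(np.cos(t)), radius * float(np.sin(t)))
        for t in theta
    ]


def fit_linear_system(
    window_signal: np.ndarray,
    window_index: int = -1,
    ridge_scale: float = 1e-6,
) -> LinearSystem:
    """Least-squares fit of x(t+1) = A x(t) over a window's transitions.

    A minimizes ||X1 - A X0||_F with X0, X1 the lagged sample matrices.
    Rank-deficient windows (constant or duplicated channels) fall back to a
    ridge solution with regularizer ``ridge_scale * trace(X0 X0^T) / N`` and
    emit a warning.
    """
    sig = np.asarray(window_signal, dtype=float)
    n, t = sig.shape
    if t < n + 1:
        raise ValueError(f"window of {t} samples cannot identify {n} channels")
    x0, x1 = sig[:, :-1], sig[:, 1:]
    sol, _, rank, sv = np.linalg.lstsq(x0.T, x1.T, rcond=None)
    if rank < n:
        warnings.warn(
            f"rank-deficient window (rank {rank} < {n}); using ridge fallback",
            RuntimeWarning,
            stacklevel=2,
        )
        gram = x0 @ x0.T
        alpha = ridge_scale * np.trace(gram) / n
        if alpha <= 0:
            alpha = ridge_scale
        A = x1 @ x0.T @ np.linalg.inv(gram + alpha * np.eye(n))
    else:
        A = sol.T
    cond = float(sv[0] / sv[-1]) if sv.size and sv[-1] > 0 else np.inf
    return LinearSystem(A=A, window_index=window_index, condition=cond)


def min_norm_column_perturbation(
    sys: LinearSystem,
    j: int,
    target: PerturbationTarget,
    tol_eig: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Minimum-norm vector d so that A + d e_j^T has eigenvalue at the target.

    Returns ``(d, ||d||)``.  If A already carries the target eigenvalue the
    zero perturbation is returned.  Raises ``np.linalg.LinAlgError`` when the
    resolvent (A - lambda I)^{-1} does not exist for a non-eigenvalue reason
    (callers sweeping a grid skip such targets).
    """
    A = sys.A
    n = A.shape[0]
    lam = target.value
    eigs = np.linalg.eigvals(A)
    if np.min(np.abs(eigs - lam)) < tol_eig:
        return np.zeros(n), 0.0
    M = np.linalg.inv(A - lam * np.eye(n))
    r = M[j, :]
    im, re = r.imag, r.real
    if abs(target.omega) > 0 and np.dot(im, im) > _IM_TINY * max(np.dot(re, re), 1.0):
        B = np.vstack([im, re])
        b = np.array([0.0, -1.0])
        d = B.T @ np.linalg.solve(B @ B.T, b)
    else:
        # real target (or vanishing imaginary part): single constraint re.d = -1
        nr = np.dot(re, re)
        if nr == 0:
            raise np.linalg.LinAlgError("degenerate resolvent row")
        d = -re / nr
    return d, float(np.linalg.norm(d))


def _min_norms_all_channels(A: np.ndarray, lam: complex, omega: float) -> np.ndarray:
    """Vectorized per-channel minimal perturbation norms for one target."""
    n = A.shape[0]
    M = np.linalg.inv(A - lam * np.eye(n))
    im, re = M.imag, M.real
    a = np.einsum("ij,ij->i", im, im)
    c = np.einsum("ij,ij->i", re, re)
    if abs(omega) > 0:
        m = np.einsum("ij,ij->i", im, re)
        det = a * c - m * m
        norms = np.full(n, np.inf)
        ok = det > _IM_TINY * np.maximum(c, 1.0) ** 2
        norms[ok] = np.sqrt(a[ok] / det[ok])
        # a degenerate Gram comes either from a (numerically) real resolvent
        # row — then the single constraint re.d = -1 applies — or from
        # colinear Im/Re rows, which make the target infeasible (norm inf)
        real_row = (~ok) & (a <= _IM_TINY * np.maximum(c, 1.0)) & (c > 0)
        norms[real_row] = 1.0 / np.sqrt(c[real_row])
        return norms
    norms = np.full(n, np.inf)
    ok = c > 0
    norms[ok] = 1.0 / np.sqrt(c[ok])
    return norms


def fragility_map(
    ws: WindowSet,
    targets: list[PerturbationTarget] | None = None,
    tol_eig: float = 1e-6,
) -> MarkerMatrix:
    """Channels x windows fragility, normalized per window to [0, 1].

    Per window: fit A, take for each channel the minimum perturbation norm
    d_hat over the target grid, then emit (max_j d_hat - d_hat_j) / max_j
    d_hat so the most fragile channel (smallest d_hat) scores highest and the
    least fragile scores 0.  Windows where every target fails are flagged in
    the missing mask.
    """
    targets = targets if targets is not None else default_target_grid()
    if not targets:
        raise ValueError("target grid must be non-empty")
    n = ws.source.n_channels
    w = len(ws)
    values = np.zeros((n, w))
    missing = np.zeros(w, dtype=bool)
    for wi in range(w):
        sys = fit_linear_system(ws.window_signal(wi), window_index=wi)
        eigs = np.linalg.eigvals(sys.A)
        dhat = np.full(n, np.inf)
        for tg in targets:
            lam = tg.value
            if np.min(np.abs(eigs - lam)) < tol_eig:
                dhat[:] = 0.0
                break
            try:
                norms = _min_norms_all_channels(sys.A, lam, tg.omega)
            except np.linalg.LinAlgError:
                continue
            np.minimum(dhat, norms, out=dhat)
        if not np.all(np.isfinite(dhat)):
            missing[wi] = True
            continue
        top = dhat.max()
        if top > 0:
            values[:, wi] = (top - dhat) / top
    return MarkerMatrix(values=values, marker_id="fragility", normalized=True, missing=missing)
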