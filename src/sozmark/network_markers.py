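"""Connectivity matrices and graph-centrality markers, plus the full
21-marker registry.

Connectivity between channels is measured two ways: Pearson correlation in
the time domain, and band-averaged magnitude-squared coherence
|G_ij|^2 / (G_ii G_jj) in the frequency domain, with the cross-spectral
densities G estimated by Welch averaging (0.5 s Hann segments, 50 % overlap)
inside each 2.5 s window.  Each connectivity basis feeds two node-importance
measures — normalized weighted degree and the leading-eigenvector fixed
point — giving 14 centrality markers (correlation plus six coherence bands,
times two centralities).  Together with the fragility marker and the six
band powers these make up the 21-marker registry.

The 21-marker decomposition (1 fragility + 6 spectral + 7 degree + 7
eigenvector centralities) is an interpretation: the marker families and the
total are fixed, but the per-family enumeration chosen here is the unique
one consistent with correlation being a time-domain and coherence a
six-band frequency-domain measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows as spwindows

from .preprocess import WindowSet
from .spectral_markers import Band, BAND_NAMES, MarkerMatrix, default_bands, minmax_normalize

__all__ = [
    "ConnectivityMatrix",
    "MarkerSpec",
    "marker_registry",
    "SEVEN_HYBRID_MARKERS",
    "correlation_matrix",
    "band_coherence_matrix",
    "coherence_band_stack",
    "degree_centrality",
    "eigenvector_centrality",
    "centrality_map",
]

#: the seven markers later fused into the hybrid marker: neural fragility
#: plus the six band-power averages
SEVEN_HYBRID_MARKERS = ("fragility",) + tuple(f"pow_{b}" for b in BAND_NAMES)


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel connectivity with unit diagonal."""

    values: np.ndarray
    basis: str  # "correlation" | "coherence"
    band: Band | None = None
    window_index: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("connectivity matrix must be square")
        if self.basis not in ("correlation", "coherence"):
            raise ValueError(f"unknown basis {self.basis!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def edge_weights(self) -> np.ndarray:
        """Nonnegative weight matrix with zeroed diagonal for centralities."""
        w = np.abs(self.values) if self.basis == "correlation" else self.values.copy()
        np.fill_diagonal(w, 0.0)
        return w


@dataclass(frozen=True)
class MarkerSpec:
    marker_id: str
    family: str  # fragility | spectral | degree_centrality | eigenvector_centrality
    basis: str | None = None  # correlation | coherence (centrality families)
    band: str | None = None
    normalized: bool = True


def marker_registry() -> list[MarkerSpec]:
    """All 21 markers: 1 fragility + 6 spectral + 7 degree + 7 eigenvector."""
    specs = [MarkerSpec("fragility", "fragility")]
    specs += [MarkerSpec(f"pow_{b}", "spectral", band=b) for b in BAND_NAMES]
    specs.append(MarkerSpec("dc_corr", "degree_centrality", basis="correlation"))
    specs += [
        MarkerSpec(f"dc_coh_{b}", "degree_centrality", basis="coherence", band=b)
        for b in BAND_NAMES
    ]
    specs.append(
        MarkerSpec("evc_corr", "eigenvector_centrality", basis="correlation", normalized=False)
    )
    specs += [
        MarkerSpec(
            f"evc_coh_{b}", "eigenvector_centrality", basis="coherence", band=b, normalized=False
        )
        for b in BAND_NAMES
    ]
    return specs


def correlation_matrix(window_signal: np.ndarray, window_index: int = -1) -> ConnectivityMatrix:
    """Pearson correlation of all channel pairs over a window.

    Zero-variance channels get zero off-diagonal entries (unit diagonal) and
    a warning rather than NaNs.
    """
    sig = np.asarray(window_signal, dtype=float)
    n, t = sig.shape
    if t < 2:
        raise ValueError("need at least 2 samples for a correlation")
    sd = sig.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance channel(s) in correlation window",
            RuntimeWarning,
            stacklevel=2,
        )
        c = np.zeros((n, n))
        idx = np.flatnonzero(~flat)
        if idx.size:
            c[np.ix_(idx, idx)] = np.atleast_2d(np.corrcoef(sig[idx]))
        np.fill_diagonal(c, 1.0)
    else:
        c = np.corrcoef(sig)
        np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(values=np.clip(c, -1.0, 1.0), basis="correlation",
                              window_index=window_index)


def _welch_cross_spectra(
    sig: np.ndarray, rate: float, nperseg: int = 256, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Segment-averaged cross-spectral density stack G[i, j, f] (Welch, Hann).

    Scaling constants are omitted: they cancel in the coherence quotient.
    """
    n, t = sig.shape
    step = int(nperseg * (1 - overlap))
    if t < nperseg + step:
        raise ValueError(
            f"window of {t} samples too short for >= 2 Welch segments of {nperseg}"
        )
    starts = range(0, t - nperseg + 1, step)
    taper = spwindows.hann(nperseg, sym=False)
    segs = np.stack([sig[:, s : s + nperseg] for s in starts], axis=1)  # (n, nseg, L)
    segs = segs - segs.mean(axis=2, keepdims=True)
    X = np.fft.rfft(segs * taper, axis=2)
    G = np.einsum("isf,jsf->ijf", X, np.conj(X)) / segs.shape[1]
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / rate)
    return G, freqs


def coherence_band_stack(
    window_signal: np.ndarray,
    bands: list[Band],
    rate: float,
    nperseg: int = 256,
    overlap: float = 0.5,
) -> dict[str, np.ndarray]:
    """Band-averaged coherence matrices for several bands in one Welch pass."""
    sig = np.asarray(window_signal, dtype=float)
    G, freqs = _welch_cross_spectra(sig, rate, nperseg=nperseg, overlap=overlap)
    auto = np.real(np.einsum("iif->if", G))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(G) ** 2 / denom, 0.0)
    nyq = rate / 2.0
    out: dict[str, np.ndarray] = {}
    for band in bands:
        if band.lo_hz >= nyq:
            raise ValueError(f"band {band.name} lies entirely above Nyquist")
        mask = band.bin_mask(freqs, nyq)
        if not mask.any():
            raise ValueError(f"band {band.name} covers no Welch bins")
        c = coh[:, :, mask].mean(axis=2)
        c = np.clip(0.5 * (c + c.T), 0.0, 1.0)
        np.fill_diagonal(c, 1.0)
        out[band.name] = c
    return out


def band_coherence_matrix(
    window_signal: np.ndarray,
    band: Band,
    rate: float,
    window_index: int = -1,
    nperseg: int = 256,
    overlap: float = 0.5,
) -> ConnectivityMatrix:
    """Magnitude-squared coherence averaged over one band's bins."""
    stack = coherence_band_stack(window_signal, [band], rate, nperseg=nperseg, overlap=overlap)
    return ConnectivityMatrix(
        values=stack[band.name], basis="coherence", band=band, window_index=window_index
    )


def degree_centrality(conn: ConnectivityMatrix) -> np.ndarray:
    """Sum of off-diagonal edge weights per node, divided by N - 1."""
    n = conn.n
    if n < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    w = conn.edge_weights()
    return w.sum(axis=1) / (n - 1)


def eigenvector_centrality(
    conn: ConnectivityMatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    return_eigenvalue: bool = False,
):
    """Leading eigenvector of the nonnegative weight matrix, unit norm.

    Power iteration on the shifted matrix W + sI (s = max row sum, which by
    Gershgorin makes the spectrum nonnegative so the Perron pair dominates);
    falls back to a dense symmetric eigendecomposition if the iteration does
    not converge.  The vector is oriented nonnegative.
    """
    if isinstance(conn, ConnectivityMatrix):
        w = conn.edge_weights()
    else:
        w = np.asarray(conn, dtype=float)
    n = w.shape[0]
    if n == 1:
        v, lam = np.ones(1), float(w[0, 0])
        return (v, lam) if return_eigenvalue else v
    shift = float(w.sum(axis=1).max())
    if shift == 0:  # empty graph: flat centrality by convention
        v = np.ones(n) / np.sqrt(n)
        return (v, 0.0) if return_eigenvalue else v
    M = w + shift * np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    converged = False
    for _ in range(max_iter):
        nv = M @ v
        nv /= np.linalg.norm(nv)
        if np.linalg.norm(nv - v) < tol:
            v = nv
            converged = True
            break
        v = nv
    if not converged:
        evals, evecs = np.linalg.eigh(w)
        v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector of a nonnegative matrix is nonnegative
    v /= np.linalg.norm(v)
    lam = float(v @ w @ v)
    return (v, lam) if return_eigenvalue else v


def centrality_map(ws: WindowSet, spec: MarkerSpec) -> MarkerMatrix:
    """Per-window centrality marker for a degree/eigenvector MarkerSpec.

    Degree maps are min-max normalized within each window; eigenvector maps
    keep their unit-Euclidean-norm columns unscaled (they already live on a
    common scale, and rescaling would break the fixed-point interpretation).
    """
    if spec.family not in ("degree_centrality", "eigenvector_centrality"):
        raise ValueError(f"{spec.marker_id} is not a centrality marker")
    rate = ws.source.rate
    bands = default_bands(rate)
    n, nw = ws.source.n_channels, len(ws)
    values = np.zeros((n, nw))
    for wi in range(nw):
        sig = ws.window_signal(wi)
        if spec.basis == "correlation":
            conn = correlation_matrix(sig, window_index=wi)
        else:
            conn = band_coherence_matrix(sig, bands[spec.band], rate, window_index=wi)
        if spec.family == "degree_centrality":
            values[:, wi] = minmax_normalize(degree_centrality(conn))
        else:
            values[:, wi] = eigenvector_centrality(conn)
    return MarkerMatrix(
        values=values,
        marker_id=spec.marker_id,
        normalized=(spec.family == "degree_centrality"),
    )
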