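"""Band-averaged spectral power markers.

Six canonical iEEG bands — delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30,
gamma 30-90 and high-gamma 90 Hz-Nyquist (which subsumes high-frequency
oscillations) — are summarized per 2.5 s window and channel as the mean
magnitude of the discrete Fourier transform over the band's bins, then
min-max normalized across channels within each window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowSet

__all__ = [
    "Band",
    "default_bands",
    "BAND_NAMES",
    "MarkerMatrix",
    "band_average_power",
    "minmax_normalize",
    "spectral_map",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma", "high_gamma")


@dataclass(frozen=True)
class Band:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: need lo < hi, got {self.lo_hz}, {self.hi_hz}")

    def bin_mask(self, freqs: np.ndarray, nyquist: float) -> np.ndarray:
        """FFT bins in [lo, hi); the top band also takes the Nyquist bin."""
        if self.hi_hz >= nyquist - 1e-9:
            return (freqs >= self.lo_hz) & (freqs <= self.hi_hz + 1e-9)
        return (freqs >= self.lo_hz) & (freqs < self.hi_hz)


def default_bands(rate: float = 512.0) -> dict[str, Band]:
    """The six-band partition of [0.5 Hz, Nyquist] at the given rate."""
    nyq = rate / 2.0
    edges = [
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma", 30.0, 90.0),
        ("high_gamma", 90.0, nyq),
    ]
    return {name: Band(name, lo, hi) for name, lo, hi in edges}


@dataclass
class MarkerMatrix:
    """Channels x windows values of one marker.

    ``normalized`` records whether each window column was min-max scaled
    (eigenvector-centrality markers are the one family left unscaled);
    ``missing`` flags windows where the marker could not be computed.
    """

    values: np.ndarray
    marker_id: str
    normalized: bool = True
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("marker values must be channels x windows")
        if self.missing is None:
            self.missing = np.zeros(self.values.shape[1], dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def band_average_power(
    window_signal: np.ndarray,
    band: Band,
    rate: float,
    mode: str = "magnitude",
) -> np.ndarray:
    """Per-channel mean spectral magnitude (or power) over a band's bins.

    The plain (untapered) DFT of the window is used; ``mode="power"``
    averages |F|^2 instead of |F|.
    """
    sig = np.asarray(window_signal, dtype=float)
    n, t = sig.shape
    if t < 2:
        raise ValueError("window too short for a spectrum")
    nyq = rate / 2.0
    if band.lo_hz >= nyq:
        raise ValueError(f"band {band.name} lies entirely above Nyquist ({nyq} Hz)")
    freqs = np.fft.rfftfreq(t, d=1.0 / rate)
    mask = band.bin_mask(freqs, nyq)
    if not mask.any():
        raise ValueError(f"band {band.name} covers no FFT bins at T={t}, rate={rate}")
    spec = np.abs(np.fft.rfft(sig, axis=1))
    if mode == "power":
        spec = spec**2
    elif mode != "magnitude":
        raise ValueError(f"unknown mode {mode!r}")
    return spec[:, mask].mean(axis=1)


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """(v - min) / (max - min); a constant vector maps to all zeros."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot normalize non-finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def spectral_map(ws: WindowSet, band: Band, mode: str = "magnitude") -> MarkerMatrix:
    """Band-power marker over a 2.5 s window set, min-max scaled per window."""
    rate = ws.source.rate
    n, w = ws.source.n_channels, len(ws)
    values = np.zeros((n, w))
    for wi in range(w):
        values[:, wi] = minmax_normalize(
            band_average_power(ws.window_signal(wi), band, rate, mode=mode)
        )
    return MarkerMatrix(values=values, marker_id=f"pow_{band.name}", normalized=True)
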