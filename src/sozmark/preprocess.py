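"""Signal standardization and the two sliding-window schemes.

Every recording is brought to 512 Hz, notch-filtered around the 60 Hz mains
line (band-stop 59-61 Hz) and band-pass filtered 0.5 Hz to just below
Nyquist with a fourth-order zero-phase Butterworth.  The analysis epoch runs
from 30 s before the annotated seizure onset to the seizure end.  Markers
are then computed on sliding windows: 250 ms / 125 ms step for the fragility
marker, 2.5 s / 500 ms step for all others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io_formats import Recording

__all__ = [
    "PreprocessConfig",
    "WindowSet",
    "resample",
    "standard_filters",
    "extract_epoch",
    "windows",
]

#: seconds of pre-ictal context included in the analysis epoch
PRE_ONSET_CONTEXT_S = 30.0


@dataclass(frozen=True)
class PreprocessConfig:
    rate: float = 512.0
    notch_hz: float = 60.0
    notch_halfwidth_hz: float = 1.0
    bp_low_hz: float = 0.5
    butter_order: int = 4
    fragility_window_ms: float = 250.0
    fragility_step_ms: float = 125.0
    marker_window_ms: float = 2500.0
    marker_step_ms: float = 500.0


@dataclass
class WindowSet:
    """Ordered half-open sample windows over one recording's epoch."""

    source: Recording
    window_len_ms: float
    step_ms: float
    windows: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.windows)

    def window_signal(self, i: int) -> np.ndarray:
        s, e = self.windows[i]
        return self.source.signal[:, s:e]

    def window_index_of_sample(self, sample: int) -> int:
        """Index of the first window whose span contains ``sample`` (or -1)."""
        for i, (s, e) in enumerate(self.windows):
            if s <= sample < e:
                return i
        return -1


def resample(rec: Recording, target_rate: float) -> Recording:
    """Polyphase resampling to ``target_rate``; identity when already there."""
    if target_rate <= 0:
        raise ValueError(f"target rate must be positive, got {target_rate}")
    if abs(target_rate - rec.rate) < 1e-9:
        return replace(rec, signal=rec.signal.copy())
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    out = sps.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=1)
    scale = target_rate / rec.rate
    return replace(
        rec,
        signal=out,
        rate=float(target_rate),
        onset_s=rec.onset_s,
        end_s=min(rec.end_s, out.shape[1] / target_rate) if rec.end_s is not None else None,
    )


def _sos_filters(rate: float, cfg: PreprocessConfig):
    nyq = rate / 2.0
    bp = sps.butter(
        cfg.butter_order,
        [cfg.bp_low_hz, 0.999 * nyq],
        btype="bandpass",
        fs=rate,
        output="sos",
    )
    notch = sps.butter(
        cfg.butter_order,
        [cfg.notch_hz - cfg.notch_halfwidth_hz, cfg.notch_hz + cfg.notch_halfwidth_hz],
        btype="bandstop",
        fs=rate,
        output="sos",
    )
    return bp, notch


def standard_filters(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase band-pass (0.5 Hz - Nyquist) and 60 Hz notch.

    Applied forward-backward (``sosfiltfilt``) so markers carry no filter
    latency.  Raises on signals shorter than the filter warm-up length.
    """
    cfg = cfg or PreprocessConfig()
    bp, notch = _sos_filters(rec.rate, cfg)
    padlen = 3 * (2 * max(bp.shape[0], notch.shape[0]) + 1)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"signal of {rec.n_samples} samples shorter than filter warm-up ({padlen})"
        )
    out = sps.sosfiltfilt(bp, rec.signal, axis=1)
    out = sps.sosfiltfilt(notch, out, axis=1)
    return replace(rec, signal=out)


def extract_epoch(rec: Recording, pre_onset_s: float = PRE_ONSET_CONTEXT_S) -> Recording:
    """Cut the analysis epoch: ``pre_onset_s`` before onset through seizure end.

    If the record starts less than ``pre_onset_s`` before onset the epoch is
    clamped to the record start and the returned Recording's ``clamped`` flag
    is set.  The onset is re-expressed relative to the epoch start.
    """
    if rec.onset_s is None or rec.end_s is None:
        raise ValueError("recording has no seizure annotations")
    start_s = rec.onset_s - pre_onset_s
    clamped = start_s < 0
    start_s = max(start_s, 0.0)
    s0 = int(round(start_s * rec.rate))
    s1 = int(round(rec.end_s * rec.rate))
    return replace(
        rec,
        signal=rec.signal[:, s0:s1],
        onset_s=rec.onset_s - start_s,
        end_s=rec.end_s - start_s,
        clamped=clamped,
    )


def windows(rec: Recording, window_len_ms: float, step_ms: float) -> WindowSet:
    """Sliding half-open windows; the trailing partial window is discarded."""
    L = int(round(window_len_ms * rec.rate / 1000.0))
    S = int(round(step_ms * rec.rate / 1000.0))
    if L <= 0 or S <= 0:
        raise ValueError("window and step must be positive")
    if L > rec.n_samples:
        raise ValueError(
            f"window of {L} samples longer than epoch of {rec.n_samples}"
        )
    count = (rec.n_samples - L) // S + 1
    spans = [(i * S, i * S + L) for i in range(count)]
    return WindowSet(source=rec, window_len_ms=window_len_ms, step_ms=step_ms, windows=spans)
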