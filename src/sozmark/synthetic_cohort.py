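"""Synthetic iEEG patient cohorts with a controllable seizure-onset-zone
signal.

Each patient is a first-order vector autoregression (VAR(1)) driven by unit
white noise: pre-onset the transition matrix has spectral radius rho0 = 0.9
(stable background), and at onset the intra-SOZ coupling block is boosted
and the matrix rescaled to rho1 = 0.99, pushing the network toward marginal
instability with the near-unstable mode localized on the SOZ channels.  The
SOZ channels additionally receive band-limited 40-80 Hz activity post-onset
(emulating ictal gamma).  The resection mask is drawn so that intended
surgical successes resect the whole SOZ while failures overlap it by at
most half, and the recorded outcome is that overlap rule's verdict flipped
with probability ``label_noise``.

What this emulates — and what it does not: the generator reproduces the
statistical structure the markers assume (post-onset destabilization,
SOZ-confined gamma and coherence elevation, outcome determined by
resection/SOZ overlap) but none of the biophysics of real seizures, no
artifacts, and no electrode geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import (
    PatientMeta,
    Recording,
    load_recording,
    save_recording,
    write_channels_tsv,
)

__all__ = [
    "CohortConfig",
    "stable_var_matrix",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 60
    n_channels: int = 16
    n_soz: int = 4
    rate: float = 512.0
    pre_onset_s: float = 40.0
    seizure_s: float = 60.0
    rho0: float = 0.9  # background spectral radius
    rho1: float = 0.99  # post-onset radius (SOZ-dominated mode)
    gamma_amp: float = 3.0  # std of added band-limited SOZ activity
    gamma_band: tuple[float, float] = (40.0, 80.0)
    burst_shared_frac: float = 0.8  # amplitude fraction from the common source
    coupling_boost: float = 1.5  # intra-SOZ block multiplier at onset
    background_coupling: float = 0.4  # off-diagonal strength of the background VAR
    success_overlap: float = 0.9  # resection must cover this SOZ fraction
    label_noise: float = 0.0
    success_rate: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho0 < self.rho1 < 1:
            raise ValueError("need 0 < rho0 < rho1 < 1")
        if not self.n_soz < self.n_channels:
            raise ValueError("n_soz must be smaller than n_channels")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must lie in [0, 1)")


def stable_var_matrix(n: int, rho: float, seed, coupling: float = 1.0) -> np.ndarray:
    """Random n x n matrix rescaled to spectral radius exactly ``rho``.

    ``coupling`` < 1 shrinks the off-diagonal entries before rescaling,
    yielding channels that are mostly autonomous (diagonal persistence) with
    weak cross-talk — the structure background iEEG coherence suggests.
    ``coupling=1`` is a fully random matrix.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n)) / np.sqrt(n)
    if coupling != 1.0:
        off = A - np.diag(np.diag(A))
        A = np.diag(rng.uniform(0.3, 0.9, n)) + coupling * off
    radius = np.max(np.abs(np.linalg.eigvals(A)))
    return A * (rho / radius)


def _rescale_radius(A: np.ndarray, rho: float) -> np.ndarray:
    radius = np.max(np.abs(np.linalg.eigvals(A)))
    return A * (rho / radius)


def _simulate_var(A_pre, A_post, n_pre: int, n_post: int, rng) -> np.ndarray:
    n = A_pre.shape[0]
    total = n_pre + n_post
    noise = rng.standard_normal((total, n))
    out = np.empty((total, n))
    x = np.zeros(n)
    for t in range(total):
        A = A_pre if t < n_pre else A_post
        x = A @ x + noise[t]
        out[t] = x
    return out.T


def _draw_resection(cfg: CohortConfig, soz_idx: np.ndarray, rng) -> tuple[np.ndarray, bool]:
    """Resection mask per the overlap rule; returns (mask, rule verdict)."""
    n, k = cfg.n_channels, cfg.n_soz
    non_soz = np.setdiff1d(np.arange(n), soz_idx)
    intended_success = rng.random() < cfg.success_rate
    if intended_success:
        extra = rng.choice(non_soz, size=int(rng.integers(0, 3)), replace=False)
        resected = np.concatenate([soz_idx, extra])
    else:
        n_overlap = int(rng.integers(0, int(np.floor(k / 2)) + 1))
        inside = rng.choice(soz_idx, size=n_overlap, replace=False)
        outside = rng.choice(non_soz, size=k - n_overlap, replace=False)
        resected = np.concatenate([inside, outside])
    mask = np.zeros(n, dtype=bool)
    mask[resected.astype(int)] = True
    overlap = mask[soz_idx].sum() / k
    return mask, bool(overlap >= cfg.success_overlap)


def simulate_patient(
    cfg: CohortConfig, patient_seed, patient_id: str = "sim"
) -> tuple[Recording, PatientMeta]:
    """One synthetic patient: recording with masks plus outcome metadata."""
    rng = np.random.default_rng(patient_seed)
    n = cfg.n_channels
    n_pre = int(round(cfg.pre_onset_s * cfg.rate))
    n_post = int(round(cfg.seizure_s * cfg.rate))

    soz_idx = np.sort(rng.choice(n, size=cfg.n_soz, replace=False))
    A0 = stable_var_matrix(n, cfg.rho0, rng, coupling=cfg.background_coupling)
    A1 = A0.copy()
    A1[np.ix_(soz_idx, soz_idx)] *= cfg.coupling_boost
    A1 = _rescale_radius(A1, cfg.rho1)

    signal = _simulate_var(A0, A1, n_pre, n_post, rng)

    # band-limited ictal gamma on the SOZ channels: a shared generator plus a
    # small per-channel component, so SOZ channels gain both gamma power and
    # mutual gamma-band coherence
    sos = sps.butter(4, cfg.gamma_band, btype="bandpass", fs=cfg.rate, output="sos")
    common = sps.sosfilt(sos, rng.standard_normal(n_post))
    common /= common.std()
    indiv = sps.sosfilt(sos, rng.standard_normal((cfg.n_soz, n_post)), axis=1)
    indiv /= indiv.std(axis=1, keepdims=True)
    c = cfg.burst_shared_frac
    burst = c * common[None, :] + np.sqrt(1.0 - c**2) * indiv
    signal[soz_idx, n_pre:] += cfg.gamma_amp * burst

    soz_mask = np.zeros(n, dtype=bool)
    soz_mask[soz_idx] = True
    resection_mask, rule_success = _draw_resection(cfg, soz_idx, rng)
    flipped = rng.random() < cfg.label_noise
    success = rule_success != flipped

    rec = Recording(
        signal=signal,
        rate=cfg.rate,
        channel_labels=[f"ch{i:02d}" for i in range(n)],
        onset_s=cfg.pre_onset_s,
        end_s=cfg.pre_onset_s + cfg.seizure_s,
        soz_mask=soz_mask,
        resection_mask=resection_mask,
        patient_id=patient_id,
    )
    meta = PatientMeta(
        patient_id=patient_id,
        outcome="success" if success else "failure",
        sex="M" if rng.random() < 0.5 else "F",
        handedness="R" if rng.random() < 0.88 else "L",
    )
    return rec, meta


def simulate_cohort(cfg: CohortConfig) -> list[tuple[Recording, PatientMeta]]:
    """A cohort of independent patients with per-patient seeds derived from
    the master seed."""
    if cfg.n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_patients)
    return [
        simulate_patient(cfg, child, patient_id=f"sub-{i:03d}")
        for i, child in enumerate(children)
    ]


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Write HDF5 recordings, per-patient channels TSVs and participants.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, meta in cohort:
        save_recording(rec, out_dir / f"{meta.patient_id}_ieeg.h5")
        write_channels_tsv(rec, out_dir / f"{meta.patient_id}_channels.tsv")
        rows.append(
            {
                "participant_id": meta.patient_id,
                "outcome": meta.outcome,
                "sex": meta.sex,
                "handedness": meta.handedness,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "participants.tsv", sep="\t", index=False)
    return out_dir


def load_cohort(cohort_dir: str | Path) -> list[tuple[Recording, PatientMeta]]:
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "participants.tsv", sep="\t")
    out = []
    for row in table.itertuples():
        pid = row.participant_id
        rec = load_recording(
            cohort_dir / f"{pid}_ieeg.h5", cohort_dir / f"{pid}_channels.tsv"
        )
        out.append(
            (
                rec,
                PatientMeta(
                    patient_id=pid,
                    outcome=row.outcome,
                    sex=row.sex,
                    handedness=row.handedness,
                ),
            )
        )
    return out
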