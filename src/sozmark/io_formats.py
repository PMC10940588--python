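"""Reading, writing and rendering of the pipeline's on-disk formats.

The internal round-trip container for multichannel intracranial EEG is HDF5
(datasets ``/signal``, ``/rate``, ``/labels``, ``/masks/soz``,
``/masks/resected``) because it preserves float64 samples bit-exactly; EDF,
the clinical exchange format, is supported read-only (it quantizes to 16
bits).  Channel metadata travels as a BIDS-style ``channels.tsv`` with two
extra boolean columns, ``soz`` and ``resected``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "PatientMeta",
    "load_recording",
    "save_recording",
    "read_channels_tsv",
    "write_channels_tsv",
    "render_heatmap",
    "save_marker_matrices",
    "load_marker_matrices",
    "write_results",
    "read_results",
]


@dataclass
class Recording:
    """A channels x samples iEEG signal with its clinical annotations.

    ``soz_mask`` flags the channels clinicians identified as the seizure
    onset zone; ``resection_mask`` flags the surgically removed channels.
    ``onset_s``/``end_s`` delimit the annotated seizure in seconds from the
    start of the record and may be ``None`` until annotated.
    """

    signal: np.ndarray
    rate: float
    channel_labels: list[str]
    onset_s: float | None = None
    end_s: float | None = None
    soz_mask: np.ndarray | None = None
    resection_mask: np.ndarray | None = None
    patient_id: str = ""
    clamped: bool = False

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        n = self.signal.shape[0]
        if len(self.channel_labels) != n:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n} channels"
            )
        if len(set(self.channel_labels)) != n:
            raise ValueError("channel labels must be unique")
        for name in ("soz_mask", "resection_mask"):
            m = getattr(self, name)
            if m is None:
                setattr(self, name, np.zeros(n, dtype=bool))
            else:
                m = np.asarray(m, dtype=bool)
                if m.shape != (n,):
                    raise ValueError(f"{name} length {m.size} != {n} channels")
                setattr(self, name, m)
        if self.onset_s is not None and self.end_s is not None:
            dur = self.n_samples / self.rate
            if not (0 <= self.onset_s < self.end_s <= dur + 1e-9):
                raise ValueError(
                    f"need 0 <= onset ({self.onset_s}) < end ({self.end_s}) "
                    f"<= duration ({dur:.3f})"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class PatientMeta:
    """Per-patient outcome label and covariates.

    ``outcome`` follows the Engel/ILAE mapping: Engel I or ILAE 1-2 after at
    least 12 months is ``"success"``, anything worse is ``"failure"``.
    """

    patient_id: str
    outcome: str
    sex: str | None = None
    handedness: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("success", "failure"):
            raise ValueError(f"outcome must be success/failure, got {self.outcome!r}")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M/F, got {self.sex!r}")
        if self.handedness is not None and self.handedness not in ("L", "R"):
            raise ValueError(f"handedness must be L/R, got {self.handedness!r}")

    @property
    def y(self) -> int:
        return 1 if self.outcome == "success" else 0


# ---------------------------------------------------------------------------
# channel metadata TSV


def read_channels_tsv(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-style channels.tsv carrying ``name``, ``soz``, ``resected``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "soz", "resected"} - set(df.columns)
    if missing:
        raise ValueError(f"channels TSV {path} lacks columns {sorted(missing)}")
    return df


def write_channels_tsv(rec: Recording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": rec.channel_labels,
            "type": "SEEG",
            "soz": rec.soz_mask.astype(int),
            "resected": rec.resection_mask.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def _align_masks(rec: Recording, meta: pd.DataFrame) -> None:
    """Attach soz/resected masks from a channels table, in signal order."""
    table = meta.set_index("name")
    absent = [c for c in rec.channel_labels if c not in table.index]
    if absent:
        raise ValueError(f"channels present in signal but absent from TSV: {absent}")
    extra = [c for c in table.index if c not in rec.channel_labels]
    if extra:
        raise ValueError(f"channels listed in TSV but absent from signal: {extra}")
    rec.soz_mask = table.loc[rec.channel_labels, "soz"].to_numpy().astype(bool)
    rec.resection_mask = (
        table.loc[rec.channel_labels, "resected"].to_numpy().astype(bool)
    )


# ---------------------------------------------------------------------------
# HDF5 container (round-trip) and EDF (read only)


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording to the HDF5 container, bit-exactly."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("rate", data=float(rec.rate))
        f.create_dataset(
            "labels", data=np.array(rec.channel_labels, dtype=h5py.string_dtype())
        )
        g = f.create_group("masks")
        g.create_dataset("soz", data=rec.soz_mask)
        g.create_dataset("resected", data=rec.resection_mask)
        f.attrs["patient_id"] = rec.patient_id
        f.attrs["clamped"] = rec.clamped
        if rec.onset_s is not None:
            f.attrs["onset_s"] = rec.onset_s
        if rec.end_s is not None:
            f.attrs["end_s"] = rec.end_s


def _load_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            signal=f["signal"][()],
            rate=float(f["rate"][()]),
            channel_labels=[s.decode() if isinstance(s, bytes) else str(s)
                            for s in f["labels"][()]],
            onset_s=float(f.attrs["onset_s"]) if "onset_s" in f.attrs else None,
            end_s=float(f.attrs["end_s"]) if "end_s" in f.attrs else None,
            soz_mask=f["masks/soz"][()],
            resection_mask=f["masks/resected"][()],
            patient_id=str(f.attrs.get("patient_id", "")),
            clamped=bool(f.attrs.get("clamped", False)),
        )


def _load_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is optional
        raise ImportError(
            "reading EDF requires the optional dependency mne "
            "(pip install sozmark[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rates = {raw.info["sfreq"]}
    if len(rates) != 1:
        raise ValueError("non-uniform sampling rate in EDF")
    return Recording(
        signal=raw.get_data(),
        rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        patient_id=path.stem,
    )


def load_recording(signal_path: str | Path, meta_path: str | Path | None = None) -> Recording:
    """Load a Recording from EDF or the HDF5 container, plus a channels TSV.

    The TSV is mandatory for EDF (which carries no masks) and optional for
    HDF5 (which does); if given it overrides the container's masks.  Channels
    present in the signal but absent from the TSV raise ``ValueError``.
    """
    signal_path = Path(signal_path)
    if not signal_path.exists():
        raise FileNotFoundError(signal_path)
    suffix = signal_path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        rec = _load_hdf5(signal_path)
    elif suffix == ".edf":
        if meta_path is None:
            raise ValueError("EDF input requires a channels TSV (meta_path)")
        rec = _load_edf(signal_path)
    else:
        raise ValueError(f"unsupported signal format: {signal_path.suffix!r}")
    if meta_path is not None:
        _align_masks(rec, read_channels_tsv(meta_path))
    return rec


# ---------------------------------------------------------------------------
# figures and results


def render_heatmap(
    marker,
    resection_mask: np.ndarray,
    onset_window_index: int,
    out: str | Path,
    channel_labels: list[str] | None = None,
    cmap: str = "viridis",
    plain: bool = False,
) -> Path:
    """Render a channels x windows marker heatmap to PNG.

    Resected channels get red tick labels and a red side bar; the seizure
    onset window is marked with a dashed vertical line — the "EEG source
    imaging" view clinicians read against the resected contacts.  With
    ``plain=True`` only the matrix itself is drawn (no axes, colorbar or
    flags), so image rows map linearly onto channels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.asarray(marker.values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot render an empty marker matrix")
    n_ch, n_win = values.shape
    resection_mask = np.asarray(resection_mask, dtype=bool)

    if plain:
        fig = plt.figure(figsize=(4, 4), dpi=100)
        ax = fig.add_axes([0, 0, 1, 1])
        ax.imshow(values, aspect="auto", interpolation="nearest", cmap=cmap)
        ax.set_axis_off()
        out = Path(out)
        fig.savefig(out, dpi=100)
        plt.close(fig)
        return out

    fig, ax = plt.subplots(figsize=(8, max(2.5, 0.25 * n_ch)))
    im = ax.imshow(values, aspect="auto", interpolation="nearest", cmap=cmap)
    ax.set_xlabel("window")
    ax.set_ylabel("channel")
    ax.set_title(getattr(marker, "marker_id", "marker"))
    if channel_labels is not None:
        ax.set_yticks(range(n_ch))
        ax.set_yticklabels(channel_labels, fontsize=6)
    for i in np.flatnonzero(resection_mask):
        ax.plot(-0.7, i, marker="s", color="red", markersize=4, clip_on=False)
        if channel_labels is not None:
            ax.get_yticklabels()[i].set_color("red")
    if 0 <= onset_window_index < n_win:
        ax.axvline(onset_window_index, color="black", linestyle="--", linewidth=1)
    fig.colorbar(im, ax=ax, shrink=0.8)
    out = Path(out)
    fig.savefig(out, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return out


def save_marker_matrices(matrices: dict, path: str | Path) -> None:
    """Write a {marker_id: MarkerMatrix} mapping to one HDF5 file."""
    with h5py.File(path, "w") as f:
        for mid, mm in matrices.items():
            g = f.create_group(mid)
            g.create_dataset("values", data=mm.values)
            g.create_dataset("missing", data=mm.missing)
            g.attrs["normalized"] = bool(mm.normalized)


def load_marker_matrices(path: str | Path) -> dict:
    from .spectral_markers import MarkerMatrix

    out = {}
    with h5py.File(path, "r") as f:
        for mid in f:
            g = f[mid]
            out[mid] = MarkerMatrix(
                values=g["values"][()],
                marker_id=mid,
                normalized=bool(g.attrs["normalized"]),
                missing=g["missing"][()],
            )
    return out


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(results, out: str | Path) -> Path:
    """Serialize a collection of evaluation results to JSON, losslessly."""
    payload = _jsonable(list(results))
    out = Path(out)
    with open(out, "w") as f:
        json.dump(payload, f, indent=1)
    return out


def read_results(path: str | Path) -> list:
    with open(path) as f:
        return json.load(f)
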