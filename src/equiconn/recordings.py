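"""Recording container, file IO and artifact-free segment selection.

Two on-disk representations are supported:

* EDF (read-only; parsed with :mod:`mne`, physical units converted to µV,
  channels reordered to the canonical montage by label matching);
* a plain numeric matrix (TSV, one column per channel in montage order,
  one row per sample) next to a YAML sidecar describing the sampling rate,
  channel labels and per-recording metadata. This text format is also the
  write format.

Sample indexing is 0-based half-open throughout. Clean-segment selection is
a transparent amplitude rule standing in for the expert artifact screening
used on real recordings: maximal runs in which every channel stays within
``amplitude_limit`` µV of its own median, at least ``min_duration`` long.
Pre-annotated segments can be attached to a recording instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .montage import Montage, default_montage

POPULATIONS = ("sport", "non-sport")
CONDITIONS = ("home", "guest")


class RecordingFormatError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentSpec:
    start_sample: int
    end_sample: int  # half-open
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError(f"bad segment [{self.start_sample}, {self.end_sample})")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass(frozen=True)
class Recording:
    signal: np.ndarray  # (8, n_samples), µV
    fs: float
    montage: Montage
    subject_id: str = ""
    population: str = "non-sport"
    condition: str = "home"
    segment_annotations: Tuple[SegmentSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[0] != 8:
            raise RecordingFormatError(f"signal must be (8, n), got {sig.shape}")
        if not np.all(np.isfinite(sig)):
            raise RecordingFormatError("signal contains non-finite samples")
        if self.fs <= 0:
            raise RecordingFormatError(f"fs must be positive, got {self.fs}")
        if self.population not in POPULATIONS:
            raise RecordingFormatError(f"population must be one of {POPULATIONS}")
        if self.condition not in CONDITIONS:
            raise RecordingFormatError(f"condition must be one of {CONDITIONS}")
        object.__setattr__(self, "signal", sig)
        for seg in self.segment_annotations:
            if seg.end_sample > self.n_samples:
                raise RecordingFormatError(f"segment {seg} exceeds recording length")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_segments(self, segments: Sequence[SegmentSpec]) -> "Recording":
        return replace(self, segment_annotations=tuple(segments))


def write_recording(path, rec: Recording) -> Path:
    """Write a recording as TSV matrix + YAML sidecar.

    ``path`` is the matrix file; the sidecar is written next to it with a
    ``.yaml`` suffix. Returns the sidecar path.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raise RecordingFormatError(
            "EDF export is not supported; write the matrix+sidecar format instead"
        )
    np.savetxt(path, rec.signal.T, fmt="%.6f", delimiter="\t")
    sidecar = path.with_suffix(".yaml")
    meta = {
        "fs": float(rec.fs),
        "units": "uV",
        "channel_labels": rec.montage.labels,
        "subject_id": rec.subject_id,
        "population": rec.population,
        "condition": rec.condition,
        "segments": [
            {"start_sample": s.start_sample, "end_sample": s.end_sample, "label": s.label}
            for s in rec.segment_annotations
        ],
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    return sidecar


def _read_matrix(path: Path, montage: Montage) -> Recording:
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise RecordingFormatError(f"missing sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    if "fs" not in meta:
        raise RecordingFormatError(f"sidecar {sidecar} declares no sampling rate")
    data = np.loadtxt(path, delimiter="\t", ndmin=2).T
    if data.shape[0] != 8:
        raise RecordingFormatError(f"expected 8 channels, found {data.shape[0]} in {path}")
    labels = [str(l).lower() for l in meta.get("channel_labels", montage.labels)]
    data = _reorder(data, labels, montage, origin=str(path))
    segments = tuple(
        SegmentSpec(int(s["start_sample"]), int(s["end_sample"]), str(s.get("label", "")))
        for s in meta.get("segments", []) or []
    )
    return Recording(
        signal=data,
        fs=float(meta["fs"]),
        montage=montage,
        subject_id=str(meta.get("subject_id", path.stem)),
        population=str(meta.get("population", "non-sport")),
        condition=str(meta.get("condition", "home")),
        segment_annotations=segments,
    )


def _reorder(data: np.ndarray, labels: Sequence[str], montage: Montage, origin: str) -> np.ndarray:
    want = [l.lower() for l in montage.labels]
    if list(labels) == want:
        return data
    try:
        order = [labels.index(l) for l in want]
    except ValueError as exc:
        raise RecordingFormatError(
            f"{origin}: channel labels {labels} do not match montage {want}"
        ) from exc
    return data[order]


def _read_edf(path: Path, montage: Montage) -> Recording:
    import mne  # heavy import kept local

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if len(raw.ch_names) != 8:
        raise RecordingFormatError(f"expected 8 channels, found {len(raw.ch_names)} in {path}")
    data = raw.get_data() * 1e6  # Volts -> µV
    data = _reorder(data, [c.lower() for c in raw.ch_names], montage, origin=str(path))
    return Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        montage=montage,
        subject_id=path.stem,
    )


def read_recording(path, montage: Optional[Montage] = None) -> Recording:
    """Read an EDF or matrix+sidecar recording; channels end up in montage order."""
    path = Path(path)
    m = montage if montage is not None else default_montage()
    if not path.exists():
        raise RecordingFormatError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        return _read_edf(path, m)
    return _read_matrix(path, m)


def select_clean_segments(
    rec: Recording, amplitude_limit: float = 200.0, min_duration: float = 10.0
) -> List[SegmentSpec]:
    """Maximal artifact-free runs of at least ``min_duration`` seconds.

    A sample is clean when every channel's deviation from its own median is
    below ``amplitude_limit`` µV. Returns sorted, non-overlapping segments.
    """
    if amplitude_limit <= 0 or min_duration <= 0:
        raise ValueError("amplitude_limit and min_duration must be positive")
    dev = np.abs(rec.signal - np.median(rec.signal, axis=1, keepdims=True))
    clean = np.all(dev < amplitude_limit, axis=0)
    min_samples = int(round(min_duration * rec.fs))
    segments: List[SegmentSpec] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], clean.view(np.int8), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_samples:
            segments.append(SegmentSpec(int(start), int(end), "clean"))
    return segments


def analysis_segments(
    rec: Recording, amplitude_limit: float = 200.0, min_duration: float = 10.0
) -> List[SegmentSpec]:
    """Annotated segments if present, else the amplitude-rule selection."""
    if rec.segment_annotations:
        return list(rec.segment_annotations)
    return select_clean_segments(rec, amplitude_limit, min_duration)


def concatenate_segments(channel: np.ndarray, segments: Sequence[SegmentSpec]) -> np.ndarray:
    """Concatenate one channel's samples over a list of segments."""
    if not segments:
        raise ValueError("no segments to concatenate")
    return np.concatenate([channel[s.start_sample : s.end_sample] for s in segments])
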