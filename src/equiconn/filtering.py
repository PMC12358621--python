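"""Zero-phase Butterworth band decomposition.

Five conventional EEG bands: delta 0-4 Hz (pure lowpass, DC preserved —
the acquisition is full-band DC), theta 4-8, alpha 8-13, beta 13-30 and
gamma 30-120 Hz (bandpass). Filters are 3rd-order Butterworth designs with
normalized cutoffs Wn = f / (fs/2) applied forward-backward (filtfilt), so
the effective magnitude response is |H(f)|^2 and the net phase shift is
zero. At a band edge the forward-backward gain is therefore exactly 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import signal as sps

BAND_ORDER = 3

#: name -> (low_hz, high_hz, kind)
BAND_DEFINITIONS: Dict[str, Tuple[float, float, str]] = {
    "delta": (0.0, 4.0, "lowpass"),
    "theta": (4.0, 8.0, "bandpass"),
    "alpha": (8.0, 13.0, "bandpass"),
    "beta": (13.0, 30.0, "bandpass"),
    "gamma": (30.0, 120.0, "bandpass"),
}

BAND_NAMES = tuple(BAND_DEFINITIONS)


class FilterDesignError(ValueError):
    pass


@dataclass(frozen=True)
class BandSpec:
    name: str
    low_hz: float
    high_hz: float
    kind: str  # "lowpass" or "bandpass"

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise FilterDesignError(f"unknown filter kind {self.kind!r}")
        if not 0 <= self.low_hz < self.high_hz:
            raise FilterDesignError(
                f"band edges must satisfy 0 <= low < high, got [{self.low_hz}, {self.high_hz}]"
            )


def band(name_or_spec) -> BandSpec:
    """Resolve a band name, (low, high) tuple or BandSpec into a BandSpec."""
    if isinstance(name_or_spec, BandSpec):
        return name_or_spec
    if isinstance(name_or_spec, str):
        try:
            low, high, kind = BAND_DEFINITIONS[name_or_spec]
        except KeyError:
            raise FilterDesignError(f"unknown band {name_or_spec!r}") from None
        return BandSpec(name_or_spec, low, high, kind)
    low, high = name_or_spec
    kind = "lowpass" if low == 0 else "bandpass"
    return BandSpec(f"{low:g}-{high:g}Hz", float(low), float(high), kind)


@dataclass(frozen=True)
class FilterSpec:
    order: int
    wn: Tuple[float, ...]  # normalized cutoff(s), fraction of Nyquist
    kind: str
    b: np.ndarray  # numerator
    a: np.ndarray  # denominator

    @property
    def stable(self) -> bool:
        return bool(np.all(np.abs(np.roots(self.a)) < 1.0))


def design_filter(band_spec: BandSpec | str, fs: float, order: int = BAND_ORDER) -> FilterSpec:
    """Design the recursive Butterworth filter for one band at sampling rate fs."""
    spec = band(band_spec)
    nyquist = fs / 2.0
    if spec.high_hz >= nyquist:
        raise FilterDesignError(
            f"band {spec.name}: upper edge {spec.high_hz} Hz >= Nyquist {nyquist} Hz"
        )
    if spec.kind == "lowpass":
        wn: Tuple[float, ...] = (spec.high_hz / nyquist,)
        b, a = sps.butter(order, wn[0], btype="lowpass")
    else:
        wn = (spec.low_hz / nyquist, spec.high_hz / nyquist)
        b, a = sps.butter(order, wn, btype="bandpass")
    fspec = FilterSpec(order=order, wn=wn, kind=spec.kind, b=np.asarray(b), a=np.asarray(a))
    if not fspec.stable:
        raise FilterDesignError(f"unstable design for band {spec.name} at fs={fs}")
    return fspec


def zero_phase_filter(x: Sequence[float], fspec: FilterSpec) -> np.ndarray:
    """Forward-backward (zero-phase) application of a FilterSpec to a 1-D series.

    Edge transients are suppressed by odd-reflection padding of
    3*max(len(a), len(b)) samples at each end; the series must be longer
    than that pad.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("zero_phase_filter expects a 1-D series")
    padlen = 3 * max(len(fspec.a), len(fspec.b))
    if x.size <= padlen:
        raise ValueError(f"series of {x.size} samples too short for padlen {padlen}")
    return sps.filtfilt(fspec.b, fspec.a, x, padlen=padlen)


def band_filter(x, band_spec, fs: float) -> np.ndarray:
    """Convenience: design + zero-phase filter a 1-D series into one band."""
    return zero_phase_filter(np.asarray(x, dtype=float), design_filter(band_spec, fs))


def notch_filter(x, fs: float, freq_hz: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Optional mains notch (off by default everywhere in the pipeline:
    line-noise-contaminated segments are excluded rather than notched)."""
    b, a = sps.iirnotch(freq_hz, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))
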