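"""Rank-biserial correlation maps over the 28 electrode pairs.

The per-pair statistic is the two-sample rank-biserial correlation

    r = 2 U / (n_x n_y) - 1,

where U counts cross-pairs (x_i, y_j) with x_i > y_j, ties counted 1/2
(the Mann-Whitney U1 statistic). r is +1 when every x sample exceeds every
y sample, -1 in the opposite case and 0 for exchangeable samples — it
measures stochastic dominance of one channel's amplitude distribution over
the other's, which on full-band DC recordings is driven by sustained
potential offsets between sites. Percentile bootstrap intervals, per-cohort
median maps and home-guest difference maps complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .filtering import band, band_filter
from .montage import PairTable, build_pair_table
from .recordings import Recording, SegmentSpec, analysis_segments, concatenate_segments


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 3000
    seed: int = 0
    ci_level: float = 0.95
    paired: bool = False  # resample both series over the same indices
    block_length: Optional[int] = None  # moving-block bootstrap when set

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {self.n_boot}")
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0,1), got {self.ci_level}")


@dataclass(frozen=True)
class ConnectivityResult:
    band: str
    values: Dict[int, float]  # pair_index -> statistic
    ci: Dict[int, Tuple[float, float]] = field(default_factory=dict)
    subject_id: str = ""
    condition: str = ""


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U1 via the rank-sum identity (O(n log n)); ties contribute 1/2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def rank_biserial(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample rank-biserial correlation, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_biserial requires non-empty series")
    u = mann_whitney_u(x, y)
    return 2.0 * u / (x.size * y.size) - 1.0


def _resample_indices(rng: np.random.Generator, n: int, block_length: Optional[int]) -> np.ndarray:
    if block_length is None:
        return rng.integers(0, n, n)
    # moving-block bootstrap: concatenate random blocks, trim to n
    n_blocks = -(-n // block_length)
    starts = rng.integers(0, max(n - block_length + 1, 1), n_blocks)
    idx = (starts[:, None] + np.arange(block_length)[None, :]).ravel()[:n]
    return idx % n


def bootstrap_ci(
    x: Sequence[float], y: Sequence[float], cfg: BootstrapConfig
) -> Tuple[float, float]:
    """Percentile bootstrap interval for the rank-biserial statistic.

    Samples are resampled over time indices with replacement, independently
    for the two series by default (``cfg.paired`` reuses one index draw for
    both; ``cfg.block_length`` switches to a moving-block scheme for
    autocorrelated series). Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("bootstrap requires series of length >= 2")
    if cfg.paired and x.size != y.size:
        raise ValueError("paired resampling requires equal-length series")
    rng = np.random.default_rng(cfg.seed)
    stats = np.empty(cfg.n_boot)
    for i in range(cfg.n_boot):
        ix = _resample_indices(rng, x.size, cfg.block_length)
        iy = ix if cfg.paired else _resample_indices(rng, y.size, cfg.block_length)
        stats[i] = rank_biserial(x[ix], y[iy])
    tail = 100.0 * (1.0 - cfg.ci_level) / 2.0
    low, high = np.percentile(stats, [tail, 100.0 - tail])
    return float(low), float(high)


def correlation_map(
    rec: Recording,
    band_name: str,
    segments: Optional[Sequence[SegmentSpec]] = None,
    pair_table: Optional[PairTable] = None,
    bootstrap: Optional[BootstrapConfig] = None,
) -> ConnectivityResult:
    """Rank-biserial statistic for all 28 pairs of one band-filtered recording.

    Each segment is band-filtered on its own (no transient across segment
    joins) and the filtered samples are concatenated per channel.
    """
    segs = list(segments) if segments is not None else analysis_segments(rec)
    if not segs:
        raise ValueError(f"recording {rec.subject_id!r}: no clean segments to analyse")
    spec = band(band_name)
    table = pair_table if pair_table is not None else build_pair_table(rec.montage)
    filtered = np.stack(
        [
            np.concatenate(
                [band_filter(rec.signal[ch, s.start_sample : s.end_sample], spec, rec.fs) for s in segs]
            )
            for ch in range(8)
        ]
    )
    values: Dict[int, float] = {}
    ci: Dict[int, Tuple[float, float]] = {}
    for e in table:
        xa, xb = filtered[e.channel_a - 1], filtered[e.channel_b - 1]
        values[e.pair_index] = rank_biserial(xa, xb)
        if bootstrap is not None:
            ci[e.pair_index] = bootstrap_ci(xa, xb, bootstrap)
    return ConnectivityResult(
        band=spec.name, values=values, ci=ci, subject_id=rec.subject_id, condition=rec.condition
    )


def median_map(results: Sequence[ConnectivityResult]) -> Dict[int, float]:
    """Element-wise median over subjects (same band required)."""
    if not results:
        raise ValueError("median_map requires at least one result")
    bands = {r.band for r in results}
    if len(bands) > 1:
        raise ValueError(f"mixed bands in median_map: {sorted(bands)}")
    pairs = sorted(results[0].values)
    for r in results:
        if sorted(r.values) != pairs:
            raise ValueError("results cover different pair domains")
    return {p: float(np.median([r.values[p] for r in results])) for p in pairs}


def condition_difference(
    median_home: Dict[int, float], median_guest: Dict[int, float]
) -> Dict[int, float]:
    """home - guest per pair (the sign convention used in all outputs)."""
    if set(median_home) != set(median_guest):
        raise ValueError("pair domains differ between conditions")
    return {p: median_home[p] - median_guest[p] for p in sorted(median_home)}


def threshold_pairs(values: Dict[int, float], threshold: float = 0.8) -> List[int]:
    """Pairs whose statistic exceeds the significance threshold (strict)."""
    return [p for p, v in sorted(values.items()) if v > threshold]
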