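"""Grouped zero-lag correlation counts and rank-sum contrasts.

For each band-filtered channel pair the connectivity scalar is the
normalized cross-correlation at zero delay (a Pearson-type coefficient:
mean-removed inner product over the product of norms). Per subject, band
and spatial group, the fraction of member pairs whose coefficient meets
the 0.8 threshold (inclusive for this statistic) gives a normalized count
in [0, 1]; the home - guest difference of these counts is the habituation
signal. Two Wilcoxon rank-sum contrasts are run: sport vs non-sport on the
difference values (per band x group), and home vs guest within one
population (per group, one band). Delta is excluded from the grouped
analysis by default because broadly shared slow activity saturates every
group's count. No multiple-testing correction is applied by default; a
Benjamini-Hochberg switch is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .filtering import band, band_filter
from .montage import GROUP_LABELS, GroupScheme, PairTable, build_group_scheme, build_pair_table
from .recordings import Recording, SegmentSpec, analysis_segments

#: bands entering the grouped analysis (delta excluded)
GROUPED_BANDS = ("theta", "alpha", "beta", "gamma")

XCORR_THRESHOLD = 0.8


@dataclass(frozen=True)
class GroupCount:
    subject_id: str
    condition: str
    band: str
    counts: Dict[str, float]  # group label -> fraction in [0, 1]


@dataclass(frozen=True)
class ContrastResult:
    band: str
    group: str
    h: int
    p: float
    contrast_kind: str  # "population-difference" or "condition-within-population"


def zero_lag_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Normalized cross-correlation at zero delay, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("zero_lag_correlation expects two equal-length series of >= 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    nx = np.linalg.norm(xd)
    ny = np.linalg.norm(yd)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.clip(xd @ yd / (nx * ny), -1.0, 1.0))


def pairwise_zero_lag(
    rec: Recording,
    band_name: str,
    segments: Optional[Sequence[SegmentSpec]] = None,
    pair_table: Optional[PairTable] = None,
) -> Dict[int, float]:
    """Zero-lag correlation for all 28 pairs of one band-filtered recording."""
    segs = list(segments) if segments is not None else analysis_segments(rec)
    if not segs:
        raise ValueError(f"recording {rec.subject_id!r}: no clean segments")
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
    return {
        e.pair_index: zero_lag_correlation(filtered[e.channel_a - 1], filtered[e.channel_b - 1])
        for e in table
    }


def group_counts(
    rec: Recording,
    band_name: str,
    scheme: Optional[GroupScheme] = None,
    threshold: float = XCORR_THRESHOLD,
    segments: Optional[Sequence[SegmentSpec]] = None,
) -> GroupCount:
    """Normalized suprathreshold pair count per spatial group.

    A pair counts when its zero-lag correlation is >= ``threshold``; the
    denominator is the group's total pair count.
    """
    sch = scheme if scheme is not None else build_group_scheme(rec.montage)
    values = pairwise_zero_lag(rec, band_name, segments=segments)
    counts: Dict[str, float] = {}
    for g in GROUP_LABELS:
        members = sch.members(g)
        counts[g] = sum(values[p] >= threshold for p in members) / len(members)
    return GroupCount(
        subject_id=rec.subject_id, condition=rec.condition, band=band(band_name).name, counts=counts
    )


def condition_difference_counts(home: GroupCount, guest: GroupCount) -> Dict[str, float]:
    """home - guest normalized counts per group (same subject and band)."""
    if home.subject_id != guest.subject_id or home.band != guest.band:
        raise ValueError(
            f"mismatched counts: {home.subject_id}/{home.band} vs {guest.subject_id}/{guest.band}"
        )
    return {g: home.counts[g] - guest.counts[g] for g in GROUP_LABELS}


def ranksum_test(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> Tuple[int, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact null distribution when both samples have <= 10 values and no
    ties are present; otherwise the normal approximation with tie and
    continuity corrections. Returns (h, p) with h = 1 iff p < alpha.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ranksum_test requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return int(p < alpha), p


def _differences_by_subject(
    counts: Iterable[GroupCount], band_name: str
) -> Dict[str, Dict[str, float]]:
    """subject -> group -> (home - guest) for one band; incomplete subjects dropped."""
    by_subject: Dict[str, Dict[str, GroupCount]] = {}
    for gc in counts:
        if gc.band != band_name:
            continue
        by_subject.setdefault(gc.subject_id, {})[gc.condition] = gc
    diffs: Dict[str, Dict[str, float]] = {}
    for subject, conds in sorted(by_subject.items()):
        if "home" not in conds or "guest" not in conds:
            warnings.warn(
                f"subject {subject!r} lacks a condition for band {band_name}; dropped",
                stacklevel=2,
            )
            continue
        diffs[subject] = condition_difference_counts(conds["home"], conds["guest"])
    return diffs


def _bh_adjust(results: List[ContrastResult], alpha: float) -> List[ContrastResult]:
    ps = np.array([r.p for r in results])
    order = np.argsort(ps)
    m = ps.size
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, ps[i] * m / (rank_pos + 1))
        adj[i] = running
    return [
        ContrastResult(r.band, r.group, int(adj[i] < alpha), float(adj[i]), r.contrast_kind)
        for i, r in enumerate(results)
    ]


def population_contrast(
    nonsport_counts: Sequence[GroupCount],
    sport_counts: Sequence[GroupCount],
    bands: Sequence[str] = GROUPED_BANDS,
    groups: Sequence[str] = GROUP_LABELS,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> List[ContrastResult]:
    """Rank-sum sport vs non-sport on per-subject home-guest differences.

    One test per (band, group); with the default four bands and seven
    groups that is 28 tests. Subject order is irrelevant.
    """
    results: List[ContrastResult] = []
    for band_name in bands:
        ns = _differences_by_subject(nonsport_counts, band_name)
        sp = _differences_by_subject(sport_counts, band_name)
        if not ns or not sp:
            raise ValueError(f"band {band_name}: need subjects with both conditions in each population")
        for g in groups:
            h, p = ranksum_test(
                [d[g] for d in ns.values()], [d[g] for d in sp.values()], alpha=alpha
            )
            results.append(ContrastResult(band_name, g, h, p, "population-difference"))
    return _bh_adjust(results, alpha) if bh_correction else results


def condition_contrast(
    population_counts: Sequence[GroupCount],
    band_name: str,
    groups: Sequence[str] = GROUP_LABELS,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> List[ContrastResult]:
    """Rank-sum home vs guest counts within one population, per group."""
    home = [gc for gc in population_counts if gc.band == band_name and gc.condition == "home"]
    guest = [gc for gc in population_counts if gc.band == band_name and gc.condition == "guest"]
    if not home or not guest:
        raise ValueError(f"band {band_name}: need counts for both conditions")
    results = []
    for g in groups:
        h, p = ranksum_test(
            [gc.counts[g] for gc in home], [gc.counts[g] for gc in guest], alpha=alpha
        )
        results.append(ContrastResult(band_name, g, h, p, "condition-within-population"))
    return _bh_adjust(results, alpha) if bh_correction else results
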