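"""Synthetic 8-channel EEG cohorts with controlled cross-channel structure.

Each recording is built from three ingredients:

* a per-channel background of 1/f ("pink") noise plus a white floor,
  scaled to a realistic 10-50 µV peak-to-peak range;
* band-limited shared sources: within a source's frequency band the target
  channels carry sqrt(c) * shared + sqrt(1-c) * private content, so the
  shared-variance fraction c is exactly the expected zero-lag correlation
  of the band-filtered pair (and c^2 the expected in-band coherence). The
  background's own content in that band is first carved out of the target
  channels (three subtraction passes of the same zero-phase filter, so
  leakage into the band is <1% in power) and the injected mixture is
  scaled to the carved power, keeping the spectrum realistic;
* optional sustained potential shifts ("DC shifts"), expressed per channel
  in units of that channel's delta-band standard deviation. These emulate
  the slow interhemispheric potential asymmetries a full-band DC
  acquisition preserves in an unfamiliar environment; they move the
  rank-biserial (stochastic-dominance) statistic without affecting
  mean-removed correlations or nonzero-frequency coherence.

Sources and shifts are attached per (population, condition) recipe, so the
home/guest and sport/non-sport contrasts of the study design have known
ground truth. Generation is deterministic given (seed, population,
condition, subject): every recording draws from its own seeded stream.
The band filters used by the generator are the analysis filters
themselves, so generator and pipeline share one band definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import erf, sqrt
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .filtering import band, band_filter
from .montage import Montage, build_pair_table, default_montage
from .recordings import Recording

Population = str
Condition = str


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SourceSpec:
    """One band-limited shared source.

    ``coupling`` is the shared-variance fraction sigma_s^2 / (sigma_s^2 +
    sigma_n^2) on each target channel. ``band_spec`` is a band name or a
    (low_hz, high_hz) tuple. ``waveform`` is "bandlimited-noise" or
    "sinusoid" (then ``freq_hz`` is required). ``amplitude_uv`` overrides
    the carved-background scaling (useful with zero background).
    """

    band_spec: object
    channels: Tuple[int, ...]
    coupling: float
    waveform: str = "bandlimited-noise"
    freq_hz: Optional[float] = None
    amplitude_uv: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise SyntheticConfigError(f"coupling must be in [0,1], got {self.coupling}")
        if not set(self.channels) <= set(range(1, 9)):
            raise SyntheticConfigError(f"target channels must be within 1..8: {self.channels}")
        if self.waveform not in ("bandlimited-noise", "sinusoid"):
            raise SyntheticConfigError(f"unknown waveform {self.waveform!r}")
        if self.waveform == "sinusoid" and self.freq_hz is None:
            raise SyntheticConfigError("sinusoid source needs freq_hz")

    @property
    def band_interval(self) -> Tuple[float, float]:
        b = band(self.band_spec)
        return (b.low_hz, b.high_hz)


@dataclass(frozen=True)
class ConditionRecipe:
    sources: Tuple[SourceSpec, ...] = ()
    #: channel -> sustained shift in units of the channel's delta-band SD
    dc_shift_sd: Dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class BackgroundSpec:
    exponent: float = 1.0  # 1/f^exponent
    pink_uv: float = 4.0  # SD of the pink component, µV
    white_uv: float = 2.0  # SD of the white floor, µV


@dataclass(frozen=True)
class CohortSpec:
    recipes: Dict[Tuple[Population, Condition], ConditionRecipe]
    n_subjects: int = 5
    duration_s: float = 60.0
    fs: float = 1000.0
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    coupling_jitter: float = 0.05  # per-subject uniform jitter on coupling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s * self.fs < 2 * 2000:
            raise SyntheticConfigError(
                "recordings must span at least two Welch windows (4000 samples)"
            )
        for (pop, cond), recipe in self.recipes.items():
            for src in recipe.sources:
                low, high = src.band_interval
                if high >= self.fs / 2:
                    raise SyntheticConfigError(
                        f"source band {low}-{high} Hz exceeds Nyquist for fs={self.fs}"
                    )

    @property
    def populations(self) -> List[Population]:
        return sorted({pop for pop, _ in self.recipes})

    @property
    def conditions(self) -> List[Condition]:
        return sorted({cond for _, cond in self.recipes})


_POP_CODE = {"non-sport": 0, "sport": 1}
_COND_CODE = {"home": 0, "guest": 1}


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-SD 1/f^exponent noise via spectral shaping."""
    n_bins = n // 2 + 1
    spec = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros(n_bins)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _carve(x: np.ndarray, band_spec, fs: float, passes: int = 3) -> np.ndarray:
    """Remove a band from a series by repeated zero-phase subtraction."""
    r = x
    for _ in range(passes):
        r = r - band_filter(r, band_spec, fs)
    return r


def _unit_band_noise(rng: np.random.Generator, n: int, band_spec, fs: float) -> np.ndarray:
    s = band_filter(rng.standard_normal(n), band_spec, fs)
    sd = s.std()
    return s / sd if sd > 0 else s


def subject_id(population: Population, index: int) -> str:
    prefix = "sp" if population == "sport" else "ns"
    return f"{prefix}{index + 1:02d}"


def generate_recording(
    spec: CohortSpec,
    subject_index: int,
    population: Population,
    condition: Condition,
    montage: Optional[Montage] = None,
) -> Recording:
    """One deterministic synthetic recording for (subject, population, condition)."""
    key = (population, condition)
    if key not in spec.recipes:
        raise SyntheticConfigError(f"no recipe for {key}")
    recipe = spec.recipes[key]
    m = montage if montage is not None else default_montage()
    n = int(round(spec.duration_s * spec.fs))
    ss = np.random.SeedSequence(
        spec.seed,
        spawn_key=(_POP_CODE.get(population, 7), _COND_CODE.get(condition, 7), subject_index),
    )
    rng = np.random.default_rng(ss)

    # shared source signals and per-subject effective couplings, in recipe order
    shared: List[np.ndarray] = []
    couplings: List[float] = []
    for src in recipe.sources:
        if src.waveform == "sinusoid":
            phase = rng.uniform(0.0, 2.0 * np.pi)
            t = np.arange(n) / spec.fs
            s = np.sqrt(2.0) * np.sin(2.0 * np.pi * src.freq_hz * t + phase)
        else:
            s = _unit_band_noise(rng, n, src.band_spec, spec.fs)
        shared.append(s)
        jitter = rng.uniform(-spec.coupling_jitter, spec.coupling_jitter)
        couplings.append(float(np.clip(src.coupling + jitter, 0.0, 1.0)))

    bg = spec.background
    signal = np.zeros((8, n))
    for ch in range(1, 9):
        base = np.zeros(n)
        if bg.pink_uv > 0:
            base += bg.pink_uv * _pink_noise(rng, n, bg.exponent)
        if bg.white_uv > 0:
            base += bg.white_uv * rng.standard_normal(n)
        resid = base
        injected = np.zeros(n)
        band_amp: Dict[Tuple[float, float], float] = {}
        for src, s, c in zip(recipe.sources, shared, couplings):
            if ch not in src.channels:
                continue
            iv = src.band_interval
            if iv not in band_amp:
                # scale injections to the ORIGINAL background's band power so
                # overlapping sources inject at equal amplitude (the
                # variance-addition model ground_truth assumes)
                band_amp[iv] = float((base - _carve(base, src.band_spec, spec.fs)).std())
            resid = _carve(resid, src.band_spec, spec.fs)
            amp = src.amplitude_uv if src.amplitude_uv is not None else band_amp[iv]
            private = _unit_band_noise(rng, n, src.band_spec, spec.fs)
            injected += amp * (np.sqrt(c) * s + np.sqrt(1.0 - c) * private)
        signal[ch - 1] = resid + injected

    # sustained potential shifts, scaled per channel to its delta-band SD
    if recipe.dc_shift_sd:
        for ch, k in recipe.dc_shift_sd.items():
            sd = band_filter(signal[ch - 1], "delta", spec.fs).std()
            signal[ch - 1] = signal[ch - 1] + k * sd

    return Recording(
        signal=signal,
        fs=spec.fs,
        montage=m,
        subject_id=subject_id(population, subject_index),
        population=population,
        condition=condition,
    )


def generate_cohort(
    spec: CohortSpec,
    population: Optional[Population] = None,
    condition: Optional[Condition] = None,
) -> List[Recording]:
    """All recordings of a cohort, optionally restricted to one population/condition."""
    recs = []
    for pop, cond in sorted(spec.recipes):
        if population is not None and pop != population:
            continue
        if condition is not None and cond != condition:
            continue
        for i in range(spec.n_subjects):
            recs.append(generate_recording(spec, i, pop, cond))
    return recs


# ---------------------------------------------------------------------------
# presets

#: channels carrying the interhemispheric alpha source (covers two H1, both
#: H4 and both V3 pairs)
_ALPHA_SET = (1, 4, 5, 8)
#: right occipitotemporal slow source (pair 9): a 0-3.5 Hz lowpass source, so
#: the sub-Hz background (whose spectral leakage would otherwise dilute the
#: 1 Hz coherence bin) is carved and replaced by coupled content
_PAIR9_BAND = (0.0, 3.5)
#: occipital slow-potential asymmetry, in delta-band SD units
_GUEST_DC = {4: 1.3, 5: -1.3}


def default_presets(n_subjects: int = 5, duration_s: float = 60.0, seed: int = 0) -> CohortSpec:
    """Cohort emulating the qualitative home/guest study structure.

    Guest condition (both populations): strong occipitotemporal slow-wave
    coupling on channels (2, 4) -> suprathreshold 1-3 Hz coherence at pair
    9; occipital slow-potential asymmetry on channels (4, 5) -> the
    rank-biserial delta map peaks above 0.8 at pair 19. Non-sport horses
    additionally recruit a strong interhemispheric alpha source only in
    the guest box, so their home-guest group-count differences spread out;
    sport horses keep the same weak alpha coupling in both boxes
    (habituation), so their differences stay near zero.
    """
    pair9 = lambda c: SourceSpec(_PAIR9_BAND, (2, 4), c)
    alpha = lambda c: SourceSpec("alpha", _ALPHA_SET, c)
    recipes = {
        ("non-sport", "home"): ConditionRecipe(sources=(pair9(0.25), alpha(0.2))),
        ("non-sport", "guest"): ConditionRecipe(
            sources=(pair9(0.95), alpha(0.9)), dc_shift_sd=dict(_GUEST_DC)
        ),
        ("sport", "home"): ConditionRecipe(sources=(pair9(0.25), alpha(0.2))),
        ("sport", "guest"): ConditionRecipe(
            sources=(pair9(0.95), alpha(0.2)), dc_shift_sd=dict(_GUEST_DC)
        ),
    }
    return CohortSpec(recipes=recipes, n_subjects=n_subjects, duration_s=duration_s, seed=seed)


def coupled_pair_spec(
    coupling: float,
    band_spec="delta",
    channels: Tuple[int, int] = (4, 5),
    n_subjects: int = 6,
    duration_s: float = 60.0,
    seed: int = 0,
    population: Population = "non-sport",
    condition: Condition = "home",
) -> CohortSpec:
    """Single-source cohort for parameter-recovery experiments."""
    recipe = ConditionRecipe(sources=(SourceSpec(band_spec, tuple(channels), coupling),))
    return CohortSpec(
        recipes={(population, condition): recipe},
        n_subjects=n_subjects,
        duration_s=duration_s,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# analytic expectations


def _phi(z: float) -> float:
    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


def _overlaps(a: Tuple[float, float], b: Tuple[float, float]) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) > 0


def ground_truth(spec: CohortSpec) -> Dict[Tuple[Population, Condition], dict]:
    """Closed-form expectations for every pair touched by a source.

    Per (population, condition) recipe and per distinct source band:

    * ``zero_lag``: expected zero-lag correlation of the pair filtered in
      that band — the coupling c for a single shared source, and the
      variance-addition combination sum(c_s) / sqrt(k_a k_b) when several
      sources with overlapping bands load the two channels (equal injected
      amplitudes assumed, as the generator scales each injection to the
      carved background power);
    * ``msc``: the squared expected correlation (in-band coherence);
    * ``rank_biserial_delta``: 2*Phi(dk / sqrt(2)) - 1 for a sustained
      shift difference of dk delta-band SDs between the two channels.

    Pairs without any source or shift are expected at zero and omitted.
    """
    table = build_pair_table(default_montage())
    out: Dict[Tuple[Population, Condition], dict] = {}
    for key, recipe in spec.recipes.items():
        bands = []
        for src in recipe.sources:
            iv = src.band_interval
            if iv not in bands:
                bands.append(iv)
        zero_lag: Dict[Tuple[float, float], Dict[int, float]] = {}
        msc_exp: Dict[Tuple[float, float], Dict[int, float]] = {}
        for iv in bands:
            corr_map: Dict[int, float] = {}
            for e in table:
                a, b = e.channel_a, e.channel_b
                num = sum(
                    c.coupling
                    for c in recipe.sources
                    if a in c.channels and b in c.channels and _overlaps(c.band_interval, iv)
                )
                var_a = sum(
                    1 for c in recipe.sources if a in c.channels and _overlaps(c.band_interval, iv)
                )
                var_b = sum(
                    1 for c in recipe.sources if b in c.channels and _overlaps(c.band_interval, iv)
                )
                if num > 0 and var_a > 0 and var_b > 0:
                    corr_map[e.pair_index] = num / sqrt(var_a * var_b)
            if corr_map:
                zero_lag[iv] = corr_map
                msc_exp[iv] = {p: v * v for p, v in corr_map.items()}
        rb: Dict[int, float] = {}
        for e in table:
            dk = recipe.dc_shift_sd.get(e.channel_a, 0.0) - recipe.dc_shift_sd.get(
                e.channel_b, 0.0
            )
            if dk != 0.0:
                rb[e.pair_index] = 2.0 * _phi(dk / sqrt(2.0)) - 1.0
        out[key] = {"zero_lag": zero_lag, "msc": msc_exp, "rank_biserial_delta": rb}
    return out
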