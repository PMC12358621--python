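"""Shared fixtures: montage objects and session-scoped synthetic cohorts."""

import numpy as np
import pytest

import equiconn as eq

COHORT_SEED = 20250925 % (2**16)


@pytest.fixture(scope="session")
def montage():
    return eq.default_montage()


@pytest.fixture(scope="session")
def pair_table(montage):
    return eq.build_pair_table(montage)


@pytest.fixture(scope="session")
def scheme(montage):
    return eq.build_group_scheme(montage)


@pytest.fixture(scope="session")
def preset_spec():
    return eq.default_presets(n_subjects=5, duration_s=60.0, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def preset_cohorts(preset_spec):
    """All four (population, condition) cohorts of the default presets."""
    return {
        (pop, cond): [
            eq.generate_recording(preset_spec, i, pop, cond)
            for i in range(preset_spec.n_subjects)
        ]
        for pop in ("non-sport", "sport")
        for cond in ("home", "guest")
    }


@pytest.fixture(scope="session")
def preset_group_counts(preset_cohorts):
    """Per-population group counts for the non-delta bands, both conditions."""
    counts = {"non-sport": [], "sport": []}
    for (pop, _cond), recs in preset_cohorts.items():
        for rec in recs:
            for band_name in eq.GROUPED_BANDS:
                counts[pop].append(eq.group_counts(rec, band_name))
    return counts


def flat_recording(montage, signal, fs=1000.0, **meta):
    """Recording from a raw (8, n) array with default metadata."""
    return eq.Recording(signal=np.asarray(signal, dtype=float), fs=fs, montage=montage, **meta)
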