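import numpy as np
import pytest

from biletree import (
    NOISE_FREE,
    Spectrum,
    builtin_tree,
    default_dihydroxy_profiles,
    generate_benchmark,
    normalize,
)


def make_spectrum(peaks, scan_id="s1", precursor_mz=500.0):
    """Build a Spectrum from a list of (mz, intensity) pairs."""
    mz = [p[0] for p in peaks]
    inten = [p[1] for p in peaks]
    return Spectrum.from_arrays(scan_id, precursor_mz, mz, inten)


def make_relative(peaks, scan_id="s1", precursor_mz=500.0):
    return normalize(make_spectrum(peaks, scan_id, precursor_mz))


@pytest.fixture(scope="session")
def dihydroxy_tree():
    return builtin_tree("dihydroxy")


@pytest.fixture(scope="session")
def profiles():
    return default_dihydroxy_profiles()


@pytest.fixture(scope="session")
def noise_free_benchmark(profiles):
    """20 noise-free spectra per shipped profile, with ground-truth labels."""
    spectra, labels = generate_benchmark(profiles, 20, NOISE_FREE, seed=2024)
    return [normalize(s) for s in spectra], labels
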