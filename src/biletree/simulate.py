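"""Labelled synthetic bile-acid-like MS/MS spectra.

The generator produces spectra with the *structure* the filtering trees key
on — hydroxylation-class ions, low-intensity diagnostic ion pairs with
controlled intensity ratios, a ketone marker where appropriate — under a
configurable noise model: log-normal intensity scatter, m/z jitter,
intensity-dependent peak dropout (emulating the inconsistent detection of
very low-intensity marker ions) and uniform chemical-noise peaks.

These profiles are test fixtures and sensitivity-analysis levers, not claims
about real fragmentation chemistry; the shipped defaults mirror the terminal
bins of the shipped dihydroxy tree. All randomness flows from one explicit
seed and output is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .spectra import Spectrum, write_mgf

__all__ = [
    "IsomerProfile",
    "NoiseModel",
    "NOISE_FREE",
    "generate_spectrum",
    "generate_benchmark",
    "load_profiles",
    "default_dihydroxy_profiles",
]

#: Mean relative intensity (percent of base peak) given to class ions.
CLASS_ION_INTENSITY = 50.0


@dataclass(frozen=True)
class IsomerProfile:
    """Template for spectra of one isomer bin.

    ``ratio_constraints`` entries (numerator_mz, denominator_mz, ratio) pin
    the numerator's mean intensity to ratio × the denominator's mean, so the
    constraint holds exactly in the noise-free limit and in expectation on
    the log scale under noise.
    """

    bin_label: str
    precursor_mz: float
    diagnostic_ions: tuple[tuple[float, float], ...]
    class_ions: tuple[float, ...] = ()
    ratio_constraints: tuple[tuple[float, float, float], ...] = ()
    hydroxylation_level: str = "di"
    conjugate: str | None = None

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.diagnostic_ions] + list(self.class_ions)
        if len(set(mzs)) != len(mzs):
            raise ValueError(f"profile {self.bin_label!r}: duplicate ion m/z")
        for _, inten in self.diagnostic_ions:
            if not 0 < inten <= 100:
                raise ValueError(f"profile {self.bin_label!r}: mean intensity must be in (0, 100]")

    def mean_ions(self) -> list[tuple[float, float]]:
        """Resolved (mz, mean intensity) list with ratio constraints applied."""
        means = {mz: inten for mz, inten in self.diagnostic_ions}
        for mz in self.class_ions:
            means[mz] = CLASS_ION_INTENSITY
        for num, den, ratio in self.ratio_constraints:
            if den not in means:
                raise ValueError(f"profile {self.bin_label!r}: ratio denominator {den} not among ions")
            means[num] = means[den] * ratio
        return sorted(means.items())


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic distortions applied to a profile's ideal peak list.

    ``dropout_max_prob``/``dropout_scale`` parameterise the monotone
    non-increasing dropout curve p(I) = p_max · exp(−I / scale): weak peaks
    vanish often, strong ones rarely — mirroring the unreliable detection of
    low-intensity diagnostic ions at low sample concentration.
    """

    intensity_cv: float = 0.25
    n_noise_peaks: int = 15
    noise_mz_range: tuple[float, float] = (150.0, 500.0)
    noise_max_rel_intensity: float = 5.0
    dropout_max_prob: float = 0.2
    dropout_scale: float = 10.0
    mz_jitter_sd: float = 0.002

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_max_prob <= 1:
            raise ValueError("dropout_max_prob must be in [0, 1]")
        if self.mz_jitter_sd < 0 or self.intensity_cv < 0 or self.n_noise_peaks < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.dropout_scale <= 0:
            raise ValueError("dropout_scale must be positive")

    def dropout_prob(self, rel_intensity: float) -> float:
        """Dropout probability for a peak of the given relative intensity."""
        return self.dropout_max_prob * math.exp(-rel_intensity / self.dropout_scale)


#: The deterministic limit: exact profile peaks, nothing added or removed.
NOISE_FREE = NoiseModel(
    intensity_cv=0.0,
    n_noise_peaks=0,
    noise_max_rel_intensity=5.0,
    dropout_max_prob=0.0,
    mz_jitter_sd=0.0,
)


def generate_spectrum(
    profile: IsomerProfile,
    noise: NoiseModel,
    rng: np.random.Generator,
    scan_id: str = "1",
) -> tuple[Spectrum, str]:
    """Sample one spectrum from a profile; returns (spectrum, true bin label).

    Peak intensities are perturbed multiplicatively by a log-normal factor
    with the requested coefficient of variation, m/z values get Gaussian
    jitter, each peak then survives a Bernoulli dropout trial with
    probability ``noise.dropout_prob(sampled intensity)``, and uniform noise
    peaks are appended. The profile's ions are always retained when the noise
    model is fully disabled.
    """
    sigma = math.sqrt(math.log(1.0 + noise.intensity_cv**2)) if noise.intensity_cv > 0 else 0.0
    mzs: list[float] = []
    intens: list[float] = []
    for mz, mean in profile.mean_ions():
        inten = mean * (math.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0) if sigma else 1.0)
        jmz = mz + (rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0)
        if rng.random() < noise.dropout_prob(inten):
            continue
        mzs.append(jmz)
        intens.append(inten)
    for _ in range(noise.n_noise_peaks):
        lo, hi = noise.noise_mz_range
        mzs.append(float(rng.uniform(lo, hi)))
        intens.append(float(rng.uniform(0.0, noise.noise_max_rel_intensity)) + 1e-6)
    if not mzs:  # every peak dropped: keep the strongest profile ion
        mz, mean = max(profile.mean_ions(), key=lambda t: t[1])
        mzs, intens = [mz], [mean]
    spectrum = Spectrum.from_arrays(scan_id, profile.precursor_mz, mzs, intens, charge=1)
    return spectrum, profile.bin_label


def generate_benchmark(
    profiles: Sequence[IsomerProfile],
    n_per_profile: int,
    noise: NoiseModel,
    seed: int,
    mgf_path: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate a labelled benchmark set; optionally write MGF + labels TSV.

    The labels table (scan_id, true_label, hydroxylation_level, conjugate) is
    directly consumable by the FDR evaluation alongside the MGF.
    """
    if n_per_profile < 1:
        raise ValueError("n_per_profile must be at least 1")
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    rows = []
    scan = 0
    for profile in profiles:
        for _ in range(n_per_profile):
            scan += 1
            spectrum, label = generate_spectrum(profile, noise, rng, scan_id=str(scan))
            spectra.append(spectrum)
            rows.append(
                {
                    "scan_id": str(scan),
                    "true_label": label,
                    "hydroxylation_level": profile.hydroxylation_level,
                    "conjugate": profile.conjugate or "",
                }
            )
    labels = pd.DataFrame(rows, columns=["scan_id", "true_label", "hydroxylation_level", "conjugate"])
    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if labels_path is not None:
        labels.to_csv(labels_path, sep="\t", index=False)
    return spectra, labels


def _profile_from_mapping(raw: Mapping) -> IsomerProfile:
    return IsomerProfile(
        bin_label=str(raw["bin_label"]),
        precursor_mz=float(raw["precursor_mz"]),
        diagnostic_ions=tuple((float(mz), float(i)) for mz, i in raw.get("diagnostic_ions", [])),
        class_ions=tuple(float(mz) for mz in raw.get("class_ions", [])),
        ratio_constraints=tuple(
            (float(n), float(d), float(r)) for n, d, r in raw.get("ratio_constraints", [])
        ),
        hydroxylation_level=str(raw.get("hydroxylation_level", "di")),
        conjugate=raw.get("conjugate"),
    )


def load_profiles(source: str | Path | Mapping) -> list[IsomerProfile]:
    """Load isomer profiles from a YAML file path or a parsed mapping."""
    if isinstance(source, Mapping):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    return [_profile_from_mapping(p) for p in raw["profiles"]]


def default_dihydroxy_profiles() -> list[IsomerProfile]:
    """The shipped profiles mirroring the dihydroxy tree's terminal bins."""
    ref = resources.files("biletree").joinpath("configs/profiles_dihydroxy.yaml")
    return load_profiles(yaml.safe_load(ref.read_text()))
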