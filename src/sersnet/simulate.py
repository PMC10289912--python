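"""Synthetic serum SERS spectrum generator.

Emulates the statistical structure of 4-group serum SERS datasets so that
every downstream stage (preprocessing, augmentation, CNN training, Grad-CAM
interpretation) can be exercised without measured sera. Each group is defined
by a :class:`GroupProfile`: mean amplitudes over the 17 prominent serum peaks,
plus per-sample amplitude jitter, a smooth degree-<=5 polynomial fluorescence
baseline, a per-spectrum log-normal multiplicative gain (the sample-to-sample
SERS intensity variability that per-spectrum min-max normalisation is meant
to remove) and additive white noise. Peaks are Lorentzian by default —
the natural line shape of Raman bands — with Gaussian available.

The default group profiles encode the direction of the reported serum
differences: relative to healthy controls, bladder cancer (BC) raises
494/589/639/1135 cm^-1 and lowers 1443; adrenal cancer (AC) raises
531/589/1135 and lowers 959/1443; acute myeloid leukemia (AML) raises
531/1206/1443 and lowers 1073/1654. The +/-25% default effect size is a free
simulation parameter, not a claim about sera.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io import CLASS_ORDER, PeakLexicon, Spectrum, SpectrumSet

__all__ = [
    "GroupProfile",
    "SimConfig",
    "default_profiles",
    "simulate",
    "make_fixture",
    "BASE_AMPLITUDES",
    "GROUP_MODULATIONS",
]

# Mean peak heights (a.u.) shared by all groups before modulation. Relative
# magnitudes loosely follow serum SERS practice (strong phenylalanine 1004,
# adenine 725, CH2 1443; weaker mid-range bands); absolute scale is arbitrary.
BASE_AMPLITUDES: dict[float, float] = {
    494.0: 0.50,
    531.0: 0.45,
    589.0: 0.60,
    639.0: 0.55,
    725.0: 0.90,
    812.0: 0.40,
    887.0: 0.50,
    959.0: 0.55,
    1004.0: 1.00,
    1073.0: 0.60,
    1093.0: 0.50,
    1135.0: 0.55,
    1206.0: 0.50,
    1330.0: 0.70,
    1443.0: 0.75,
    1581.0: 0.60,
    1654.0: 0.65,
}

# Signed per-peak modulation: +1 raised relative to healthy, -1 lowered.
GROUP_MODULATIONS: dict[str, dict[float, int]] = {
    "healthy": {},
    "BC": {494.0: +1, 589.0: +1, 639.0: +1, 1135.0: +1, 1443.0: -1},
    "AC": {531.0: +1, 589.0: +1, 1135.0: +1, 959.0: -1, 1443.0: -1},
    "AML": {531.0: +1, 1206.0: +1, 1443.0: +1, 1073.0: -1, 1654.0: -1},
}

# Degree-5 polynomial baseline in the normalised coordinate u in [0, 1]:
# a broad positive fluorescence hump. Degree 5 on purpose, so the iterative
# fifth-order baseline-removal stage can in principle remove it exactly.
DEFAULT_BASELINE_COEFFS = (0.8, 2.4, -1.5, -2.0, 1.0, 0.3)


@dataclass
class GroupProfile:
    """Statistical description of one diagnostic group's spectra."""

    group: str
    peak_amplitudes: dict[float, float]
    amplitude_cv: float = 0.08
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE_COEFFS
    gain_sigma: float = 0.15
    noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        if min(self.amplitude_cv, self.gain_sigma, self.noise_sigma) < 0:
            raise ConfigError("all profile sigmas must be >= 0")
        if len(self.baseline_coeffs) > 6:
            raise ConfigError("baseline polynomial degree must be <= 5")


@dataclass
class SimConfig:
    """Simulation layout: axis, group sizes, replicates, line shape, seed."""

    wn_min: float = 400.0
    wn_max: float = 1800.0
    n_points: int = 2046
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"healthy": 30, "BC": 30, "AC": 30, "AML": 20}
    )
    replicates_per_sample: int = 5
    peak_width_fwhm: float = 14.0
    peak_shape: str = "lorentzian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_width_fwhm <= 0:
            raise ConfigError("peak_width_fwhm must be positive")
        if self.peak_shape not in ("lorentzian", "gaussian"):
            raise ConfigError(f"unknown peak_shape {self.peak_shape!r}")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be >= 1")
        if self.replicates_per_sample < 1:
            raise ConfigError("replicates_per_sample must be >= 1")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.wn_min, self.wn_max, self.n_points)


def default_profiles(
    modulation: float = 0.25,
    lexicon: PeakLexicon | None = None,
    **overrides,
) -> dict[str, GroupProfile]:
    """Build the four default group profiles.

    Parameters
    ----------
    modulation
        Fractional amplitude shift applied at each group's modulated peaks
        (raised peaks get ``1 + modulation``, lowered ``1 - modulation``).
        0 makes all four profiles identical.
    overrides
        Passed through to every :class:`GroupProfile` (e.g. ``noise_sigma``).
    """
    lexicon = lexicon or PeakLexicon.default()
    base = {p: BASE_AMPLITUDES[p] for p in lexicon.positions if p in BASE_AMPLITUDES}
    if len(base) != len(lexicon):
        base = dict(zip(lexicon.positions, [0.5] * len(lexicon)))
    profiles = {}
    for group in CLASS_ORDER:
        amps = dict(base)
        for pos, sign in GROUP_MODULATIONS.get(group, {}).items():
            if pos in amps:
                amps[pos] = amps[pos] * (1.0 + sign * modulation)
        profiles[group] = GroupProfile(group=group, peak_amplitudes=amps, **overrides)
    return profiles


def _lineshape(axis: np.ndarray, pos: float, fwhm: float, shape: str) -> np.ndarray:
    if shape == "lorentzian":
        half = fwhm / 2.0
        return half**2 / ((axis - pos) ** 2 + half**2)
    return np.exp(-4.0 * np.log(2.0) * (axis - pos) ** 2 / fwhm**2)


def _baseline(axis: np.ndarray, coeffs: tuple[float, ...]) -> np.ndarray:
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    return np.polynomial.polynomial.polyval(u, coeffs)


def simulate(
    config: SimConfig, profiles: dict[str, GroupProfile] | None = None
) -> SpectrumSet:
    """Draw a replicate-level synthetic dataset.

    For each sample the per-peak amplitudes are jittered once
    (``mean * (1 + cv * z)``, truncated at 0); each replicate is then
    ``gain * (sum of peaks + baseline) + noise`` with a per-replicate
    log-normal gain, clipped at zero. Deterministic given ``config.seed``.
    """
    profiles = profiles if profiles is not None else default_profiles()
    for group in config.group_sizes:
        if group not in profiles:
            raise ConfigError(f"group {group!r} has no profile")
    rng = np.random.default_rng(config.seed)
    axis = config.axis
    spectra: list[Spectrum] = []
    for group in config.group_sizes:
        prof = profiles[group]
        positions = sorted(prof.peak_amplitudes)
        shapes = np.stack(
            [
                _lineshape(axis, p, config.peak_width_fwhm, config.peak_shape)
                for p in positions
            ]
        )
        means = np.asarray([prof.peak_amplitudes[p] for p in positions])
        base = _baseline(axis, prof.baseline_coeffs)
        for i in range(config.group_sizes[group]):
            sid = f"{group}-{i + 1:03d}"
            amps = means * np.maximum(
                0.0, 1.0 + prof.amplitude_cv * rng.standard_normal(len(means))
            )
            clean = amps @ shapes + base
            for rep in range(1, config.replicates_per_sample + 1):
                gain = np.exp(prof.gain_sigma * rng.standard_normal())
                noisy = gain * clean + prof.noise_sigma * rng.standard_normal(
                    len(axis)
                )
                spectra.append(
                    Spectrum(axis, np.maximum(noisy, 0.0), sid, rep, group)
                )
    return SpectrumSet(spectra, axis)


def make_fixture(size: str = "tiny", seed: int = 0, **profile_overrides) -> SpectrumSet:
    """Canned datasets for tests and examples.

    ``tiny`` — 6 samples per group on a 256-point axis, 3 replicates each;
    ``paper_scale`` — 30/30/30/20 samples, 5 replicates, default 2046-point
    axis. Both are replicate-level sets; collapse with
    :func:`sersnet.io.average_replicates` for sample-level data.
    """
    if size == "tiny":
        cfg = SimConfig(
            n_points=256,
            group_sizes={g: 6 for g in CLASS_ORDER},
            replicates_per_sample=3,
            seed=seed,
        )
    elif size == "paper_scale":
        cfg = SimConfig(seed=seed)
    else:
        raise ConfigError(f"unknown fixture size {size!r}")
    return simulate(cfg, default_profiles(**profile_overrides))
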