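import numpy as np
import pytest

import sersnet as sn


@pytest.fixture(scope="session")
def tiny_replicates() -> sn.SpectrumSet:
    """Replicate-level 4-group fixture on a 256-point axis."""
    return sn.make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_samples(tiny_replicates) -> sn.SpectrumSet:
    return sn.average_replicates(tiny_replicates)


TOY_MARKERS = {"healthy": 1004.0, "BC": 1330.0}


def two_class_toy(
    n_per_class: int = 16,
    n_points: int = 128,
    jitter: float = 0.0,
    seed: int = 0,
) -> sn.SpectrumSet:
    """Two classes, each carrying one private marker peak plus a shared band.

    Class ``healthy`` has a peak at 1004 1/cm that ``BC`` lacks, and vice
    versa at 1330 1/cm; both share a reference band at 725. Each class
    therefore differs from the other only at its marker position, and the
    marker is *positive* evidence for its class (a raised peak), which
    gradient-based attribution can localise.
    """
    rng = np.random.default_rng(seed)
    axis = np.linspace(400.0, 1800.0, n_points)

    def lorentz(pos, fwhm=30.0):
        half = fwhm / 2
        return half**2 / ((axis - pos) ** 2 + half**2)

    common = 0.8 * lorentz(725.0)
    spectra = []
    for label, marker in TOY_MARKERS.items():
        for i in range(n_per_class):
            a = 0.8 * (1 + jitter * rng.standard_normal())
            y = a * lorentz(marker) + common + 0.05
            spectra.append(sn.Spectrum(axis, y, f"{label}-{i}", None, label))
    return sn.SpectrumSet(spectra, axis, class_names=("healthy", "BC"))


@pytest.fixture(scope="session")
def separable_toy() -> sn.SpectrumSet:
    return two_class_toy(jitter=0.05, seed=3)


MARKER_PEAKS = {"healthy": 1004.0, "BC": 1330.0, "AC": 639.0, "AML": 1581.0}


def four_class_marker_toy(
    n_per_class: int = 16,
    n_points: int = 512,
    jitter: float = 0.05,
    seed: int = 1,
) -> sn.SpectrumSet:
    """Four classes, each with one private marker peak plus a shared band.

    Every class differs from the others only at its own raised marker, so
    each class's discriminative evidence is positive and localised — the
    construction gradient-based attribution is expected to recover. (With
    only two classes the softmax logits are complementary and one class's
    evidence can collapse onto the other's detectors; four classes avoid
    that degeneracy.)
    """
    rng = np.random.default_rng(seed)
    axis = np.linspace(400.0, 1800.0, n_points)

    def lorentz(pos, fwhm=30.0):
        half = fwhm / 2
        return half**2 / ((axis - pos) ** 2 + half**2)

    common = 0.8 * lorentz(725.0)
    spectra = []
    for label, marker in MARKER_PEAKS.items():
        for i in range(n_per_class):
            a = 0.8 * (1 + jitter * rng.standard_normal())
            y = a * lorentz(marker) + common + 0.05
            spectra.append(sn.Spectrum(axis, y, f"{label}-{i}", None, label))
    return sn.SpectrumSet(spectra, axis)
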