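import dataclasses

import numpy as np
import pytest

import lenscurve as lc


def ellipse_points(a, b, theta, cx, cy, angles):
    """Exact points on a rotated, translated ellipse at parameter angles."""
    t = np.asarray(angles, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    x = cx + a * np.cos(t) * c - b * np.sin(t) * s
    y = cy + a * np.cos(t) * s + b * np.sin(t) * c
    return np.column_stack([x, y])


def ellipse_coefficients(a, b, theta, cx, cy):
    """Unit-norm conic coefficients of the same ellipse, by direct expansion."""
    c, s = np.cos(theta), np.sin(theta)
    # ((X c + Y s)/a)^2 + ((-X s + Y c)/b)^2 = 1 with X = x - cx, Y = y - cy
    A = (c / a) ** 2 + (s / b) ** 2
    B = 2 * c * s * (1 / a**2 - 1 / b**2)  # coefficient of X Y
    C = (s / a) ** 2 + (c / b) ** 2
    # expand around the centre
    g2 = -A * cx - B / 2 * cy
    f2 = -B / 2 * cx - C * cy
    n = A * cx**2 + B * cx * cy + C * cy**2 - 1
    return lc.ConicCoefficients.from_array([A, B / 2, C, g2, f2, n])


def profiles_without_subject_noise():
    """Default response profiles with zero between/within-subject variation."""
    return {
        g: dataclasses.replace(p, between_subject_sd=0.0, within_subject_sd=0.0)
        for g, p in lc.DEFAULT_PROFILES.items()
    }


@pytest.fixture(scope="session")
def small_config():
    """A 13-subject cohort with the default noise level (fast pipeline runs)."""
    return lc.PhantomConfig(
        n_subjects={"G1": 5, "G2": 3, "G3": 2, "G4": 2, "G5": 1}, seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return lc.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    return lc.AccommodationStudy.from_cohort(small_cohort).fit()


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free cohort (no pixel, between- or within-subject noise)."""
    cfg = lc.PhantomConfig(
        n_subjects={"G1": 3, "G2": 2, "G3": 2, "G4": 2, "G5": 2},
        pixel_noise_sd=0.0,
        seed=7,
    )
    return lc.generate_cohort(cfg, profiles=profiles_without_subject_noise())
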