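"""Shared fixtures: synthetic geometric images and small phantom cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from breastcad import phantom


@pytest.fixture(scope="session")
def disk_image():
    """Bright disk (200) on dark background (50), 100x100."""
    yy, xx = np.mgrid[0:100, 0:100]
    mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
    return np.where(mask, 200.0, 50.0), mask


@pytest.fixture(scope="session")
def benign_case():
    return phantom.generate_case(phantom.benign_spec(1), "benign1")


@pytest.fixture(scope="session")
def malignant_case():
    return phantom.generate_case(phantom.malignant_spec(1), "malignant1")


@pytest.fixture(scope="session")
def small_cohort():
    """Ten mixed cases used by the segmentation-quality tests."""
    return phantom.generate_cohort(5, 5, seed=3)
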