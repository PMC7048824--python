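import numpy as np
import pytest

from nasoflow import (
    default_template,
    default_variation_spec,
    generate_corpus,
    tube_template,
)


@pytest.fixture(scope="session")
def small_template():
    """Coarse nasal-like template used throughout the suite (fast)."""
    return default_template(n_stations=11, n_ring=12)


@pytest.fixture(scope="session")
def small_corpus(small_template):
    spec = default_variation_spec(small_template, n_modes=2, seed=11)
    return generate_corpus(small_template, spec, 5)


@pytest.fixture(scope="session")
def tube3():
    """Straight bilateral circular tube, r = 3 mm, L = 80 mm."""
    return tube_template(3.0, length_mm=80.0, n_stations=11, n_ring=16).base


def poiseuille_dp_pa(radius_mm, length_mm, q_mls, mu=1.86e-5):
    """Independent closed-form oracle: Δp = 8 μ L Q / (π r⁴)."""
    r = radius_mm * 1e-3
    return 8.0 * mu * (length_mm * 1e-3) * (q_mls * 1e-6) / (np.pi * r**4)
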