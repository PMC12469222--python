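"""Shared fixtures: small synthetic samples generated once per session."""

import numpy as np
import pytest

from fundus_vcdr.synthetic import FundusSample, generate_samples, render_fundus, sample_spec


@pytest.fixture(scope="session")
def clean_sample():
    """One noise-free glaucomatous sample at full frame size."""
    spec = sample_spec("glaucoma", 42)
    spec = spec.__class__(**{**spec.__dict__, "noise_sd": 0.0})
    return render_fundus(spec)


@pytest.fixture(scope="session")
def sample_batch():
    """Ten mixed samples (default noise) at full frame size."""
    return generate_samples(5, 5, 1234, image_size=640)


def make_tiny_sample(glaucoma: bool, size: int = 48, name: str | None = None
                     ) -> FundusSample:
    """Handmade sample with a rectangular disc/cup: cheap for count tests.

    Disc region spans rows 10..39 (30 rows); the cup spans 12 rows
    (vCDR 0.4) or 21 rows (vCDR 0.7) depending on the class.
    """
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[10:40, 12:36] = 1
    cup_rows = 21 if glaucoma else 12
    mask[14 : 14 + cup_rows, 18:30] = 2
    image = np.full((size, size, 3), 60, dtype=np.uint8)
    image[mask == 1] = 200
    image[mask == 2] = 240
    vcdr = cup_rows / 30
    return FundusSample(image=image, mask=mask, glaucoma=glaucoma,
                        true_vcdr=vcdr, name=name)
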