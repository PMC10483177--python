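import numpy as np
import pytest

import matplotlib

matplotlib.use("Agg")

from chromaplot import SynthSpec, synth_chromatogram


@pytest.fixture
def small_spec():
    """A fast-to-process run: 601 samples, one peak, six fractions."""
    return SynthSpec(
        peaks=((3.0, 100.0, 0.2),),
        drift=(1.0, 0.1),
        noise_sd=0.3,
        x_start=0.0,
        x_end=6.0,
        step=0.01,
        fraction_start=2.0,
        fraction_width=0.5,
        n_fractions=6,
        seed=42,
    )


@pytest.fixture
def small_chrom(small_spec):
    chrom, _ = synth_chromatogram(small_spec)
    return chrom


def random_spec(rng: np.random.Generator) -> SynthSpec:
    """Draw a plausible random run recipe (used by round-trip properties)."""
    x_end = float(rng.uniform(8.0, 20.0))
    n_peaks = int(rng.integers(1, 4))
    peaks = tuple(
        (
            float(rng.uniform(1.5, x_end - 1.5)),
            float(rng.uniform(20.0, 150.0)),
            float(rng.uniform(0.1, 0.5)),
        )
        for _ in range(n_peaks)
    )
    n_fr = int(rng.integers(0, 12))
    width = float(rng.uniform(0.3, 0.8))
    start = float(rng.uniform(0.5, max(0.6, x_end - n_fr * width - 0.5)))
    if start + n_fr * width > x_end:
        n_fr = 0
    return SynthSpec(
        peaks=peaks,
        drift=(float(rng.uniform(0.0, 5.0)), float(rng.uniform(-0.2, 0.3))),
        noise_sd=float(rng.uniform(0.0, 1.0)),
        x_start=0.0,
        x_end=x_end,
        step=0.05,
        channels=(("UV 1_280", 1.0), ("UV 2_260", float(rng.uniform(0.3, 0.9)))),
        fraction_start=start,
        fraction_width=width,
        n_fractions=n_fr,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
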