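"""Synthetic chromatogram generator with known ground truth.

Emulates a size-exclusion run on a ~24 ml analytical column: one dominant
elution peak plus optional minor peaks on a slow linear drift, Gaussian
detector noise, two UV channels (280 nm and a scaled 260 nm), and a block
of equal-width collected fractions.  Because the drift, peak positions and
true per-peak areas are known exactly, every parsing / baseline / area
operation can be tested without instrument data.

The defaults mimic a typical preparative run: x from 0 to 24 ml sampled
every 0.002 ml, a main protein peak at 14 ml (height 120 mAU, sd 0.35 ml),
fractions of 0.5 ml collected from 8 ml.  What the generator does *not*
emulate: conductivity gradients, injection marks mid-run, detector
saturation, or non-Gaussian peak tailing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Chromatogram, ChromatogramMeta, Curve, FractionEvent

__all__ = ["SynthSpec", "GroundTruth", "synth_chromatogram"]

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic run.

    peaks:
        (center ml, height mAU, sigma ml) per Gaussian peak.
    drift:
        (intercept mAU, slope mAU/ml) of the linear baseline drift, shared
        by all channels.
    channels:
        (curve name, per-peak height scale) — e.g. the 260 nm trace of a
        pure protein is a scaled-down copy of the 280 nm trace.
    noise_sd:
        Gaussian detector noise, mAU.
    fraction_start, fraction_width, n_fractions:
        Equal-width collection scheme; must fit inside [x_start, x_end].
    """

    peaks: tuple[tuple[float, float, float], ...] = ((14.0, 120.0, 0.35),)
    drift: tuple[float, float] = (2.0, 0.15)
    noise_sd: float = 0.5
    x_start: float = 0.0
    x_end: float = 24.0
    step: float = 0.002
    channels: tuple[tuple[str, float], ...] = (("UV 1_280", 1.0), ("UV 2_260", 0.55))
    fraction_start: float = 8.0
    fraction_width: float = 0.5
    n_fractions: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.x_start < self.x_end:
            raise ValueError("need x_start < x_end")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.channels:
            raise ValueError("need at least one channel")
        for c, h, s in self.peaks:
            if s <= 0:
                raise ValueError(f"peak at {c} ml: sigma must be positive")
        if self.n_fractions < 0:
            raise ValueError("n_fractions must be >= 0")
        if self.n_fractions:
            if self.fraction_width <= 0:
                raise ValueError("fraction_width must be positive")
            f_end = self.fraction_start + self.n_fractions * self.fraction_width
            if self.fraction_start < self.x_start or f_end > self.x_end:
                raise ValueError(
                    f"fraction scheme [{self.fraction_start}, {f_end}] does not "
                    f"fit inside [{self.x_start}, {self.x_end}]"
                )


@dataclass
class GroundTruth:
    """What the generator actually put into the trace."""

    x: np.ndarray
    drift_values: np.ndarray  # drift evaluated on x (shared by channels)
    peak_auc: dict[str, list[float]]  # channel -> true area per peak (ml*mAU)
    noiseless: dict[str, np.ndarray]  # channel -> drift + scaled peaks on x


def _gaussian(x: np.ndarray, center: float, height: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def synth_chromatogram(spec: SynthSpec) -> tuple[Chromatogram, GroundTruth]:
    """Generate one synthetic run plus its ground truth.

    Per channel: ``y(x) = drift(x) + sum_k scale * peak_k(x) + N(0, noise_sd^2)``
    with a single seeded RNG stream, so equal specs give identical runs.
    The true area of peak k in a channel is ``height * sigma * sqrt(2*pi) *
    scale``.  Fraction labels are "1", "2", ... at the stated starts.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round((spec.x_end - spec.x_start) / spec.step)) + 1
    x = spec.x_start + spec.step * np.arange(n)
    a, b = spec.drift
    drift = a + b * x

    curves = []
    peak_auc: dict[str, list[float]] = {}
    noiseless: dict[str, np.ndarray] = {}
    for name, scale in spec.channels:
        clean = drift.copy()
        for center, height, sigma in spec.peaks:
            clean += scale * _gaussian(x, center, height, sigma)
        y = clean
        if spec.noise_sd > 0:
            y = clean + rng.normal(0.0, spec.noise_sd, size=n)
        curves.append(Curve(name=name, x=x, y=y, x_unit="ml", y_unit="mAU"))
        peak_auc[name] = [h * s * SQRT_2PI * scale for _, h, s in spec.peaks]
        noiseless[name] = clean

    events = [
        FractionEvent(spec.fraction_start + i * spec.fraction_width, str(i + 1))
        for i in range(spec.n_fractions)
    ]
    chrom = Chromatogram(
        curves=curves,
        fraction_events=events,
        meta=ChromatogramMeta(source="<synthetic>"),
    )
    truth = GroundTruth(x=x, drift_values=drift, peak_auc=peak_auc, noiseless=noiseless)
    return chrom, truth
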