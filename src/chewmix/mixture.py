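"""VhH: variance of the hue histogram, the masticatory-performance statistic.

The mixing degree of a chewed two-coloured gum is scored by the population
variance of the hue-bin count vector of its bolus pixels.  An unmixed bolus
spreads pixels over two hue clusters (red and green); a fully mixed bolus
concentrates them in one intermediate-hue bin, which maximises the variance
of the bin counts.  Higher VhH therefore accompanies better mixing.  VhH is
not normalised by bolus size: with n pixels and B bins the maximum is
n^2 (B-1) / B^2, so values scale ~n^2 (1e7 for 1e5-pixel boluses).

One measurement is produced per sample from its two scanned sides by pooling
both sides' bolus pixels into a single histogram; per-side values are kept
for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsi import DEFAULT_CHROMA_THRESHOLD, rgb_to_hue

DEFAULT_BINS = 256


@dataclass(frozen=True)
class HueHistogram:
    counts: np.ndarray      # (B,) non-negative ints
    n_pixels: int           # sum of counts (chromatic pixels only)

    @property
    def bin_count(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class MPMeasurement:
    sample_id: str
    vhh: float
    n_pixels: int
    side_vhh: tuple[float, float] | None = None
    n_excluded: int = 0


def hue_histogram(hues: np.ndarray, bins: int = DEFAULT_BINS) -> HueHistogram:
    """Equal-width histogram of hue angles over [0, 360)."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    hues = np.asarray(hues, dtype=float)
    if hues.size and (hues.min() < 0 or hues.max() >= 360.0):
        raise ValueError("hues must lie in [0, 360)")
    counts, _ = np.histogram(hues, bins=bins, range=(0.0, 360.0))
    return HueHistogram(counts=counts, n_pixels=int(counts.sum()))


def vhh(hist: HueHistogram) -> float:
    """Population variance of the bin counts: sum(c_k^2)/B - (n/B)^2."""
    c = hist.counts.astype(float)
    b = hist.bin_count
    n = c.sum()
    return float((c ** 2).sum() / b - (n / b) ** 2)


def vhh_of_pixels(pixels: np.ndarray, bins: int = DEFAULT_BINS,
                  chroma_threshold: float = DEFAULT_CHROMA_THRESHOLD):
    """VhH of an RGB pixel list; returns (vhh, n_pixels, n_excluded)."""
    hues, n_excluded = rgb_to_hue(pixels, chroma_threshold)
    hist = hue_histogram(hues, bins)
    return vhh(hist), hist.n_pixels, n_excluded


def measure_sample(side1_pixels: np.ndarray, side2_pixels: np.ndarray,
                   sample_id: str = "", bins: int = DEFAULT_BINS,
                   chroma_threshold: float = DEFAULT_CHROMA_THRESHOLD) -> MPMeasurement:
    """One masticatory-performance value from the two sides of a sample.

    Bolus pixels of both sides are pooled into one hue histogram; the
    per-side variances are also computed as diagnostics.
    """
    sides = []
    for name, px in (("side1", side1_pixels), ("side2", side2_pixels)):
        px = np.asarray(px)
        if px.size == 0:
            raise ValueError(f"{name}: empty pixel list")
        try:
            hues, excl = rgb_to_hue(px, chroma_threshold)
        except ValueError as err:
            raise ValueError(f"{name}: {err}") from err
        sides.append((hues, excl))

    pooled = np.concatenate([h for h, _ in sides])
    hist = hue_histogram(pooled, bins)
    side_values = tuple(vhh(hue_histogram(h, bins)) for h, _ in sides)
    return MPMeasurement(sample_id=sample_id, vhh=vhh(hist),
                         n_pixels=hist.n_pixels, side_vhh=side_values,
                         n_excluded=sides[0][1] + sides[1][1])
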