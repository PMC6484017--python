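"""HSI (hue-saturation-intensity) colour model conversions.

The mixing statistic operates on the hue angle of the HSI model, where
0 deg is red and 120 deg is green.  Hue is undefined on the grey axis, so
near-achromatic pixels must be excluded by the caller via a chroma
threshold (channel spread on the 8-bit scale).
"""

from __future__ import annotations

import numpy as np

#: pixels whose max-min channel spread is below this (8-bit scale) are
#: treated as achromatic: HSI hue is numerically unstable near the grey axis
DEFAULT_CHROMA_THRESHOLD = 8.0


def rgb_to_hue(pixels: np.ndarray, chroma_threshold: float = DEFAULT_CHROMA_THRESHOLD):
    """Hue angles (degrees, [0, 360)) of chromatic pixels.

    Parameters
    ----------
    pixels : (n, 3) array of 8-bit RGB values.
    chroma_threshold : minimum max-min channel spread for a pixel to count
        as chromatic, on the 0-255 scale.

    Returns
    -------
    hues : float array of hue angles for the chromatic pixels, in input order.
    n_excluded : number of achromatic pixels dropped.

    Raises
    ------
    ValueError if no chromatic pixel remains.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 3:
        raise ValueError(f"expected (n, 3) RGB pixel list, got shape {pixels.shape}")
    if pixels.shape[0] == 0:
        raise ValueError("empty pixel list")

    spread = pixels.max(axis=1) - pixels.min(axis=1)
    chromatic = spread >= chroma_threshold
    n_excluded = int((~chromatic).sum())
    if not chromatic.any():
        raise ValueError("no chromatic bolus pixels (all below chroma threshold)")

    r, g, b = pixels[chromatic].T
    # theta = arccos( ((r-g)+(r-b))/2 / sqrt((r-g)^2 + (r-b)(g-b)) )
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = np.degrees(np.arccos(np.clip(num / np.maximum(den, 1e-12), -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    return np.mod(hue, 360.0), n_excluded


def hsi_to_rgb(hue_deg: np.ndarray, saturation: float, intensity: float) -> np.ndarray:
    """Convert (H, S, I) to RGB in [0, 1] using the sector formulas.

    ``hue_deg`` may be any shape; output has a trailing axis of size 3.
    ``intensity * (1 + saturation)`` must stay <= 1 for in-gamut output.
    """
    h = np.mod(np.asarray(hue_deg, dtype=float), 360.0)
    s, i = float(saturation), float(intensity)
    sector = (h // 120.0).astype(int)  # 0: RG, 1: GB, 2: BR
    hp = np.radians(h - 120.0 * sector)
    c1 = i * (1.0 - s)
    c2 = i * (1.0 + s * np.cos(hp) / np.cos(np.radians(60.0) - hp))
    c3 = 3.0 * i - (c1 + c2)
    rgb = np.empty(h.shape + (3,), dtype=float)
    for sec, order in ((0, (2, 0, 1)), (1, (0, 1, 2)), (2, (1, 2, 0))):
        m = sector == sec
        # order gives the channel index of (c1, c2, c3) per sector
        rgb[m, order[0]] = c1
        rgb[m, order[1]] = c2[m]
        rgb[m, order[2]] = c3[m]
    return np.clip(rgb, 0.0, 1.0)
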