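"""Colour-based bolus segmentation.

Isolates the flattened gum bolus from the scanner background in five steps:

1. convert the RGB image to CIE L*a*b* and estimate the background colour
   ``bg`` as the mean colour of the mean-shift superpixels touching the four
   image corners;
2. build a distance map ``d_i = log(||x_i - bg|| + eps)`` (the log compresses
   colour texture inside the bolus while the near-zero background stays
   homogeneous);
3. split the distance map in two clusters with scalar k-means (k=2);
4. pick the cluster lying at the image centre as the bolus (smaller mean
   member distance to the geometric centre; ties go to the smaller cluster);
5. keep the largest connected component, fill holes, and extract the bolus
   RGB pixel values.

Every step is deterministic (k-means is seeded by percentile initialisation),
so repeated runs on the same image return byte-identical masks -- the basis
of the pipeline's systematic-error check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, measure
from sklearn.cluster import MeanShift
from sklearn.metrics import pairwise_distances_argmin

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    spatial_bw: float = 8.0        # mean-shift spatial bandwidth, px
    range_bw: float = 8.0          # mean-shift colour bandwidth, Lab units
    eps: float = 1e-6              # distance-map log stabiliser
    max_ms_samples: int = 900      # subsample budget for mode seeking


@dataclass
class SuperpixelMap:
    labels: np.ndarray            # (H, W) int cluster label per pixel
    means: np.ndarray             # (n_clusters, 3) mean Lab per cluster


@dataclass
class BolusMask:
    mask: np.ndarray              # (H, W) bool
    pixels: np.ndarray            # (n, 3) uint8 bolus RGB values


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """sRGB (8-bit, D65) -> CIE L*a*b*."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    return color.rgb2lab(image.astype(np.uint8))


def mean_shift_superpixels(lab: np.ndarray, spatial_bw: float = 8.0,
                           range_bw: float = 8.0,
                           max_samples: int = 2500) -> SuperpixelMap:
    """Mean-shift colour clustering of a Lab image into superpixels.

    Mode seeking runs in the colour (range) domain on a regular pixel
    subsample whose spacing is set by ``spatial_bw`` (the spatial
    granularity); converged modes closer than ``range_bw / 2`` are merged,
    and every pixel is assigned to the nearest merged mode.  Cluster means
    are then recomputed as the arithmetic mean of member Lab values so the
    partition invariant holds exactly.
    """
    if spatial_bw <= 0 or range_bw <= 0:
        raise ValueError("bandwidths must be > 0")
    h, w = lab.shape[:2]
    step = max(1, int(round(spatial_bw / 2)),
               int(np.ceil(np.sqrt(h * w / max_samples))))
    rr, cc = np.mgrid[0:h:step, 0:w:step]
    feats = lab[rr.ravel(), cc.ravel()] / range_bw
    ms = MeanShift(bandwidth=1.0, bin_seeding=len(feats) > 500, cluster_all=True)
    ms.fit(feats)
    modes_lab = ms.cluster_centers_ * range_bw

    # merge modes within range_bw/2 in colour (union-find over mode pairs)
    n_modes = len(modes_lab)
    parent = list(range(n_modes))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_modes):
        for j in range(i + 1, n_modes):
            if np.linalg.norm(modes_lab[i] - modes_lab[j]) < range_bw / 2:
                parent[find(i)] = find(j)
    roots = sorted({find(i) for i in range(n_modes)})
    root_index = {r: k for k, r in enumerate(roots)}
    merged = np.stack([modes_lab[[i for i in range(n_modes) if find(i) == r]].mean(axis=0)
                       for r in roots])

    flat = lab.reshape(-1, 3)
    labels = pairwise_distances_argmin(flat, merged).reshape(h, w)

    # recompute means over actual members; drop empty clusters
    present = np.unique(labels)
    remap = np.zeros(len(merged), dtype=int)
    means = []
    for k, lbl in enumerate(present):
        remap[lbl] = k
        means.append(flat[labels.ravel() == lbl].mean(axis=0))
    labels = remap[labels]
    means = np.stack(means)
    if len(means) > 10_000:
        logger.warning("mean shift produced %d clusters; bandwidths may be too small",
                       len(means))
    return SuperpixelMap(labels=labels, means=means)


def estimate_background(sp: SuperpixelMap) -> np.ndarray:
    """Mean Lab colour of the (<= 4 distinct) superpixels at the image corners."""
    h, w = sp.labels.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2")
    corner_labels = {int(sp.labels[r, c]) for r in (0, h - 1) for c in (0, w - 1)}
    return np.stack([sp.means[lbl] for lbl in sorted(corner_labels)]).mean(axis=0)


def distance_map(lab: np.ndarray, bg: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Per-pixel log colour distance to the background, log(||x - bg|| + eps)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    return np.log(np.linalg.norm(lab - np.asarray(bg, dtype=float), axis=-1) + eps)


def _kmeans2_scalar(values: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D 2-means: centroids start at the 10th/90th percentiles."""
    c = np.percentile(values, [10.0, 90.0]).astype(float)
    if c[0] == c[1]:
        raise ValueError("degenerate image: no foreground/background contrast")
    for _ in range(max_iter):
        assign = np.abs(values[:, None] - c[None, :]).argmin(axis=1)
        new_c = np.array([values[assign == k].mean() if (assign == k).any() else c[k]
                          for k in (0, 1)])
        if np.allclose(new_c, c):
            break
        c = new_c
    return np.abs(values[:, None] - c[None, :]).argmin(axis=1)


def kmeans_bolus(dm: np.ndarray) -> np.ndarray:
    """Binary bolus mask from the distance map.

    Scalar k-means (k=2) splits the map; the bolus is the cluster whose
    members lie nearest the image centre (selection is spatial, never
    intensity-ordered, so it is invariant to contrast inversion).  The mask
    is post-processed to its largest connected component with holes filled.
    """
    dm = np.asarray(dm, dtype=float)
    if np.ptp(dm) == 0:
        raise ValueError("degenerate image: no foreground/background contrast")
    h, w = dm.shape
    assign = _kmeans2_scalar(dm.ravel()).reshape(h, w)

    rr, cc = np.mgrid[0:h, 0:w]
    centre_dist = np.hypot(rr - (h - 1) / 2.0, cc - (w - 1) / 2.0)
    stats = []
    for k in (0, 1):
        members = assign == k
        stats.append((centre_dist[members].mean(), int(members.sum()), k))
    # nearest to centre wins; ties go to the smaller cluster
    stats.sort(key=lambda t: (t[0], t[1]))
    mask = assign == stats[0][2]

    lbl = measure.label(mask, connectivity=2)
    if lbl.max() > 1:
        sizes = np.bincount(lbl.ravel())[1:]
        mask = lbl == (1 + sizes.argmax())
    return ndimage.binary_fill_holes(mask)


def segment(image: np.ndarray, config: SegmentationConfig | None = None) -> BolusMask:
    """Full pipeline: RGB image -> bolus mask + extracted bolus RGB pixels."""
    config = config or SegmentationConfig()
    lab = rgb_to_lab(image)
    sp = mean_shift_superpixels(lab, config.spatial_bw, config.range_bw,
                                config.max_ms_samples)
    bg = estimate_background(sp)
    dm = distance_map(lab, bg, config.eps)
    mask = kmeans_bolus(dm)
    return BolusMask(mask=mask, pixels=np.asarray(image)[mask])


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|) between two boolean masks."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0
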