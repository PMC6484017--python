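"""Synthetic data: two-coloured gum wafer images and longitudinal cohorts.

Two generators back the test and validation machinery:

* :func:`generate_wafer` renders a flattened red/green gum wafer on a light
  scanner background with a known ("latent") mixing degree ``m`` and an exact
  ground-truth bolus mask, so segmentation and mixing-statistic behaviour can
  be scored against truth.
* :func:`generate_cohort` draws a cohort with the design of the underlying
  study: 3 measurement sessions per subject, an age-dependent chewing-gum
  consumption rate (CGC), and an additive linear model for the hue-histogram
  variance (VhH) outcome with a subject random intercept.

:func:`read_supplementary` ingests an externally supplied per-subject dataset
(spreadsheet or delimited text) into the same long-format cohort table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hsi import hsi_to_rgb

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "subject_id", "age", "age_group", "sex", "dental_status", "cgc", "session", "vhh",
]

#: age-group upper edges (years): 18-24, 25-44, 45-65, 66+
AGE_GROUP_EDGES = (24, 44, 65)

# Saturation/intensity used for rendered patch colours; I*(1+S) <= 1 keeps
# the sector conversion in gamut.
_WAFER_SATURATION = 0.65
_WAFER_INTENSITY = 0.5


# --------------------------------------------------------------------------
# wafer images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaferSpec:
    """Rendering parameters for one synthetic wafer image.

    ``mixing_degree`` is the latent mixture in [0, 1]: at 0 the bolus is a
    patchwork of the two pure dye hues, at 1 every patch has converged to the
    circular midpoint hue (fully mixed).  Patches are ``patch_scale_px`` grid
    cells (jittered) so unmixed wafers show spatially coherent colour regions
    as real boluses do.
    """

    width_px: int = 192
    height_px: int = 192
    blob_radius_px: int = 70
    blob_center: tuple[int, int] | None = None  # (row, col); None = canvas centre
    mixing_degree: float = 0.5
    hue_a: float = 0.0     # red end
    hue_b: float = 120.0   # green end
    hue_jitter_sd: float = 12.0  # per-patch hue texture at m=0, degrees; scales as (1-m)
    patch_scale_px: int = 12
    background_rgb: tuple[int, int, int] = (200, 200, 200)
    noise_sd: float = 4.0
    seed: int = 0

    def center(self) -> tuple[int, int]:
        if self.blob_center is not None:
            return self.blob_center
        return (self.height_px // 2, self.width_px // 2)

    def validate(self) -> None:
        if not (0.0 <= self.mixing_degree <= 1.0):
            raise ValueError(f"mixing_degree must be in [0, 1], got {self.mixing_degree}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.patch_scale_px < 1:
            raise ValueError("patch_scale_px must be >= 1")
        r, c = self.center()
        rad = self.blob_radius_px
        if (r - rad < 0 or c - rad < 0 or r + rad >= self.height_px
                or c + rad >= self.width_px):
            raise ValueError(
                f"blob (center={(r, c)}, radius={rad}) extends outside the "
                f"{self.height_px}x{self.width_px} canvas"
            )


def _patch_hues(spec: WaferSpec, rng: np.random.Generator,
                n_rows: int, n_cols: int) -> np.ndarray:
    """Per-patch hue: each patch starts at hue_a or hue_b (p=1/2) and is
    rotated toward the circular midpoint of the two by fraction ``m`` of the
    half-arc, along the shorter arc (red->green mixing passes through yellow).
    """
    delta = (spec.hue_b - spec.hue_a + 180.0) % 360.0 - 180.0  # signed shorter arc
    is_a = rng.random((n_rows, n_cols)) < 0.5
    m = spec.mixing_degree
    hue_from_a = spec.hue_a + m * delta / 2.0
    hue_from_b = spec.hue_b - m * delta / 2.0
    hues = np.where(is_a, hue_from_a, hue_from_b)
    # hue texture: unmixed boluses show patch-to-patch hue variation that
    # vanishes as mixing completes (exactly zero at m=1, so the fully mixed
    # limit is a single hue)
    if spec.hue_jitter_sd > 0 and m < 1.0:
        hues = hues + rng.normal(0.0, spec.hue_jitter_sd * (1.0 - m), hues.shape)
    return hues % 360.0


def generate_wafer(spec: WaferSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one wafer image and its ground-truth bolus mask.

    Returns ``(image, truth_mask)``: an (H, W, 3) uint8 RGB raster and a
    boolean raster that is exactly the rendered blob footprint.  Same spec
    (incl. seed) gives byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    h, w = spec.height_px, spec.width_px
    rr, cc = np.mgrid[0:h, 0:w]
    cr, ccol = spec.center()
    mask = (rr - cr) ** 2 + (cc - ccol) ** 2 <= spec.blob_radius_px ** 2

    # jittered patch grid
    ps = spec.patch_scale_px
    off_r = int(rng.integers(0, ps))
    off_c = int(rng.integers(0, ps))
    prow = (rr + off_r) // ps
    pcol = (cc + off_c) // ps
    hues = _patch_hues(spec, rng, int(prow.max()) + 1, int(pcol.max()) + 1)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(spec.background_rgb, dtype=float)
    bolus_rgb = hsi_to_rgb(hues[prow[mask], pcol[mask]],
                           _WAFER_SATURATION, _WAFER_INTENSITY) * 255.0
    img[mask] = bolus_rgb

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

# defaults below reproduce the study design: group sizes 71/53/70/71 across
# the four age groups, a strong age->CGC gradient (older subjects rarely
# consume gum), and additive session / consumption / age effects on VhH at
# the 1e7 scale of real hue-histogram variances.
_AGE_GROUP_PROPS = (71 / 265, 53 / 265, 70 / 265, 71 / 265)
_CGC_GIVEN_AGE = (
    (7 / 71, 31 / 71, 33 / 71),
    (28 / 53, 12 / 53, 13 / 53),
    (57 / 70, 9 / 70, 4 / 70),
    (70 / 71, 1 / 71, 0.0),
)
_P_ARTIFICIAL_GIVEN_AGE = (0.0, 4 / 53, 23 / 70, 31 / 71)


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a 3-session masticatory-performance cohort.

    vhh_{i,s} = beta0 + beta_c[cgc_i] + beta_s[s] + beta_age * age_i
                + b_i + eps_{i,s},   b_i ~ N(0, subject_sd^2),
                                     eps ~ N(0, residual_sd^2).
    """

    n_subjects: int = 265
    age_range: tuple[int, int] = (18, 90)
    age_group_edges: tuple[int, int, int] = AGE_GROUP_EDGES
    age_group_props: tuple[float, ...] = _AGE_GROUP_PROPS
    cgc_given_age: tuple[tuple[float, float, float], ...] = _CGC_GIVEN_AGE
    p_artificial_denture_given_age: tuple[float, ...] = _P_ARTIFICIAL_GIVEN_AGE
    p_male: float = 143 / 265
    baseline_vhh: float = 2.07e7
    session_effects: tuple[float, float] = (8.5e5, 9.4e5)   # sessions 2, 3
    cgc_effects: tuple[float, float] = (3.22e6, 4.54e6)     # CGC 1, 2
    age_slope: float = -4.51e4
    subject_sd: float = 1.2e6
    residual_sd: float = 8.0e5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("subject_sd and residual_sd must be >= 0")
        for row in self.cgc_given_age:
            if abs(sum(row) - 1.0) > 1e-9 or min(row) < 0:
                raise ValueError(f"cgc_given_age row {row} is not a probability vector")
        if abs(sum(self.age_group_props) - 1.0) > 1e-9:
            raise ValueError("age_group_props must sum to 1")
        for p in self.p_artificial_denture_given_age:
            if not 0.0 <= p <= 1.0:
                raise ValueError("p_artificial_denture_given_age entries must be in [0,1]")


def age_group_of(age, edges=AGE_GROUP_EDGES):
    """Age group 1..4 for an age (scalar or array) given the upper edges."""
    return np.digitize(np.asarray(age), bins=np.asarray(edges), right=True) + 1


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: 3 rows (sessions) per subject, long format."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    lo, hi = spec.age_range
    e1, e2, e3 = spec.age_group_edges
    group_bounds = [(lo, e1), (e1 + 1, e2), (e2 + 1, e3), (e3 + 1, hi)]
    ag = rng.choice(4, size=n, p=np.asarray(spec.age_group_props))
    ages = np.array([rng.integers(group_bounds[g][0], group_bounds[g][1] + 1)
                     for g in ag])
    cgc_p = np.asarray(spec.cgc_given_age)
    cgc = np.array([rng.choice(3, p=cgc_p[g]) for g in ag])
    sex = np.where(rng.random(n) < spec.p_male, "male", "female")
    p_art = np.asarray(spec.p_artificial_denture_given_age)
    ds = np.where(rng.random(n) < p_art[ag], "artificial", "natural")

    b = rng.normal(0.0, spec.subject_sd, size=n)
    beta_s = np.array([0.0, *spec.session_effects])
    beta_c = np.array([0.0, *spec.cgc_effects])

    rows = []
    for i in range(n):
        mu_i = (spec.baseline_vhh + beta_c[cgc[i]] + spec.age_slope * ages[i] + b[i])
        eps = rng.normal(0.0, spec.residual_sd, size=3)
        for s in (1, 2, 3):
            rows.append((f"S{i + 1:04d}", int(ages[i]), int(ag[i]) + 1, sex[i],
                         ds[i], int(cgc[i]), s, mu_i + beta_s[s - 1] + eps[s - 1]))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Enforce the cohort-table invariants (3 sessions/subject, vhh > 0)."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    counts = cohort.groupby("subject_id")["session"].agg(["size", "nunique"])
    bad = counts[(counts["size"] != 3) | (counts["nunique"] != 3)]
    if len(bad):
        raise ValueError(
            "subjects without exactly one row per session {1,2,3}: "
            + ", ".join(map(str, bad.index.tolist()))
        )
    if (cohort["vhh"] <= 0).any():
        raise ValueError("vhh values must be positive")


# --------------------------------------------------------------------------
# cohort -> images
# --------------------------------------------------------------------------

def render_cohort_images(cohort: pd.DataFrame, spec: WaferSpec,
                         out_dir: str | Path) -> list[dict]:
    """Render two wafer images ("sides") per cohort row.

    Each row's latent vhh is mapped monotonically to a mixing degree via
    min-max scaling over the cohort; a degenerate cohort (all vhh equal)
    maps every row to m=0.5 with a warning.  Images are written as
    uncompressed TIFF; the returned manifest (also written as
    ``manifest.json``) records sample ids, paths and the m mapping.
    """
    import tifffile

    if len(cohort) == 0:
        raise ValueError("empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    vhh = cohort["vhh"].to_numpy(dtype=float)
    lo, hi = vhh.min(), vhh.max()
    if hi - lo <= 0:
        warnings.warn("degenerate cohort: all vhh equal; rendering all m=0.5")
        m_values = np.full(len(vhh), 0.5)
    else:
        m_values = (vhh - lo) / (hi - lo)

    manifest = []
    for idx, (row, m) in enumerate(zip(cohort.itertuples(index=False), m_values)):
        sample_id = f"{row.subject_id}_s{row.session}"
        entry = {"sample_id": sample_id, "m": float(m), "vhh_latent": float(row.vhh)}
        for side in (1, 2):
            seed = (spec.seed * 1000003 + 7919 * idx + side) % (2 ** 31)
            img, _ = generate_wafer(
                WaferSpec(**{**spec.__dict__, "mixing_degree": float(m), "seed": seed}))
            path = out_dir / f"{sample_id}_side{side}.tiff"
            tifffile.imwrite(path, img, compression=None)
            entry[f"side{side}_path"] = path.name
        manifest.append(entry)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"wafer_spec": {**spec.__dict__}, "samples": manifest}, fh, indent=1)
    return manifest


# --------------------------------------------------------------------------
# supplementary-table reader
# --------------------------------------------------------------------------

_SEX_CODES = {"m": "male", "male": "male", "1": "male",
              "f": "female", "female": "female", "0": "female"}
_DS_CODES = {"natural": "natural", "0": "natural",
             "artificial": "artificial", "artificial denture": "artificial",
             "denture": "artificial", "1": "artificial"}

REQUIRED_MAP_KEYS = ("subject_id", "age", "sex", "dental_status", "cgc",
                     "session", "vhh")


def read_supplementary(path: str | Path, column_map: dict[str, str],
                       age_group_edges=AGE_GROUP_EDGES) -> pd.DataFrame:
    """Read a deposited per-subject dataset into a cohort table.

    ``column_map`` names the source column for each of subject id, age, sex,
    dental status, CGC, session and VhH (the published table's layout is not
    standardised, so the mapping is caller-supplied).  Spreadsheets (.xlsx)
    and delimited text are both accepted; categorical codes are normalised
    and the 3-sessions-per-subject invariant is enforced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for key in REQUIRED_MAP_KEYS:
        if key not in column_map:
            raise ValueError(f"column_map is missing required key '{key}'")

    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, sep=None, engine="python")

    missing = [col for col in column_map.values() if col not in raw.columns]
    if missing:
        raise ValueError(f"mapped columns not found in {path.name}: {missing}")

    df = pd.DataFrame({key: raw[col] for key, col in column_map.items()})
    vhh = pd.to_numeric(df["vhh"], errors="coerce")
    if vhh.isna().any():
        bad = df.index[vhh.isna()].tolist()
        raise ValueError(f"non-numeric vhh at row index(es) {bad}")
    df["vhh"] = vhh
    df["age"] = pd.to_numeric(df["age"]).astype(int)
    df["cgc"] = pd.to_numeric(df["cgc"]).astype(int)
    df["session"] = pd.to_numeric(df["session"]).astype(int)
    df["sex"] = df["sex"].astype(str).str.strip().str.lower().map(_SEX_CODES)
    df["dental_status"] = (df["dental_status"].astype(str).str.strip()
                           .str.lower().map(_DS_CODES))
    if df["sex"].isna().any() or df["dental_status"].isna().any():
        raise ValueError("unrecognised sex or dental_status codes")
    if not df["cgc"].isin([0, 1, 2]).all():
        raise ValueError("cgc codes outside {0, 1, 2}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["age_group"] = age_group_of(df["age"], age_group_edges)
    df = df[COHORT_COLUMNS]
    validate_cohort(df)
    logger.info("read %d rows / %d subjects from %s",
                len(df), df["subject_id"].nunique(), path)
    return df
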