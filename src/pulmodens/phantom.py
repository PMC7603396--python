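"""Synthetic murine chest micro-CT phantoms with exact ground truth.

The generator builds stylized chest volumes — a soft-tissue body
cylinder in air, two ellipsoidal lungs, a branching airway tube — and
fills the parenchyma with HU values drawn from condition-specific
density mixtures:

* ``healthy``: a dominant aerated component peaking near −600 HU plus a
  right-shifted artifact/noise component above −435 HU, reproducing the
  anesthetized-mouse end-expiration distribution in which roughly 20 %
  of lung voxels exceed −435 HU;
* ``mild_blm``: a fibrotic distribution wholly contained in
  [−860, −121] HU (mild/moderate bleomycin disease);
* ``severe_blm``: the mild distribution plus contiguous dense patches in
  the non-aerated range [−121, +121] HU fused to the chest wall, which
  threshold-based segmentation cannot recover (the "undetectable"
  volume).

Geometry is deliberately stylized — ellipsoids and tubes, not anatomy —
so that the ground-truth lung map, airway tree, compartment fractions
and total volume are exact by construction.  Spatial texture comes from
a smoothed Gaussian random field pushed through the inverse CDF of the
condition's mixture, so the marginal HU distribution is exact while
values remain spatially correlated at a few-voxel scale (motion/noise
artifacts in real scans are regional, not voxel-wise salt).

All randomness flows from one seeded generator; cohort members draw
child seeds by seed-sequence spawning, so cohorts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .aeration import COMPARTMENTS, preclinical_thresholds
from .segmentation import (
    LABEL_AIRWAY,
    LABEL_LUNG,
    LABEL_UNDETECTABLE,
    LungMap,
)
from .volume_io import CTVolume, RawVolume, calibrate_hu

CONDITIONS = ("healthy", "mild_blm", "severe_blm")

#: Grey-level anchors of the synthetic scanner: air → 1000, water → 5000,
#: i.e. 4 grey levels per HU (0.25 HU quantization).
PHANTOM_AIR_GREY = 1000.0
PHANTOM_WATER_GREY = 5000.0

# ---------------------------------------------------------------------------
# Parenchyma density mixtures (truncated-normal components over an HU
# support).  The healthy constants are calibration outputs of
# scripts/calibrate_phantom.py: they are solved so that a segmented
# healthy cohort shows ~20 % of lung voxels above −435 HU and mean
# normo-aerated percentages of ~79 % (preclinical) / ~64 % (clinical).
# ---------------------------------------------------------------------------

#: (weight, mean HU, sd HU) per component; supports clip the components.
HEALTHY_MIXTURE = (
    (0.7643, -610.0, 131.28),
    (0.1575, -440.0, 70.0),
    (0.0782, -240.0, 130.0),
)
HEALTHY_SUPPORT = (-1000.0, 60.0)

MILD_MIXTURE = ((1.0, -440.0, 95.0),)
MILD_SUPPORT = (-840.0, -150.0)

#: Severe dense patches: non-aerated HU values centred on soft tissue.
SEVERE_PATCH_MEAN = 0.0
SEVERE_PATCH_SD = 50.0
SEVERE_PATCH_SUPPORT = (-115.0, 115.0)

#: Spatial correlation length (voxels) of the parenchyma texture field.
TEXTURE_SIGMA = 3.0

#: Ashcroft-score coupling: monotone map from the true hypo+non-aerated
#: fraction to a fractional score, before integer noise and clamping.
SCORE_ANCHOR_FRACTIONS = (0.0, 0.13, 0.21, 0.35, 0.50, 0.66, 1.0)
SCORE_ANCHOR_VALUES = (0.0, 0.5, 2.0, 3.0, 4.0, 5.5, 8.0)
SCORE_NOISE_P = 0.15  # probability of a ±1 integer perturbation each side


class PhantomSpecError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic chest volume."""

    condition: str = "healthy"
    dims: tuple[int, int, int] = (192, 192, 192)
    spacing_um: float = 50.0
    mixture: tuple = None  # defaults per condition
    support: tuple[float, float] = None
    severe_patch_fraction: float = 0.25
    noise_hu_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise PhantomSpecError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if len(self.dims) != 3 or min(self.dims) < 64:
            raise PhantomSpecError("phantom dims must be 3-D with every edge >= 64")
        if not self.spacing_um > 0:
            raise PhantomSpecError("spacing_um must be positive")
        if not 0.0 < self.severe_patch_fraction < 0.9:
            raise PhantomSpecError("severe_patch_fraction must lie in (0, 0.9)")
        if self.mixture is None:
            self.mixture = HEALTHY_MIXTURE if self.condition == "healthy" else MILD_MIXTURE
            self.support = HEALTHY_SUPPORT if self.condition == "healthy" else MILD_SUPPORT
        if self.support is None:
            raise PhantomSpecError("a custom mixture requires an explicit support")
        w = sum(c[0] for c in self.mixture)
        if abs(w - 1.0) > 1e-9:
            raise PhantomSpecError(f"mixture weights must sum to 1, got {w}")


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a phantom volume."""

    lung_map: LungMap  # labels incl. airway and (severe) undetectable
    airway_seed: tuple[int, int, int]
    compartment_fractions: dict[str, float]  # preclinical, over lung voxels
    out_of_range_fraction: float
    total_lung_mm3: float  # lung + undetectable (true anatomical volume)
    lung_mm3: float  # detectable parenchyma only
    undetectable_mm3: float
    ashcroft_score: int
    hypo_non_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.hypo_non_fraction = (
            self.compartment_fractions["hypo_aerated"]
            + self.compartment_fractions["non_aerated"]
        )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _ellipsoid(dims, center, semi) -> np.ndarray:
    z, y, x = np.ogrid[: dims[0], : dims[1], : dims[2]]
    return (
        ((z - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((x - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _tube(dims, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0→p1 (z,y,x coords)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1).astype(int), dims)
    mask = np.zeros(dims, dtype=bool)
    if np.any(lo >= hi):
        return mask
    z, y, x = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    pts = np.stack([z, y, x], axis=-1).astype(float)
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / L2 if L2 > 0 else 0.0, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = dist2 <= radius**2
    return mask


def _chest_geometry(dims):
    """Body cylinder, lung ellipsoids, airway tree and trachea seed."""
    nz, ny, nx = dims
    cz, cy, cx = nz / 2.0, ny / 2.0, nx / 2.0

    yy, xx = np.ogrid[:ny, :nx]
    body2d = ((yy - cy) / (0.46 * ny)) ** 2 + ((xx - cx) / (0.46 * nx)) ** 2 <= 1.0
    body = np.broadcast_to(body2d[None, :, :], dims).copy()

    semi = (0.30 * nz, 0.19 * ny, 0.145 * nx)
    left = _ellipsoid(dims, (cz, 1.04 * cy, 0.67 * cx), semi)
    right = _ellipsoid(dims, (cz, 1.04 * cy, 1.33 * cx), semi)
    lungs = left | right

    r_trachea = max(3, int(round(nz / 38)))
    r_branch = max(2, int(round(nz / 48)))
    top = (0.08 * nz, 0.82 * cy, cx)
    carina = (cz, 0.96 * cy, cx)
    airway = _tube(dims, top, carina, r_trachea)
    airway |= _tube(dims, carina, (1.25 * cz, 1.04 * cy, 0.70 * cx), r_branch)
    airway |= _tube(dims, carina, (1.25 * cz, 1.04 * cy, 1.30 * cx), r_branch)

    seed = (int(round(top[0])) + 2, int(round(top[1])), int(round(top[2])))
    return body, lungs, left, airway, seed


# ---------------------------------------------------------------------------
# Density sampling
# ---------------------------------------------------------------------------

def _mixture_cdf_grid(mixture, support, n_grid: int = 4096):
    """Tabulated CDF of a truncated-normal mixture on its support."""
    lo, hi = support
    grid = np.linspace(lo, hi, n_grid)
    cdf = np.zeros_like(grid)
    for w, mu, sd in mixture:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        cdf += w * sps.truncnorm.cdf(grid, a, b, loc=mu, scale=sd)
    cdf[0], cdf[-1] = 0.0, 1.0
    return grid, cdf


def mixture_quantile(u: np.ndarray, mixture, support) -> np.ndarray:
    """Inverse CDF of the mixture, evaluated by interpolation."""
    grid, cdf = _mixture_cdf_grid(mixture, support)
    return np.interp(u, cdf, grid)


def _textured_values(rng, dims, region: np.ndarray, mixture, support) -> np.ndarray:
    """Spatially correlated values with the exact mixture marginal.

    A smoothed Gaussian field is rank-transformed to uniform over the
    region's voxels and pushed through the mixture's inverse CDF.
    """
    smooth = ndimage.gaussian_filter(rng.standard_normal(dims), TEXTURE_SIGMA)
    vals = smooth[region]
    ranks = np.empty(vals.size, dtype=np.int64)
    ranks[np.argsort(vals, kind="stable")] = np.arange(vals.size)
    u = (ranks + 0.5) / vals.size
    return mixture_quantile(u, mixture, support)


def _quantize_hu(hu: np.ndarray) -> np.ndarray:
    """Round HU onto the synthetic scanner's 16-bit grid (0.25 HU)."""
    grey = np.round((hu + 1000.0) * 4.0 + PHANTOM_AIR_GREY)
    return (grey - PHANTOM_WATER_GREY) / 4.0


def _score_from_fraction(frac_hn: float, rng) -> int:
    base = float(np.interp(frac_hn, SCORE_ANCHOR_FRACTIONS, SCORE_ANCHOR_VALUES))
    noise = int(rng.choice([-1, 0, 1], p=[SCORE_NOISE_P, 1 - 2 * SCORE_NOISE_P, SCORE_NOISE_P]))
    return int(np.clip(round(base) + noise, 0, 8))


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def make_phantom_raw(spec: PhantomSpec) -> tuple[RawVolume, PhantomTruth]:
    """Generate a phantom as scanner output (uint16 grey) plus truth."""
    rng = np.random.default_rng(spec.seed)
    dims = tuple(spec.dims)
    body, lungs, left, airway, seed = _chest_geometry(dims)

    hu = np.full(dims, -1000.0, dtype=np.float64)  # air
    tissue_tex = ndimage.gaussian_filter(rng.standard_normal(dims), 2.0)
    hu[body] = 15.0 * tissue_tex[body]  # soft tissue around 0 HU

    parenchyma = lungs & ~airway
    undetectable = np.zeros(dims, dtype=bool)
    if spec.condition == "severe_blm":
        # Dense patch: lateral slab of the left lung, fused to the chest
        # wall, holding the requested fraction of all parenchyma voxels.
        target = spec.severe_patch_fraction * parenchyma.sum()
        xs = np.nonzero(parenchyma & left)[2]
        if target > xs.size:
            raise PhantomSpecError("severe_patch_fraction exceeds the left lung")
        cut = np.quantile(xs, target / xs.size)
        xcoord = np.arange(dims[2])[None, None, :]
        undetectable = parenchyma & left & (xcoord <= cut)
        parenchyma = parenchyma & ~undetectable

    hu[parenchyma] = _textured_values(rng, dims, parenchyma, spec.mixture, spec.support)
    if undetectable.any():
        n = int(undetectable.sum())
        lo, hi = SEVERE_PATCH_SUPPORT
        a = (lo - SEVERE_PATCH_MEAN) / SEVERE_PATCH_SD
        b = (hi - SEVERE_PATCH_MEAN) / SEVERE_PATCH_SD
        patch_vals = sps.truncnorm.rvs(
            a, b, loc=SEVERE_PATCH_MEAN, scale=SEVERE_PATCH_SD, size=n, random_state=rng
        )
        hu[undetectable] = patch_vals
    hu[airway] = -1000.0

    if spec.noise_hu_sd > 0:
        hu += rng.normal(0.0, spec.noise_hu_sd, size=dims)
    hu = _quantize_hu(hu)

    labels = np.zeros(dims, dtype=np.uint8)
    labels[parenchyma] = LABEL_LUNG
    labels[airway] = LABEL_AIRWAY
    labels[undetectable] = LABEL_UNDETECTABLE
    lung_map = LungMap(labels=labels, spacing_um=spec.spacing_um, source="phantom_truth")

    # True compartment fractions over the anatomical lung (detectable
    # parenchyma plus any undetectable patch), from the final (quantized)
    # values, under the preclinical thresholds.
    th = preclinical_thresholds()
    anatomical = parenchyma | undetectable
    lung_vals = hu[anatomical]
    b = th.boundaries
    codes = np.digitize(lung_vals, bins=b, right=False)
    codes[lung_vals == b[4]] = 4
    fractions = {
        name: float(np.mean(codes == i + 1)) for i, name in enumerate(COMPARTMENTS)
    }
    oor = float(np.mean((codes == 0) | (codes == 5)))

    voxel_mm3 = (spec.spacing_um / 1000.0) ** 3
    lung_mm3 = float(parenchyma.sum()) * voxel_mm3
    undet_mm3 = float(undetectable.sum()) * voxel_mm3
    # The hypo + non-aerated burden drives the coupled histological score.
    frac_hn = fractions["hypo_aerated"] + fractions["non_aerated"]
    score = _score_from_fraction(frac_hn, rng)

    grey = np.clip(np.round((hu + 1000.0) * 4.0 + PHANTOM_AIR_GREY), 0, 65535).astype(
        np.uint16
    )
    raw = RawVolume(voxels=grey, spacing_um=spec.spacing_um)
    truth = PhantomTruth(
        lung_map=lung_map,
        airway_seed=seed,
        compartment_fractions=fractions,
        out_of_range_fraction=oor,
        total_lung_mm3=lung_mm3 + undet_mm3,
        lung_mm3=lung_mm3,
        undetectable_mm3=undet_mm3,
        ashcroft_score=score,
    )
    return raw, truth


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate a phantom as a calibrated HU volume plus ground truth."""
    raw, truth = make_phantom_raw(spec)
    ct = calibrate_hu(raw, air_grey=PHANTOM_AIR_GREY, water_grey=PHANTOM_WATER_GREY)
    return ct, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def make_cohort(
    n_per_condition: dict[str, int],
    seed: int = 0,
    dims: tuple[int, int, int] = (96, 96, 96),
    spacing_um: float = 50.0,
    timepoint: int = 21,
    noise_hu_sd: float = 10.0,
) -> tuple[list[tuple[PhantomSpec, CTVolume, PhantomTruth]], pd.DataFrame]:
    """Generate a seeded cohort of phantoms plus its cohort table.

    ``n_per_condition`` maps condition name → subject count.  Each
    subject receives a child seed spawned from ``seed``.  The table
    carries subject id, group, timepoint, true volumes, compartment
    fractions, the 70th-percentile HU index (computed on the true lung
    mask) and the coupled synthetic Ashcroft score.
    """
    total = sum(n_per_condition.values())
    if total < 1:
        raise ValueError("cohort must contain at least one subject")
    for cond in n_per_condition:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
    from .densitometry import percentile_hu

    children = np.random.SeedSequence(seed).spawn(total)
    subjects = []
    rows = []
    i = 0
    for cond in CONDITIONS:
        for k in range(n_per_condition.get(cond, 0)):
            child_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
            spec = PhantomSpec(
                condition=cond,
                dims=dims,
                spacing_um=spacing_um,
                noise_hu_sd=noise_hu_sd,
                seed=child_seed,
            )
            ct, truth = make_phantom(spec)
            p70 = percentile_hu(ct, truth.lung_map, 70.0)
            subjects.append((spec, ct, truth))
            rows.append(
                {
                    "subject_id": f"{cond}_{k:03d}",
                    "group": cond,
                    "timepoint": timepoint,
                    "v_total_mm3": truth.total_lung_mm3,
                    "v_lung_mm3": truth.lung_mm3,
                    "v_undetectable_mm3": truth.undetectable_mm3,
                    "p70_hu": p70,
                    "frac_normo": truth.compartment_fractions["normo_aerated"],
                    "frac_hypo_non": truth.hypo_non_fraction,
                    "ashcroft": truth.ashcroft_score,
                }
            )
            i += 1
    return subjects, pd.DataFrame(rows)
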