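"""Semi-automatic airway and lung segmentation.

The screening workflow segments the airway tree by seeded region growing
inside an HU window around air, then extracts the lung parenchyma by
thresholding a second HU window, removing the airways, keeping the large
thoracic components and morphologically closing the result so that
intrapulmonary vessels and septa are counted as lung.  Severely fibrotic
lungs, whose dense regions merge with the chest wall at soft-tissue HU,
defeat this procedure; those are handled by a manually drawn mask or by
the predictive-volume rule (see :mod:`pulmodens.predictive_volume`).

Label convention for lung maps: 0 background, 1 lung, 2 airway,
3 undetectable (dense fibrotic tissue missed by thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, read_volume

LABEL_BACKGROUND = 0
LABEL_LUNG = 1
LABEL_AIRWAY = 2
LABEL_UNDETECTABLE = 3

_KNOWN_LABELS = {LABEL_BACKGROUND, LABEL_LUNG, LABEL_AIRWAY, LABEL_UNDETECTABLE}

#: Default parenchyma HU window for semi-automatic lung extraction.  The
#: mild/moderate fibrotic density distribution is wholly contained in
#: [-860, -121] HU and normal parenchyma lies within it as well.
DEFAULT_LUNG_HU_WINDOW = (-860.0, -121.0)

#: Default HU window for seeded airway region growing (air-like voxels).
DEFAULT_AIRWAY_HU_WINDOW = (-1100.0, -900.0)

#: 6-connected structuring element: conservative against leakage through
#: thin chest-wall gaps.
_CONN6 = ndimage.generate_binary_structure(3, 1)


class SegmentationError(RuntimeError):
    """Raised when the semi-automatic procedure cannot produce a lung map."""


class SeedError(ValueError):
    """Raised when a region-growing seed is invalid."""


@dataclass
class LungMap:
    """Voxel label map aligned to a :class:`~pulmodens.volume_io.CTVolume`."""

    labels: np.ndarray
    spacing_um: float
    source: str = "semi_automatic"  # or "manual" / "phantom_truth"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("LungMap labels must be 3-D")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def lung(self) -> np.ndarray:
        return self.labels == LABEL_LUNG

    @property
    def airway(self) -> np.ndarray:
        return self.labels == LABEL_AIRWAY

    @property
    def undetectable(self) -> np.ndarray:
        return self.labels == LABEL_UNDETECTABLE


def extract_airways(
    ct: CTVolume,
    seed: tuple[int, int, int],
    hu_range: tuple[float, float] = DEFAULT_AIRWAY_HU_WINDOW,
) -> np.ndarray:
    """Seeded region growing for the airway tree.

    Returns the 6-connected component of voxels whose HU lies within
    ``hu_range`` that contains ``seed`` (a ``(z, y, x)`` voxel index).
    """
    seed = tuple(int(c) for c in seed)
    if len(seed) != 3 or any(c < 0 or c >= s for c, s in zip(seed, ct.shape)):
        raise SeedError(f"seed {seed} lies outside the volume of shape {ct.shape}")
    low, high = hu_range
    value = float(ct.voxels[seed])
    if not (low <= value <= high):
        raise SeedError(
            f"seed voxel HU {value:.1f} is outside the airway window [{low}, {high}]"
        )
    in_window = (ct.voxels >= low) & (ct.voxels <= high)
    components, _ = ndimage.label(in_window, structure=_CONN6)
    return components == components[seed]


def _binary_closing_ball(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with a Euclidean ball, via distance transforms.

    Equivalent to dilation then erosion with a ball of ``radius`` voxels,
    but much faster on large volumes than structuring-element iteration.
    """
    if radius <= 0:
        return mask
    dilated = ndimage.distance_transform_edt(~mask) <= radius
    closed = ndimage.distance_transform_edt(dilated) > radius
    # Erosion via EDT measures distance to the background of the dilated
    # set; voxels deeper than `radius` survive.  Union with the original
    # mask guards against erosion nibbling thin original structures.
    return closed | mask


def segment_lung(
    ct: CTVolume,
    hu_range: tuple[float, float] = DEFAULT_LUNG_HU_WINDOW,
    airway_mask: np.ndarray | None = None,
    closing_radius: int = 3,
    component_fraction: float = 0.01,
) -> LungMap:
    """Semi-automatic parenchyma extraction.

    Thresholds ``ct`` to ``hu_range``, removes the airway component,
    keeps connected components at least ``component_fraction`` of the
    largest (so both lungs survive even if disconnected), closes with a
    ball of ``closing_radius`` voxels to re-include vessels and septa,
    and labels the result as lung.

    Raises
    ------
    SegmentationError
        If no parenchyma component is found — the signature of a severely
        fibrotic lung needing manual or predictive-volume handling.
    """
    low, high = hu_range
    in_window = (ct.voxels >= low) & (ct.voxels <= high)
    if airway_mask is not None:
        if airway_mask.shape != ct.shape:
            raise SegmentationError("airway mask is not aligned to the CT volume")
        in_window &= ~airway_mask
    else:
        airway_mask = np.zeros(ct.shape, dtype=bool)

    components, n = ndimage.label(in_window, structure=_CONN6)
    if n == 0:
        raise SegmentationError(
            "no parenchyma detected in the HU window; manual segmentation or the "
            "predictive-volume rule is required"
        )
    counts = np.bincount(components.ravel())
    counts[0] = 0
    largest = counts.max()
    if largest == 0:
        raise SegmentationError("no parenchyma detected in the HU window")
    keep_ids = np.flatnonzero(counts >= component_fraction * largest)
    lung = np.isin(components, keep_ids)

    lung = _binary_closing_ball(lung, closing_radius)
    lung &= ~airway_mask  # closing must never claim airway voxels

    labels = np.zeros(ct.shape, dtype=np.uint8)
    labels[lung] = LABEL_LUNG
    labels[airway_mask] = LABEL_AIRWAY
    return LungMap(labels=labels, spacing_um=ct.spacing_um, source="semi_automatic")


def load_manual_mask(path: str, ct: CTVolume) -> LungMap:
    """Ingest a manually drawn label mask aligned to ``ct``.

    The mask file must contain only the labels {0 background, 1 lung,
    2 airway, 3 undetectable}.  An empty mask is accepted with a warning.
    """
    import logging

    raw = read_volume(path)
    if raw.shape != ct.shape:
        raise ValueError(
            f"manual mask dims {raw.shape} do not match CT volume dims {ct.shape}"
        )
    labels = raw.voxels.astype(np.int64)
    unknown = sorted(set(int(v) for v in np.unique(labels)) - _KNOWN_LABELS)
    if unknown:
        raise ValueError(f"manual mask contains unknown labels: {unknown}")
    if not labels.any():
        logging.getLogger("pulmodens").warning("manual mask %s is empty", path)
    return LungMap(labels=labels.astype(np.uint8), spacing_um=ct.spacing_um, source="manual")


def mask_volume(lung_map: LungMap, label_set=(LABEL_LUNG,)) -> float:
    """Volume in mm³ of the voxels carrying any label in ``label_set``."""
    label_set = set(int(l) for l in label_set)
    if not label_set:
        return 0.0
    n = int(np.isin(lung_map.labels, sorted(label_set)).sum())
    voxel_mm3 = (lung_map.spacing_um / 1000.0) ** 3
    return n * voxel_mm3


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A|+|B|) between boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
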