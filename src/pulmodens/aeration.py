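"""Aeration-compartment classification of lung voxels.

Four compartments by air content, bounded by five HU values
``b0 < b1 < b2 < b3 < b4``:

* hyper-inflated  ``[b0, b1)``
* normo-aerated   ``[b1, b2)``
* hypo-aerated    ``[b2, b3)``
* non-aerated     ``[b3, b4]``

The preclinical (murine) set is (−1040, −860, −435, −121, +121); the
hyper-inflated and non-aerated ranges are centred on the theoretical
95 % air + 5 % tissue mixture (−950 HU) and pure tissue (0 HU).  The
clinical comparison set is (−1000, −900, −500, −100, +100), the human
whole-lung aeration ranges; its hypo-aerated interval [−500, −100) is
the gap between the published normally- and poorly-aerated ranges.

Shared boundaries are resolved left-closed/right-open (the final edge is
closed) so that every HU value maps to exactly one compartment.  Lung
voxels outside ``[b0, b4]`` are reported as ``out_of_range`` rather than
forced into an edge compartment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .segmentation import LABEL_LUNG, LungMap
from .volume_io import CTVolume

COMPARTMENTS = ("hyper_inflated", "normo_aerated", "hypo_aerated", "non_aerated")

#: Compartment codes in the classification label map.
CODE_OUT_OF_RANGE = 5
_CODES = {name: i + 1 for i, name in enumerate(COMPARTMENTS)}  # 1..4


@dataclass(frozen=True)
class AerationThresholds:
    """Named, strictly increasing set of five HU boundaries."""

    name: str
    boundaries: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.boundaries) != 5:
            raise ValueError("exactly five HU boundaries are required")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    def interval(self, compartment: str) -> tuple[float, float]:
        i = COMPARTMENTS.index(compartment)
        return (self.boundaries[i], self.boundaries[i + 1])


@dataclass
class AerationReport:
    """Per-compartment volumes and percentages of total lung volume."""

    thresholds: AerationThresholds
    volume_mm3: dict[str, float]
    percent: dict[str, float]
    out_of_range_mm3: float
    out_of_range_percent: float
    total_lung_mm3: float

    def to_dict(self) -> dict:
        rows = []
        for name in COMPARTMENTS:
            lo, hi = self.thresholds.interval(name)
            rows.append(
                {
                    "compartment": name,
                    "hu_low": lo,
                    "hu_high": hi,
                    "volume_mm3": self.volume_mm3[name],
                    "percent": self.percent[name],
                }
            )
        rows.append(
            {
                "compartment": "out_of_range",
                "hu_low": None,
                "hu_high": None,
                "volume_mm3": self.out_of_range_mm3,
                "percent": self.out_of_range_percent,
            }
        )
        return {
            "thresholds": self.thresholds.name,
            "total_lung_mm3": self.total_lung_mm3,
            "compartments": rows,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def preclinical_thresholds() -> AerationThresholds:
    """Murine aeration boundaries (−1040, −860, −435, −121, +121) HU."""
    return AerationThresholds("preclinical", (-1040.0, -860.0, -435.0, -121.0, 121.0))


def clinical_thresholds() -> AerationThresholds:
    """Human whole-lung boundaries (−1000, −900, −500, −100, +100) HU."""
    return AerationThresholds("clinical", (-1000.0, -900.0, -500.0, -100.0, 100.0))


def classify_voxels(
    ct: CTVolume, lung_map: LungMap, thresholds: AerationThresholds
) -> np.ndarray:
    """Assign every lung voxel to one compartment (or out_of_range).

    Returns a uint8 label volume: 0 non-lung, 1 hyper-inflated,
    2 normo-aerated, 3 hypo-aerated, 4 non-aerated, 5 out-of-range.
    """
    if lung_map.shape != ct.shape:
        raise ValueError("lung map is not aligned to the CT volume")
    b = thresholds.boundaries
    lung = lung_map.labels == LABEL_LUNG
    hu = ct.voxels
    out = np.zeros(ct.shape, dtype=np.uint8)
    # np.digitize with right=False gives left-closed/right-open cuts.
    codes = np.digitize(hu[lung], bins=b, right=False)  # 0..5
    # codes: 0 -> below b0 (out of range); 1..4 -> compartments; 5 -> above b4.
    labels = np.where((codes == 0) | (codes == 5), CODE_OUT_OF_RANGE, codes).astype(np.uint8)
    # Final edge is right-closed: HU exactly b4 belongs to non-aerated.
    labels[hu[lung] == b[4]] = _CODES["non_aerated"]
    out[lung] = labels
    return out


def compartment_report(
    labelmap: np.ndarray,
    spacing_um: float,
    thresholds: AerationThresholds,
) -> AerationReport:
    """Volumes and percentages from a compartment label map."""
    voxel_mm3 = (spacing_um / 1000.0) ** 3
    counts = np.bincount(labelmap.ravel(), minlength=CODE_OUT_OF_RANGE + 1)
    lung_total = int(counts[1 : CODE_OUT_OF_RANGE + 1].sum())
    if lung_total == 0:
        raise ValueError("label map contains no lung voxels")
    volume = {}
    percent = {}
    for name, code in _CODES.items():
        n = int(counts[code])
        volume[name] = n * voxel_mm3
        percent[name] = 100.0 * n / lung_total
    n_oor = int(counts[CODE_OUT_OF_RANGE])
    return AerationReport(
        thresholds=thresholds,
        volume_mm3=volume,
        percent=percent,
        out_of_range_mm3=n_oor * voxel_mm3,
        out_of_range_percent=100.0 * n_oor / lung_total,
        total_lung_mm3=lung_total * voxel_mm3,
    )


def aeration_report(
    ct: CTVolume, lung_map: LungMap, thresholds: AerationThresholds
) -> AerationReport:
    """Classify and report in one call."""
    labels = classify_voxels(ct, lung_map, thresholds)
    return compartment_report(labels, lung_map.spacing_um, thresholds)


def double_threshold_compare(
    ct: CTVolume, lung_map: LungMap
) -> tuple[AerationReport, AerationReport, dict[str, float]]:
    """Classify the same lung voxels under preclinical and clinical sets.

    Returns ``(preclinical_report, clinical_report, delta)`` where
    ``delta[compartment] = preclinical% − clinical%``.
    """
    pre = aeration_report(ct, lung_map, preclinical_thresholds())
    cli = aeration_report(ct, lung_map, clinical_thresholds())
    delta = {name: pre.percent[name] - cli.percent[name] for name in COMPARTMENTS}
    return pre, cli, delta
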