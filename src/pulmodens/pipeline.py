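"""End-to-end per-subject processing and cohort-level convenience runs.

One subject's path through the method: median pre-filter, seeded airway
extraction, semi-automatic lung segmentation, densitometric summary,
percentile indices, and aeration reports under both threshold sets.
These helpers are what the command-line interface and the calibration
checks drive; they contain no logic of their own beyond sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import aeration, densitometry, segmentation, volume_io
from .phantom import PhantomSpec, make_phantom


@dataclass
class SubjectResult:
    """Per-subject outputs of the standard processing chain."""

    lung_map: segmentation.LungMap
    summary: densitometry.LungSummary
    p40_hu: float
    p70_hu: float
    frac_above_minus435: float
    report_preclinical: aeration.AerationReport
    report_clinical: aeration.AerationReport
    hist: densitometry.DensityHistogram


def process_subject(
    ct: volume_io.CTVolume,
    airway_seed: tuple[int, int, int],
    *,
    median_kernel: int = 5,
    airway_hu_range=segmentation.DEFAULT_AIRWAY_HU_WINDOW,
    lung_hu_range=segmentation.DEFAULT_LUNG_HU_WINDOW,
    closing_radius: int = 3,
    lung_map: segmentation.LungMap | None = None,
) -> SubjectResult:
    """Run the standard chain on one calibrated volume.

    When ``lung_map`` is supplied (manual segmentation or phantom truth)
    the segmentation steps are skipped and densitometry runs on it
    directly; the median pre-filter is still applied.
    """
    filtered = volume_io.median_filter(ct, median_kernel)
    if lung_map is None:
        airway = segmentation.extract_airways(filtered, airway_seed, airway_hu_range)
        lung_map = segmentation.segment_lung(
            filtered, lung_hu_range, airway_mask=airway, closing_radius=closing_radius
        )
    lung_values = filtered.voxels[lung_map.labels == segmentation.LABEL_LUNG]
    summary = densitometry.summarize(filtered, lung_map)
    pre, cli, _ = aeration.double_threshold_compare(filtered, lung_map)
    return SubjectResult(
        lung_map=lung_map,
        summary=summary,
        p40_hu=densitometry.percentile_hu(filtered, lung_map, 40.0),
        p70_hu=densitometry.percentile_hu(filtered, lung_map, 70.0),
        frac_above_minus435=float(np.mean(lung_values > -435.0)),
        report_preclinical=pre,
        report_clinical=cli,
        hist=densitometry.histogram(filtered, lung_map),
    )


@dataclass
class HealthyCohortCalibration:
    """Cohort-mean calibration read-outs on segmented healthy phantoms."""

    n: int
    mean_pct_above_minus435: float
    mean_normo_preclinical_pct: float
    mean_normo_clinical_pct: float

    @property
    def normo_delta_pct(self) -> float:
        return self.mean_normo_preclinical_pct - self.mean_normo_clinical_pct


def healthy_cohort_calibration(
    n: int = 20,
    base_seed: int = 1,
    dims: tuple[int, int, int] = (192, 192, 192),
) -> HealthyCohortCalibration:
    """Generate, segment and classify ``n`` healthy phantoms.

    Per-phantom seeds are ``base_seed, base_seed+1, ...``.  Returns the
    cohort means of: percentage of segmented lung voxels above −435 HU,
    and normo-aerated percentage under the preclinical and clinical
    threshold sets.
    """
    above, normo_pre, normo_cli = [], [], []
    for i in range(n):
        spec = PhantomSpec(condition="healthy", dims=dims, seed=base_seed + i)
        ct, truth = make_phantom(spec)
        res = process_subject(ct, truth.airway_seed)
        above.append(100.0 * res.frac_above_minus435)
        normo_pre.append(res.report_preclinical.percent["normo_aerated"])
        normo_cli.append(res.report_clinical.percent["normo_aerated"])
    return HealthyCohortCalibration(
        n=n,
        mean_pct_above_minus435=float(np.mean(above)),
        mean_normo_preclinical_pct=float(np.mean(normo_pre)),
        mean_normo_clinical_pct=float(np.mean(normo_cli)),
    )
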