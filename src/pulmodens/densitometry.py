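"""Histogram-based lung densitometry.

Quantitative read-outs from the HU values of segmented lung voxels:
summary statistics, 10-HU-bin attenuation histograms with cumulative
curves, nearest-rank percentile indices, longitudinal ΔHU percentile
profiles, and the data-driven derivations of the staging threshold and
of the normo-/hypo-aerated compartment limits.

The staging read-out of choice is the 70th percentile of the lung HU
distribution: it rises as fibrotic consolidation replaces aerated
parenchyma, and its midpoint between the healthiest pathological and
densest healthy cohorts defines the normo/hypo boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import LABEL_LUNG, LungMap
from .volume_io import CTVolume

logger = logging.getLogger("pulmodens")

#: Default attenuation-histogram range and bin width: 100 bins of 10 HU
#: over [-1000, 0].
DEFAULT_HIST_RANGE = (-1000.0, 0.0)
DEFAULT_BIN_WIDTH = 10.0

#: Extended range covering all four aeration compartments.
EXTENDED_HIST_RANGE = (-1040.0, 121.0)

#: Percentile grid for longitudinal ΔHU profiling: every 5th percentile
#: from the 10th to the 90th.
DELTA_PERCENTILE_GRID = tuple(range(10, 95, 5))


class EmptyLungError(ValueError):
    """Raised when an operation requires at least one lung voxel."""


@dataclass
class LungSummary:
    """Whole-lung summary metrics (airways excluded)."""

    volume_mm3: float
    mean_hu: float
    sd_hu: float
    min_hu: float
    max_hu: float


@dataclass
class DensityHistogram:
    """Equal-width attenuation histogram of lung voxels.

    Bins are left-closed/right-open, except the final bin which also
    includes the right edge.  Voxels outside the range are tracked in
    ``out_of_range_count`` so no mass is silently lost.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    total: int
    out_of_range_count: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("histogram bins must have constant width")
        if self.counts.sum() + self.out_of_range_count != self.total:
            raise ValueError("histogram counts do not conserve the voxel total")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total


@dataclass
class PercentileProfile:
    """HU value at each percentile of a lung density distribution."""

    percentiles: np.ndarray
    hu_values: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.hu_values = np.asarray(self.hu_values, dtype=float)
        if np.any(np.diff(self.percentiles) <= 0):
            raise ValueError("percentiles must be strictly increasing")
        if np.any(np.diff(self.hu_values) < -1e-9):
            raise ValueError("hu_values must be non-decreasing in percentile")


def _lung_values(ct: CTVolume, lung_map: LungMap) -> np.ndarray:
    if lung_map.shape != ct.shape:
        raise ValueError("lung map is not aligned to the CT volume")
    values = ct.voxels[lung_map.labels == LABEL_LUNG]
    if values.size == 0:
        raise EmptyLungError("no lung-labelled voxels")
    return values


def summarize(ct: CTVolume, lung_map: LungMap) -> LungSummary:
    """Summary statistics over lung voxels (label 1 only)."""
    values = _lung_values(ct, lung_map)
    voxel_mm3 = (lung_map.spacing_um / 1000.0) ** 3
    return LungSummary(
        volume_mm3=values.size * voxel_mm3,
        mean_hu=float(values.mean()),
        sd_hu=float(values.std(ddof=0)),
        min_hu=float(values.min()),
        max_hu=float(values.max()),
    )


def histogram(
    ct: CTVolume,
    lung_map: LungMap,
    bin_width: float = DEFAULT_BIN_WIDTH,
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE,
) -> DensityHistogram:
    """10-HU-bin attenuation histogram of the lung voxels.

    ``hist_range`` width must be an integer multiple of ``bin_width``.
    """
    lo, hi = hist_range
    n_bins = (hi - lo) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"range [{lo}, {hi}] is not divisible into bins of width {bin_width}"
        )
    n_bins = int(round(n_bins))
    values = _lung_values(ct, lung_map)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    in_range = int(counts.sum())
    return DensityHistogram(
        bin_edges=edges,
        counts=counts,
        total=int(values.size),
        out_of_range_count=int(values.size) - in_range,
    )


def cumulative(hist: DensityHistogram) -> np.ndarray:
    """Cumulative frequency curve; reaches 1 when no voxel fell outside."""
    return np.cumsum(hist.frequencies)


def percentile_hu(ct: CTVolume, lung_map: LungMap, p: float) -> float:
    """Nearest-rank percentile of the lung HU distribution.

    The ``p``-th percentile is the value at rank ``ceil(p/100 * n)`` of
    the sorted lung voxel HU values (1-based), for ``p`` in (0, 100).
    """
    if not 0 < p < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {p}")
    values = np.sort(_lung_values(ct, lung_map))
    rank = int(np.ceil(p / 100.0 * values.size))
    return float(values[max(rank, 1) - 1])


def percentile_profile(
    ct: CTVolume,
    lung_map: LungMap,
    percentiles=DELTA_PERCENTILE_GRID,
    subject_id: str | None = None,
) -> PercentileProfile:
    """Percentile profile over a grid (default 10th–90th, step 5)."""
    values = np.sort(_lung_values(ct, lung_map))
    ps = np.asarray(sorted(percentiles), dtype=float)
    ranks = np.ceil(ps / 100.0 * values.size).astype(int)
    hu = values[np.maximum(ranks, 1) - 1]
    return PercentileProfile(percentiles=ps, hu_values=hu, subject_id=subject_id)


def histogram_percentile(hist: DensityHistogram, p: float) -> float:
    """Approximate percentile read from a binned histogram.

    Returns the right edge of the first bin at which the cumulative
    frequency reaches ``p/100``.  Accurate to within one bin width; meant
    for memory-constrained batch processing where raw voxels are not kept.
    """
    if not 0 < p < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {p}")
    if hist.total == 0:
        raise EmptyLungError("empty histogram")
    cum = np.cumsum(hist.counts) / hist.total
    idx = int(np.searchsorted(cum, p / 100.0))
    idx = min(idx, hist.n_bins - 1)
    return float(hist.bin_edges[idx + 1])


def delta_hu_profile(
    cohort_t0: dict[str, PercentileProfile],
    cohort_t1: dict[str, PercentileProfile],
) -> PercentileProfile:
    """Mean longitudinal HU increase per percentile, subject-matched.

    ``cohort_t0`` and ``cohort_t1`` map subject id → profile at the first
    and second timepoint (e.g. day 7 and day 21); subjects must match and
    share the percentile grid.  Returns the per-percentile mean of
    ``HU_t1 − HU_t0`` across subjects (as a profile whose ``hu_values``
    are ΔHU; they need not be monotone).
    """
    if set(cohort_t0) != set(cohort_t1):
        raise ValueError("subjects are not matched across the two timepoints")
    if not cohort_t0:
        raise ValueError("empty cohort")
    subjects = sorted(cohort_t0)
    grid = cohort_t0[subjects[0]].percentiles
    deltas = []
    for s in subjects:
        p0, p1 = cohort_t0[s], cohort_t1[s]
        if not (np.array_equal(p0.percentiles, grid) and np.array_equal(p1.percentiles, grid)):
            raise ValueError(f"subject {s!r} has a mismatched percentile grid")
        deltas.append(p1.hu_values - p0.hu_values)
    mean_delta = np.mean(deltas, axis=0)
    out = PercentileProfile.__new__(PercentileProfile)
    out.percentiles = np.asarray(grid, dtype=float)
    out.hu_values = mean_delta  # ΔHU, deliberately not monotonicity-checked
    out.subject_id = None
    return out


def select_discriminative_percentiles(
    profile_a: PercentileProfile, profile_b: PercentileProfile
) -> list[tuple[float, float]]:
    """Rank percentiles by between-group |ΔHU| separation.

    Returns ``(percentile, |ΔHU_A − ΔHU_B|)`` pairs sorted by descending
    separation; ties resolve toward the higher percentile.
    """
    if not np.array_equal(profile_a.percentiles, profile_b.percentiles):
        raise ValueError("profiles are on different percentile grids")
    sep = np.abs(profile_a.hu_values - profile_b.hu_values)
    order = sorted(
        range(len(sep)),
        key=lambda i: (-sep[i], -profile_a.percentiles[i]),
    )
    return [(float(profile_a.percentiles[i]), float(sep[i])) for i in order]


def derive_staging_threshold(saline_70th, blm_70th) -> float:
    """Normo/hypo boundary from cohort 70th-percentile indices.

    The threshold is the mean of the highest 70th percentile among
    healthy (saline) subjects and the lowest among fibrotic (BLM)
    subjects.  If the groups overlap the value is still returned but a
    warning is emitted.
    """
    saline = np.asarray(list(saline_70th), dtype=float)
    blm = np.asarray(list(blm_70th), dtype=float)
    if saline.size == 0 or blm.size == 0:
        raise ValueError("both cohorts must be non-empty")
    hi_saline = saline.max()
    lo_blm = blm.min()
    if hi_saline > lo_blm:
        warnings.warn(
            "saline and BLM 70th-percentile ranges overlap; the derived "
            "threshold does not separate the groups",
            stacklevel=2,
        )
    return float((hi_saline + lo_blm) / 2.0)


def _mean_frequencies(histograms) -> tuple[np.ndarray, np.ndarray]:
    hists = list(histograms)
    if not hists:
        raise ValueError("empty histogram cohort")
    edges = hists[0].bin_edges
    for h in hists:
        if not np.array_equal(h.bin_edges, edges):
            raise ValueError("cohort histograms must share bin edges")
    freqs = np.mean([h.frequencies for h in hists], axis=0)
    return edges, freqs


def derive_normo_lower_limit(healthy_histograms, tail_fraction: float = 0.0002) -> float:
    """Lower normo-aerated limit from the healthy cohort's left tail.

    Using the cohort-mean frequency vector (mean of per-subject
    frequencies, not pooled voxels), returns the largest bin edge below
    which the mean cumulative mass is still ≤ ``tail_fraction`` (default
    0.02%).  With the observed healthy distributions this lands on the
    edge −860 HU.
    """
    edges, freqs = _mean_frequencies(healthy_histograms)
    cum = np.concatenate([[0.0], np.cumsum(freqs)])  # mass strictly below each edge
    ok = np.flatnonzero(cum <= tail_fraction + 1e-12)
    return float(edges[ok[-1]])


def derive_hypo_upper_limit(auto_segmented_histograms) -> float:
    """Upper hypo-aerated limit: densest HU reached by the cohort.

    Returns the upper edge of the highest occupied bin across all
    automatically segmented lung histograms.
    """
    hists = list(auto_segmented_histograms)
    if not hists:
        raise ValueError("empty histogram cohort")
    edges = hists[0].bin_edges
    best = None
    for h in hists:
        if not np.array_equal(h.bin_edges, edges):
            raise ValueError("cohort histograms must share bin edges")
        occupied = np.flatnonzero(h.counts)
        if occupied.size:
            top = occupied[-1]
            best = top if best is None else max(best, top)
    if best is None:
        raise ValueError("all histograms in the cohort are empty")
    return float(edges[best + 1])
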