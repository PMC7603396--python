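# Methods

This note documents the models, conventions and numerical choices
behind `pulmodens`, and what its synthetic phantoms do and do not show
about real micro-CT data.

## Calibration and pre-filtering

Scanner output is assumed to be unsigned 16-bit grey values on an
isotropic lattice (50 µm in typical murine chest protocols; the reader
falls back to 50 µm with a warning when a file carries no spacing).
Grey levels are converted to CT numbers by a two-point linear map
anchored at reference regions: HU(air) = −1000, HU(water) = 0.  Real
scanners calibrate internally; the explicit two-point scheme exists so
that synthetic data can be driven through the identical code path, and
a pass-through flag accepts volumes already expressed in HU.  Stored HU
are clipped to the conventional [−1024, +3071] window, in float32 (finer
than 1 HU).  A cubic median filter (default 5×5×5) is applied before
every analysis; borders are handled by edge replication so no
out-of-range values are invented.  All modules share the (z, y, x) axis
order and 0-based voxel indexing.

## Segmentation

The airway tree is grown as the 6-connected component of voxels inside
an HU window (default [−1100, −900]) containing a user-supplied seed.
6-connectivity is deliberately conservative: it resists leakage through
single-voxel chest-wall gaps.  The lung is then the union of connected
components of the parenchyma window (default [−860, −121] HU — the
window that contains both normal parenchyma and mild/moderate fibrotic
densities) after removal of the airway mask; components at least 1 % the
size of the largest are kept so that anatomically disconnected left and
right lungs both survive.  A morphological closing with a Euclidean ball
(default radius 3 voxels, computed via two distance transforms for
speed) re-includes intrapulmonary vessels and septa, which lie above the
window.  The closing never claims airway voxels, so lung and airway
labels are disjoint by construction.  An empty threshold result raises a
segmentation-failure error — the signature of severe fibrosis, routed to
manual masks or the predictive-volume rule.

## Densitometry

Attenuation histograms use left-closed/right-open bins of 10 HU over
[−1000, 0] (100 bins), the final bin right-closed; voxels outside the
range are counted separately so total mass is conserved (an extended
range [−1040, +121] covering all four compartments is available).
Percentile indices use the nearest-rank convention on raw voxel values —
the p-th percentile is the value at rank ⌈p/100·n⌉ of the sorted lung
HU — which makes small worked examples exactly reproducible; a
histogram-based percentile (accurate to one bin width) is provided for
batch processing that does not retain raw voxels.  Whether percentiles
should be computed from voxels or from 10-HU-binned histograms is
genuinely open in practice; both are exposed, voxel-based being the
default.  Longitudinal ΔHU profiles average per-subject percentile
differences (day 21 − day 7 in the standard design) on the
10th–90th/step-5 grid; candidate staging indices are ranked by absolute
between-group ΔHU separation, ties resolving toward the higher
percentile.  Cohort-mean histograms are means of per-subject frequency
vectors, not pooled voxels, so each animal carries equal weight.

Three data-driven derivations define the murine thresholds:

* staging threshold: the midpoint between the highest healthy-cohort and
  lowest fibrotic-cohort 70th percentile (−435 HU in the reference
  data); overlapping cohorts still return the midpoint but warn;
* normo-aerated lower limit: the largest histogram edge below which the
  healthy cohort's mean cumulative mass stays within a 0.02 % tail
  (−860 HU).  The rule presumes contiguous support above the tail, which
  real lung histograms have;
* hypo-aerated upper limit: the highest HU reached by any automatically
  segmented lung histogram (−121 HU).

## Aeration compartments

Two threshold sets are built in: preclinical (−1040, −860, −435, −121,
+121) and clinical (−1000, −900, −500, −100, +100).  The hyper-inflated
and non-aerated preclinical ranges are centred on the theoretical 95 %
air + 5 % tissue mixture (−950 HU) and pure tissue (0 HU).  The clinical
hypo-aerated interval is not tabulated alongside the published low /
normal / high ranges; [−500, −100) fills the gap and follows standard
whole-lung aeration usage, and is configurable.  Published range pairs
touch at their shared boundaries; classification resolves this as
left-closed/right-open (final edge closed) so every HU maps to exactly
one compartment and compartment volumes partition the lung exactly.
Lung voxels outside [b0, b4] are reported as out-of-range rather than
forced into edge compartments.  The hyper-inflated compartment is
carried through all reports although fibrosis studies rarely populate
it; it is the read-out of interest for emphysema models.

## Predictive lung volume

Severe fibrotic consolidation reaches soft-tissue HU and fuses with the
chest wall, so threshold segmentation under-estimates the lung.  The
rule maps the automatic volume v_auto through a piecewise function with
parameters A < B taken from the distribution of manually segmented total
volumes in fibrotic cohorts: below A it predicts A, between A and B it
predicts B, above B it returns v_auto.  Three calibration strategies are
implemented — quartiles (A, B = 25th, 75th percentile, nearest-rank),
mean ± SD, and the 95 % CI of the mean (the CI-of-the-mean reading of an
ambiguous specification; flagged in the docstring).  Quartiles are the
retained default, giving A = 534 mm³ and B = 646 mm³ on the reference
murine cohort.  As printed, the lower branch returns A (< B), so the
prediction steps downward as v_auto crosses A from above; the rule is
implemented exactly as stated rather than "fixed", with a note in the
docs, and boundary ties (v_auto = A or B) join the middle branch for
continuity with it.  Predictions never fall below the input, so the
undetectable volume v_pred − v_auto is non-negative.  Validation reports
residual normality (Lilliefors KS, Shapiro–Wilk, D'Agostino–Pearson,
Anderson–Darling), QQ coordinates, and the fractions of animals
predicted within 10 % and 20 % of the manual volume.

## Statistics

Spearman correlation (average ranks on ties) and the paired Wilcoxon
signed-rank test wrap scipy; the Lilliefors-corrected KS test uses
statsmodels' table-interpolated (Dallal–Wilkinson) p-values; Dunnett's
many-to-one comparisons use scipy's multivariate-t implementation.
Steiger's test for two dependent correlations sharing a variable uses
the Z̄₁* variant: Fisher-transformed correlations, with the sampling
covariance evaluated at the pooled correlation r̄ = (r13+r23)/2 through
the Pearson–Filon expression
ψ = r12(1−2r̄²) − ½r̄²(1−2r̄²−r12²), giving
Z = (z13−z23)·√((n−3)/(2−2ψ/(1−r̄²)²)).  One-tailed p-values halve the
two-tailed normal probability.  Ashcroft scores (0–8, modified scale)
class as mild (0–3), moderate (4) and severe (≥5).

## Synthetic phantoms

The generator produces stylized chests: a soft-tissue cylinder (~0 HU)
in air, two ellipsoidal lungs (at the default 192³/50 µm grid, about
61 mm³ of parenchyma), and a three-segment airway tube at −1000 HU whose
trachea is sealed inside the mediastinum so region growing cannot leak
to exterior air.  Parenchyma HU values are generated by rank-transforming
a smoothed Gaussian field (correlation length 3 voxels) to uniform and
pushing it through the inverse CDF of a truncated-normal mixture, so the
marginal HU distribution is *exact* while values stay spatially
correlated — real motion and noise artifacts are regional, and spatially
uncorrelated salt would be annihilated by the median pre-filter.
Gaussian noise (default SD 10 HU) and 16-bit quantization (0.25 HU
steps) follow; ground-truth compartment fractions are computed from the
final quantized values, so with noise disabled they match voxel
classification exactly.

Condition mixtures:

* **healthy** — a dominant aerated component centred at −610 HU plus two
  right-shifted components representing denser parenchyma and
  motion/noise artifacts.  The exact weights and the aerated spread are
  calibration outputs of `scripts/calibrate_phantom.py`, solved so that
  a segmented 20-phantom cohort reproduces the murine end-expiration
  facts the generator is meant to emulate: ≈20 % of lung voxels above
  −435 HU, ≈79 % normo-aerated under preclinical thresholds and ≈64 %
  under clinical ones (≈15-point difference);
* **mild_blm** — a single truncated normal at −440 ± 95 HU with support
  [−840, −150], i.e. wholly inside [−860, −121]: mild/moderate fibrotic
  lungs contain no non-aerated tissue and remain fully segmentable;
* **severe_blm** — the mild distribution plus a contiguous lateral patch
  (default 25 % of the parenchyma) at non-aerated HU (0 ± 50, support
  [−115, 115]) fused to the chest wall, labelled *undetectable* in the
  truth map: threshold segmentation loses it, exercising the
  predictive-volume pathway.

Synthetic Ashcroft-like scores are a monotone piecewise-linear map of
the true hypo+non-aerated fraction (anchors chosen so healthy ≈ 2, mild
≈ 4, severe ≥ 5) with a ±1 integer perturbation at probability 0.15 per
side, clamped to [0, 8].  In a 15+15 healthy/mild cohort this coupling
is designed to yield a Spearman correlation between the 70th-percentile
index and the score in the 0.6–0.9 band, bracketing the 0.7-ish regime
seen in real cohorts.

What the phantoms do **not** model: anatomy (lobes, diaphragm doming,
pleural space), projection-domain physics (beam hardening, rings,
scatter), respiratory motion as such (only its densitometric
footprint), and partial-volume mixtures beyond sharp boundaries plus
noise.  Passing phantom-based tests therefore validates the *analysis
chain* — calibration, filtering, segmentation topology, histogramming,
thresholds, volumes and their couplings — not robustness to anatomical
variability or reconstruction artifacts.

## Problem sizes and tolerances

Phantom-based checks run at 192³ for cohort calibration (20 subjects)
and 96³ or 64³ for couplings and smoke tests — sizes chosen so the whole
suite runs comfortably on a laptop-class CPU while every lung still
contains hundreds of thousands of voxels.  At sub-192³ grids the airway
tubes (radius floored at 2–3 voxels) are thinner than the default
5-voxel median kernel, so small-grid pipelines use a 3-voxel kernel.
Cohort calibration targets carry ±3-percentage-point test tolerances;
quartile recovery is asserted to ±10 mm³ at n = 400; Steiger Z agreement
with an independently written implementation is asserted to 1e-6.
Dunnett p-values are compared at 1e-3 against reference behaviour.  The
phantom's inter-subject geometry is deterministic (only texture, noise
and score noise vary with the seed), so phantom-scale predictive-model
calibration cohorts add an explicit 5 % volume spread to stand in for
inter-animal variability.
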