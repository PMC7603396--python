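"""Calibrate the healthy phantom parenchyma mixture.

The healthy generator must reproduce three cohort-level properties of
anesthetized-mouse end-expiration lung densitometry after the full
processing chain (median filter, semi-automatic segmentation,
compartment classification):

* ~20 % of segmented lung voxels above −435 HU,
* ~79 % mean normo-aerated tissue under preclinical thresholds,
* ~64 % under clinical thresholds.

The script solves the truncated-normal mixture (weights w1, w2, w3 and
the aerated component's spread) so the *marginal* distribution hits a
set of targets, runs a small seeded phantom cohort through the pipeline
to measure the realized values, and updates the marginal targets by the
measured offsets.  A couple of outer iterations converge; the resulting
constants are frozen in ``pulmodens.phantom.HEALTHY_MIXTURE``.

Run from the repository root:

    python scripts/calibrate_phantom.py [--iterations 2] [--n 4]
"""

from __future__ import annotations

import argparse

from scipy import optimize
from scipy import stats as sps

import pulmodens.phantom as phantom
from pulmodens.pipeline import healthy_cohort_calibration

# Cohort-level targets (percent).
TARGET_ABOVE_435 = 20.0
TARGET_NORMO_PRE = 79.0
TARGET_NORMO_CLI = 64.0

# Fixed shape parameters (means and the two auxiliary spreads, HU).
MU1, MU2, SD2, MU3, SD3 = -610.0, -440.0, 70.0, -240.0, 130.0
SUPPORT = phantom.HEALTHY_SUPPORT


def _mixture_cdf(x, w1, w2, sd1):
    lo, hi = SUPPORT
    comps = ((w1, MU1, sd1), (w2, MU2, SD2), (1 - w1 - w2, MU3, SD3))
    total = 0.0
    for w, mu, sd in comps:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        total += w * sps.truncnorm.cdf(x, a, b, loc=mu, scale=sd)
    return total


def solve_marginal(below_860: float, below_435: float, clinical_normo: float):
    """Solve (w1, w2, sd1) so the marginal hits the three masses."""

    def equations(params):
        w1, w2, sd1 = params
        return [
            _mixture_cdf(-860.0, w1, w2, sd1) - below_860,
            _mixture_cdf(-435.0, w1, w2, sd1) - below_435,
            (_mixture_cdf(-500.0, w1, w2, sd1) - _mixture_cdf(-900.0, w1, w2, sd1))
            - clinical_normo,
        ]

    sol = optimize.fsolve(equations, x0=[0.75, 0.16, 95.0], full_output=False)
    w1, w2, sd1 = sol
    if not (0 < w1 < 1 and 0 < w2 < 1 and w1 + w2 < 1 and sd1 > 0):
        raise RuntimeError(f"marginal solve left the feasible region: {sol}")
    resid = equations(sol)
    if max(abs(r) for r in resid) > 1e-8:
        raise RuntimeError(f"marginal solve did not converge: residuals {resid}")
    return float(w1), float(w2), float(sd1)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--iterations", type=int, default=2)
    ap.add_argument("--n", type=int, default=4, help="phantoms per check cohort")
    ap.add_argument("--dims", type=int, default=192)
    args = ap.parse_args()

    # Initial marginal targets: the cohort targets taken at face value.
    below_860 = 0.01
    below_435 = 1.0 - TARGET_ABOVE_435 / 100.0
    clinical = TARGET_NORMO_CLI / 100.0

    for it in range(args.iterations):
        w1, w2, sd1 = solve_marginal(below_860, below_435, clinical)
        phantom.HEALTHY_MIXTURE = (
            (w1, MU1, sd1),
            (w2, MU2, SD2),
            (1 - w1 - w2, MU3, SD3),
        )
        print(f"[iter {it}] mixture: w1={w1:.4f} sd1={sd1:.2f} w2={w2:.4f} "
              f"w3={1 - w1 - w2:.4f}")
        cal = healthy_cohort_calibration(n=args.n, base_seed=101, dims=(args.dims,) * 3)
        print(f"[iter {it}] measured: above-435 {cal.mean_pct_above_minus435:.2f}% "
              f"normo-pre {cal.mean_normo_preclinical_pct:.2f}% "
              f"normo-cli {cal.mean_normo_clinical_pct:.2f}% "
              f"delta {cal.normo_delta_pct:.2f}")
        # Shift the marginal targets by the measured cohort offsets.
        below_435 += (cal.mean_pct_above_minus435 - TARGET_ABOVE_435) / 100.0
        below_860 += (
            (cal.mean_normo_preclinical_pct - TARGET_NORMO_PRE) / 100.0
            + (cal.mean_pct_above_minus435 - TARGET_ABOVE_435) / 100.0
        )
        clinical += (TARGET_NORMO_CLI - cal.mean_normo_clinical_pct) / 100.0

    print("\nFinal constants for pulmodens.phantom.HEALTHY_MIXTURE:")
    for w, mu, sd in phantom.HEALTHY_MIXTURE:
        print(f"    ({w:.4f}, {mu:.1f}, {sd:.2f}),")


if __name__ == "__main__":
    main()
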