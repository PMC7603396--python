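"""Statistical procedures for densitometric cohort analysis.

Pure functions over cohort tables: Ashcroft-score classing, Spearman
correlation, Steiger's Z for dependent correlations, one-way ANOVA with
Dunnett's many-to-one post-hoc, the Lilliefors-corrected KS normality
test, and the paired Wilcoxon signed-rank test.

The Steiger test compares two correlations ``r13`` and ``r23`` that
share the variable 3 (e.g. Ashcroft score against two densitometric
indices measured on the same animals).  We use the Z̄₁* variant: both
correlations are Fisher-transformed and their difference scaled by the
sampling covariance evaluated at the pooled correlation
``r̄ = (r13 + r23)/2``::

    Z = (z13 − z23) · sqrt( (n − 3) / (2 − 2·c̄) )
    c̄ = ψ(r̄, r̄, r12) / (1 − r̄²)²
    ψ(r13, r23, r12) = r12·(1 − r13² − r23²)
                       − ½·r13·r23·(1 − r13² − r23² − r12²)
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

ASHCROFT_CLASSES = ("mild", "moderate", "severe")


def ashcroft_class(score: float) -> str:
    """Histological fibrosis class from a (modified) Ashcroft score.

    0–3 mild, 4 moderate, ≥ 5 severe; scores live on the 0–8 scale.
    Fractional scores (means over microscopic fields) are classed by the
    same cut-points.
    """
    if not 0 <= score <= 8:
        raise ValueError(f"Ashcroft score must lie in [0, 8], got {score}")
    if score < 4:
        return "mild"
    if score < 5:
        return "moderate"
    return "severe"


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, two-sided p)``.  Constant input has no defined rank
    correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _fisher_z(r: float) -> float:
    return math.atanh(r)


def _steiger_psi(r13: float, r23: float, r12: float) -> float:
    """Pearson–Filon covariance numerator between two dependent r's."""
    return r12 * (1.0 - r13**2 - r23**2) - 0.5 * r13 * r23 * (
        1.0 - r13**2 - r23**2 - r12**2
    )


def steiger_z(
    r13: float, r23: float, r12: float, n: int, tail: str = "one"
) -> tuple[float, float]:
    """Steiger's Z̄₁* test for two dependent correlations sharing a variable.

    Parameters
    ----------
    r13, r23 : float
        Correlations of variables 1 and 2 with the shared variable 3.
    r12 : float
        Correlation between variables 1 and 2.
    n : int
        Sample size (> 3).
    tail : {'one', 'two'}
        One-tailed halves the two-tailed normal p-value (appropriate when
        the direction r13 > r23 is pre-specified).

    Returns ``(Z, p)``; Z is positive when ``r13 > r23``.
    """
    for name, r in (("r13", r13), ("r23", r23), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise ValueError(f"n must exceed 3, got {n}")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    z13, z23 = _fisher_z(r13), _fisher_z(r23)
    rbar = 0.5 * (r13 + r23)
    cbar = _steiger_psi(rbar, rbar, r12) / (1.0 - rbar**2) ** 2
    z = (z13 - z23) * math.sqrt((n - 3) / (2.0 - 2.0 * cbar))
    p_two = 2.0 * sps.norm.sf(abs(z))
    p = p_two / 2.0 if tail == "one" else p_two
    return float(z), float(p)


def anova_dunnett(groups: dict[str, np.ndarray], control: str) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett's many-to-one comparisons vs a control.

    ``groups`` maps group name → 1-D array of values.  Returns a tidy
    frame with one row per non-control group (adjusted p) plus the ANOVA
    F and p attached as frame attributes ``f_statistic`` / ``f_pvalue``.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing from {sorted(groups)}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    f_stat, f_p = sps.f_oneway(*arrays.values())
    others = [k for k in arrays if k != control]
    res = sps.dunnett(*(arrays[k] for k in others), control=arrays[control])
    out = pd.DataFrame(
        {
            "group": others,
            "statistic": np.atleast_1d(res.statistic),
            "p_adjusted": np.atleast_1d(res.pvalue),
            "n": [arrays[k].size for k in others],
        }
    )
    out.attrs["f_statistic"] = float(f_stat)
    out.attrs["f_pvalue"] = float(f_p)
    out.attrs["control"] = control
    return out


def ks_lilliefors(x) -> float:
    """Normality p-value: KS test with the Lilliefors correction.

    Mean and variance are estimated from the sample; the p-value uses the
    Dallal–Wilkinson approximation (via table interpolation).  Requires
    n ≥ 4.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError(f"Lilliefors test needs n >= 4, got {x.size}")
    from statsmodels.stats.diagnostic import lilliefors as _lf

    _, p = _lf(x, dist="norm", pvalmethod="table")
    return float(p)


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded (Wilcoxon's convention); at least five
    non-zero pairs must remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    if nz.size < 5:
        raise ValueError(f"need at least 5 non-zero differences, got {nz.size}")
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def load_cohort_table(path: str) -> pd.DataFrame:
    """Read a cohort CSV and validate its invariants.

    Requires columns ``subject_id``, ``group``, ``timepoint``; validates
    that subject ids are unique within each timepoint and that any
    ``ashcroft`` column stays in [0, 8].
    """
    df = pd.read_csv(path)
    required = {"subject_id", "group", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table misses required columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise ValueError("subject_id must be unique within each timepoint")
    if "ashcroft" in df.columns:
        bad = df["ashcroft"].dropna()
        if ((bad < 0) | (bad > 8)).any():
            raise ValueError("ashcroft scores must lie in [0, 8]")
    return df
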