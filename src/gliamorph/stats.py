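"""Group statistics and the two-sample sample-size calculator.

Comparisons follow the conventional animal-level workflow: per-animal
summaries (mean or median of each criterion over that animal's retained
cells) are the sampling units.  Two groups are compared by Student's t
test when both pass a Shapiro-Wilk normality check, otherwise by the
Mann-Whitney test (exact for small samples); three or more groups by
Kruskal-Wallis; categorical phenotype distributions by chi-square; paired
continuous variables by the Spearman coefficient.

The sample-size calculator implements the classical two-sample normal
approximation

    n = 2 * t * sigma^2 / (mA - mB)^2,      t = (z_{1-a/2} + z_{1-b})^2

per group (nA = nB), with ceiling rounding; at alpha = 0.05 and power =
0.90 the multiplier t is approximately 10.507.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "TestReport",
    "SampleSizeSpec",
    "summarize_by_animal",
    "compare_two_groups",
    "compare_regions",
    "compare_proportions",
    "correlate",
    "normal_multiplier",
    "required_sample_size",
]

#: criteria summarized per animal
ANIMAL_CRITERIA = (
    "body_area_um2",
    "cytoplasm_area_um2",
    "CI",
    "CEA_um2",
    "mean_intensity",
)


@dataclass
class TestReport:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int = 0
    detail: str = ""


def summarize_by_animal(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and median of each criterion per animal (x region x condition).

    Should be fed filtered, deduplicated records only.  Adds the amoeboid
    frequency and the retained cell count.
    """
    group_cols = [c for c in ("animal_id", "condition", "region") if c in records.columns]
    if "animal_id" not in group_cols:
        raise DataError("records must carry animal_id")
    rows = []
    for key, sub in records.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_cols, key))
        for crit in ANIMAL_CRITERIA:
            if crit in sub.columns:
                row[f"{crit}_mean"] = float(sub[crit].mean())
                row[f"{crit}_median"] = float(sub[crit].median())
        if "is_amoeboid" in sub.columns:
            row["amoeboid_frequency"] = float(sub["is_amoeboid"].astype(bool).mean())
        row["n_cells"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows)


def _as_values(x, criterion: str | None) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        if criterion is None:
            raise DataError("criterion required when passing a summary table")
        col = criterion if criterion in x.columns else f"{criterion}_mean"
        return x[col].to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def compare_two_groups(
    a,
    b,
    criterion: str | None = None,
    alpha_normality: float = 0.05,
    exact_max_n: int = 12,
) -> TestReport:
    """Two-sided two-group comparison on per-animal values.

    Both groups normal by Shapiro-Wilk (at ``alpha_normality``) -> Student's
    t test; otherwise Mann-Whitney, exact up to ``exact_max_n`` per group
    (ties force the tie-corrected normal approximation).  A U statistic at
    its null midpoint reports p = 1.
    """
    xa, xb = _as_values(a, criterion), _as_values(b, criterion)
    if len(xa) < 3 or len(xb) < 3:
        raise DataError("need at least 3 animals per group")
    normal = True
    for x in (xa, xb):
        if np.ptp(x) == 0:
            normal = False
            break
        if sps.shapiro(x).pvalue < alpha_normality:
            normal = False
            break
    if normal:
        res = sps.ttest_ind(xa, xb, equal_var=True)
        return TestReport("student_t", float(res.statistic), float(res.pvalue), len(xa), len(xb))
    ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
    method = "exact" if (max(len(xa), len(xb)) <= exact_max_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    u = float(res.statistic)
    p = float(res.pvalue)
    if u == len(xa) * len(xb) / 2.0:
        p = 1.0  # null midpoint: no evidence whatsoever
    return TestReport(f"mann_whitney_{method}", u, p, len(xa), len(xb))


def compare_regions(groups: dict[str, np.ndarray] | list, criterion: str | None = None) -> TestReport:
    """Kruskal-Wallis comparison across >= 3 regions/groups."""
    if isinstance(groups, dict):
        arrays = [_as_values(v, criterion) for v in groups.values()]
    else:
        arrays = [_as_values(v, criterion) for v in groups]
    if len(arrays) < 3:
        raise DataError("need at least 3 groups for Kruskal-Wallis")
    if all(np.array_equal(arrays[0], arr) for arr in arrays[1:]):
        return TestReport("kruskal_wallis", 0.0, 1.0, sum(map(len, arrays)))
    res = sps.kruskal(*arrays)
    return TestReport("kruskal_wallis", float(res.statistic), float(res.pvalue), sum(map(len, arrays)))


def compare_proportions(table) -> TestReport:
    """Chi-square test on an r x m count table (e.g. SP1-4 by condition).

    Expected counts must all be positive; otherwise the error suggests
    pooling sparse categories.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataError("need an r x m table with r, m >= 2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected <= 0).any():
        raise DataError(
            "zero expected count; pool sparse sub-populations before testing"
        )
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return TestReport("chi_square", float(chi2), float(p), int(obs.sum()), detail=f"df={dof}")


def correlate(x, y) -> TestReport:
    """Spearman rank correlation of two paired vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 3:
        raise DataError("need paired vectors of length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return TestReport("spearman", np.nan, np.nan, len(xa), detail="undefined: constant input")
    res = sps.spearmanr(xa, ya)
    return TestReport("spearman", float(res.statistic), float(res.pvalue), len(xa))


# ---------------------------------------------------------------------------
# sample size


@dataclass
class SampleSizeSpec:
    """Inputs of the two-sample normal-approximation calculator."""

    mean_a: float
    mean_b: float
    sigma: float
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        if self.mean_a == self.mean_b:
            raise DataError("equal means: required sample size is infinite")
        if self.sigma <= 0:
            raise DataError("sigma must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise DataError("alpha and power must lie in (0, 1)")


def normal_multiplier(alpha: float = 0.05, power: float = 0.90) -> float:
    """(z_{1-alpha/2} + z_{1-beta})^2; ~10.507 at the defaults."""
    return float((sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)) ** 2)


def required_sample_size(
    mean_a: float,
    mean_b: float,
    sigma: float,
    alpha: float = 0.05,
    power: float = 0.90,
) -> int:
    """Animals per group for a two-sided two-sample comparison.

    ``ceil(2 * t * sigma^2 / (mean_a - mean_b)^2)`` with
    ``t = (z_{1-alpha/2} + z_{1-power})^2``; symmetric in the means,
    increasing in sigma, decreasing in |mean_a - mean_b|.
    """
    spec = SampleSizeSpec(mean_a, mean_b, sigma, alpha, power)
    t = normal_multiplier(spec.alpha, spec.power)
    n = 2.0 * t * spec.sigma**2 / (spec.mean_a - spec.mean_b) ** 2
    return int(math.ceil(n - 1e-12))
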