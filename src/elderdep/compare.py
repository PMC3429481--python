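"""Statistical comparison of a simulated prevalence curve with a survey curve.

Four indices summarise the fit between a simulated mean prevalence-by-age
curve and an empirical curve with 95% confidence intervals:

* the number of ages (out of 28) at which the simulated estimate falls
  within the empirical confidence interval (bounds inclusive);
* the two-sided Wilcoxon signed-rank p-value for the nullity of the paired
  differences between the two curves;
* the two-sample Kolmogorov-Smirnov statistic D between the simulated
  values and the ordinary-least-squares regression line fitted to the
  empirical curve (with 28-point samples D is a multiple of 1/28);
* the Pearson correlation r between the simulated values and that
  regression line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .population import PrevalenceCurve

logger = logging.getLogger(__name__)


@dataclass
class ComparisonReport:
    occurrences_within_ci: int
    wsr_p: float
    ks_D: float
    ks_p: float
    pearson_r: float
    slope: float
    intercept: float

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "ComparisonReport":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls(**data)


def _check_grids(sim: PrevalenceCurve, emp: PrevalenceCurve) -> None:
    if sim.ages.shape != emp.ages.shape or np.any(sim.ages != emp.ages):
        raise ValueError(
            f"age grids differ: sim {sim.ages.min()}-{sim.ages.max()} "
            f"({len(sim.ages)} pts) vs emp {emp.ages.min()}-{emp.ages.max()} "
            f"({len(emp.ages)} pts)"
        )


def count_within_ci(sim: PrevalenceCurve, emp: PrevalenceCurve) -> int:
    """Number of ages where the simulated estimate lies inside the empirical
    95% CI (inclusive bounds)."""
    _check_grids(sim, emp)
    if not emp.has_ci:
        raise ValueError("empirical curve carries no confidence intervals")
    inside = (emp.ci_low <= sim.prevalence) & (sim.prevalence <= emp.ci_high)
    return int(np.sum(inside))


def wilcoxon_signed_rank(sim: PrevalenceCurve, emp: PrevalenceCurve) -> float:
    """Two-sided Wilcoxon signed-rank p-value for the paired differences.

    Zero differences are discarded (classical convention).  The exact null
    distribution is used for n <= 25 remaining pairs; above that a normal
    approximation with tie correction.  All-zero differences return p = 1.
    """
    _check_grids(sim, emp)
    d = sim.prevalence - emp.prevalence
    nz = int(np.sum(d != 0))
    if nz == 0:
        logger.warning("all paired differences are zero; returning p = 1")
        return 1.0
    abs_nonzero = np.abs(d[d != 0])
    ties = len(np.unique(abs_nonzero)) < len(abs_nonzero)
    method = "exact" if (nz <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        sim.prevalence,
        emp.prevalence,
        zero_method="wilcox",
        alternative="two-sided",
        method=method,
    )
    return float(res.pvalue)


def fit_regression(emp: PrevalenceCurve) -> tuple[float, float, np.ndarray]:
    """OLS of empirical prevalence on age: (slope, intercept, fitted values)."""
    if len(emp.ages) < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(emp.ages) == 0:
        raise ValueError("degenerate regression: constant age")
    res = stats.linregress(emp.ages.astype(float), emp.prevalence)
    fitted = res.slope * emp.ages + res.intercept
    return float(res.slope), float(res.intercept), fitted


def ks_two_sample(sim_values: np.ndarray, fitted_values: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: (D, p).

    D = sup |ECDF1 - ECDF2|; with two 28-point samples of distinct values D
    is a multiple of 1/28.
    """
    sim_values = np.asarray(sim_values, dtype=float)
    fitted_values = np.asarray(fitted_values, dtype=float)
    if sim_values.size == 0 or fitted_values.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(sim_values, fitted_values, method="auto")
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(sim_values: np.ndarray, fitted_values: np.ndarray) -> float:
    """Pearson product-moment correlation between two equal-length samples."""
    sim_values = np.asarray(sim_values, dtype=float)
    fitted_values = np.asarray(fitted_values, dtype=float)
    if sim_values.shape != fitted_values.shape or sim_values.size < 3:
        raise ValueError("need two aligned samples of length >= 3")
    if np.std(sim_values) == 0 or np.std(fitted_values) == 0:
        raise ValueError("correlation undefined: zero variance sample")
    return float(stats.pearsonr(sim_values, fitted_values).statistic)


def compare_curves(sim: PrevalenceCurve, emp: PrevalenceCurve) -> ComparisonReport:
    """The full battery: CI occurrences, Wilcoxon, KS vs the empirical
    regression line, and the correlation with that line."""
    _check_grids(sim, emp)
    occurrences = count_within_ci(sim, emp)
    wsr_p = wilcoxon_signed_rank(sim, emp)
    slope, intercept, fitted = fit_regression(emp)
    ks_D, ks_p = ks_two_sample(sim.prevalence, fitted)
    r = pearson_correlation(sim.prevalence, fitted)
    return ComparisonReport(
        occurrences_within_ci=occurrences,
        wsr_p=wsr_p,
        ks_D=ks_D,
        ks_p=ks_p,
        pearson_r=r,
        slope=slope,
        intercept=intercept,
    )
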