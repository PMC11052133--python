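"""Small-sample geochemical statistics for groundwater time series.

Five or so sampling dates rule out asymptotic inference, so the monotone
trend test is Spearman's rank correlation with an exact permutation
p-value (all n! orderings enumerated for n <= 9).  Water-isotope samples
are located relative to the global meteoric water line via the deuterium
excess, and conservative-tracer mixing fractions quantify the seawater
contribution to the aquifer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WaterIsotopeSample",
    "spearman_trend",
    "trend_table",
    "deuterium_excess",
    "right_of_gmwl",
    "seawater_mixing_fraction",
]

EXACT_ENUMERATION_MAX_N = 9

# Craig's global meteoric water line: dD = 8 * d18O + 10 (permil, VSMOW).
GMWL_SLOPE = 8.0
GMWL_INTERCEPT = 10.0


@dataclass(frozen=True)
class WaterIsotopeSample:
    """Stable water isotopes of one sample, permil vs VSMOW."""

    dD: float
    d18O: float


def spearman_trend(times: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """Spearman rho of values against time, with an exact two-sided p-value.

    Ties receive average ranks.  For n <= 9 the p-value is the exact
    fraction of all n! orderings of the observed values whose |rho| is at
    least |rho_observed|; beyond that the scipy asymptotic p is returned.
    Constant values have undefined rank correlation and raise.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(t)
    if n < 3 or len(v) != n:
        raise ValueError("need n >= 3 paired observations")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(v) == 0:
        raise ValueError("values are constant; Spearman rho is undefined")

    rt = stats.rankdata(t)
    rv = stats.rankdata(v)
    rho = float(stats.pearsonr(rt, rv).statistic)

    if n > EXACT_ENUMERATION_MAX_N:
        return rho, float(stats.spearmanr(t, v).pvalue)

    # Exact permutation null: every ordering of the observed values
    # (hence of their rank multiset) is equally likely under no trend.
    perms = np.array(list(itertools.permutations(range(n))))
    rv_perm = rv[perms]  # (n!, n)
    rtc = rt - rt.mean()
    rvc = rv_perm - rv.mean()
    denom = np.sqrt((rtc**2).sum()) * np.sqrt((rvc[0] ** 2).sum())
    rho_perm = (rvc @ rtc) / denom
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


def trend_table(
    months: Sequence[float],
    parameters: dict[str, Sequence[float]],
    alpha: float = 0.05,
) -> "pd.DataFrame":
    """Per-parameter rho, exact p, and trend verdict at significance alpha."""
    import pandas as pd

    rows = []
    for name, series in parameters.items():
        rho, p = spearman_trend(months, series)
        rows.append(
            {
                "parameter": name,
                "rho": rho,
                "p_exact": p,
                "significant_trend": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def deuterium_excess(sample: WaterIsotopeSample) -> float:
    """Deuterium excess d = dD - 8 * d18O (permil).

    d < 10 means the sample plots to the right of / below the global
    meteoric water line (evaporation or water-rock interaction signal).
    """
    return sample.dD - GMWL_SLOPE * sample.d18O


def right_of_gmwl(
    sample: WaterIsotopeSample,
    slope: float = GMWL_SLOPE,
    intercept: float = GMWL_INTERCEPT,
) -> bool:
    """Whether the sample plots to the right of the meteoric water line."""
    return sample.dD < slope * sample.d18O + intercept


def seawater_mixing_fraction(
    value: float,
    seawater_endmember: float,
    freshwater_endmember: float = 0.0,
) -> float:
    """Two-endmember conservative mixing fraction, as a percentage.

    Works for EC, chloride or any conservative tracer; 100% means pure
    seawater endmember, 0% pure freshwater endmember.
    """
    if seawater_endmember == freshwater_endmember:
        raise ValueError("endmember values must be distinct")
    return 100.0 * (value - freshwater_endmember) / (seawater_endmember - freshwater_endmember)
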