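"""P_G+C computation and linear growth-temperature models with uncertainty.

The guanine-plus-cytosine content of (partial) archaeal 16S rRNA genes
correlates strongly with growth temperature, tightly enough that a linear
model maps the P_G+C of a sequence to minimum, optimal and maximum growth
temperatures:

    T = slope * P_G+C + intercept        (degrees C; P_G+C in percent)

Each coefficient carries a published half-width; uncertainty is propagated
worst-case (half_width = slope_hw * P_G+C + intercept_hw), the convention
that reproduces the published per-OTU intervals, rather than in quadrature.
Community-level temperatures apply the same models to the clone-count-
weighted mean P_G+C of the library's OTUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from gctherm.clustering import CloneLibrary, EmptyLibraryError
from gctherm.sequences import SequenceRecord, normalize

__all__ = [
    "RegressionModel",
    "TemperatureEstimate",
    "CommunityTemperatureReport",
    "DEFAULT_MODELS",
    "round_half_up",
    "compute_pgc",
    "estimate_temperature",
    "weighted_community_pgc",
    "community_report",
    "compare_to_field_temperature",
]

#: P_G+C band (percent) outside which temperature estimates are extrapolation
#: far from the archaeal calibration data and a warning is emitted.
VALID_PGC_RANGE = (50.0, 70.0)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero upward, as the published tables do.

    Python's builtin ``round`` is banker's rounding; reported temperatures
    follow the half-up convention (18.25 -> 18.3).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RegressionModel:
    """One linear growth-temperature model: T = slope * P_G+C + intercept."""

    which: str  # "T_min" | "T_opt" | "T_max"
    slope: float  # degC per P_G+C percentage point
    slope_hw: float  # half-width of the slope
    intercept: float  # degC
    intercept_hw: float  # half-width of the intercept

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.which}: slope must be positive")
        if self.slope_hw < 0 or self.intercept_hw < 0:
            raise ValueError(f"{self.which}: half-widths must be non-negative")


#: Published coefficient set for archaeal 16S rRNA P_G+C thermometry.
#: Overridable wherever a model set is accepted.
DEFAULT_MODELS: dict[str, RegressionModel] = {
    "T_min": RegressionModel("T_min", slope=3.91, slope_hw=0.12, intercept=-201.1, intercept_hw=7.34),
    "T_opt": RegressionModel("T_opt", slope=4.24, slope_hw=0.13, intercept=-202.5, intercept_hw=7.62),
    "T_max": RegressionModel("T_max", slope=4.28, slope_hw=0.12, intercept=-195.3, intercept_hw=7.11),
}

MODEL_ORDER = ("T_min", "T_opt", "T_max")


@dataclass(frozen=True)
class TemperatureEstimate:
    which: str
    value: float  # degC, full precision
    half_width: float  # degC, >= 0

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")

    def rounded(self, decimals: int = 1) -> tuple[float, float]:
        return round_half_up(self.value, decimals), round_half_up(self.half_width, decimals)

    def __str__(self) -> str:
        v, hw = self.rounded()
        return f"{v:.1f}(±{hw:.1f})"


class UndefinedPgcError(ValueError):
    """A sequence has no unambiguous bases, so P_G+C is undefined."""


def compute_pgc(seq: str | SequenceRecord) -> float:
    """Guanine-plus-cytosine content as a percentage of unambiguous bases.

    Case-insensitive, U counted as T; IUPAC ambiguity codes are excluded
    from both numerator and denominator.
    """
    s = seq.norm if isinstance(seq, SequenceRecord) else normalize(seq)
    if not s:
        raise UndefinedPgcError("empty sequence")
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedPgcError("sequence has no unambiguous A/C/G/T bases")
    return 100.0 * gc / (gc + at)


def estimate_temperature(pgc: float, model: RegressionModel) -> TemperatureEstimate:
    """Apply one linear model to a P_G+C percentage.

    Uncertainty is the worst-case linear propagation of the published
    coefficient half-widths.  Values are kept at full precision; callers
    round for display.  A P_G+C far outside the archaeal calibration band
    triggers a warning (the arithmetic still runs).
    """
    if not (0 <= pgc <= 100):
        raise ValueError(f"P_G+C must be a percentage in [0, 100], got {pgc}")
    if not (VALID_PGC_RANGE[0] <= pgc <= VALID_PGC_RANGE[1]):
        warnings.warn(
            f"P_G+C {pgc:.1f}% is outside the calibration band "
            f"{VALID_PGC_RANGE}; the estimated temperature is an extrapolation",
            stacklevel=2,
        )
    return TemperatureEstimate(
        which=model.which,
        value=model.slope * pgc + model.intercept,
        half_width=model.slope_hw * pgc + model.intercept_hw,
    )


def weighted_community_pgc(library: CloneLibrary) -> float:
    """Clone-count-weighted mean P_G+C of a library's OTUs (full precision)."""
    if not library.otus:
        raise EmptyLibraryError(f"library {library.label!r} has no OTUs")
    missing = [o.otu_id for o in library.otus if o.pgc is None]
    if missing:
        raise ValueError(f"OTUs without P_G+C: {missing}")
    total = library.total_clones
    return sum(o.count * o.pgc for o in library.otus) / total


@dataclass
class CommunityTemperatureReport:
    """Per-OTU and community growth-temperature estimates for one library."""

    label: str
    per_otu: list[tuple[str, int, float, dict[str, TemperatureEstimate]]]
    weighted_pgc: float
    community: dict[str, TemperatureEstimate]

    def __post_init__(self) -> None:
        if self.per_otu:
            pgcs = [p for _, _, p, _ in self.per_otu]
            if not (min(pgcs) - 1e-9 <= self.weighted_pgc <= max(pgcs) + 1e-9):
                raise ValueError("weighted P_G+C outside the per-OTU P_G+C range")


def community_report(
    library: CloneLibrary,
    models: dict[str, RegressionModel] = DEFAULT_MODELS,
) -> CommunityTemperatureReport:
    """Estimate per-OTU and community growth temperatures for one library.

    Community estimates apply each model to the *unrounded* weighted
    P_G+C; because the models are affine this equals the clone-weighted
    mean of the unrounded per-OTU temperatures.
    """
    per_otu = []
    for otu in library.otus:
        if otu.pgc is None:
            raise ValueError(f"OTU {otu.otu_id} has no P_G+C")
        ests = {w: estimate_temperature(otu.pgc, models[w]) for w in MODEL_ORDER if w in models}
        per_otu.append((otu.otu_id, otu.count, otu.pgc, ests))
    wpgc = weighted_community_pgc(library)
    community = {w: estimate_temperature(wpgc, models[w]) for w in MODEL_ORDER if w in models}
    return CommunityTemperatureReport(
        label=library.label, per_otu=per_otu, weighted_pgc=wpgc, community=community
    )


def compare_to_field_temperature(
    report: CommunityTemperatureReport,
    measured_temp: float,
    aquifer_range: tuple[float, float],
) -> list[dict]:
    """Compare community estimates with a measured temperature and aquifer range.

    For each model: the signed difference (estimate - measured) and whether
    the closed interval [value - hw, value + hw] overlaps the closed
    aquifer range.
    """
    low, high = aquifer_range
    if low > high:
        raise ValueError(f"aquifer range low {low} exceeds high {high}")
    out = []
    for which, est in report.community.items():
        out.append(
            {
                "which": which,
                "value": est.value,
                "half_width": est.half_width,
                "difference": est.value - measured_temp,
                "overlaps_aquifer": (est.value - est.half_width) <= high
                and (est.value + est.half_width) >= low,
            }
        )
    return out
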