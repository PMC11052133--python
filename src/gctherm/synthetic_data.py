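"""Synthetic clone libraries and groundwater scenarios with known ground truth.

Every input the pipeline consumes can be generated here: amplicon-like
clone sequences with exactly planted G+C counts, embedded primer sites and
bounded within-OTU divergence; skewed OTU abundances; and a five-time-point
groundwater scenario (library compositions shifting from low- to high-G+C
OTUs, plus a physicochemical table with configurable trend and noise).
Generation is substitution-only and seed-deterministic, so clustering,
trimming and thermometry can be tested against exact planted truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gctherm.clustering import pairwise_identity
from gctherm.sequences import (
    IUPAC_SETS,
    PRIMER_PROFILES,
    PrimerPair,
    SequenceRecord,
    normalize,
    reverse_complement,
)

__all__ = [
    "OtuSpec",
    "LibrarySpec",
    "ScenarioSpec",
    "GenerationError",
    "generate_centroid",
    "mutate_within_otu",
    "generate_library",
    "generate_timeseries_scenario",
]


class GenerationError(RuntimeError):
    """Centroid separability could not be reached within the attempt budget."""


@dataclass(frozen=True)
class OtuSpec:
    pgc_target: float  # percent
    count: int
    label: str


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for one synthetic clone library.

    Defaults emulate the study conditions: ~800 nt internal regions, G+C
    content in the mid-50s to low-60s percent, <=1% within-OTU divergence,
    and well-separated OTU centroids so truth recovery at a 97% clustering
    threshold is guaranteed by construction.
    """

    otu_specs: tuple[OtuSpec, ...]
    internal_length: int = 800
    within_otu_divergence: float = 0.01
    inter_otu_min_distance: float = 0.06
    primer_pair: PrimerPair = PRIMER_PROFILES["arch_109aF_915aR"]
    flank_lengths: tuple[int, int] = (20, 20)
    rc_fraction: float = 0.25  # fraction of clones emitted reverse-complemented
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.otu_specs:
            raise ValueError("need at least one OTU spec")
        if not (0 <= self.within_otu_divergence <= 0.03):
            raise ValueError("within_otu_divergence must be in [0, 0.03]")

    def separability_ok(self, threshold: float = 0.97) -> bool:
        """Planted truth is recoverable by clustering at ``threshold``."""
        return self.inter_otu_min_distance > (1 - threshold) + self.within_otu_divergence

    @property
    def total_clones(self) -> int:
        return sum(o.count for o in self.otu_specs)

    def planted_weighted_pgc(self, length: int | None = None) -> float:
        """Clone-weighted mean of the achievable per-OTU P_G+C values."""
        length = length or self.internal_length
        total = self.total_clones
        return sum(o.count * _achievable_pgc(o.pgc_target, length) for o in self.otu_specs) / total


def _achievable_pgc(pgc_target: float, length: int) -> float:
    return 100.0 * round(pgc_target * length / 100.0) / length


def generate_centroid(pgc_target: float, length: int, seed: int) -> SequenceRecord:
    """A random sequence with exactly round(pgc_target * length / 100) G/C bases.

    G vs C (and A vs T) are equiprobable; the arrangement is uniform.
    When the target percentage is not exactly representable at this length
    a warning reports the achieved P_G+C.
    """
    if not (0 <= pgc_target <= 100):
        raise ValueError("pgc_target must be a percentage")
    rng = np.random.default_rng(seed)
    n_gc = round(pgc_target * length / 100.0)
    achieved = 100.0 * n_gc / length
    if abs(achieved - pgc_target) > 1e-9:
        warnings.warn(
            f"P_G+C target {pgc_target}% not representable at length {length}; "
            f"achieved {achieved:.4f}%",
            stacklevel=2,
        )
    bases = np.empty(length, dtype="<U1")
    gc_positions = rng.choice(length, size=n_gc, replace=False)
    is_gc = np.zeros(length, dtype=bool)
    is_gc[gc_positions] = True
    bases[is_gc] = rng.choice(np.array(["G", "C"]), size=n_gc)
    bases[~is_gc] = rng.choice(np.array(["A", "T"]), size=length - n_gc)
    return SequenceRecord(id=f"centroid_gc{pgc_target:g}", seq="".join(bases))


_GC_SWAP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def mutate_within_otu(
    centroid: SequenceRecord,
    divergence: float,
    gc_preserving: bool = True,
    seed: int = 0,
    clone_id: str | None = None,
) -> SequenceRecord:
    """Substitute floor(divergence * length) positions of a centroid.

    GC-preserving mode (the default for truth-recovery fixtures) swaps only
    A<->T or G<->C, so the mutant's P_G+C equals the centroid's exactly.
    Free mode substitutes to any different base.
    """
    if not (0 <= divergence <= 0.03):
        raise ValueError("divergence must be in [0, 0.03]")
    rng = np.random.default_rng(seed)
    s = list(centroid.norm)
    n_sub = math.floor(divergence * len(s))
    positions = rng.choice(len(s), size=n_sub, replace=False)
    for p in positions:
        if gc_preserving:
            s[p] = _GC_SWAP[s[p]]
        else:
            alternatives = [b for b in "ACGT" if b != s[p]]
            s[p] = alternatives[rng.integers(len(alternatives))]
    return SequenceRecord(id=clone_id or f"{centroid.id}_mut", seq="".join(s))


def _concretize_primer(primer: str, rng: np.random.Generator) -> str:
    """Replace degenerate codes by one uniformly chosen encoded base."""
    out = []
    for c in normalize(primer):
        choices = sorted(IUPAC_SETS[c])
        out.append(choices[rng.integers(len(choices))] if len(choices) > 1 else c)
    return "".join(out)


def _random_flank(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)]) if length else ""


def generate_library(
    spec: LibrarySpec,
    gc_preserving: bool = True,
    max_attempts: int = 20,
    label: str = "",
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate a full clone library plus its ground-truth table.

    Each clone is flank + forward primer + internal region + revcomp of the
    reverse primer + flank; a ``spec.rc_fraction`` share of clones is
    emitted reverse-complemented to exercise orientation handling, and the
    clone order is shuffled.  Centroids are regenerated until every pair is
    at most ``1 - inter_otu_min_distance`` identical (GenerationError after
    ``max_attempts`` rounds).

    Returns the records and a truth table with columns clone_id,
    otu_label, planted_pgc, orientation.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    max_identity = 1.0 - spec.inter_otu_min_distance

    centroids: list[SequenceRecord] = []
    for attempt in range(max_attempts):
        centroids = [
            generate_centroid(o.pgc_target, spec.internal_length, seed=int(rng.integers(2**31)))
            for o in spec.otu_specs
        ]
        separated = all(
            pairwise_identity(centroids[i], centroids[j]) <= max_identity
            for i in range(len(centroids))
            for j in range(i + 1, len(centroids))
        )
        if separated:
            break
    else:
        raise GenerationError(
            f"could not generate centroids with pairwise identity <= {max_identity} "
            f"in {max_attempts} attempts"
        )

    records: list[SequenceRecord] = []
    truth_rows = []
    clone_no = 0
    for otu_spec, centroid in zip(spec.otu_specs, centroids):
        planted = _achievable_pgc(otu_spec.pgc_target, spec.internal_length)
        for _ in range(otu_spec.count):
            clone_no += 1
            clone_id = f"{label or 'clone'}_{clone_no:03d}"
            div = float(rng.uniform(0, spec.within_otu_divergence))
            internal = mutate_within_otu(
                centroid, div, gc_preserving=gc_preserving,
                seed=int(rng.integers(2**31)), clone_id=clone_id,
            )
            fwd = _concretize_primer(spec.primer_pair.forward, rng)
            rev = _concretize_primer(spec.primer_pair.reverse, rng)
            full = (
                _random_flank(spec.flank_lengths[0], rng)
                + fwd
                + internal.seq
                + reverse_complement(rev)
                + _random_flank(spec.flank_lengths[1], rng)
            )
            records.append(SequenceRecord(id=clone_id, seq=full))
            truth_rows.append(
                {"clone_id": clone_id, "otu_label": otu_spec.label,
                 "planted_pgc": planted, "orientation": "+"}
            )

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])

    n_rc = math.floor(spec.rc_fraction * len(records))
    rc_idx = rng.choice(len(records), size=n_rc, replace=False)
    for i in rc_idx:
        records[i] = SequenceRecord(id=records[i].id, seq=reverse_complement(records[i].seq))
        truth.loc[i, "orientation"] = "-"
    return records, truth


@dataclass(frozen=True)
class ScenarioSpec:
    """A five-time-point groundwater study: libraries plus physicochemistry."""

    library_specs: dict[str, LibrarySpec]
    physicochem: pd.DataFrame
    trend_truth: dict[str, str]  # parameter -> "none" | "increasing" | "decreasing"
    planted_weighted_pgc: dict[str, float]


# Time-course OTU compositions for the default scenario: the community
# shifts from a low-G+C (mesophile-like) dominant OTU toward high-G+C
# (thermophile-like) OTUs, so the planted weighted P_G+C rises monotonically.
_SCENARIO_COMPOSITIONS: dict[str, list[tuple[float, int, str]]] = {
    "0 months": [(56.1, 48, "OTU_meso"), (54.7, 10, "OTU_cool"), (57.9, 10, "OTU_mid"), (61.2, 2, "OTU_hot")],
    "7 months": [(56.1, 45, "OTU_meso"), (59.9, 15, "OTU_thermo1"), (57.9, 10, "OTU_mid"), (61.2, 2, "OTU_hot")],
    "13 months": [(59.9, 40, "OTU_thermo1"), (56.1, 30, "OTU_meso"), (59.2, 10, "OTU_thermo2")],
    "19 months": [(59.9, 50, "OTU_thermo1"), (56.1, 17, "OTU_meso"), (59.2, 14, "OTU_thermo2"), (60.2, 1, "OTU_warm")],
    "26 months": [(59.9, 45, "OTU_thermo1"), (59.2, 30, "OTU_thermo2"), (61.2, 10, "OTU_hot")],
}

# parameter -> (baseline, per-month trend slope, noise sd)
_SCENARIO_PARAMS: dict[str, tuple[float, float, float]] = {
    "temperature_c": (50.0, 0.0, 1.2),
    "ph": (8.6, 0.0, 0.08),
    "orp_mv": (-330.0, 0.0, 55.0),
    "ec_ms_per_m": (2800.0, 0.0, 90.0),
    "dD_permil": (-14.3, 0.1, 0.1),
    "cl_mg_per_l": (9500.0, 40.0, 80.0),
}


def generate_timeseries_scenario(
    seed: int = 0,
    months: tuple[int, ...] = (0, 7, 13, 19, 26),
    params: dict[str, tuple[float, float, float]] | None = None,
) -> ScenarioSpec:
    """The default synthetic study: five libraries plus a groundwater table.

    Library compositions shift from low- to high-G+C OTUs so the planted
    community weighted P_G+C (hence every modeled community temperature)
    increases strictly over time.  Physicochemical parameters are baseline
    + slope * months + Gaussian noise; the truth table records which were
    generated with a trend.
    """
    params = params if params is not None else _SCENARIO_PARAMS
    rng = np.random.default_rng(seed)
    lib_specs: dict[str, LibrarySpec] = {}
    planted: dict[str, float] = {}
    for label, comp in _SCENARIO_COMPOSITIONS.items():
        spec = LibrarySpec(
            otu_specs=tuple(OtuSpec(pgc_target=p, count=c, label=l) for p, c, l in comp),
            seed=int(rng.integers(2**31)),
        )
        lib_specs[label] = spec
        planted[label] = spec.planted_weighted_pgc()

    t = np.asarray(months, dtype=float)
    cols: dict[str, object] = {"months": list(months)}
    truth: dict[str, str] = {}
    for name, (base, slope, noise_sd) in params.items():
        cols[name] = base + slope * t + rng.normal(0.0, noise_sd, size=len(t))
        truth[name] = "none" if slope == 0 else ("increasing" if slope > 0 else "decreasing")
    return ScenarioSpec(
        library_specs=lib_specs,
        physicochem=pd.DataFrame(cols),
        trend_truth=truth,
        planted_weighted_pgc=planted,
    )
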