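"""Pipeline orchestration: trim -> cluster -> thermometry -> diversity.

Two entry modes: the full sequence pipeline from labelled FASTA files, and
a math-only table mode that starts from a per-OTU (otu_id, count, pgc)
table of exactly the shape the published clone-library table has.  All
tabular output is TSV (UTF-8, '.' decimal separator, "NA" for missing);
every report embeds the hash of the configuration that produced it, and
reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from gctherm import diversity as _div
from gctherm.clustering import CloneLibrary, OtuRecord, cluster_otus, library_coverage
from gctherm.sequences import (
    PRIMER_PROFILES,
    PrimerPair,
    SequenceRecord,
    read_fasta,
    trim_to_internal_region,
)
from gctherm.thermometry import (
    DEFAULT_MODELS,
    MODEL_ORDER,
    CommunityTemperatureReport,
    RegressionModel,
    community_report,
    compute_pgc,
    round_half_up,
)

__all__ = ["PipelineConfig", "PipelineError", "run_full", "run_table_mode", "report_frame"]

log = logging.getLogger("gctherm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the pipeline, with the study defaults."""

    primer_profile: str = "arch_109aF_915aR"
    primer_pair: PrimerPair | None = None  # overrides the profile when set
    max_mismatches: int = 2
    clustering_threshold: float = 0.97
    models: tuple[RegressionModel, ...] = tuple(DEFAULT_MODELS[w] for w in MODEL_ORDER)
    decimals: int = 1
    shannon_base: float = math.e
    ace_rare_threshold: int = 10
    chao1_bias_corrected: bool = True
    gmwl_slope: float = 8.0
    gmwl_intercept: float = 10.0
    seawater_ec_endmember: float = 5900.0  # mS/m, open-ocean EC (configuration, not a study value)
    aquifer_range: tuple[float, float] = (55.0, 63.0)

    def __post_init__(self) -> None:
        if not (0 < self.clustering_threshold <= 1):
            raise ValueError("clustering threshold must be in (0, 1]")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")
        if self.aquifer_range[0] > self.aquifer_range[1]:
            raise ValueError("aquifer range low exceeds high")

    def resolved_primer_pair(self) -> PrimerPair:
        if self.primer_pair is not None:
            return self.primer_pair
        try:
            return PRIMER_PROFILES[self.primer_profile]
        except KeyError:
            raise ValueError(
                f"unknown primer profile {self.primer_profile!r}; known: {list(PRIMER_PROFILES)}"
            ) from None

    def model_map(self) -> dict[str, RegressionModel]:
        return {m.which: m for m in self.models}

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def report_frame(
    report: CommunityTemperatureReport,
    decimals: int = 1,
    annotations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate a community report in the published table layout.

    One row per OTU plus a final ``community`` summary row; temperatures
    and half-widths rounded half-up to ``decimals``.
    """
    annotations = annotations or {}
    rows = []
    for otu_id, count, pgc, ests in report.per_otu:
        row = {
            "otu_id": otu_id,
            "order_annotation": annotations.get(otu_id, "NA"),
            "n_clones": count,
            "pgc": round_half_up(pgc, decimals),
        }
        for which, est in ests.items():
            v, hw = est.rounded(decimals)
            key = which.lower().replace("t_", "t")
            row[key] = v
            row[f"{key}_hw"] = hw
        rows.append(row)
    crow = {
        "otu_id": "community",
        "order_annotation": "NA",
        "n_clones": sum(c for _, c, _, _ in report.per_otu),
        "pgc": round_half_up(report.weighted_pgc, decimals),
    }
    for which, est in report.community.items():
        v, hw = est.rounded(decimals)
        key = which.lower().replace("t_", "t")
        crow[key] = v
        crow[f"{key}_hw"] = hw
    rows.append(crow)
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def library_from_table(table: pd.DataFrame, label: str = "") -> CloneLibrary:
    """Build a math-only clone library from an (otu_id, count, pgc) table.

    Placeholder representatives are used: table mode exists for reanalysis
    of published per-OTU tables where the sequences are not at hand.
    """
    required = {"otu_id", "count", "pgc"}
    missing = required - set(table.columns)
    if missing:
        raise PipelineError(f"table mode: missing column(s) {sorted(missing)}")
    otus = []
    for _, row in table.iterrows():
        count = int(row["count"])
        if count < 1:
            raise PipelineError(f"table mode: OTU {row['otu_id']!r} has non-positive count")
        member_ids = [f"{row['otu_id']}_{i + 1}" for i in range(count)]
        otus.append(
            OtuRecord(
                otu_id=str(row["otu_id"]),
                representative=SequenceRecord(id=member_ids[0], seq="N"),
                member_ids=member_ids,
                pgc=float(row["pgc"]),
            )
        )
    otus.sort(key=lambda o: -o.count)
    return CloneLibrary(label=label, otus=otus)


def run_table_mode(
    table: pd.DataFrame | str | Path,
    config: PipelineConfig = PipelineConfig(),
    label: str = "",
) -> CommunityTemperatureReport:
    """Thermometry only, from a TSV or DataFrame with otu_id/count/pgc columns."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", comment="#")
    library = library_from_table(table, label=label)
    return community_report(library, config.model_map())


def _process_label(
    label: str, fasta_path: str | Path, config: PipelineConfig
) -> tuple[CloneLibrary, CommunityTemperatureReport]:
    primer_pair = config.resolved_primer_pair()
    try:
        records = read_fasta(fasta_path)
    except Exception as exc:
        raise PipelineError(f"stage read [{label}]: {exc}") from exc
    if not records:
        raise PipelineError(f"stage read [{label}]: no records in {fasta_path}")
    trimmed = []
    for rec in records:
        try:
            trimmed.append(trim_to_internal_region(rec, primer_pair, config.max_mismatches))
        except Exception as exc:
            raise PipelineError(f"stage trim [{label}]: record {rec.id}: {exc}") from exc
    try:
        library = cluster_otus(trimmed, config.clustering_threshold, label=label)
        for otu in library.otus:
            otu.pgc = compute_pgc(otu.representative)
        report = community_report(library, config.model_map())
    except Exception as exc:
        raise PipelineError(f"stage cluster/thermometry [{label}]: {exc}") from exc
    return library, report


def run_full(
    fasta_paths_by_label: dict[str, str | Path],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    measured_temps: dict[str, float] | None = None,
) -> dict:
    """Run the whole workflow over labelled FASTA files.

    Returns a bundle with per-label libraries and reports, a diversity
    table and a combined time-course table; when ``out_dir`` is given all
    tables are written there as TSV.
    """
    if not fasta_paths_by_label:
        raise PipelineError("no input FASTA files given")
    measured_temps = measured_temps or {}
    log.info("pipeline config %s (hash %s)", config, config.config_hash())

    libraries: dict[str, CloneLibrary] = {}
    reports: dict[str, CommunityTemperatureReport] = {}
    for label, path in fasta_paths_by_label.items():
        log.info("processing %s (%s)", label, path)
        libraries[label], reports[label] = _process_label(label, path, config)

    div = _div.alpha_summary(
        {label: lib.counts for label, lib in libraries.items()},
        shannon_base=config.shannon_base,
        ace_rare_threshold=config.ace_rare_threshold,
        chao1_bias_corrected=config.chao1_bias_corrected,
    )

    combined_rows = []
    for label, report in reports.items():
        row = {
            "label": label,
            "n_otus": len(libraries[label].otus),
            "total_clones": libraries[label].total_clones,
            "coverage_percent": round_half_up(library_coverage(libraries[label]), config.decimals),
            "weighted_pgc": round_half_up(report.weighted_pgc, config.decimals),
        }
        for which, est in report.community.items():
            v, hw = est.rounded(config.decimals)
            key = which.lower().replace("t_", "t")
            row[f"community_{key}"] = v
            row[f"community_{key}_hw"] = hw
        row["measured_temp"] = measured_temps.get(label, float("nan"))
        combined_rows.append(row)
    combined = pd.DataFrame(combined_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, report in reports.items():
            safe = label.replace(" ", "_").replace("/", "_")
            _write_tsv(report_frame(report, config.decimals), out_dir / f"report_{safe}.tsv", config)
        _write_tsv(div, out_dir / "diversity.tsv", config)
        _write_tsv(combined, out_dir / "timecourse.tsv", config)
        log.info("wrote reports to %s", out_dir)

    return {"libraries": libraries, "reports": reports, "diversity": div, "combined": combined}
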