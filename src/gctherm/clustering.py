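"""Pairwise identity, greedy OTU clustering, and clone-library coverage.

An OTU groups clones whose sequences exceed a similarity threshold (97% in
the classic clone-library convention).  Identity is computed from a global
alignment (match +1, mismatch -1, gap -2, end gaps penalized) as identical
columns over alignment length including internal gaps.  Clustering is
greedy centroid/first-fit in input order, the common deterministic
amplicon practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from gctherm.sequences import SequenceRecord

__all__ = [
    "OtuRecord",
    "CloneLibrary",
    "EmptyLibraryError",
    "pairwise_identity",
    "cluster_otus",
    "library_coverage",
    "write_otu_table",
    "write_library_summary",
]


class EmptyLibraryError(ValueError):
    """Clustering or aggregation was asked to operate on zero sequences."""


@dataclass
class OtuRecord:
    """One OTU: representative sequence, member clone ids, and (optionally) P_G+C."""

    otu_id: str
    representative: SequenceRecord
    member_ids: list[str] = field(default_factory=list)
    pgc: float | None = None  # percentage in [0, 100]; filled by thermometry

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"OTU {self.otu_id} has no members")
        if self.representative.id not in self.member_ids:
            raise ValueError(
                f"OTU {self.otu_id}: representative {self.representative.id!r} not a member"
            )

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass
class CloneLibrary:
    """A dated collection of OTUs, ordered by descending clone count."""

    label: str
    otus: list[OtuRecord]

    def __post_init__(self) -> None:
        all_ids = [m for otu in self.otus for m in otu.member_ids]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError(f"library {self.label!r}: a sequence id appears in two OTUs")

    @property
    def total_clones(self) -> int:
        return sum(otu.count for otu in self.otus)

    @property
    def counts(self) -> list[int]:
        return [otu.count for otu in self.otus]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _aligner()


def pairwise_identity(a: str | SequenceRecord, b: str | SequenceRecord) -> float:
    """Global-alignment identity of two sequences, in [0, 1].

    Identity = identical aligned columns / alignment length (internal and
    end gaps count toward the length).  The first optimal alignment under
    the fixed scoring is used, so the value is deterministic for fixed
    inputs.  Case and U/T spelling are normalized first, hence identical
    sequences score exactly 1.0.
    """
    sa = a.norm if isinstance(a, SequenceRecord) else SequenceRecord("a", a).norm
    sb = b.norm if isinstance(b, SequenceRecord) else SequenceRecord("b", b).norm
    if sa == sb:
        return 1.0
    aln = _ALIGNER.align(sa, sb)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_otus(
    records: list[SequenceRecord],
    threshold: float = 0.97,
    label: str = "",
    otu_prefix: str = "OTU",
) -> CloneLibrary:
    """Greedy centroid clustering of sequences into OTUs.

    Sequences are processed in input order; each joins the first existing
    OTU whose representative (founder) exceeds ``threshold`` identity
    (strict inequality), otherwise it founds a new OTU.  OTUs are returned
    sorted by descending count, ties broken by founding order.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not records:
        raise EmptyLibraryError("cannot cluster an empty record list")
    otus: list[OtuRecord] = []
    for rec in records:
        placed = False
        for otu in otus:
            if pairwise_identity(rec, otu.representative) > threshold:
                otu.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            otus.append(
                OtuRecord(
                    otu_id=f"{otu_prefix}{len(otus) + 1:03d}",
                    representative=rec,
                    member_ids=[rec.id],
                )
            )
    otus.sort(key=lambda o: -o.count)  # stable: founding order breaks ties
    return CloneLibrary(label=label, otus=otus)


def library_coverage(library: CloneLibrary) -> float:
    """Clone-library coverage, 100 x (1 - n/N).

    n is the number of singleton OTUs (one clone) and N the total clone
    count; the classic estimate of sampling completeness for clone
    libraries.
    """
    n_total = library.total_clones
    if n_total < 1:
        raise EmptyLibraryError(f"library {library.label!r} has no clones")
    n_singletons = sum(1 for otu in library.otus if otu.count == 1)
    return 100.0 * (1.0 - n_singletons / n_total)


def write_otu_table(library: CloneLibrary, path: str | Path) -> None:
    """Write one row per OTU: otu_id, count, representative_id, member_ids."""
    with open(path, "w") as fh:
        fh.write("otu_id\tcount\trepresentative_id\tmember_ids\n")
        for otu in library.otus:
            fh.write(
                f"{otu.otu_id}\t{otu.count}\t{otu.representative.id}\t"
                f"{','.join(otu.member_ids)}\n"
            )


def write_library_summary(libraries: list[CloneLibrary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tn_otus\ttotal_clones\tcoverage_percent\n")
        for lib in libraries:
            fh.write(
                f"{lib.label}\t{len(lib.otus)}\t{lib.total_clones}\t"
                f"{library_coverage(lib):.1f}\n"
            )
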