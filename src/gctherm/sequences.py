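"""Sequence I/O, IUPAC-aware utilities, and primer-bounded trimming.

Clone inserts are amplified with an archaea-specific primer pair; all
downstream thermometry operates on the internal region strictly between
the forward primer site and the reverse primer site.  Primer matching is
substitution-only (Sanger clone inserts begin at the primer, so indel
tolerance buys nothing) and IUPAC-aware: a degenerate primer code matches
any base it encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "PrimerPair",
    "AlphabetError",
    "FastaParseError",
    "PrimerNotFoundError",
    "OrientationError",
    "PRIMER_PROFILES",
    "load_primer_profiles",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "find_primer",
    "trim_to_internal_region",
]

#: Expansion of each IUPAC nucleotide code into the unambiguous bases it encodes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(IUPAC_SETS)


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class FastaParseError(ValueError):
    """A FASTA file is malformed (content before first header, empty record...)."""


class PrimerNotFoundError(ValueError):
    """A primer site could not be located within the mismatch budget."""


class OrientationError(ValueError):
    """Primer sites were found but in an impossible relative orientation."""


def normalize(seq: str) -> str:
    """Uppercase, map U to T, and validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_CODES
    if bad:
        raise AlphabetError(
            f"invalid nucleotide code(s) {sorted(bad)!r}; allowed: IUPAC {''.join(sorted(IUPAC_CODES))}"
        )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence over the IUPAC alphabet.

    Case and U/T spelling are preserved as read; every comparison and
    computation downstream works on the normalized (uppercase, U->T) form
    available as :attr:`norm`.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        normalize(self.seq)  # validates alphabet

    @property
    def norm(self) -> str:
        return normalize(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3' as primers are ordered.

    The reverse primer anneals to the plus strand, so its site appears on a
    plus-strand sequence as the reverse complement of ``reverse``.
    """

    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{label} primer must be at least 10 nt, got {len(p)}")
            normalize(p)


# Literature-derived default profile for the archaea-specific pair used on
# 16S rRNA clone libraries (A109f / Arch915).  These sequences are defaults,
# not constants of the method: any profile or explicit pair may be supplied.
PRIMER_PROFILES: dict[str, PrimerPair] = {
    "arch_109aF_915aR": PrimerPair(
        forward="ACKGCTCAGTAACACGT",
        reverse="GTGCTCCCCCGCCAATTCCT",
        name="arch_109aF_915aR",
    ),
}


def load_primer_profiles(path: str | Path) -> dict[str, PrimerPair]:
    """Read primer profiles from a small key-value config file.

    Each non-blank, non-comment line is ``name<TAB>forward<TAB>reverse``.
    """
    profiles: dict[str, PrimerPair] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'name<TAB>forward<TAB>reverse'")
        name, fwd, rev = (p.strip() for p in parts)
        profiles[name] = PrimerPair(forward=fwd, reverse=rev, name=name)
    return profiles


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Records are returned in file order with whitespace stripped from
    sequences.  Malformed input — sequence data before the first header,
    a header with no sequence, duplicated ids — raises
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    # Pre-scan for structural problems SeqIO silently tolerates.
    header_line: int | None = None
    has_seq = False
    seen_any_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header_line is not None and not has_seq:
                raise FastaParseError(f"{path}:{header_line}: record with no sequence")
            header_line, has_seq, seen_any_header = lineno, False, True
        else:
            if not seen_any_header:
                raise FastaParseError(f"{path}:{lineno}: sequence data before first '>' header")
            has_seq = True
    if header_line is not None and not has_seq:
        raise FastaParseError(f"{path}:{header_line}: record with no sequence")

    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq).replace(" ", ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FastaParseError(f"{path}: duplicate sequence id {dup!r}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, N->N); U as T."""
    return str(Seq(normalize(seq)).reverse_complement())


def _mismatches(window: str, primer_sets: list[frozenset[str]]) -> int:
    n = 0
    for base, allowed in zip(window, primer_sets):
        # Sequence ambiguity codes match when the encoded base sets intersect.
        if not (IUPAC_SETS[base] & allowed):
            n += 1
    return n


def find_primer(seq: str, primer: str, max_mismatches: int = 2) -> int | None:
    """Locate the best IUPAC-compatible primer window in ``seq``.

    Substitutions only, no indels.  Returns the 0-based start of the
    best-scoring window (leftmost on ties), or ``None`` when no window has
    at most ``max_mismatches`` mismatches.  A primer longer than the
    sequence is a no-match, not an error.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    s = normalize(seq)
    p = normalize(primer)
    if len(p) > len(s):
        return None
    primer_sets = [IUPAC_SETS[c] for c in p]
    best_pos, best_mm = None, None
    for i in range(len(s) - len(p) + 1):
        mm = _mismatches(s[i : i + len(p)], primer_sets)
        if best_mm is None or mm < best_mm:
            best_pos, best_mm = i, mm
            if mm == 0:
                break
    return best_pos if best_mm is not None and best_mm <= max_mismatches else None


def _locate_sites(s: str, pair: PrimerPair, max_mismatches: int) -> tuple[int, int] | str:
    """Return (forward site end, reverse site start) on the plus strand of ``s``.

    On failure returns the name of the missing primer; raises
    :class:`OrientationError` when both sites exist but the reverse site
    lies upstream of the forward site.
    """
    f = find_primer(s, pair.forward, max_mismatches)
    if f is None:
        return "forward"
    rc_rev = reverse_complement(pair.reverse)
    r = find_primer(s, rc_rev, max_mismatches)
    if r is None:
        return "reverse"
    f_end = f + len(pair.forward)
    if r < f_end:
        raise OrientationError(
            f"reverse primer site (pos {r}) upstream of forward primer site end (pos {f_end})"
        )
    return f_end, r


def trim_to_internal_region(
    record: SequenceRecord, primer_pair: PrimerPair, max_mismatches: int = 2
) -> SequenceRecord:
    """Trim a clone sequence to the region strictly between the primer sites.

    Both primer sequences are excluded from the result.  Orientation is
    auto-detected: when the sites are only found on the reverse-complemented
    record, the record is flipped before trimming.
    """
    s = record.norm
    result = _locate_sites(s, primer_pair, max_mismatches)
    if isinstance(result, str):
        flipped = reverse_complement(s)
        flipped_result = _locate_sites(flipped, primer_pair, max_mismatches)
        if isinstance(flipped_result, str):
            raise PrimerNotFoundError(
                f"{record.id}: {result} primer not found within {max_mismatches} mismatches"
            )
        s, result = flipped, flipped_result
    f_end, r_start = result
    return SequenceRecord(id=record.id, seq=s[f_end:r_start])
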