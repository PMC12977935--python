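"""Reading and writing the formats a DMC workflow touches.

A diagnostic molecular combination (DMC) is an ordered set of
(alignment position, nucleotide state) pairs that jointly distinguish one
taxon from every other sequence in a barcode library.  This module owns the
external representations: FASTA alignments (via Biopython), the one-column
query-taxon CSV, the bracketed DMC string dialect ``[25: A; 69: G]``, and
the DMC result table CSV.  It also resolves which sequences belong to which
query taxon from the sequence identifiers themselves.

Positions are 1-based alignment columns throughout, matching how diagnoses
are printed in taxonomic practice.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "BACKGROUND",
    "IUPAC",
    "MISSING",
    "Alignment",
    "DMC",
    "DMCRow",
    "DMCTable",
    "QueryList",
    "AlignmentShapeError",
    "AmbiguousTaxonError",
    "DmcKitError",
    "DmcParseError",
    "FormatError",
    "assign_taxa",
    "format_dmc_string",
    "parse_dmc_string",
    "read_alignment",
    "read_dmc_table",
    "read_fasta_records",
    "read_query_list",
    "write_alignment",
    "write_dmc_table",
    "write_fasta",
]

#: Reserved taxon label for sequences that match no query taxon.
BACKGROUND = "BACKGROUND"

#: Characters treated as undetermined states in any mode.
MISSING = frozenset("N?")

GAP = "-"

#: IUPAC nucleotide codes and their expansions into unambiguous bases.
IUPAC: Mapping[str, frozenset[str]] = {
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
}

_ALPHABET = frozenset(IUPAC) | MISSING | {GAP}
_SEPARATORS = "_|"


class DmcKitError(Exception):
    """Base class for all errors raised by dmckit."""


class FormatError(DmcKitError):
    """An input file violates its expected format."""


class AlignmentShapeError(FormatError):
    """Alignment records do not all share the same length."""


class AmbiguousTaxonError(DmcKitError):
    """A sequence id matches two query taxa of equal length."""


class DmcParseError(FormatError):
    """A DMC string does not follow the ``[pos: state; ...]`` dialect."""


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """An equal-length nucleotide alignment with taxon assignments.

    ``taxon_of`` maps every sequence id to a query-taxon label or to
    :data:`BACKGROUND`; it is populated by :func:`assign_taxa` (or directly
    by the synthetic generator).  ``members`` records the id list of each
    query taxon in alignment order.
    """

    ids: list[str]
    seqs: list[str]
    taxon_of: dict[str, str] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ids:
            raise FormatError("alignment has no records")
        if len(self.ids) != len(set(self.ids)):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise FormatError(f"duplicate sequence id: {dup!r}")
        n = len(self.seqs[0])
        bad = [i for i, s in zip(self.ids, self.seqs) if len(s) != n]
        if bad:
            raise AlignmentShapeError(
                f"records not all of length {n}: {', '.join(bad)}"
            )
        if n < 1:
            raise FormatError("alignment has zero columns")

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0])

    @property
    def n_records(self) -> int:
        return len(self.ids)

    def seq_of(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def column(self, position: int) -> list[str]:
        """States of every record at a 1-based alignment column."""
        if not 1 <= position <= self.n_sites:
            raise IndexError(f"column {position} outside [1, {self.n_sites}]")
        return [s[position - 1] for s in self.seqs]


def read_alignment(path: str | Path) -> Alignment:
    """Parse a FASTA alignment, normalizing case and U→T.

    Raises :class:`AlignmentShapeError` when record lengths differ and
    :class:`FormatError` for empty files or characters outside the
    nucleotide/IUPAC/missing/gap alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) < 2:
        raise FormatError(f"alignment needs at least 2 records, got {len(records)}")
    ids = [r.id for r in records]
    seqs = []
    for rid, rec in zip(ids, records):
        s = _normalize(str(rec.seq))
        for pos, ch in enumerate(s, start=1):
            if ch not in _ALPHABET:
                raise FormatError(
                    f"record {rid!r}: invalid character {ch!r} at position {pos}"
                )
        seqs.append(s)
    return Alignment(ids=ids, seqs=seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(zip(aln.ids, aln.seqs), path)


def read_fasta_records(path: str | Path) -> list[tuple[str, str]]:
    """Read (possibly unaligned) FASTA records with the same normalization."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return [(r.id, _normalize(str(r.seq))) for r in records]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Query list and taxon assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QueryList:
    """Ordered, unique taxon labels to be diagnosed.

    Entries may be species-level (``Diachlorus_curvipes``) or a higher-level
    prefix such as a genus (``Diachlorus``).
    """

    queries: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.queries:
            raise FormatError("query list is empty")
        if len(set(self.queries)) != len(self.queries):
            raise FormatError("query list has duplicates")
        if any(not q.strip() for q in self.queries):
            raise FormatError("query list has a blank entry")

    def __iter__(self):
        return iter(self.queries)

    def __len__(self) -> int:
        return len(self.queries)


def read_query_list(path: str | Path) -> QueryList:
    """Read the one-column query CSV.

    A first row whose first cell is literally ``taxon`` or ``query``
    (case-insensitive) is treated as a header.  Duplicates are dropped with
    a warning, preserving first-occurrence order.
    """
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and row[0].strip()]
    if rows and rows[0][0].strip().lower() in {"taxon", "query"}:
        rows = rows[1:]
    seen: dict[str, None] = {}
    for row in rows:
        label = row[0].strip()
        if label in seen:
            warnings.warn(f"duplicate query taxon {label!r} dropped", stacklevel=2)
        else:
            seen[label] = None
    if not seen:
        raise FormatError(f"no query taxa found in {path}")
    return QueryList(tuple(seen))


def _matches(seq_id: str, query: str, separators: str) -> bool:
    if not seq_id.startswith(query):
        return False
    return len(seq_id) == len(query) or seq_id[len(query)] in separators


def assign_taxa(
    aln: Alignment, queries: QueryList, separators: str = _SEPARATORS
) -> Alignment:
    """Assign every sequence to a query taxon by delimited-prefix match.

    An id belongs to query *q* when *q* is a prefix of the id ending at an id
    boundary (end of id, or one of ``separators``).  The longest matching
    query wins; ids matching nothing become :data:`BACKGROUND`.  Two distinct
    equal-length matches raise :class:`AmbiguousTaxonError`.
    """
    taxon_of: dict[str, str] = {}
    members: dict[str, list[str]] = {q: [] for q in queries}
    for rid in aln.ids:
        hits = [q for q in queries if _matches(rid, q, separators)]
        if not hits:
            taxon_of[rid] = BACKGROUND
            continue
        best = max(len(q) for q in hits)
        top = [q for q in hits if len(q) == best]
        if len(top) > 1:
            raise AmbiguousTaxonError(
                f"sequence {rid!r} matches equally long queries: {sorted(top)}"
            )
        taxon_of[rid] = top[0]
        members[top[0]].append(rid)
    return replace(aln, taxon_of=taxon_of, members=members)


# ---------------------------------------------------------------------------
# DMC strings and tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DMC:
    """One diagnostic molecular combination for one taxon.

    ``sites`` are (1-based alignment position, unambiguous state) pairs in
    strictly increasing position order.  ``exclusivity`` is the minimum
    number of DMC sites at which any background sequence differs — the
    number of state changes needed to break the diagnosis.  ``reference_id``
    names the designated reference sequence used for coordinate projection
    when testing unaligned sequences.
    """

    taxon: str
    sites: tuple[tuple[int, str], ...]
    exclusivity: int
    kind: str = "candidate"  # consensus | alternative | candidate
    reference_id: str = ""

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.sites]
        if positions != sorted(set(positions)):
            raise DmcParseError(f"positions not strictly increasing: {positions}")
        for p, s in self.sites:
            if p < 1:
                raise DmcParseError(f"position {p} is not 1-based")
            if s not in "ACGT":
                raise DmcParseError(f"state {s!r} is not an unambiguous nucleotide")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.sites)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(s for _, s in self.sites)

    def __str__(self) -> str:
        return format_dmc_string(self.sites)


def parse_dmc_string(text: str) -> list[tuple[int, str]]:
    """Parse ``[25: A; 69: G]`` into ``[(25, 'A'), (69, 'G')]``."""
    t = text.strip()
    if not (t.startswith("[") and t.endswith("]")):
        raise DmcParseError(f"DMC string must be bracketed: {text!r}")
    body = t[1:-1].strip()
    if not body:
        return []
    sites: list[tuple[int, str]] = []
    seen: set[int] = set()
    for i, token in enumerate(body.split(";")):
        parts = token.split(":")
        if len(parts) != 2:
            raise DmcParseError(f"malformed token {i}: {token.strip()!r}")
        pos_txt, state = parts[0].strip(), parts[1].strip().upper()
        if not pos_txt.isdigit():
            raise DmcParseError(f"malformed position in token {i}: {pos_txt!r}")
        pos = int(pos_txt)
        if pos in seen:
            raise DmcParseError(f"duplicate position {pos} in token {i}")
        if state not in "ACGT" or len(state) != 1:
            raise DmcParseError(f"non-nucleotide state in token {i}: {state!r}")
        seen.add(pos)
        sites.append((pos, state))
    return sites


def format_dmc_string(sites: Sequence[tuple[int, str]]) -> str:
    """Inverse of :func:`parse_dmc_string` on canonical input."""
    return "[" + "; ".join(f"{p}: {s}" for p, s in sites) + "]"


@dataclass(frozen=True)
class DMCRow:
    """One output row: consensus + alternative DMC for one query taxon."""

    taxon: str
    consensus: DMC | None
    alternative: DMC | None
    n_optimal_candidates: int
    status: str  # ok | no_dmc_found | no_query_sequences

    def __post_init__(self) -> None:
        if self.status == "ok" and (self.consensus is None or self.alternative is None):
            raise DmcKitError(f"row {self.taxon!r}: status ok but DMC missing")


@dataclass(frozen=True)
class DMCTable:
    rows: tuple[DMCRow, ...]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, taxon: str) -> DMCRow:
        for r in self.rows:
            if r.taxon == taxon:
                return r
        raise KeyError(taxon)

    @property
    def dmcs(self) -> list[DMC]:
        """Consensus DMC of every successful row."""
        return [r.consensus for r in self.rows if r.status == "ok"]


_TABLE_COLUMNS = [
    "taxon",
    "consensus_dmc",
    "consensus_length",
    "consensus_exclusivity",
    "alternative_dmc",
    "alternative_exclusivity",
    "n_optimal_candidates",
    "status",
    "reference_id",
]


def write_dmc_table(table: DMCTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TABLE_COLUMNS)
        for r in table:
            cons, alt = r.consensus, r.alternative
            writer.writerow(
                [
                    r.taxon,
                    str(cons) if cons else "",
                    len(cons) if cons else "",
                    cons.exclusivity if cons else "",
                    str(alt) if alt else "",
                    alt.exclusivity if alt else "",
                    r.n_optimal_candidates,
                    r.status,
                    cons.reference_id if cons else "",
                ]
            )


def read_dmc_table(path: str | Path) -> DMCTable:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:8] != _TABLE_COLUMNS[:8]:
            raise FormatError(f"unexpected DMC table header in {path}")
        rows = []
        for rec in reader:
            taxon = rec["taxon"]
            status = rec["status"]
            cons = alt = None
            if rec["consensus_dmc"]:
                cons = DMC(
                    taxon=taxon,
                    sites=tuple(parse_dmc_string(rec["consensus_dmc"])),
                    exclusivity=int(rec["consensus_exclusivity"]),
                    kind="consensus",
                    reference_id=rec.get("reference_id", ""),
                )
            if rec["alternative_dmc"]:
                alt = DMC(
                    taxon=taxon,
                    sites=tuple(parse_dmc_string(rec["alternative_dmc"])),
                    exclusivity=int(rec["alternative_exclusivity"]),
                    kind="alternative",
                    reference_id=rec.get("reference_id", ""),
                )
            rows.append(
                DMCRow(
                    taxon=taxon,
                    consensus=cons,
                    alternative=alt,
                    n_optimal_candidates=int(rec["n_optimal_candidates"]),
                    status=status,
                )
            )
    return DMCTable(rows=tuple(rows))
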