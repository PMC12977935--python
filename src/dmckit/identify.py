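"""Testing DMCs against sequences: aligned, globally aligned, and sliding.

Three verification modes mirror how barcode test data actually arrive:

* ``aligned`` — the test sequences share the training coordinate system;
  states are read off directly at the DMC positions.
* ``global_aligned`` — unaligned test sequences are pairwise-aligned
  (semi-global dynamic programming, free end gaps) to the DMC's designated
  reference sequence; DMC columns are projected through the reference onto
  the test sequence.
* ``sliding`` — alignment-free: the DMC's sites, rigidly spaced as in the
  degapped reference, are slid over every start position of the test
  sequence and the best window (fewest mismatches, leftmost tie-break) is
  reported.

A sequence matches a DMC when its number of non-missing mismatches is at
most the tolerance and at least one DMC site is informative.  Undetermined
states (N, ?, gaps) count as missing, never as mismatches; they are tallied
so that evaluation can apply its missing-data exclusion rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align

from .seqio import (
    DMC,
    GAP,
    IUPAC,
    MISSING,
    Alignment,
    DmcKitError,
    DMCTable,
    FormatError,
)

__all__ = [
    "AlignScoring",
    "CoordinateError",
    "MatchOutcome",
    "MatchReport",
    "ProjectionError",
    "build_position_map",
    "identify_aligned",
    "identify_sliding",
    "identify_unaligned_global",
    "match_profile",
    "read_match_report",
    "write_match_report",
]


class CoordinateError(DmcKitError):
    """A DMC position falls outside the test alignment."""


class ProjectionError(DmcKitError):
    """A DMC position cannot be projected onto its reference sequence."""


@dataclass(frozen=True)
class AlignScoring:
    """Pairwise-alignment scoring for the position map (semi-global)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class MatchOutcome:
    """Result of testing one sequence against one DMC."""

    sequence_id: str
    taxon: str
    n_sites: int
    n_match: int
    n_mismatch: int
    n_missing: int
    matched: bool
    offset: int | None = None  # 1-based sliding-window start; None otherwise


@dataclass(frozen=True)
class MatchReport:
    outcomes: tuple[MatchOutcome, ...]
    mode: str  # aligned | global_aligned | sliding
    tolerance: int

    def __iter__(self):
        return iter(self.outcomes)

    def __len__(self) -> int:
        return len(self.outcomes)

    def matched_ids(self, taxon: str) -> set[str]:
        return {o.sequence_id for o in self.outcomes if o.taxon == taxon and o.matched}


def _classify_state(state: str, dmc_state: str, ambiguity_matches: bool) -> str:
    if state in MISSING or state == GAP:
        return "missing"
    if state == dmc_state:
        return "match"
    expansion = IUPAC.get(state)
    if expansion is not None and len(expansion) > 1:
        if ambiguity_matches and dmc_state in expansion:
            return "match"
        return "mismatch"
    return "mismatch"


def match_profile(
    dmc: DMC,
    states_at_sites: Sequence[str],
    tolerance: int,
    sequence_id: str = "",
    ambiguity_matches: bool = True,
    offset: int | None = None,
) -> MatchOutcome:
    """Classify observed states against a DMC and decide the match.

    Each state is a match (equal, or an ambiguity code whose expansion
    contains the DMC state), a mismatch, or missing (N/?/gap).  The sequence
    matches when mismatches ≤ tolerance and at least one site is
    informative; an all-missing profile is uninformative and never matches.
    """
    if len(states_at_sites) != len(dmc):
        raise DmcKitError(
            f"{len(states_at_sites)} states supplied for a {len(dmc)}-site DMC"
        )
    n_match = n_mismatch = n_missing = 0
    for state, (_, dmc_state) in zip(states_at_sites, dmc.sites):
        kind = _classify_state(state.upper(), dmc_state, ambiguity_matches)
        if kind == "match":
            n_match += 1
        elif kind == "mismatch":
            n_mismatch += 1
        else:
            n_missing += 1
    n = len(dmc)
    matched = n_mismatch <= tolerance and (n_missing < n or n == 0)
    return MatchOutcome(
        sequence_id=sequence_id,
        taxon=dmc.taxon,
        n_sites=n,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_missing=n_missing,
        matched=matched,
        offset=offset,
    )


# ---------------------------------------------------------------------------
# Aligned mode
# ---------------------------------------------------------------------------


def identify_aligned(
    dmcs: DMCTable,
    test_aln: Alignment,
    tolerance: int = 0,
    ambiguity_matches: bool = True,
    which: str = "consensus",
) -> MatchReport:
    """Test every sequence of an aligned test set against every DMC."""
    outcomes: list[MatchOutcome] = []
    for dmc in _select(dmcs, which):
        if dmc.positions and max(dmc.positions) > test_aln.n_sites:
            raise CoordinateError(
                f"DMC for {dmc.taxon!r} uses position {max(dmc.positions)} but the "
                f"test alignment has {test_aln.n_sites} columns"
            )
        for rid, seq in zip(test_aln.ids, test_aln.seqs):
            states = [seq[p - 1] for p in dmc.positions]
            outcomes.append(
                match_profile(dmc, states, tolerance, rid, ambiguity_matches)
            )
    return MatchReport(outcomes=tuple(outcomes), mode="aligned", tolerance=tolerance)


def _select(dmcs: DMCTable, which: str) -> list[DMC]:
    if which not in {"consensus", "alternative"}:
        raise ValueError(f"unknown DMC choice {which!r}")
    out = []
    for row in dmcs:
        if row.status != "ok":
            continue
        out.append(row.consensus if which == "consensus" else row.alternative)
    return out


# ---------------------------------------------------------------------------
# Global-alignment mode
# ---------------------------------------------------------------------------


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # free end gaps: test barcodes may truncate or overhang the reference
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def build_position_map(
    test_seq: str,
    reference_seq: str,
    scoring: AlignScoring = AlignScoring(),
) -> dict[int, int | None]:
    """Map 1-based reference positions to 1-based test positions.

    The map is induced by a semi-global pairwise alignment (end gaps free);
    reference positions aligned to a gap in the test sequence map to
    ``None``.
    """
    if not test_seq or not reference_seq:
        raise DmcKitError("empty sequence passed to build_position_map")
    aligner = _make_aligner(scoring)
    best = aligner.align(reference_seq, test_seq)[0]
    ref_blocks, test_blocks = best.aligned
    mapping: dict[int, int | None] = {p: None for p in range(1, len(reference_seq) + 1)}
    for (rs, re), (ts, _te) in zip(ref_blocks, test_blocks):
        for k in range(re - rs):
            mapping[rs + k + 1] = ts + k + 1
    return mapping


def _column_to_ref_position(reference_row: str) -> list[int | None]:
    """Project training-alignment columns to degapped reference positions."""
    out: list[int | None] = []
    pos = 0
    for ch in reference_row:
        if ch == GAP:
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def identify_unaligned_global(
    dmcs: DMCTable,
    test_records: Sequence[tuple[str, str]],
    training_aln: Alignment,
    tolerance: int = 0,
    scoring: AlignScoring = AlignScoring(),
    ambiguity_matches: bool = True,
    which: str = "consensus",
) -> MatchReport:
    """Test unaligned sequences by aligning each to the DMC's reference.

    For every (test sequence × DMC) pair, the test sequence is aligned
    semi-globally to the degapped designated reference of the DMC's taxon;
    DMC columns are projected through the reference's gap pattern, read off
    the test sequence, and scored.  Sites lost to gaps or truncation count
    as missing.
    """
    outcomes: list[MatchOutcome] = []
    for dmc in _select(dmcs, which):
        if dmc.reference_id not in training_aln.ids:
            raise DmcKitError(
                f"reference id {dmc.reference_id!r} for {dmc.taxon!r} "
                "not found in the training alignment"
            )
        ref_row = training_aln.seq_of(dmc.reference_id)
        col2ref = _column_to_ref_position(ref_row)
        ref_degapped = ref_row.replace(GAP, "")
        for rid, raw in test_records:
            test = raw.replace(GAP, "")
            mapping = build_position_map(test, ref_degapped, scoring)
            states = []
            for pos in dmc.positions:
                refpos = col2ref[pos - 1]
                testpos = mapping[refpos] if refpos is not None else None
                states.append(test[testpos - 1] if testpos is not None else "?")
            outcomes.append(
                match_profile(dmc, states, tolerance, rid, ambiguity_matches)
            )
    return MatchReport(
        outcomes=tuple(outcomes), mode="global_aligned", tolerance=tolerance
    )


# ---------------------------------------------------------------------------
# Sliding-window mode
# ---------------------------------------------------------------------------


def identify_sliding(
    dmcs: DMCTable,
    test_records: Sequence[tuple[str, str]],
    training_aln: Alignment,
    tolerance: int = 0,
    ambiguity_matches: bool = True,
    which: str = "consensus",
) -> MatchReport:
    """Alignment-free verification by scanning a rigid site footprint.

    DMC sites are spaced as in the degapped reference; every start position
    with the full footprint inside the test sequence is scored and the
    window with the fewest mismatches (leftmost on ties) is reported.  The
    1-based start of the best window is returned as ``offset``.  Sequences
    shorter than the footprint yield an all-missing, unmatched outcome.
    """
    outcomes: list[MatchOutcome] = []
    for dmc in _select(dmcs, which):
        ref_row = training_aln.seq_of(dmc.reference_id)
        col2ref = _column_to_ref_position(ref_row)
        refpos = []
        for pos in dmc.positions:
            rp = col2ref[pos - 1]
            if rp is None:
                raise ProjectionError(
                    f"DMC position {pos} for {dmc.taxon!r} falls on a gap in "
                    f"reference {dmc.reference_id!r}"
                )
            refpos.append(rp)
        deltas = [rp - refpos[0] for rp in refpos]
        span = deltas[-1] + 1
        for rid, raw in test_records:
            test = raw.replace(GAP, "")
            if len(test) < span:
                outcomes.append(
                    MatchOutcome(
                        sequence_id=rid,
                        taxon=dmc.taxon,
                        n_sites=len(dmc),
                        n_match=0,
                        n_mismatch=0,
                        n_missing=len(dmc),
                        matched=False,
                        offset=None,
                    )
                )
                continue
            best: MatchOutcome | None = None
            for s in range(len(test) - span + 1):
                states = [test[s + d] for d in deltas]
                out = match_profile(
                    dmc, states, tolerance, rid, ambiguity_matches, offset=s + 1
                )
                if best is None or out.n_mismatch < best.n_mismatch:
                    best = out
            outcomes.append(best)
    return MatchReport(outcomes=tuple(outcomes), mode="sliding", tolerance=tolerance)


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "sequence_id",
    "taxon",
    "n_sites",
    "n_match",
    "n_mismatch",
    "n_missing",
    "matched",
    "offset",
]


def write_match_report(report: MatchReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REPORT_COLUMNS + ["mode", "tolerance"])
        for o in report:
            writer.writerow(
                [
                    o.sequence_id,
                    o.taxon,
                    o.n_sites,
                    o.n_match,
                    o.n_mismatch,
                    o.n_missing,
                    int(o.matched),
                    "" if o.offset is None else o.offset,
                    report.mode,
                    report.tolerance,
                ]
            )


def read_match_report(path: str | Path) -> MatchReport:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        outcomes = []
        mode, tolerance = "aligned", 0
        for rec in reader:
            mode = rec["mode"]
            tolerance = int(rec["tolerance"])
            outcomes.append(
                MatchOutcome(
                    sequence_id=rec["sequence_id"],
                    taxon=rec["taxon"],
                    n_sites=int(rec["n_sites"]),
                    n_match=int(rec["n_match"]),
                    n_mismatch=int(rec["n_mismatch"]),
                    n_missing=int(rec["n_missing"]),
                    matched=bool(int(rec["matched"])),
                    offset=int(rec["offset"]) if rec["offset"] else None,
                )
            )
    if not outcomes:
        raise FormatError(f"empty match report in {path}")
    return MatchReport(outcomes=tuple(outcomes), mode=mode, tolerance=tolerance)
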