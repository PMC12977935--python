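"""Synthetic species-structured barcode libraries with planted diagnoses.

The generator emulates the statistical structure of a curated barcode
library: an ancestral sequence diverges into per-species consensus
sequences (between-species substitutions), individuals vary around their
species consensus (within-species substitutions), and noise is layered on
top as undetermined bases and column-coherent gap events.  On top of that,
each species receives a set of *planted* diagnostic sites — disjoint
columns where the species is fixed for a state no other species carries —
so the ground-truth diagnosable signal of every instance is known exactly
and search results can be checked against it.

Defaults mimic a small mini-barcode library: 313-bp sequences, 8 species
of 5 individuals, two fully exclusive planted sites per species, 20%
between-species divergence and 0.5% within-species variation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import Alignment, DmcKitError

__all__ = [
    "SynthSpec",
    "SynthTruth",
    "generate_test_set",
    "generate_training_alignment",
    "write_truth_csv",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic barcode library."""

    n_species: int = 8
    seqs_per_species: int = 5
    n_sites: int = 313  # mini-barcode length
    planted_sites_per_species: int = 2
    intraspecific_rate: float = 0.005  # per-site substitution within species
    missing_rate: float = 0.0  # per-cell probability of an N
    gap_rate: float = 0.0  # expected gap events per column
    background_divergence: float = 0.2  # per-site substitution between species
    scrub_chance_diagnostics: bool = True  # keep planted sites the only clean signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.seqs_per_species < 1 or self.n_sites < 1:
            raise ValueError("need ≥2 species, ≥1 sequence each, ≥1 site")
        if self.planted_sites_per_species * self.n_species > self.n_sites:
            raise DmcKitError(
                "planted sites exceed alignment columns: "
                f"{self.planted_sites_per_species} × {self.n_species} > {self.n_sites}"
            )
        for name in ("intraspecific_rate", "missing_rate", "gap_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 < self.background_divergence <= 1.0:
            raise ValueError("background_divergence must lie in (0, 1]")


@dataclass(frozen=True)
class SynthTruth:
    """Planted diagnostic sites per species, plus the generating spec."""

    planted: dict[str, tuple[tuple[int, str], ...]]  # species -> ((1-based pos, state), ...)
    spec: SynthSpec

    def species(self) -> list[str]:
        return list(self.planted)


def _species_name(i: int) -> str:
    return f"Synthia_sp{i + 1:02d}"


def generate_training_alignment(spec: SynthSpec) -> tuple[Alignment, SynthTruth]:
    """Simulate a labelled training alignment with planted diagnostic sites.

    Sequence ids follow ``Genus_species_counter`` so the standard
    delimited-prefix taxon assignment resolves them; ``taxon_of`` is also
    populated directly.  Deterministic for a given spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n_sp, per, n_sites = spec.n_species, spec.seqs_per_species, spec.n_sites
    ancestral = rng.integers(0, 4, n_sites)

    # species consensus: ancestral plus between-species substitutions
    consensus = np.tile(ancestral, (n_sp, 1))
    mask = rng.random((n_sp, n_sites)) < spec.background_divergence
    shift = rng.integers(1, 4, (n_sp, n_sites))
    consensus = (consensus + shift * mask) % 4

    # plant disjoint diagnostic sites: owner fixed, everyone else different
    n_planted = spec.planted_sites_per_species
    planted_cols = rng.choice(n_sites, size=n_planted * n_sp, replace=False)
    planted: dict[str, tuple[tuple[int, str], ...]] = {}
    for s in range(n_sp):
        cols = np.sort(planted_cols[s * n_planted : (s + 1) * n_planted])
        sites = []
        for col in cols:
            state = int(rng.integers(0, 4))
            consensus[s, col] = state
            for t in range(n_sp):
                if t != s and consensus[t, col] == state:
                    consensus[t, col] = (state + int(rng.integers(1, 4))) % 4
            sites.append((int(col) + 1, str(_BASES[state])))
        planted[_species_name(s)] = tuple(sites)

    # optionally remove chance autapomorphies outside the planted columns:
    # a consensus state carried by a single species is folded into the
    # column majority, so the planted sites stay the only exclusive signal
    if spec.scrub_chance_diagnostics:
        owner_of = {}
        for s in range(n_sp):
            for col in planted_cols[s * n_planted : (s + 1) * n_planted]:
                owner_of[int(col)] = s
        for j in range(n_sites):
            owner = owner_of.get(j)
            rows_j = [t for t in range(n_sp) if t != owner]
            if len(rows_j) < 2:
                continue
            while True:
                vals, cnts = np.unique(consensus[rows_j, j], return_counts=True)
                singles = vals[cnts == 1]
                if singles.size == 0 or vals.size == 1:
                    break
                majority = vals[np.argmax(cnts)]
                sel = [t for t in rows_j if consensus[t, j] in singles]
                consensus[sel, j] = majority

    # individuals: within-species substitutions, then missing data
    ids: list[str] = []
    rows = np.zeros((n_sp * per, n_sites), dtype=int)
    for s in range(n_sp):
        for k in range(per):
            row = consensus[s].copy()
            m = rng.random(n_sites) < spec.intraspecific_rate
            row[m] = (row[m] + rng.integers(1, 4, int(m.sum()))) % 4
            rows[s * per + k] = row
            ids.append(f"{_species_name(s)}_{k + 1:03d}")
    chars = _BASES[rows].astype("<U1")
    if spec.missing_rate > 0:
        chars[rng.random(chars.shape) < spec.missing_rate] = "N"

    # column-coherent gap events shared by a random subset of species
    if spec.gap_rate > 0:
        n_events = int(round(spec.gap_rate * n_sites))
        for _ in range(n_events):
            start = int(rng.integers(0, n_sites))
            length = int(rng.integers(1, 4))
            k = int(rng.integers(1, max(2, n_sp // 2 + 1)))
            hit = rng.choice(n_sp, size=k, replace=False)
            for s in hit:
                chars[s * per : (s + 1) * per, start : start + length] = "-"

    seqs = ["".join(row) for row in chars]
    taxon_of = {rid: rid.rsplit("_", 1)[0] for rid in ids}
    members: dict[str, list[str]] = {}
    for rid in ids:
        members.setdefault(taxon_of[rid], []).append(rid)
    aln = Alignment(ids=ids, seqs=seqs, taxon_of=taxon_of, members=members)
    return aln, SynthTruth(planted=planted, spec=spec)


def generate_test_set(
    aln: Alignment,
    truth: SynthTruth,
    n_copies: int = 1,
    indel_rate: float = 0.0,
    truncation: tuple[int, int] = (0, 0),
    subst_rate: float = 0.0,
    seed: int = 0,
    protected: dict[str, set[int]] | None = None,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Derive an unaligned test set from a training alignment.

    Each training sequence yields ``n_copies`` degapped copies with random
    head/tail truncations (lengths drawn uniformly from ``truncation``),
    per-site substitutions and indels at the stated rates.  ``protected``
    optionally lists 0-based degapped positions per species that no edit may
    touch (used to keep a DMC footprint intact).  Ids carry the true species
    label as a prefix; the returned mapping gives id → species.
    """
    rng = np.random.default_rng(seed)
    lo, hi = truncation
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid truncation range {truncation}")
    records: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    counter = 0
    for rid in aln.ids:
        species = aln.taxon_of.get(rid, "")
        degapped = aln.seq_of(rid).replace("-", "")
        keep = protected.get(species, set()) if protected else set()
        for _ in range(n_copies):
            head = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
            tail = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
            if head + tail >= len(degapped):
                raise DmcKitError(
                    f"truncation {head}+{tail} consumes sequence {rid!r} "
                    f"of length {len(degapped)}"
                )
            if keep:
                head = min(head, min(keep)) if keep else head
                tail = min(tail, len(degapped) - 1 - max(keep))
            out: list[str] = []
            for pos in range(head, len(degapped) - tail):
                ch = degapped[pos]
                if pos in keep:
                    out.append(ch)
                    continue
                if ch in "ACGT" and rng.random() < subst_rate:
                    ch = str(_BASES[(int(np.flatnonzero(_BASES == ch)[0])
                                     + int(rng.integers(1, 4))) % 4])
                r = rng.random()
                if r < indel_rate / 2:
                    continue  # deletion
                if r < indel_rate:
                    out.append(str(_BASES[rng.integers(0, 4)]))  # insertion before
                out.append(ch)
            counter += 1
            new_id = f"{species}_t{counter:04d}"
            records.append((new_id, "".join(out)))
            labels[new_id] = species
    return records, labels


def write_truth_csv(truth_labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sequence_id", "taxon"])
        for rid, taxon in truth_labels.items():
            writer.writerow([rid, taxon])
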