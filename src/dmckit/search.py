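"""Weighted-random-sampling search for diagnostic molecular combinations.

The search diagnoses one query taxon at a time against every other sequence
in the alignment (the background).  It proceeds in five stages:

1. *Eligibility*: a column can contribute a DMC site only when all
   non-missing query states there are identical and unambiguous.
2. *Weighting*: each eligible column gets a uniqueness weight — the fraction
   of informative background sequences whose state differs from the query
   state (a Jaccard-style site score).
3. *Sampling*: candidate DMCs are built by weighted random sampling without
   replacement, adding sites until the candidate is long enough and
   *exclusive* enough.  Exclusivity is the minimum, over background
   sequences, of the number of DMC sites at which that sequence differs —
   the number of state changes needed to break the diagnosis (analogous to
   Bremer support).
4. *Refinement*: sub-combinations of qualifying candidates are tested to
   find shorter DMCs that still qualify.
5. *Consensus*: the sites recurring most often across the best candidates
   are assembled into a majority-consensus DMC; the best single candidate
   distinct from it is reported as the alternative.

All randomness flows from one root seed; each taxon gets an independent
stream derived from a stable hash of its label, so adding a query never
perturbs another taxon's result.
"""

from __future__ import annotations

import bisect
import itertools
import random
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import (
    DMC,
    GAP,
    MISSING,
    Alignment,
    DmcKitError,
    DMCRow,
    DMCTable,
    QueryList,
    assign_taxa,
)

__all__ = [
    "DegenerateSearchError",
    "NoBackgroundError",
    "SearchParams",
    "TaxonContext",
    "consensus_dmc",
    "exclusivity_score",
    "find_dmcs",
    "refine_dmc",
    "sample_candidate",
    "site_eligibility",
    "site_weights",
    "taxon_context",
]


class NoBackgroundError(DmcKitError):
    """Exclusivity is undefined without at least one background sequence."""


class DegenerateSearchError(DmcKitError):
    """No column carries positive weight for the taxon."""


@dataclass(frozen=True)
class SearchParams:
    """Tunable settings of the DMC search.

    ``min_len`` is silently raised to ``exclusive`` (a DMC with *k* exclusive
    states cannot have fewer than *k* sites), so setting ``exclusive`` alone
    also floors the length.
    """

    n_iter: int = 50_000
    min_len: int = 2
    exclusive: int = 2
    ref_strength: float = 0.33
    max_len: int = 15
    gaps_new: bool = False
    top_k: int = 100
    majority_threshold: float = 0.5
    seed: int = 0
    weight_method: str = "seq_fraction"  # or "state_jaccard"
    missing_breaks: bool = False  # count missing background states as differing

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.min_len < 1 or self.exclusive < 1:
            raise ValueError("n_iter, min_len and exclusive must be positive")
        if not 0.0 <= self.ref_strength <= 1.0:
            raise ValueError("ref_strength must lie in [0, 1]")
        if not 0.0 < self.majority_threshold <= 1.0:
            raise ValueError("majority_threshold must lie in (0, 1]")
        if self.effective_min_len > self.max_len:
            raise ValueError(
                f"effective minimum length {self.effective_min_len} exceeds "
                f"max_len {self.max_len}"
            )
        if self.weight_method not in {"seq_fraction", "state_jaccard"}:
            raise ValueError(f"unknown weight_method {self.weight_method!r}")

    @property
    def effective_min_len(self) -> int:
        return max(self.min_len, self.exclusive)


# ---------------------------------------------------------------------------
# Per-taxon context: eligibility, weights, difference matrix
# ---------------------------------------------------------------------------


def _is_missing(ch: str, gaps_new: bool) -> bool:
    return ch in MISSING or (ch == GAP and not gaps_new)


def site_eligibility(
    aln: Alignment, taxon: str, gaps_new: bool = False
) -> tuple[np.ndarray, list[str | None]]:
    """Per-column eligibility flags and the shared query state.

    A column is eligible when at least one query sequence has a non-missing
    state there and all non-missing query states are the same unambiguous
    nucleotide.  Under ``gaps_new`` a gap is an ordinary fifth state (so a
    gap among the query states makes the column polymorphic); it still never
    becomes a DMC state itself.
    """
    members = aln.members.get(taxon) or [
        i for i in aln.ids if aln.taxon_of.get(i) == taxon
    ]
    if not members:
        raise DmcKitError(f"taxon {taxon!r} has no assigned sequences")
    rows = [aln.seq_of(i) for i in members]
    eligible = np.zeros(aln.n_sites, dtype=bool)
    qstate: list[str | None] = [None] * aln.n_sites
    for j in range(aln.n_sites):
        states = {r[j] for r in rows if not _is_missing(r[j], gaps_new)}
        if len(states) == 1:
            (s,) = states
            if s in "ACGT":
                eligible[j] = True
                qstate[j] = s
    return eligible, qstate


@dataclass
class TaxonContext:
    """Precomputed per-taxon search state.

    ``diff`` is an (n_background × n_sites) 0/1 matrix: entry (b, j) is 1
    when background sequence *b* has an informative state at column *j* that
    differs from the query state.  Exclusivity of a site set is then the
    column-sum minimum over rows, which makes incremental scoring during
    sampling a vector add.
    """

    taxon: str
    query_ids: list[str]
    background_ids: list[str]
    eligible: np.ndarray
    qstate: list[str | None]
    weights: np.ndarray
    diff: np.ndarray
    _cache: dict[tuple[int, ...], int] = field(default_factory=dict)
    _diff_cols: list[list[int]] = field(default_factory=list)  # per-column, for sampling

    def __post_init__(self) -> None:
        if not self._diff_cols:
            self._diff_cols = self.diff.T.tolist()
        self._table: tuple[list[int], list[float], float] | None = None

    @property
    def n_background(self) -> int:
        return len(self.background_ids)

    def sampling_table(self) -> tuple[list[int], list[float], float]:
        """Positive-weight columns with their cumulative weight table."""
        if self._table is None:
            avail = np.flatnonzero(self.weights > 0).tolist()
            cum = np.cumsum(self.weights[avail]).tolist()
            self._table = (avail, cum, cum[-1] if cum else 0.0)
        return self._table

    def exclusivity(self, sites: Sequence[int]) -> int:
        """Exclusivity of a set of 0-based column indices."""
        key = tuple(sorted(sites))
        hit = self._cache.get(key)
        if hit is None:
            hit = int(self.diff[:, key].sum(axis=1).min()) if key else 0
            self._cache[key] = hit
        return hit


def taxon_context(
    aln: Alignment, taxon: str, params: SearchParams
) -> TaxonContext:
    query_ids = aln.members.get(taxon) or [
        i for i in aln.ids if aln.taxon_of.get(i) == taxon
    ]
    if not query_ids:
        raise DmcKitError(f"taxon {taxon!r} has no assigned sequences")
    background_ids = [i for i in aln.ids if aln.taxon_of.get(i, "") != taxon]
    if not background_ids:
        raise NoBackgroundError(f"no background sequences for {taxon!r}")
    eligible, qstate = site_eligibility(aln, taxon, params.gaps_new)
    bg = np.array([list(aln.seq_of(i)) for i in background_ids])
    missing = np.isin(bg, list(MISSING))
    if not params.gaps_new:
        missing |= bg == GAP
    qrow = np.array([s if s is not None else "." for s in qstate])
    neq = bg != qrow[np.newaxis, :]
    if params.missing_breaks:
        diff = (neq | missing).astype(np.int16)
    else:
        diff = (neq & ~missing).astype(np.int16)
    diff[:, ~eligible] = 0

    weights = np.zeros(aln.n_sites)
    informative = ~missing
    if params.weight_method == "seq_fraction":
        B = informative.sum(axis=0)
        d = ((bg != qrow[np.newaxis, :]) & informative).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(B > 0, d / np.maximum(B, 1), 0.0)
        weights[eligible] = w[eligible]
    else:  # state_jaccard: 1 - |Q ∩ Bg| / |Q ∪ Bg| over observed state sets
        for j in np.flatnonzero(eligible):
            q = {qstate[j]}
            bset = {bg[b, j] for b in range(bg.shape[0]) if informative[b, j]}
            union = q | bset
            weights[j] = 1.0 - len(q & bset) / len(union) if union else 0.0
    return TaxonContext(
        taxon=taxon,
        query_ids=query_ids,
        background_ids=background_ids,
        eligible=eligible,
        qstate=qstate,
        weights=weights,
        diff=diff,
    )


def site_weights(
    aln: Alignment, taxon: str, gaps_new: bool = False,
    weight_method: str = "seq_fraction",
) -> np.ndarray:
    """Per-column uniqueness weights in [0, 1]; 0 for ineligible columns."""
    params = SearchParams(gaps_new=gaps_new, weight_method=weight_method)
    return taxon_context(aln, taxon, params).weights


# ---------------------------------------------------------------------------
# Exclusivity
# ---------------------------------------------------------------------------


def exclusivity_score(
    dmc_sites: Sequence[tuple[int, str]],
    aln: Alignment,
    taxon: str,
    gaps_new: bool = False,
    missing_breaks: bool = False,
) -> int:
    """Minimum number of DMC sites at which any background sequence differs.

    Missing background states do not count as differing (conservative): a
    state we cannot observe cannot demonstrate a difference.  Pass
    ``missing_breaks=True`` for the lenient alternative.
    """
    background = [i for i in aln.ids if aln.taxon_of.get(i, "") != taxon]
    if not background:
        raise NoBackgroundError(f"no background sequences for {taxon!r}")
    if not dmc_sites:
        return 0
    for p, _ in dmc_sites:
        if not 1 <= p <= aln.n_sites:
            raise IndexError(f"DMC position {p} outside [1, {aln.n_sites}]")
    best = None
    for bid in background:
        seq = aln.seq_of(bid)
        d = 0
        for pos, state in dmc_sites:
            ch = seq[pos - 1]
            if _is_missing(ch, gaps_new):
                if missing_breaks:
                    d += 1
            elif ch != state:
                d += 1
        best = d if best is None else min(best, d)
        if best == 0:
            return 0
    return best


# ---------------------------------------------------------------------------
# Candidate sampling and refinement
# ---------------------------------------------------------------------------


def sample_candidate(
    ctx: TaxonContext, params: SearchParams, rng: random.Random
) -> tuple[tuple[int, ...], int] | None:
    """Draw one candidate DMC by weighted sampling without replacement.

    Sites join the candidate one at a time with probability proportional to
    their weight among the not-yet-drawn positive-weight columns.  Growth
    stops at the first length ≥ the effective minimum with exclusivity ≥
    ``exclusive``.  Returns ``(sorted 0-based columns, exclusivity)``, or
    ``None`` when the candidate reaches ``max_len`` (or exhausts the
    columns) without qualifying.
    """
    avail, cum, total = ctx.sampling_table()
    if not avail:
        raise DegenerateSearchError(f"no positive-weight column for {ctx.taxon!r}")
    cols = ctx._diff_cols
    n_bg = ctx.n_background
    n_avail = len(avail)
    chosen: set[int] = set()
    counts = [0] * n_bg
    eff = params.effective_min_len
    rnd = rng.random
    # drawing from the full table and rejecting already-drawn sites is
    # distribution-identical to renormalizing over the remaining sites
    while len(chosen) < n_avail:
        while True:
            k = bisect.bisect_right(cum, rnd() * total)
            if k >= n_avail:  # guard against fp round-up
                k = n_avail - 1
            j = avail[k]
            if j not in chosen:
                break
        chosen.add(j)
        col = cols[j]
        for b in range(n_bg):
            counts[b] += col[b]
        if len(chosen) >= eff:
            excl = min(counts)
            if excl >= params.exclusive:
                key = tuple(sorted(chosen))
                ctx._cache.setdefault(key, excl)
                return key, excl
        if len(chosen) >= params.max_len:
            return None
    return None


def refine_dmc(
    sites: Sequence[int],
    ctx: TaxonContext,
    params: SearchParams,
    rng: random.Random,
) -> dict[tuple[int, ...], int]:
    """Search sub-combinations of a qualifying candidate for shorter DMCs.

    The refinement strength controls how intensively sub-combinations are
    tested: 0 skips refinement entirely.  For small candidates (2^L ≤ 4096)
    every proper subset of allowed size is enumerated outright; larger
    candidates get ``max(1, round(ref_strength × L))`` randomized
    backward-elimination passes.  Returns the distinct qualifying reductions
    with their exclusivity scores.
    """
    if params.ref_strength <= 0:
        return {}
    sites = tuple(sorted(sites))
    L = len(sites)
    eff = params.effective_min_len
    found: dict[tuple[int, ...], int] = {}
    if 2**L <= 4096:
        for size in range(eff, L):
            for comb in itertools.combinations(sites, size):
                e = ctx.exclusivity(comb)
                if e >= params.exclusive:
                    found[comb] = e
        return found
    n_passes = max(1, round(params.ref_strength * L))
    for _ in range(n_passes):
        order = list(range(L))
        rng.shuffle(order)
        current = list(sites)
        for idx in order:
            site = sites[idx]
            if site not in current or len(current) - 1 < eff:
                continue
            trial = tuple(s for s in current if s != site)
            if ctx.exclusivity(trial) >= params.exclusive:
                current = list(trial)
        if len(current) < L:
            key = tuple(current)
            found[key] = ctx.exclusivity(key)
    return found


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def _rank_key(item: tuple[tuple[int, ...], int]):
    sites, excl = item
    return (-excl, len(sites), sites)


def consensus_dmc(
    pool: dict[tuple[int, ...], int],
    ctx: TaxonContext,
    params: SearchParams,
) -> tuple[tuple[tuple[int, ...], int], tuple[tuple[int, ...], int], int, bool] | None:
    """Build the majority-consensus and alternative DMC from a candidate pool.

    Candidates are ranked by exclusivity (descending), then length
    (ascending), then lexicographic site order; the ``top_k`` best form the
    optimal subset.  The consensus starts from sites present in at least
    ``majority_threshold`` of the optimal subset and greedily adds
    next-most-frequent sites (ties: lower column first) until it qualifies.
    If it never qualifies, the rank-1 candidate is the consensus (fallback).
    The alternative is the best-ranked candidate distinct from the
    consensus.

    Returns ``((consensus_sites, excl), (alternative_sites, excl),
    n_optimal, fallback)`` or ``None`` for an empty pool.
    """
    if not pool:
        return None
    ranked = sorted(pool.items(), key=_rank_key)
    top = ranked[: params.top_k]
    n_optimal = len(top)
    freq: dict[int, float] = {}
    for sites, _ in top:
        for s in sites:
            freq[s] = freq.get(s, 0.0) + 1.0
    for s in freq:
        freq[s] /= n_optimal
    by_freq = sorted(freq, key=lambda s: (-freq[s], s))
    eff = params.effective_min_len

    consensus = sorted(s for s in freq if freq[s] >= params.majority_threshold)
    fallback = False

    def qualifies(sites: Sequence[int]) -> bool:
        return len(sites) >= eff and ctx.exclusivity(sites) >= params.exclusive

    if not qualifies(consensus):
        for s in by_freq:
            if s in consensus:
                continue
            consensus = sorted(consensus + [s])
            if qualifies(consensus):
                break
        else:
            consensus = list(ranked[0][0])
            fallback = True
    cons_key = tuple(consensus)
    cons = (cons_key, ctx.exclusivity(cons_key))
    alt = next((item for item in ranked if item[0] != cons_key), ranked[0])
    return cons, alt, n_optimal, fallback


# ---------------------------------------------------------------------------
# Full search
# ---------------------------------------------------------------------------


def _taxon_rng(seed: int, taxon: str) -> random.Random:
    # stable per-taxon stream: adding a query never shifts another's results
    return random.Random((seed & 0x7FFFFFFF) * 0x1_0000_0000 + zlib.crc32(taxon.encode()))


def _to_dmc(
    sites_excl: tuple[tuple[int, ...], int],
    ctx: TaxonContext,
    kind: str,
    reference_id: str,
) -> DMC:
    sites, excl = sites_excl
    pairs = tuple((j + 1, ctx.qstate[j]) for j in sites)
    return DMC(
        taxon=ctx.taxon,
        sites=pairs,
        exclusivity=excl,
        kind=kind,
        reference_id=reference_id,
    )


def find_dmcs(
    aln: Alignment, queries: QueryList, params: SearchParams
) -> DMCTable:
    """Run the full DMC search for every query taxon.

    The returned table has one row per query, in query order.  Queries with
    no assigned sequences get status ``no_query_sequences``; queries for
    which no qualifying combination is found get ``no_dmc_found``.  Both
    reported DMCs are re-verified against the alignment (length and
    exclusivity) before the row is emitted.
    """
    if not aln.taxon_of:
        aln = assign_taxa(aln, queries)
    rows: list[DMCRow] = []
    for taxon in queries:
        members = aln.members.get(taxon) or [
            i for i in aln.ids if aln.taxon_of.get(i) == taxon
        ]
        if not members:
            rows.append(
                DMCRow(
                    taxon=taxon,
                    consensus=None,
                    alternative=None,
                    n_optimal_candidates=0,
                    status="no_query_sequences",
                )
            )
            continue
        ctx = taxon_context(aln, taxon, params)
        rng = _taxon_rng(params.seed, taxon)
        pool: dict[tuple[int, ...], int] = {}
        if np.any(ctx.weights > 0):
            for _ in range(params.n_iter):
                cand = sample_candidate(ctx, params, rng)
                if cand is not None:
                    pool.setdefault(cand[0], cand[1])
            # refinement targets the optimal (retained) candidates only
            optimal = sorted(pool.items(), key=_rank_key)[: params.top_k]
            for sites, _ in optimal:
                pool.update(refine_dmc(sites, ctx, params, rng))
        result = consensus_dmc(pool, ctx, params)
        if result is None:
            rows.append(
                DMCRow(
                    taxon=taxon,
                    consensus=None,
                    alternative=None,
                    n_optimal_candidates=0,
                    status="no_dmc_found",
                )
            )
            continue
        cons, alt, n_optimal, _fallback = result
        reference_id = members[0]
        cons_dmc = _to_dmc(cons, ctx, "consensus", reference_id)
        alt_dmc = _to_dmc(alt, ctx, "alternative", reference_id)
        for d in (cons_dmc, alt_dmc):
            recheck = exclusivity_score(
                d.sites, aln, taxon,
                gaps_new=params.gaps_new, missing_breaks=params.missing_breaks,
            )
            if len(d) < params.effective_min_len or recheck < params.exclusive:
                raise DmcKitError(
                    f"internal error: {d.kind} DMC for {taxon!r} fails re-verification"
                )
            if recheck != d.exclusivity:
                raise DmcKitError(
                    f"internal error: exclusivity mismatch for {taxon!r}"
                )
        rows.append(
            DMCRow(
                taxon=taxon,
                consensus=cons_dmc,
                alternative=alt_dmc,
                n_optimal_candidates=n_optimal,
                status="ok",
            )
        )
    return DMCTable(rows=tuple(rows))
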