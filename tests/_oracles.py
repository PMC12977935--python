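"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: exclusivity is
recounted with vectorized numpy set operations over the raw residue
matrix, minimal qualifying DMC length is found by exhaustive combination
enumeration, and the sliding-window optimum by a naive full scan.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING_ALWAYS = {"N", "?"}


def _matrix(aln):
    return np.array([list(s) for s in aln.seqs])


def brute_exclusivity(sites, aln, taxon, gaps_new=False, missing_breaks=False):
    """Recount exclusivity: min over background rows of differing sites."""
    mat = _matrix(aln)
    bg_rows = [k for k, rid in enumerate(aln.ids) if aln.taxon_of.get(rid, "") != taxon]
    assert bg_rows, "oracle needs background sequences"
    if not sites:
        return 0
    cols = np.array([p - 1 for p, _ in sites])
    states = np.array([s for _, s in sites])
    sub = mat[np.ix_(bg_rows, cols)]
    missing = np.isin(sub, sorted(MISSING_ALWAYS))
    if not gaps_new:
        missing |= sub == "-"
    differs = (sub != states[np.newaxis, :]) & ~missing
    if missing_breaks:
        differs = differs | missing
    return int(differs.sum(axis=1).min())


def eligible_sites_with_states(aln, taxon, gaps_new=False):
    """(0-based column, state) pairs usable in a DMC for this taxon."""
    mat = _matrix(aln)
    q_rows = [k for k, rid in enumerate(aln.ids) if aln.taxon_of.get(rid) == taxon]
    out = []
    for j in range(mat.shape[1]):
        vals = set(mat[q_rows, j])
        vals -= MISSING_ALWAYS
        if not gaps_new:
            vals -= {"-"}
        if len(vals) == 1:
            (s,) = vals
            if s in "ACGT":
                out.append((j, s))
    return out


def brute_min_qualifying_length(aln, taxon, exclusive, max_k, gaps_new=False):
    """Smallest combination size (≤ max_k) reaching the exclusivity bar.

    Returns None when no combination of eligible sites up to max_k
    qualifies.  Enumeration is exhaustive over the eligible sites.
    """
    elig = eligible_sites_with_states(aln, taxon, gaps_new)
    for k in range(1, max_k + 1):
        for comb in itertools.combinations(elig, k):
            sites = [(j + 1, s) for j, s in comb]
            if brute_exclusivity(sites, aln, taxon, gaps_new) >= exclusive:
                return k
    return None


def brute_best_window(dmc_states, deltas, test_seq, ambiguity=None):
    """Naive full scan: (best n_mismatch, 1-based start) or None if too short."""
    span = deltas[-1] + 1
    if len(test_seq) < span:
        return None
    best = None
    for s in range(len(test_seq) - span + 1):
        mism = 0
        for d, state in zip(deltas, dmc_states):
            ch = test_seq[s + d]
            if ch in MISSING_ALWAYS or ch == "-":
                continue
            ok = ch == state or (ambiguity and state in ambiguity.get(ch, set()))
            if not ok:
                mism += 1
        if best is None or mism < best[0]:
            best = (mism, s + 1)
    return best
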