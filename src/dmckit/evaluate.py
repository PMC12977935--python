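"""Confusion matrices and classification metrics for DMC cross-validation.

Each DMC is scored against test sequences with known labels.  A test
sequence with any undetermined state at a DMC's sites is excluded from that
DMC's matrix (it can neither confirm nor refute the diagnosis); exclusion
is per-DMC, so the same sequence may be excluded for one species and
counted for another.  Among the rest: a conspecific match is a true
positive, a conspecific non-match a false negative, a heterospecific match
a false positive and a heterospecific non-match a true negative.

Derived metrics::

    recall      = TP / (TP + FN)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    accuracy    = (recall + specificity) / 2        # balanced, NOT (TP+TN)/n
    f1          = 2 * precision * recall / (precision + recall)

Note the accuracy here is the *balanced* form — the mean of recall and
specificity — not the conventional (TP+TN)/total.  Undefined metrics (e.g.
recall without any conspecific test sequence) are reported as NA, never as
0.  For a taxon with no conspecific test sequences only specificity is
meaningful, and only it is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .seqio import BACKGROUND, DMC, Alignment, DmcKitError, QueryList, assign_taxa
from .identify import MatchReport

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "TruthMismatchError",
    "classification_metrics",
    "confusion_counts",
    "dmc_state_matrix",
    "evaluate_dmcs",
    "truth_from_ids",
    "write_metrics_table",
]


class TruthMismatchError(DmcKitError):
    """Report sequence ids missing from the truth mapping."""


@dataclass(frozen=True)
class ConfusionCounts:
    taxon: str
    TP: int
    FP: int
    TN: int
    FN: int
    n_excluded: int
    has_conspecifics: bool

    @property
    def n_total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN + self.n_excluded


@dataclass(frozen=True)
class Metrics:
    """Classification metrics; ``None`` means undefined (serialized as NA)."""

    recall: float | None
    precision: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None


def truth_from_ids(ids, queries: QueryList) -> dict[str, str]:
    """Derive truth labels from sequence ids by the training id convention."""
    ids = list(ids)
    dummy = Alignment(ids=ids, seqs=["A"] * len(ids))
    return assign_taxa(dummy, queries).taxon_of


def confusion_counts(
    report: MatchReport, truth: Mapping[str, str]
) -> dict[str, ConfusionCounts]:
    """Per-taxon confusion counts with the missing-data exclusion rule."""
    orphans = sorted({o.sequence_id for o in report} - set(truth))
    if orphans:
        raise TruthMismatchError(
            f"{len(orphans)} report ids missing from truth: {orphans[:10]}"
        )
    taxa: dict[str, list] = {}
    for o in report:
        taxa.setdefault(o.taxon, []).append(o)
    out: dict[str, ConfusionCounts] = {}
    for taxon, outcomes in taxa.items():
        tp = fp = tn = fn = excluded = 0
        has_cons = any(truth[o.sequence_id] == taxon for o in outcomes)
        for o in outcomes:
            if o.n_missing > 0:
                excluded += 1
                continue
            conspecific = truth[o.sequence_id] == taxon
            if conspecific:
                tp += o.matched
                fn += not o.matched
            else:
                fp += o.matched
                tn += not o.matched
        out[taxon] = ConfusionCounts(
            taxon=taxon,
            TP=tp,
            FP=fp,
            TN=tn,
            FN=fn,
            n_excluded=excluded,
            has_conspecifics=has_cons,
        )
    return out


def classification_metrics(c: ConfusionCounts) -> Metrics:
    """Compute the five metrics, leaving impossible ones undefined.

    When the taxon has no conspecific test sequences at all, only
    specificity is reported.
    """
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    specificity = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    if not c.has_conspecifics:
        return Metrics(None, None, specificity, None, None)
    accuracy = (
        (recall + specificity) / 2
        if recall is not None and specificity is not None
        else None
    )
    f1 = None
    if recall is not None and precision is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(recall, precision, specificity, accuracy, f1)


_METRIC_COLUMNS = [
    "taxon", "TP", "FP", "TN", "FN", "n_excluded",
    "recall", "precision", "specificity", "accuracy", "f1",
    "has_conspecifics",
]


def evaluate_dmcs(report: MatchReport, truth: Mapping[str, str]) -> pd.DataFrame:
    """One row per DMC taxon: counts plus the five metrics."""
    counts = confusion_counts(report, truth)
    rows = []
    for taxon, c in counts.items():
        m = classification_metrics(c)
        rows.append(
            {
                "taxon": taxon,
                "TP": c.TP,
                "FP": c.FP,
                "TN": c.TN,
                "FN": c.FN,
                "n_excluded": c.n_excluded,
                "recall": m.recall,
                "precision": m.precision,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "f1": m.f1,
                "has_conspecifics": c.has_conspecifics,
            }
        )
    return pd.DataFrame(rows, columns=_METRIC_COLUMNS)


def write_metrics_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="NA")


def dmc_state_matrix(aln: Alignment, dmc: DMC) -> pd.DataFrame:
    """Per-taxon character states at a DMC's positions.

    Rows are the query taxon, every other taxon present in the alignment,
    and the designated reference sequence; columns are the DMC positions.
    A cell holds the fixed state of that taxon at that column, or a set
    like ``{A,G}`` when the taxon is polymorphic there (``?`` if all states
    are undetermined).
    """
    for p in dmc.positions:
        if not 1 <= p <= aln.n_sites:
            raise IndexError(f"DMC position {p} outside [1, {aln.n_sites}]")
    groups: dict[str, list[str]] = {}
    for rid in aln.ids:
        groups.setdefault(aln.taxon_of.get(rid, BACKGROUND), []).append(rid)
    order = [dmc.taxon] + [t for t in groups if t != dmc.taxon]

    def summarize(ids: list[str], pos: int) -> str:
        states = sorted(
            {aln.seq_of(i)[pos - 1] for i in ids}
            - {"N", "?"}
        )
        if not states:
            return "?"
        if len(states) == 1:
            return states[0]
        return "{" + ",".join(states) + "}"

    data = {
        taxon: [summarize(groups[taxon], p) for p in dmc.positions]
        for taxon in order
        if taxon in groups
    }
    if dmc.reference_id and dmc.reference_id in aln.ids:
        ref = aln.seq_of(dmc.reference_id)
        data[f"reference:{dmc.reference_id}"] = [ref[p - 1] for p in dmc.positions]
    return pd.DataFrame(data, index=list(dmc.positions)).T
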