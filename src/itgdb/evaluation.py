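"""Per-rank scoring of taxonomic assignments, synonym-aware.

Classifier predictions are compared with a truth set rank by rank.  A
prediction at a rank is correct when it names the truth taxon or any
synonym of it (NCBI names-dump groups), which neutralises the naming-
convention drift between reference databases.  Accuracy is the micro
fraction of correct reads; precision, recall and F1 are tallied per truth
class on a one-vs-rest confusion and averaged (macro by default,
``weighted`` and ``micro`` available).  True negatives are never tallied:
per-class TN inflates trivially with class count, and under micro
accounting accuracy already reduces to correct/total.

The module also computes assignment depth: the percentage of reads a
classifier labels at each rank, with and without a confidence threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import RANKS, AssignmentResult, Lineage, SynonymMap, canonical_name

logger = logging.getLogger(__name__)

#: Ranks scored by default, phylum through species.
DEFAULT_EVAL_RANKS: Tuple[str, ...] = RANKS[1:]

#: Ranks reported by default in depth tables.
DEFAULT_DEPTH_RANKS: Tuple[str, ...] = ("family", "genus", "species")

AVERAGING_MODES = ("macro", "weighted", "micro")


def names_match(a: str, b: str, synonyms: Optional[SynonymMap] = None) -> bool:
    """True iff two taxon names agree after canonicalisation, or are synonyms.

    Canonicalisation unifies underscores with spaces and case-folds, so
    ``Escherichia_coli`` matches ``Escherichia coli`` without any map.
    Empty names never match anything.
    """
    if not a or not b:
        return False
    if canonical_name(a) == canonical_name(b):
        return True
    return synonyms is not None and synonyms.same_group(a, b)


@dataclass
class RankMetrics:
    """Confusion counts and percentage metrics for one taxonomic rank."""

    rank: str
    n_evaluated: int
    n_correct: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    average: str = "macro"
    per_class: Dict[str, Tuple[int, int, int]] = field(default_factory=dict)  # class -> (TP, FP, FN)


def _representative(name: str, synonyms: Optional[SynonymMap]) -> str:
    if synonyms is not None:
        rep = synonyms.representative(name)
        if rep is not None:
            return canonical_name(rep)
    return canonical_name(name)


def _prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def score_rank(assignments: Iterable[AssignmentResult], truth: Mapping[str, Lineage],
               rank: str, synonyms: Optional[SynonymMap] = None,
               average: str = "macro", missing_ok: bool = False) -> RankMetrics:
    """Score predictions at one rank against the truth set.

    Correctness per read is synonym-aware name matching; an empty
    prediction is incorrect.  Per-class TP/FP/FN are tallied over the
    classes present in the truth set after mapping synonyms to one
    representative.  Predictions for reads absent from the truth set are
    ignored (logged); truth reads absent from the predictions are an error
    unless ``missing_ok``, in which case they count as unassigned.
    """
    if average not in AVERAGING_MODES:
        raise ValueError(f"unknown averaging mode {average!r}; expected one of {AVERAGING_MODES}")
    slot = RANKS.index(rank)
    pred_by_id: Dict[str, AssignmentResult] = {}
    n_foreign = 0
    for res in assignments:
        if res.seq_id in pred_by_id:
            raise ValueError(f"duplicate seq_id {res.seq_id!r} in assignments")
        if res.seq_id not in truth:
            n_foreign += 1
            continue
        pred_by_id[res.seq_id] = res
    if n_foreign:
        logger.info("ignored %d predictions for reads outside the truth set", n_foreign)
    missing = [sid for sid in truth if sid not in pred_by_id]
    if missing and not missing_ok:
        raise ValueError(
            f"{len(missing)} truth ids missing from assignments (e.g. {missing[:5]}); "
            "pass missing_ok=True to count them as unassigned"
        )

    truth_classes = {
        _representative(lin.ranks[slot], synonyms)
        for lin in truth.values() if lin.ranks[slot]
    }
    tp: Dict[str, int] = {c: 0 for c in truth_classes}
    fp: Dict[str, int] = {c: 0 for c in truth_classes}
    fn: Dict[str, int] = {c: 0 for c in truth_classes}
    class_weight: Dict[str, int] = {c: 0 for c in truth_classes}

    n_evaluated = 0
    n_correct = 0
    for sid, true_lin in truth.items():
        true_name = true_lin.ranks[slot]
        if not true_name:
            continue
        n_evaluated += 1
        true_rep = _representative(true_name, synonyms)
        class_weight[true_rep] += 1
        res = pred_by_id.get(sid)
        pred_name = res.predicted.ranks[slot] if res is not None else ""
        if pred_name and names_match(pred_name, true_name, synonyms):
            n_correct += 1
            tp[true_rep] += 1
        else:
            fn[true_rep] += 1
            if pred_name:
                pred_rep = _representative(pred_name, synonyms)
                if pred_rep in truth_classes:
                    fp[pred_rep] += 1

    accuracy = 100.0 * n_correct / n_evaluated if n_evaluated else 0.0
    classes = sorted(truth_classes)
    if average == "micro":
        stp = sum(tp.values())
        precision, recall, f1 = _prf(stp, sum(fp.values()), sum(fn.values()))
    else:
        per = [_prf(tp[c], fp[c], fn[c]) for c in classes]
        if not per:
            precision = recall = f1 = 0.0
        elif average == "macro":
            precision = sum(p for p, _, _ in per) / len(per)
            recall = sum(r for _, r, _ in per) / len(per)
            f1 = sum(f for _, _, f in per) / len(per)
        else:  # weighted by truth support
            total = sum(class_weight.values())
            precision = sum(p * class_weight[c] for (p, _, _), c in zip(per, classes)) / total
            recall = sum(r * class_weight[c] for (_, r, _), c in zip(per, classes)) / total
            f1 = sum(f * class_weight[c] for (_, _, f), c in zip(per, classes)) / total
    return RankMetrics(
        rank=rank,
        n_evaluated=n_evaluated,
        n_correct=n_correct,
        accuracy=accuracy,
        precision=100.0 * precision,
        recall=100.0 * recall,
        f1=100.0 * f1,
        average=average,
        per_class={c: (tp[c], fp[c], fn[c]) for c in classes},
    )


def evaluate_all(assignments: Sequence[AssignmentResult], truth: Mapping[str, Lineage],
                 ranks: Sequence[str] = DEFAULT_EVAL_RANKS,
                 synonyms: Optional[SynonymMap] = None,
                 average: str = "macro", missing_ok: bool = False) -> List[RankMetrics]:
    """Score every requested rank; ranks with no truth names are omitted."""
    out: List[RankMetrics] = []
    for rank in ranks:
        slot = RANKS.index(rank)
        if not any(lin.ranks[slot] for lin in truth.values()):
            logger.warning("rank %s has no truth names; metrics omitted", rank)
            continue
        out.append(score_rank(assignments, truth, rank, synonyms=synonyms,
                              average=average, missing_ok=missing_ok))
    return out


def metrics_table(metrics: Sequence[RankMetrics]) -> pd.DataFrame:
    """Tabulate RankMetrics for reporting (percentages, two decimals worth)."""
    return pd.DataFrame(
        [
            (m.rank, m.n_evaluated, m.accuracy, m.precision, m.recall, m.f1)
            for m in metrics
        ],
        columns=["rank", "n_evaluated", "accuracy", "precision", "recall", "f1"],
    )


@dataclass
class DepthTable:
    """Percentage of reads assigned per rank, without / with a threshold."""

    ranks: Tuple[str, ...]
    no_threshold: Dict[str, float]
    with_threshold: Optional[Dict[str, float]] = None
    threshold: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = {"no_threshold": [self.no_threshold[r] for r in self.ranks]}
        if self.with_threshold is not None:
            rows[f"threshold_{self.threshold:g}"] = [self.with_threshold[r] for r in self.ranks]
        return pd.DataFrame(rows, index=list(self.ranks)).T


def assignment_depth(assignments: Sequence[AssignmentResult],
                     threshold: Optional[float] = None,
                     ranks: Sequence[str] = DEFAULT_DEPTH_RANKS) -> DepthTable:
    """Fraction of reads labelled at each rank, optionally confidence-gated.

    A read counts as assigned at a rank when its prediction there is
    non-empty and, if a threshold is given, its confidence at that rank is
    at least the threshold.  Requesting a threshold when any read carries
    no confidences is an error.
    """
    assignments = list(assignments)
    n = len(assignments)
    if threshold is not None:
        lacking = [a.seq_id for a in assignments if a.confidences is None]
        if lacking:
            raise ValueError(
                f"threshold given but {len(lacking)} assignments carry no "
                f"confidences (e.g. {lacking[:5]})"
            )
    slots = [RANKS.index(r) for r in ranks]

    def pct(gated: bool) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for rank, slot in zip(ranks, slots):
            count = 0
            for a in assignments:
                name = a.predicted.ranks[slot]
                if not name:
                    continue
                if gated:
                    conf = a.confidences[slot]
                    if conf is None or conf < threshold:
                        continue
                count += 1
            out[rank] = 100.0 * count / n if n else 0.0
        return out

    return DepthTable(
        ranks=tuple(ranks),
        no_threshold=pct(False),
        with_threshold=pct(True) if threshold is not None else None,
        threshold=threshold,
    )
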