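"""Database integration: merging a candidate reference into a basis reference.

Two merge semantics are provided.  *Sequence-based* integration compares
nucleotide composition only: a candidate sequence that contains a basis
sequence as an exact substring replaces it; a candidate already contained
in the basis is skipped; anything else is added.  *Taxonomy-based*
integration compares canonical taxonomy strings first and adds a candidate
when its lineage is new, or when its sequence differs from every basis
sequence under the identical lineage; the basis never shrinks.

Both modes process candidates in input order against the evolving merged
set, so a chain of containments resolves to the longest sequence seen.
``build_itgdb`` folds an ordered list of sources (classically RDP, then
SILVA, then Greengenes) through either mode.

The sequence mode is backed by a k-mer anchor index so large databases do
not pay the all-pairs substring cost, but its semantics are exactly those
of the naive all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .curation import assert_curated
from .model import Lineage, ReferenceDB, SequenceRecord

ACTION_ADDED = "added"
ACTION_REPLACED = "replaced"
ACTION_SKIPPED = "skipped"


@dataclass
class IntegrationLog:
    """One decision per candidate: added, replaced (with victims), or skipped."""

    n_basis: int
    n_candidate: int
    n_added: int = 0
    n_replaced: int = 0
    n_skipped: int = 0
    decisions: List[Tuple[str, str, Tuple[str, ...]]] = field(default_factory=list)

    def record(self, candidate_id: str, action: str, matched: Sequence[str] = ()) -> None:
        self.decisions.append((candidate_id, action, tuple(matched)))
        if action == ACTION_ADDED:
            self.n_added += 1
        elif action == ACTION_REPLACED:
            self.n_replaced += 1
        elif action == ACTION_SKIPPED:
            self.n_skipped += 1
        else:
            raise ValueError(f"unknown action {action!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(cid, action, ",".join(matched)) for cid, action, matched in self.decisions],
            columns=["candidate_id", "action", "matched_basis_ids"],
        )


def contains(a: str, b: str) -> bool:
    """True iff ``b`` occurs as an exact contiguous substring of ``a``.

    Equality counts as containment.  No reverse-complement search; IUPAC
    degenerate codes are compared literally, so a single nucleotide
    difference means no containment.
    """
    return b in a


class _ContainmentIndex:
    """k-mer anchor index over a mutable set of sequences.

    Supports the two queries sequence-based integration needs: which
    indexed sequences are substrings of a query, and which indexed
    sequences contain the query.  Sequences shorter than the anchor size
    fall back to a linear scan over a (typically tiny) side list.
    """

    def __init__(self, k: int = 12) -> None:
        self.k = k
        self._seqs: Dict[str, str] = {}
        self._order: Dict[str, int] = {}
        self._counter = 0
        self._prefix: Dict[str, Set[str]] = {}   # seq[:k] -> ids
        self._kmers: Dict[str, Set[str]] = {}    # every k-window -> ids
        self._short: Set[str] = set()            # ids with len(seq) < k

    def add(self, seq_id: str, seq: str) -> None:
        self._seqs[seq_id] = seq
        self._order[seq_id] = self._counter
        self._counter += 1
        if len(seq) < self.k:
            self._short.add(seq_id)
            return
        self._prefix.setdefault(seq[: self.k], set()).add(seq_id)
        for i in range(len(seq) - self.k + 1):
            self._kmers.setdefault(seq[i : i + self.k], set()).add(seq_id)

    def remove(self, seq_id: str) -> None:
        seq = self._seqs.pop(seq_id)
        self._order.pop(seq_id)
        if len(seq) < self.k:
            self._short.discard(seq_id)
            return
        bucket = self._prefix.get(seq[: self.k])
        if bucket:
            bucket.discard(seq_id)
        for i in range(len(seq) - self.k + 1):
            bucket = self._kmers.get(seq[i : i + self.k])
            if bucket:
                bucket.discard(seq_id)

    def _sorted(self, ids: Set[str]) -> List[str]:
        return sorted(ids, key=self._order.__getitem__)

    def contained_in(self, query: str) -> List[str]:
        """Ids whose sequence is a substring of ``query``, in insertion order."""
        hits: Set[str] = set()
        k = self.k
        for i in range(max(len(query) - k + 1, 0)):
            for cand in self._prefix.get(query[i : i + k], ()):
                if cand not in hits and query.startswith(self._seqs[cand], i):
                    hits.add(cand)
        for cand in self._short:
            if self._seqs[cand] in query:
                hits.add(cand)
        return self._sorted(hits)

    def containing(self, query: str) -> List[str]:
        """Ids whose sequence contains ``query``, in insertion order."""
        if len(query) >= self.k:
            pool = self._kmers.get(query[: self.k], set())
        else:
            pool = set(self._seqs)
        hits = {cand for cand in pool if query in self._seqs[cand]}
        return self._sorted(hits)


def integrate_sequence_based(basis: ReferenceDB, candidate: ReferenceDB,
                             k: int = 12) -> Tuple[ReferenceDB, IntegrationLog]:
    """Merge by nucleotide containment; taxonomy quality is not considered.

    For each candidate sequence in input order: if it contains one or more
    sequences of the working set, all of them are removed and the candidate
    inserted once (``replaced``); else if some working sequence contains
    it, it is ``skipped``; otherwise it is ``added``.  Replacing inserts the
    candidate's own lineage.  The working set starts as the basis and
    evolves as candidates land, so later candidates see earlier ones.
    """
    log = IntegrationLog(n_basis=len(basis), n_candidate=len(candidate))
    merged = basis.copy()
    index = _ContainmentIndex(k=k)
    for rec, _ in merged:
        index.add(rec.id, rec.seq)
    for rec, lin in candidate:
        if rec.id in merged:
            raise ValueError(
                f"candidate id {rec.id!r} collides with an existing entry; "
                "prefix ids (see build_itgdb) before integrating"
            )
        victims = index.contained_in(rec.seq)
        if victims:
            for victim in victims:
                merged.remove(victim)
                index.remove(victim)
            merged.add(rec, lin)
            index.add(rec.id, rec.seq)
            log.record(rec.id, ACTION_REPLACED, victims)
            continue
        holders = index.containing(rec.seq)
        if holders:
            log.record(rec.id, ACTION_SKIPPED, holders)
            continue
        merged.add(rec, lin)
        index.add(rec.id, rec.seq)
        log.record(rec.id, ACTION_ADDED)
    return merged, log


def integrate_taxonomy_based(basis: ReferenceDB, candidate: ReferenceDB) -> Tuple[ReferenceDB, IntegrationLog]:
    """Merge by taxonomy-string lookup, then per-taxon sequence comparison.

    Requires curated inputs (every lineage resolved to an exact species).
    A candidate whose canonical lineage is absent from the working set is
    added; one whose lineage exists is added only if its sequence differs
    from every working sequence under that identical lineage, else skipped.
    Basis entries are never removed.
    """
    assert_curated(basis, context="taxonomy-based integration (basis)")
    assert_curated(candidate, context="taxonomy-based integration (candidate)")
    log = IntegrationLog(n_basis=len(basis), n_candidate=len(candidate))
    merged = basis.copy()
    by_lineage: Dict[Tuple[str, ...], List[Tuple[str, str]]] = {}
    for rec, lin in merged:
        by_lineage.setdefault(lin.ranks, []).append((rec.id, rec.seq))
    for rec, lin in candidate:
        if rec.id in merged:
            raise ValueError(
                f"candidate id {rec.id!r} collides with an existing entry; "
                "prefix ids (see build_itgdb) before integrating"
            )
        pool = by_lineage.get(lin.ranks)
        if pool is None:
            merged.add(rec, lin)
            by_lineage[lin.ranks] = [(rec.id, rec.seq)]
            log.record(rec.id, ACTION_ADDED)
            continue
        same = [pid for pid, pseq in pool if pseq == rec.seq]
        if same:
            log.record(rec.id, ACTION_SKIPPED, same)
            continue
        merged.add(rec, lin)
        pool.append((rec.id, rec.seq))
        log.record(rec.id, ACTION_ADDED)
    return merged, log


def build_itgdb(sources: Sequence[ReferenceDB], mode: str,
                names: Optional[Sequence[str]] = None,
                k: int = 12) -> Tuple[ReferenceDB, List[IntegrationLog]]:
    """Fold an ordered list of sources into one integrated database.

    ``sources[0]`` is the initial basis; each following source is merged
    in turn (the classic order being RDP, SILVA, Greengenes), yielding one
    log per round.  Ids are prefixed with the source name (``name|id``) so
    identical ids in different sources cannot collide.
    """
    if len(sources) < 2:
        raise ValueError("integration needs at least two source databases")
    if mode not in ("sequence", "taxonomy"):
        raise ValueError(f"unknown mode {mode!r}; expected 'sequence' or 'taxonomy'")
    if names is None:
        names = [f"src{i}" for i in range(len(sources))]
    if len(names) != len(sources):
        raise ValueError("names and sources must have equal length")
    if len(set(names)) != len(names):
        raise ValueError("source names must be unique")
    prefixed = [db.with_prefixed_ids(name) for db, name in zip(sources, names)]
    merged = prefixed[0]
    logs: List[IntegrationLog] = []
    for nxt in prefixed[1:]:
        if mode == "sequence":
            merged, log = integrate_sequence_based(merged, nxt, k=k)
        else:
            merged, log = integrate_taxonomy_based(merged, nxt)
        logs.append(log)
    return merged, logs
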