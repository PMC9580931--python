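"""Core domain types for 16S rRNA reference-database curation and integration.

A reference database pairs nucleotide sequences with seven-rank taxonomic
lineages (kingdom through species).  Every higher-level operation in this
package -- curation, sequence- or taxonomy-based merging, benchmark-set
construction, per-rank scoring -- is defined over these types rather than
over raw files; the :mod:`itgdb.io` module handles the dialect zoo.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

#: Taxonomic ranks, in order, used throughout the package.
RANKS: Tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
N_RANKS = len(RANKS)

#: Source-database tags a record may carry.
SOURCES = ("rdp", "silva", "greengenes", "other")

#: Taxonomy-string dialects understood by :func:`itgdb.io.parse_lineage`.
DIALECTS = ("rdp", "silva", "greengenes", "qiime2", "sintax")

#: IUPAC nucleotide codes: the four canonical bases plus degenerate codes.
#: Degenerate codes are retained verbatim in normalised sequences.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

_GAP_CHARS = ".-~"
_WS_RE = re.compile(r"\s+")


def normalize_sequence(raw: str) -> str:
    """Normalise a nucleotide string to the package's canonical alphabet.

    Uppercases, converts RNA ``U`` to ``T``, and strips gap characters
    (``.``, ``-``, ``~``) and whitespace.  IUPAC degenerate codes pass
    through unchanged.  Raises ``ValueError`` on an empty result or on
    characters outside the IUPAC alphabet.
    """
    seq = _WS_RE.sub("", raw).upper().replace("U", "T")
    for ch in _GAP_CHARS:
        seq = seq.replace(ch, "")
    if not seq:
        raise ValueError("sequence empty after normalization")
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One reference read: identifier, normalised sequence, source tag."""

    id: str
    seq: str
    source: str = "other"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source tag {self.source!r}; expected one of {SOURCES}")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    @classmethod
    def from_raw(cls, id: str, raw_seq: str, source: str = "other") -> "SequenceRecord":
        """Build a record from an un-normalised sequence string."""
        try:
            seq = normalize_sequence(raw_seq)
        except ValueError as exc:
            raise ValueError(f"record {id!r}: {exc}") from exc
        return cls(id=id, seq=seq, source=source)


@dataclass(frozen=True)
class Lineage:
    """Seven-rank taxonomy (kingdom..species) with canonicalised names.

    ``ranks`` always has exactly seven slots; missing ranks are empty
    strings.  Names are canonical: dialect prefixes (``k__``, ``d:``)
    stripped, internal whitespace replaced by underscores.  The original
    string and its dialect are retained for provenance but excluded from
    equality -- two lineages are equal iff their seven rank names are.
    """

    ranks: Tuple[str, ...]
    raw: str = field(default="", compare=False)
    dialect: str = field(default="rdp", compare=False)

    def __post_init__(self) -> None:
        if len(self.ranks) != N_RANKS:
            raise ValueError(f"lineage must have {N_RANKS} rank slots, got {len(self.ranks)}")

    @property
    def kingdom(self) -> str:
        return self.ranks[0]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species(self) -> str:
        return self.ranks[6]

    def name_at(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    def key(self) -> str:
        """Canonical semicolon-joined form used for taxonomy-string comparison."""
        return ";".join(self.ranks)

    def is_empty(self) -> bool:
        return not any(self.ranks)

    @classmethod
    def empty(cls) -> "Lineage":
        return cls(ranks=("",) * N_RANKS)


@dataclass(frozen=True)
class AssignmentResult:
    """A classifier's prediction for one read.

    ``confidences`` holds one score in [0, 1] per rank slot (``None`` where
    the format carries no score for that rank), or is ``None`` entirely for
    formats without scores.
    """

    seq_id: str
    predicted: Lineage
    confidences: Optional[Tuple[Optional[float], ...]] = None

    def confidence_at(self, rank: str) -> Optional[float]:
        if self.confidences is None:
            return None
        return self.confidences[RANKS.index(rank)]


class ReferenceDB:
    """An ordered collection of (SequenceRecord, Lineage) pairs.

    Invariants: ids are unique; every entry carries both a sequence and a
    lineage.  Iteration order is insertion order, which integration
    semantics depend on.
    """

    def __init__(self, entries: Iterable[Tuple[SequenceRecord, Lineage]] = ()) -> None:
        self._entries: Dict[str, Tuple[SequenceRecord, Lineage]] = {}
        for rec, lin in entries:
            self.add(rec, lin)

    def add(self, rec: SequenceRecord, lin: Lineage) -> None:
        if rec.id in self._entries:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        self._entries[rec.id] = (rec, lin)

    def remove(self, seq_id: str) -> None:
        del self._entries[seq_id]

    def get(self, seq_id: str) -> Tuple[SequenceRecord, Lineage]:
        return self._entries[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Tuple[SequenceRecord, Lineage]]:
        return iter(self._entries.values())

    def ids(self) -> List[str]:
        return list(self._entries)

    def copy(self) -> "ReferenceDB":
        return ReferenceDB(self)

    def entry_set(self) -> FrozenSet[Tuple[str, str, Tuple[str, ...]]]:
        """Order-independent content view: {(id, seq, ranks)}."""
        return frozenset((rec.id, rec.seq, lin.ranks) for rec, lin in self)

    def species_set(self) -> Set[str]:
        """All non-empty canonical species names in the database."""
        return {lin.species for _, lin in self if lin.species}

    def lineage_index(self) -> Dict[Tuple[str, ...], List[str]]:
        """Map each seven-rank lineage to the ids carrying it, in order."""
        idx: Dict[Tuple[str, ...], List[str]] = {}
        for rec, lin in self:
            idx.setdefault(lin.ranks, []).append(rec.id)
        return idx

    def with_prefixed_ids(self, prefix: str, sep: str = "|") -> "ReferenceDB":
        """A copy whose ids are ``{prefix}{sep}{id}`` (collision-proofing)."""
        out = ReferenceDB()
        for rec, lin in self:
            out.add(SequenceRecord(id=f"{prefix}{sep}{rec.id}", seq=rec.seq, source=rec.source), lin)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDB):
            return NotImplemented
        if len(self) != len(other):
            return False
        for (ra, la), (rb, lb) in zip(self, other):
            if ra.id != rb.id or ra.seq != rb.seq or la.ranks != lb.ranks:
                return False
        return True

    def __repr__(self) -> str:
        return f"ReferenceDB({len(self)} entries)"


def canonical_name(name: str) -> str:
    """Canonicalise a taxon name for synonym lookup.

    Underscores and runs of whitespace unify to single spaces; the result
    is case-folded.  This is the key space of :class:`SynonymMap`.
    """
    return _WS_RE.sub(" ", name.replace("_", " ")).strip().casefold()


class SynonymMap:
    """Groups of equivalent taxon names keyed by a canonical representative.

    Built from an NCBI-style names dump: all names sharing one taxon
    identifier form a group whose representative is the scientific name.
    Lookup is symmetric -- two names match iff they share a group -- and
    every name belongs to exactly one group.
    """

    def __init__(self, groups: Dict[str, Iterable[str]]) -> None:
        self._groups: Dict[str, FrozenSet[str]] = {}
        self._name_to_rep: Dict[str, str] = {}
        for rep, names in groups.items():
            members = frozenset(names) | {rep}
            self._groups[rep] = members
            for name in members:
                key = canonical_name(name)
                if key in self._name_to_rep and self._name_to_rep[key] != rep:
                    # NCBI homonyms exist; first loaded group wins.
                    continue
                self._name_to_rep[key] = rep

    @classmethod
    def empty(cls) -> "SynonymMap":
        return cls({})

    def representative(self, name: str) -> Optional[str]:
        """The group representative for ``name``, or None if unknown."""
        return self._name_to_rep.get(canonical_name(name))

    def group_of(self, name: str) -> Optional[FrozenSet[str]]:
        rep = self.representative(name)
        return None if rep is None else self._groups[rep]

    def same_group(self, a: str, b: str) -> bool:
        ra = self.representative(a)
        return ra is not None and ra == self.representative(b)

    def __len__(self) -> int:
        return len(self._groups)

    def __contains__(self, name: str) -> bool:
        return canonical_name(name) in self._name_to_rep

    def groups(self) -> Dict[str, FrozenSet[str]]:
        return dict(self._groups)
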