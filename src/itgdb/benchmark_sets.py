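"""Union / Exclusion / Intersection benchmark datasets and species overlap.

Classifier benchmarks need validation sets with controlled taxonomy
overlap: the *Union* of all species found in any source database, the
*Exclusion* of species found in exactly one source (the hard, unique
taxonomies), and the *Intersection* of species present in every source
(no unique-taxonomy advantage for anyone).  Membership is decided on
canonical species names, not sequences; a species present in two sources
with different sequences is still non-exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Tuple

import pandas as pd

from .curation import assert_curated
from .model import ReferenceDB

logger = logging.getLogger(__name__)

SourceList = Sequence[Tuple[str, ReferenceDB]]


@dataclass(frozen=True)
class SpeciesLedger:
    """Per-source species sets with their union, exclusives and common core."""

    sources: Dict[str, FrozenSet[str]]
    union: FrozenSet[str]
    exclusive: Dict[str, FrozenSet[str]]
    common: FrozenSet[str]

    def counts(self) -> pd.DataFrame:
        rows = [
            (name, len(species), len(self.exclusive[name]))
            for name, species in self.sources.items()
        ]
        frame = pd.DataFrame(rows, columns=["source", "n_species", "n_exclusive"])
        frame.attrs["n_union"] = len(self.union)
        frame.attrs["n_common"] = len(self.common)
        return frame


def _as_items(sources) -> List[Tuple[str, ReferenceDB]]:
    if isinstance(sources, dict):
        return list(sources.items())
    return list(sources)


def species_ledger(sources) -> SpeciesLedger:
    """Compute shared/unique species sets across curated sources.

    ``sources`` is a mapping or ordered list of (name, ReferenceDB).  Each
    source must be curated: species-overlap accounting over placeholder
    names would be meaningless.
    """
    items = _as_items(sources)
    per_source: Dict[str, FrozenSet[str]] = {}
    for name, db in items:
        assert_curated(db, context=f"species ledger (source {name!r})")
        per_source[name] = frozenset(db.species_set())
    union: FrozenSet[str] = frozenset().union(*per_source.values()) if per_source else frozenset()
    common = (
        frozenset.intersection(*per_source.values()) if per_source else frozenset()
    )
    exclusive: Dict[str, FrozenSet[str]] = {}
    for name, species in per_source.items():
        others = frozenset().union(
            *(s for other, s in per_source.items() if other != name)
        ) if len(per_source) > 1 else frozenset()
        exclusive[name] = species - others
    ledger = SpeciesLedger(sources=per_source, union=union, exclusive=exclusive, common=common)
    logger.info(
        "species ledger: union=%d, common=%d, exclusive=%s",
        len(union), len(common), {n: len(s) for n, s in exclusive.items()},
    )
    return ledger


def _collect(sources, keep_species: FrozenSet[str]) -> ReferenceDB:
    """Gather entries whose species is in ``keep_species``, source-prefixed,
    collapsing byte-identical (sequence, lineage) pairs across sources."""
    out = ReferenceDB()
    seen = set()
    n_dup = 0
    for name, db in _as_items(sources):
        prefixed = db.with_prefixed_ids(name)
        for rec, lin in prefixed:
            if lin.species not in keep_species:
                continue
            pair = (rec.seq, lin.ranks)
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            out.add(rec, lin)
    if n_dup:
        logger.info("collapsed %d byte-identical cross-source duplicates", n_dup)
    return out


def build_union(sources) -> ReferenceDB:
    """All sequences whose species occurs in any source (duplicates collapsed)."""
    ledger = species_ledger(sources)
    return _collect(sources, ledger.union)


def build_exclusion(sources) -> ReferenceDB:
    """Sequences whose species occurs in exactly one source."""
    ledger = species_ledger(sources)
    only_one = frozenset().union(*ledger.exclusive.values()) if ledger.exclusive else frozenset()
    return _collect(sources, only_one)


def build_intersection(sources) -> ReferenceDB:
    """Sequences whose species occurs in every source."""
    ledger = species_ledger(sources)
    return _collect(sources, ledger.common)
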