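"""Species-level curation of reference databases.

Public 16S references carry many records whose species slot is empty or a
placeholder ("bacterium", "metagenome", "uncultured_..."), which caps a
classifier's resolution at the genus level.  This module removes such
records -- plus byte-identical duplicates under an identical lineage -- and
accounts for every removal, so the manual curation step becomes an
explicit, auditable rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Tuple

import pandas as pd

from .model import Lineage, ReferenceDB

#: Placeholder tokens whose presence (as a case-folded substring of the
#: species name) marks a record as lacking an exact species.  The list is
#: deliberately a parameter: the known placeholder vocabulary is open-ended.
DEFAULT_BLOCKLIST: FrozenSet[str] = frozenset(
    {
        "bacterium",
        "metagenome",
        "candidate_division",
        "human_gut",
        "unidentified",
        "uncultured",
        "unclassified",
    }
)

#: Reasons recorded for removals.
REASON_NO_SPECIES = "no_species"
REASON_AMBIGUOUS = "ambiguous_species"
REASON_DUPLICATE = "duplicate"


@dataclass
class CurationReport:
    """Accounting of one curation pass: every removal, with its reason."""

    n_input: int
    n_removed_no_species: int
    n_removed_ambiguous: int
    n_removed_duplicate: int
    removed_ids: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return (
            self.n_input
            - self.n_removed_no_species
            - self.n_removed_ambiguous
            - self.n_removed_duplicate
        )

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_ids, columns=["id", "reason"])


def is_exact_species(lineage: Lineage, blocklist: Iterable[str] = DEFAULT_BLOCKLIST) -> bool:
    """True iff the lineage's species slot names an exact species.

    False when the species is empty, is a genus-only abbreviation
    (``..._sp.`` or bare ``sp.``), or contains any blocklist token as a
    case-folded substring (placeholders are often embedded in longer
    labels, e.g. ``uncultured_bacterium``).
    """
    species = lineage.species
    if not species:
        return False
    folded = species.casefold()
    if folded == "sp." or folded.endswith("_sp."):
        return False
    return not any(token.casefold() in folded for token in blocklist)


def curate(db: ReferenceDB, blocklist: Iterable[str] = DEFAULT_BLOCKLIST) -> Tuple[ReferenceDB, CurationReport]:
    """Remove records without an exact species name, then collapse duplicates.

    A duplicate is a byte-identical sequence under an identical canonical
    lineage; the first id encountered is kept.  The report accounts for
    every removal exactly once.  Curation is idempotent.
    """
    blockset = frozenset(blocklist)
    kept = ReferenceDB()
    removed: List[Tuple[str, str]] = []
    n_no_species = n_ambiguous = n_duplicate = 0
    seen_pairs = set()
    for rec, lin in db:
        if not lin.species:
            removed.append((rec.id, REASON_NO_SPECIES))
            n_no_species += 1
            continue
        if not is_exact_species(lin, blockset):
            removed.append((rec.id, REASON_AMBIGUOUS))
            n_ambiguous += 1
            continue
        pair = (rec.seq, lin.ranks)
        if pair in seen_pairs:
            removed.append((rec.id, REASON_DUPLICATE))
            n_duplicate += 1
            continue
        seen_pairs.add(pair)
        kept.add(rec, lin)
    report = CurationReport(
        n_input=len(db),
        n_removed_no_species=n_no_species,
        n_removed_ambiguous=n_ambiguous,
        n_removed_duplicate=n_duplicate,
        removed_ids=removed,
    )
    return kept, report


def assert_curated(db: ReferenceDB, blocklist: Iterable[str] = DEFAULT_BLOCKLIST,
                   context: str = "operation") -> None:
    """Raise ``ValueError`` if any entry lacks an exact species name."""
    for rec, lin in db:
        if not is_exact_species(lin, blocklist):
            raise ValueError(
                f"{context} requires curated input, but entry {rec.id!r} has "
                f"species {lin.species!r}; run curate() first"
            )
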