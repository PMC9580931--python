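"""Hypervariable-region coverage profiling by in-silico primer search.

The 16S gene carries nine hypervariable regions (V1..V9) flanked by
conserved primer-binding sites.  Whether a reference sequence can serve a
given metabarcoding study depends on whether it spans the study's primer
pair.  This module locates primer sites under IUPAC-aware matching with a
mismatch budget and counts, per database, how many sequences cover each
region span.

The primer panel is configuration, not code: a shipped YAML file maps the
conventional span labels (V1-V2 .. V1-V9) to the canonical primer pairs
(27F/338R, 515F/806R, ...), with the mismatch budget and amplicon length
bounds alongside.  Override any of it with your own panel file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .model import ReferenceDB

#: IUPAC code -> set of canonical bases it stands for.
IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


def bases_compatible(a: str, b: str) -> bool:
    """True iff the IUPAC expansions of two codes intersect."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair delimiting one region span."""

    region: str
    forward: str
    reverse: str
    forward_name: str = ""
    reverse_name: str = ""

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError(f"primer pair {self.region!r} has an empty primer")


@dataclass(frozen=True)
class PanelConfig:
    """A primer panel plus the matching parameters that apply to it."""

    pairs: Tuple[PrimerPair, ...]
    max_mismatch: int = 2
    min_amplicon: int = 50
    max_amplicon: int = 2000

    def __post_init__(self) -> None:
        labels = [p.region for p in self.pairs]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique within a panel")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


def find_primer(seq: str, primer: str, max_mismatch: int = 0) -> List[int]:
    """All 0-based positions where ``primer`` matches ``seq``.

    Matching is IUPAC-aware in both operands: a position matches when the
    two codes' expansions intersect.  Up to ``max_mismatch`` incompatible
    positions are tolerated.  The primer is searched as given; callers
    searching for a reverse primer pass its reverse complement.
    """
    m = len(primer)
    hits: List[int] = []
    psets = [IUPAC_SETS[c] for c in primer]
    for start in range(len(seq) - m + 1):
        mismatches = 0
        for j in range(m):
            if IUPAC_SETS[seq[start + j]].isdisjoint(psets[j]):
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            hits.append(start)
    return hits


def covers_region(seq: str, pair: PrimerPair, max_mismatch: int = 2,
                  min_amplicon: int = 50, max_amplicon: int = 2000) -> bool:
    """True iff the sequence contains a plausible amplicon for the pair.

    Requires a forward-primer site and a reverse-primer site (searched as
    the reverse complement) with the forward start strictly before the
    reverse start and the implied amplicon length inside the bounds.
    """
    fwd_hits = find_primer(seq, pair.forward, max_mismatch)
    if not fwd_hits:
        return False
    rev_rc = reverse_complement(pair.reverse)
    rev_hits = find_primer(seq, rev_rc, max_mismatch)
    if not rev_hits:
        return False
    rlen = len(rev_rc)
    for f in fwd_hits:
        for r in rev_hits:
            if f < r and min_amplicon <= (r + rlen) - f <= max_amplicon:
                return True
    return False


def load_primer_panel(path=None) -> PanelConfig:
    """Load a primer panel YAML; with no path, the shipped default panel."""
    if path is None:
        ref = importlib.resources.files("itgdb.data").joinpath("primer_panel.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    pairs = tuple(
        PrimerPair(
            region=row["region"],
            forward=row["forward"].upper(),
            reverse=row["reverse"].upper(),
            forward_name=row.get("forward_name", ""),
            reverse_name=row.get("reverse_name", ""),
        )
        for row in raw["pairs"]
    )
    return PanelConfig(
        pairs=pairs,
        max_mismatch=int(raw.get("max_mismatch", 2)),
        min_amplicon=int(raw.get("min_amplicon", 50)),
        max_amplicon=int(raw.get("max_amplicon", 2000)),
    )


def region_coverage(dbs, panel: Optional[PanelConfig] = None,
                    max_mismatch: Optional[int] = None) -> pd.DataFrame:
    """Count, per database, how many sequences cover each region span.

    ``dbs`` is a mapping or ordered list of (name, ReferenceDB).  Returns a
    region x database count table (rows in panel order).
    """
    if panel is None:
        panel = load_primer_panel()
    if not panel.pairs:
        raise ValueError("primer panel is empty")
    mm = panel.max_mismatch if max_mismatch is None else max_mismatch
    items = list(dbs.items()) if isinstance(dbs, dict) else list(dbs)
    table = {
        name: [
            sum(
                covers_region(rec.seq, pair, mm, panel.min_amplicon, panel.max_amplicon)
                for rec, _ in db
            )
            for pair in panel.pairs
        ]
        for name, db in items
    }
    return pd.DataFrame(table, index=[p.region for p in panel.pairs])
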