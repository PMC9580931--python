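"""Deterministic toy data with machine-readable ground truth.

Real 16S reference releases are hundreds of megabytes and live behind
downloads; every algorithm in this package, however, is content-agnostic
except for substring structure, species-name structure and primer motifs.
This module therefore fabricates three small source databases (one per
taxonomy dialect) with controlled species overlap, planted ambiguous
species names, planted containment pairs and duplicates, plus a toy
names-dump, classifier outputs with a planted error rate, and
primer-planted sequences -- and records, alongside, exactly what every
downstream module is expected to find.  Sequences are uniform random DNA
with planted motifs; no attempt is made at realistic 16S base
composition.

Everything is a pure function of the spec (including its seed): the same
spec yields byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .io import format_lineage, write_fasta
from .model import (
    N_RANKS,
    AssignmentResult,
    Lineage,
    ReferenceDB,
    SequenceRecord,
)
from .regions import IUPAC_SETS, PanelConfig, load_primer_panel, reverse_complement

SOURCE_NAMES = ("rdp", "silva", "greengenes")
SOURCE_DIALECTS = {"rdp": "rdp", "silva": "silva", "greengenes": "greengenes"}

#: Planted non-exact species labels, cycled per source.  The empty string
#: plants a record with no species name at all.
AMBIGUOUS_SPECIES = ("Acidocella_sp.", "metagenome", "uncultured_bacterium", "")

_PHYLA = ("Proteobacteria", "Firmicutes", "Bacteroidetes", "Actinobacteria")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one fixture universe.  The seed fixes every output byte."""

    seed: int = 0
    exclusive: Tuple[int, int, int] = (2, 3, 1)       # species unique to rdp/silva/greengenes
    shared_all: int = 2                                # species present in all three
    shared_pairs: Tuple[int, int, int] = (0, 0, 0)     # rdp+silva, silva+greengenes, rdp+greengenes
    n_ambiguous: Tuple[int, int, int] = (1, 1, 1)      # planted non-exact species per source
    n_containment: int = 2                             # silva candidates engulfing an rdp sequence
    n_duplicate: int = 1                               # byte-identical (seq, lineage) copies in rdp
    seqs_per_species: int = 1
    length_range: Tuple[int, int] = (150, 300)
    species_error_rate: float = 0.2                    # planted species mislabels in assignments
    n_synonyms: int = 2                                # species given an alias in the names dump
    region_plan: Mapping[str, int] = field(default_factory=lambda: {"V4": 3, "V1-V9": 2})
    n_region_background: int = 3                       # primer-free sequences in the region fixture


@dataclass
class GroundTruth:
    """What every module is expected to find on the generated fixture."""

    species_by_source: Dict[str, List[str]]
    union_species: List[str]
    common_species: List[str]
    exclusive_species: Dict[str, List[str]]
    removed_ids: Dict[str, List[str]]                  # per source: ids curation must remove
    duplicate_ids: List[str]
    containment_pairs: List[Tuple[str, str]]           # (silva candidate id, rdp basis id)
    expected_seq_actions: Dict[str, str]               # silva id -> action in the rdp<-silva round
    synonym_pairs: List[Tuple[str, str]]               # (species, alias) in the names dump
    region_counts: Dict[str, int]
    n_assignment_reads: int
    n_assignment_errors: int
    expected_species_accuracy: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["containment_pairs"] = [tuple(p) for p in raw["containment_pairs"]]
        raw["synonym_pairs"] = [tuple(p) for p in raw["synonym_pairs"]]
        return cls(**raw)


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _lineage_for(species: str, genus_index: int) -> Lineage:
    genus = species.split("_")[0]
    phylum = _PHYLA[genus_index % len(_PHYLA)]
    ranks = (
        "Bacteria",
        phylum,
        f"Class_{phylum}",
        f"Order{genus_index % 5}",
        f"Family{genus_index % 7}",
        genus,
        species,
    )
    return Lineage(ranks=ranks)


def _allocate_species(spec: FixtureSpec) -> Dict[str, List[str]]:
    """Assign deterministic species names to source memberships."""
    memberships: List[Tuple[str, ...]] = []
    for i, name in enumerate(SOURCE_NAMES):
        memberships += [(name,)] * spec.exclusive[i]
    memberships += [SOURCE_NAMES] * spec.shared_all
    pairs = (("rdp", "silva"), ("silva", "greengenes"), ("rdp", "greengenes"))
    for i, pair in enumerate(pairs):
        memberships += [pair] * spec.shared_pairs[i]
    by_source: Dict[str, List[str]] = {name: [] for name in SOURCE_NAMES}
    for idx, member_of in enumerate(memberships):
        species = f"Genus{idx:02d}_species{idx:02d}"
        for name in member_of:
            by_source[name].append(species)
    return by_source


def build_sources(spec: FixtureSpec) -> Tuple[Dict[str, ReferenceDB], GroundTruth]:
    """Build the three in-memory source databases plus their ground truth."""
    rng = random.Random(spec.seed)
    by_source = _allocate_species(spec)
    genus_index = {
        species: int(species.split("_")[0].removeprefix("Genus"))
        for source in by_source.values() for species in source
    }

    dbs: Dict[str, ReferenceDB] = {}
    removed_ids: Dict[str, List[str]] = {name: [] for name in SOURCE_NAMES}
    counters = {name: 0 for name in SOURCE_NAMES}
    lo, hi = spec.length_range

    def new_id(source: str) -> str:
        counters[source] += 1
        return f"{source}{counters[source]:04d}"

    for source in SOURCE_NAMES:
        db = ReferenceDB()
        src_tag = source if source in ("rdp", "silva", "greengenes") else "other"
        for species in by_source[source]:
            lin = _lineage_for(species, genus_index[species])
            for _ in range(spec.seqs_per_species):
                rec = SequenceRecord(
                    id=new_id(source), seq=_random_dna(rng, rng.randint(lo, hi)), source=src_tag
                )
                db.add(rec, lin)
        dbs[source] = db

    # Containment plants: a silva candidate whose sequence engulfs an rdp
    # basis sequence.  It reuses an existing silva species so the species
    # ledger stays exactly what the overlap arithmetic says.
    containment_pairs: List[Tuple[str, str]] = []
    rdp_entries = list(dbs["rdp"])
    silva_species_cycle = by_source["silva"]
    if spec.n_containment > len(rdp_entries):
        # Two candidates engulfing one basis record would make the second
        # candidate's action depend on processing order; keep truth exact.
        raise ValueError("n_containment must not exceed the number of rdp records")
    for i in range(spec.n_containment):
        if not rdp_entries or not silva_species_cycle:
            raise ValueError("containment plants need at least one rdp record and one silva species")
        basis_rec, _ = rdp_entries[i % len(rdp_entries)]
        species = silva_species_cycle[i % len(silva_species_cycle)]
        seq = _random_dna(rng, 25) + basis_rec.seq + _random_dna(rng, 25)
        rec = SequenceRecord(id=new_id("silva"), seq=seq, source="silva")
        dbs["silva"].add(rec, _lineage_for(species, genus_index[species]))
        containment_pairs.append((rec.id, basis_rec.id))

    # Duplicate plants: byte-identical (sequence, lineage) under a fresh id.
    duplicate_ids: List[str] = []
    rdp_entries = list(dbs["rdp"])
    for i in range(spec.n_duplicate):
        if not rdp_entries:
            raise ValueError("duplicate plants need at least one rdp record")
        rec, lin = rdp_entries[i % len(rdp_entries)]
        dup = SequenceRecord(id=new_id("rdp"), seq=rec.seq, source=rec.source)
        dbs["rdp"].add(dup, lin)
        duplicate_ids.append(dup.id)
        removed_ids["rdp"].append(dup.id)

    # Ambiguous-species plants, cycled through the placeholder vocabulary.
    for s_idx, source in enumerate(SOURCE_NAMES):
        src_tag = source
        for i in range(spec.n_ambiguous[s_idx]):
            label = AMBIGUOUS_SPECIES[(s_idx + i) % len(AMBIGUOUS_SPECIES)]
            ranks = list(_lineage_for("Genus99_speciesX", 0).ranks)
            ranks[6] = label
            rec = SequenceRecord(
                id=new_id(source), seq=_random_dna(rng, rng.randint(lo, hi)), source=src_tag
            )
            dbs[source].add(rec, Lineage(ranks=tuple(ranks)))
            removed_ids[source].append(rec.id)

    # Expected actions for sequence-integrating silva into rdp: planted
    # containments replace; everything else is fresh random DNA, added.
    expected_actions = {
        rec.id: ("replaced" if rec.id in {c for c, _ in containment_pairs} else "added")
        for rec, _ in dbs["silva"]
    }

    species_sets = {name: set(by_source[name]) for name in SOURCE_NAMES}
    union = set().union(*species_sets.values())
    common = set.intersection(*species_sets.values())
    exclusive = {
        name: species_sets[name]
        - set().union(*(s for other, s in species_sets.items() if other != name))
        for name in SOURCE_NAMES
    }

    sorted_union = sorted(union)
    synonym_pairs = [
        (sp, f"{sp.split('_')[0]}_alias{i}")
        for i, sp in enumerate(sorted_union[: spec.n_synonyms])
    ]

    region_counts = expected_region_counts(spec.region_plan)

    truth = GroundTruth(
        species_by_source={n: sorted(species_sets[n]) for n in SOURCE_NAMES},
        union_species=sorted_union,
        common_species=sorted(common),
        exclusive_species={n: sorted(exclusive[n]) for n in SOURCE_NAMES},
        removed_ids=removed_ids,
        duplicate_ids=duplicate_ids,
        containment_pairs=containment_pairs,
        expected_seq_actions=expected_actions,
        synonym_pairs=synonym_pairs,
        region_counts=region_counts,
        n_assignment_reads=0,
        n_assignment_errors=0,
        expected_species_accuracy=100.0,
    )
    return dbs, truth


# --------------------------------------------------------------------------
# Assignment-error planting
# --------------------------------------------------------------------------


def plant_assignment_errors(truth: Mapping[str, Lineage], species_error_rate: float,
                            seed: int) -> Tuple[List[AssignmentResult], float]:
    """Mislabel a known fraction of reads at the species rank.

    Exactly ``floor(rate * n)`` reads (chosen by the seeded RNG) are
    reassigned to a different species from the truth universe, genus slot
    adjusted to match the wrong binomial.  Returns the assignments plus
    the implied species-rank accuracy, ``100 * (1 - floor(rate*n)/n)``.
    """
    if not 0.0 <= species_error_rate <= 1.0:
        raise ValueError("species_error_rate must be in [0, 1]")
    ids = list(truth)
    n = len(ids)
    universe = sorted({lin.species for lin in truth.values() if lin.species})
    n_errors = int(species_error_rate * n)
    if n_errors > 0 and len(universe) < 2:
        raise ValueError("cannot plant species errors with fewer than two species in the universe")
    rng = random.Random(seed)
    error_ids = set(rng.sample(ids, n_errors)) if n_errors else set()
    results: List[AssignmentResult] = []
    for sid in ids:
        lin = truth[sid]
        ranks = list(lin.ranks)
        confs: List[Optional[float]] = [round(rng.uniform(0.85, 1.0), 2)] * N_RANKS
        if sid in error_ids:
            wrong = rng.choice([s for s in universe if s != lin.species])
            ranks[6] = wrong
            ranks[5] = wrong.split("_")[0]
            confs = list(confs)
            confs[6] = round(rng.uniform(0.3, 0.8), 2)
        results.append(
            AssignmentResult(
                seq_id=sid,
                predicted=Lineage(ranks=tuple(ranks), dialect="sintax"),
                confidences=tuple(confs),
            )
        )
    expected = 100.0 * (n - n_errors) / n if n else 0.0
    return results, expected


def write_sintax_assignments(path, assignments: Sequence[AssignmentResult],
                             header: str = "") -> None:
    """Serialise assignments in the SINTAX tabular output convention."""
    letters = ("d", "p", "c", "o", "f", "g", "s")
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for res in assignments:
            fields = []
            for i, name in enumerate(res.predicted.ranks):
                if not name:
                    continue
                conf = res.confidences[i] if res.confidences else None
                fields.append(
                    f"{letters[i]}:{name}({conf:.2f})" if conf is not None else f"{letters[i]}:{name}"
                )
            body = ",".join(fields)
            fh.write(f"{res.seq_id}\t{body}\t+\t{body}\n")


# --------------------------------------------------------------------------
# Region-fixture planting
# --------------------------------------------------------------------------

#: Offsets, loosely following E. coli numbering, at which a synthetic
#: full-length gene carries each primer site (forward sites as given,
#: reverse sites as their reverse complement).  Chosen non-overlapping and
#: in biological order so a full-gene plant covers every panel span.
_FULL_GENE_LAYOUT: Tuple[Tuple[str, str, int], ...] = (
    ("27F", "fwd", 10),
    ("338R", "rev", 300),
    ("341F", "fwd", 330),
    ("534R", "rev", 520),
    ("515F", "fwd", 550),
    ("805R", "rev", 780),
    ("806R", "rev", 810),
    ("926F", "fwd", 880),
    ("926R", "rev", 905),
    ("1115F", "fwd", 1080),
    ("1392R", "rev", 1330),
    ("1492R", "rev", 1440),
)
_FULL_GENE_LENGTH = 1600


def concretize(primer: str, rng: random.Random) -> str:
    """Replace IUPAC degenerate codes by one of their expansion bases."""
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in primer)


def _primer_by_name(panel: PanelConfig) -> Dict[str, str]:
    names: Dict[str, str] = {}
    for pair in panel.pairs:
        if pair.forward_name:
            names[pair.forward_name] = pair.forward
        if pair.reverse_name:
            names[pair.reverse_name] = pair.reverse
    return names


def plant_full_gene(rng: random.Random, panel: Optional[PanelConfig] = None) -> str:
    """A synthetic full-length 16S-like sequence carrying every primer site."""
    panel = panel or load_primer_panel()
    primers = _primer_by_name(panel)
    seq = list(_random_dna(rng, _FULL_GENE_LENGTH))
    for name, orient, offset in _FULL_GENE_LAYOUT:
        if name not in primers:
            continue
        site = concretize(primers[name], rng)
        if orient == "rev":
            site = reverse_complement(site)
        seq[offset : offset + len(site)] = site
    return "".join(seq)


def plant_amplicon(rng: random.Random, forward: str, reverse: str,
                   insert: int = 150, pad: int = 40) -> str:
    """Random sequence containing exactly one fwd-site .. rc(rev-site) span."""
    return (
        _random_dna(rng, pad)
        + concretize(forward, rng)
        + _random_dna(rng, insert)
        + reverse_complement(concretize(reverse, rng))
        + _random_dna(rng, pad)
    )


def expected_region_counts(plan: Mapping[str, int],
                           panel: Optional[PanelConfig] = None) -> Dict[str, int]:
    """Coverage counts implied by a plant plan.

    Span-specific plants cover only their own span; full-gene plants
    (label ``V1-V9``) carry every primer site and therefore count for
    every span in the panel.
    """
    panel = panel or load_primer_panel()
    full = plan.get("V1-V9", 0)
    return {
        pair.region: plan.get(pair.region, 0) + (full if pair.region != "V1-V9" else 0)
        for pair in panel.pairs
    }


def build_region_fixture(plan: Mapping[str, int], n_background: int = 3, seed: int = 0,
                         panel: Optional[PanelConfig] = None) -> Tuple[ReferenceDB, Dict[str, int]]:
    """Primer-planted sequences plus the counts profiling must report.

    ``plan`` maps region labels to planted-sequence counts; ``V1-V9``
    entries are planted as synthetic full genes (covering every span),
    all other labels as single-amplicon sequences.  Background sequences
    carry no primer sites.
    """
    panel = panel or load_primer_panel()
    by_region = {pair.region: pair for pair in panel.pairs}
    unknown = set(plan) - set(by_region)
    if unknown:
        raise ValueError(f"plan refers to regions not in the panel: {sorted(unknown)}")
    rng = random.Random(seed)
    db = ReferenceDB()
    counter = 0
    for region in sorted(plan):
        pair = by_region[region]
        for _ in range(plan[region]):
            counter += 1
            if region == "V1-V9":
                seq = plant_full_gene(rng, panel)
            else:
                seq = plant_amplicon(rng, pair.forward, pair.reverse)
            db.add(SequenceRecord(id=f"reg{counter:04d}", seq=seq), Lineage.empty())
    for _ in range(n_background):
        counter += 1
        db.add(
            SequenceRecord(id=f"reg{counter:04d}", seq=_random_dna(rng, 300)),
            Lineage.empty(),
        )
    return db, expected_region_counts(plan, panel)


# --------------------------------------------------------------------------
# File emission
# --------------------------------------------------------------------------


def _write_source_files(out_dir: Path, name: str, db: ReferenceDB, dialect: str) -> None:
    """Write one source as FASTA + taxonomy table in its native dialect."""
    write_fasta(out_dir / f"{name}.fasta", (rec for rec, _ in db))
    with open(out_dir / f"{name}.tax.tsv", "w") as fh:
        for rec, lin in db:
            if dialect == "greengenes":
                # Greengenes writes rank prefixes and an epithet-only species.
                ranks = list(lin.ranks)
                if ranks[6].startswith(ranks[5] + "_"):
                    ranks[6] = ranks[6][len(ranks[5]) + 1 :]
                text = "; ".join(
                    f"{letter}__{ranks[i]}" for i, letter in enumerate("kpcofgs")
                )
            else:
                text = ";".join(lin.ranks)
            fh.write(f"{rec.id}\t{text}\n")


def _write_names_dump(path, union_species: Sequence[str],
                      synonym_pairs: Sequence[Tuple[str, str]]) -> None:
    alias_by_species = dict(synonym_pairs)
    with open(path, "w") as fh:
        for taxid, species in enumerate(union_species, start=1000):
            sci = species.replace("_", " ")
            fh.write(f"{taxid}\t|\t{sci}\t|\t\t|\tscientific name\t|\n")
            alias = alias_by_species.get(species)
            if alias:
                fh.write(f"{taxid}\t|\t{alias.replace('_', ' ')}\t|\t\t|\tsynonym\t|\n")


def generate(spec: FixtureSpec, out_dir) -> GroundTruth:
    """Emit a complete fixture universe to ``out_dir``; return its truth.

    Writes: three source databases in their native dialects, a toy
    names-dump with planted synonyms, a truth taxonomy table over the
    curated union of sources, a SINTAX-style assignment file with a
    planted species error rate, a primer-planted FASTA, and the ground
    truth as JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dbs, truth = build_sources(spec)
    for name, db in dbs.items():
        _write_source_files(out_dir, name, db, SOURCE_DIALECTS[name])

    _write_names_dump(out_dir / "names.dmp", truth.union_species, truth.synonym_pairs)

    # Truth set for evaluation: one read per curated entry across sources.
    from .curation import curate  # local import to avoid a cycle at module load

    truth_lineages: Dict[str, Lineage] = {}
    for name in SOURCE_NAMES:
        curated, _ = curate(dbs[name])
        for rec, lin in curated:
            truth_lineages[f"{name}|{rec.id}"] = lin
    with open(out_dir / "truth.tax.tsv", "w") as fh:
        for sid, lin in truth_lineages.items():
            fh.write(f"{sid}\t{format_lineage(lin, 'qiime2')}\n")

    assignments, expected_acc = plant_assignment_errors(
        truth_lineages, spec.species_error_rate, spec.seed
    )
    write_sintax_assignments(out_dir / "assignments.sintax.tsv", assignments)
    truth.n_assignment_reads = len(assignments)
    truth.n_assignment_errors = int(spec.species_error_rate * len(assignments))
    truth.expected_species_accuracy = expected_acc

    region_db, region_counts = build_region_fixture(
        spec.region_plan, spec.n_region_background, spec.seed
    )
    write_fasta(out_dir / "regions.fasta", (rec for rec, _ in region_db))
    truth.region_counts = region_counts

    truth.to_json(out_dir / "ground_truth.json")
    return truth


def load_sources(fixture_dir) -> Dict[str, ReferenceDB]:
    """Reload the three generated source databases from a fixture directory."""
    from .io import load_reference_db  # local import keeps module load light

    fixture_dir = Path(fixture_dir)
    return {
        name: load_reference_db(
            fixture_dir / f"{name}.fasta",
            fixture_dir / f"{name}.tax.tsv",
            dialect=SOURCE_DIALECTS[name],
            source=name,
        )
        for name in SOURCE_NAMES
    }
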