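"""Readers and writers for the formats the toolkit touches.

Covers FASTA, the taxonomy-table dialects of the three classic 16S sources
(RDP-, SILVA- and Greengenes-style strings), the QIIME 2 two-file and
SINTAX single-file reference conventions, classifier output tables
(SINTAX, QIIME 2, Mothur, SPINGO), and the NCBI taxonomy names-dump file.

All readers canonicalise on the way in (see :mod:`itgdb.model`), so that
everything downstream compares sequences and taxonomy strings in one
dialect-free space.  Writers accept an optional comment header; FASTA
preamble lines before the first ``>`` are ignored by the reader, and
tabular readers skip ``#`` lines, so provenance stamps survive round trips.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .model import (
    DIALECTS,
    N_RANKS,
    RANKS,
    AssignmentResult,
    Lineage,
    ReferenceDB,
    SequenceRecord,
    SynonymMap,
)

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def read_fasta(path, source: str = "other") -> List[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects.

    Multi-line bodies are concatenated; case, RNA ``U`` and gap characters
    are normalised away.  A duplicate id or an empty sequence is a hard
    error naming the offending record.
    """
    records: List[SequenceRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta-pearson"):
        rec_id = entry.id
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id {rec_id!r} in {path}")
        seen.add(rec_id)
        records.append(SequenceRecord.from_raw(rec_id, str(entry.seq), source=source))
    return records


def write_fasta(path, records: Iterable[SequenceRecord], header: str = "",
                descriptions: Optional[Dict[str, str]] = None, width: int = 80) -> None:
    """Write records as FASTA, optionally with a ``#`` comment preamble."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for rec in records:
            desc = descriptions.get(rec.id, "")
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# Lineage parsing / formatting
# --------------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")
_SINTAX_FIELD_RE = re.compile(r"^([a-zA-Z]):(.*)$")
_WS_RE = re.compile(r"\s+")

# SINTAX rank letters -> slot index ('d' for domain doubles as kingdom).
_SINTAX_RANK_SLOT = {"d": 0, "k": 0, "p": 1, "c": 2, "o": 3, "f": 4, "g": 5, "s": 6}
_SINTAX_SLOT_LETTER = ("d", "p", "c", "o", "f", "g", "s")
_QIIME_SLOT_LETTER = ("k", "p", "c", "o", "f", "g", "s")


def _canon_token(name: str) -> str:
    return _WS_RE.sub("_", name.strip().strip('"').strip())


def parse_lineage(raw: str, dialect: str) -> Lineage:
    """Parse a taxonomy string of the given dialect into a canonical Lineage.

    Missing trailing ranks become empty slots.  In Greengenes/QIIME2-style
    strings an epithet-only ``s__`` field is joined to the genus so the
    species slot always holds the full underscored binomial; an empty
    ``s__`` yields an empty species.  More than seven fields is an error.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    text = raw.strip()
    names = [""] * N_RANKS
    if dialect == "sintax":
        body = text
        if body.lower().startswith("tax="):
            body = body[4:]
        body = body.rstrip(";")
        if body:
            fields = body.split(",")
            if len(fields) > N_RANKS:
                raise ValueError(f"more than {N_RANKS} taxonomy fields in {raw!r}")
            for i, fieldtext in enumerate(fields):
                m = _SINTAX_FIELD_RE.match(fieldtext.strip())
                if m and m.group(1).lower() in _SINTAX_RANK_SLOT:
                    names[_SINTAX_RANK_SLOT[m.group(1).lower()]] = _canon_token(m.group(2))
                else:
                    names[i] = _canon_token(fieldtext)
    else:
        fields = text.split(";") if text else []
        if fields and fields[-1].strip() == "" and len(fields) > N_RANKS:
            fields = fields[:-1]  # tolerate a trailing semicolon
        if len(fields) > N_RANKS:
            raise ValueError(f"more than {N_RANKS} taxonomy fields in {raw!r}")
        for i, fieldtext in enumerate(fields):
            names[i] = _canon_token(_PREFIX_RE.sub("", fieldtext.strip()))
    if dialect in ("greengenes", "qiime2"):
        genus, species = names[5], names[6]
        if species and genus and not species.startswith(genus + "_"):
            names[6] = f"{genus}_{species}"
    return Lineage(ranks=tuple(names), raw=raw, dialect=dialect)


def format_lineage(lin: Lineage, style: str) -> str:
    """Render a lineage in the ``qiime2`` or ``sintax`` output convention."""
    if style == "qiime2":
        return "; ".join(f"{_QIIME_SLOT_LETTER[i]}__{lin.ranks[i]}" for i in range(N_RANKS))
    if style == "sintax":
        body = ",".join(f"{_SINTAX_SLOT_LETTER[i]}:{lin.ranks[i]}" for i in range(N_RANKS))
        return f"tax={body};"
    raise ValueError(f"unknown style {style!r}; expected 'qiime2' or 'sintax'")


# --------------------------------------------------------------------------
# Reference databases (FASTA + taxonomy table)
# --------------------------------------------------------------------------


def read_taxonomy_table(path, dialect: str) -> Dict[str, Lineage]:
    """Read a two-column ``id<TAB>taxonomy`` table into lineages."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["id", "taxon"], dtype=str,
        comment="#", keep_default_na=False,
    )
    if len(frame) and frame.iloc[0, 0] in ("Feature ID", "Feature_ID", "id"):
        frame = frame.iloc[1:]
    out: Dict[str, Lineage] = {}
    for row in frame.itertuples(index=False):
        if row.id in out:
            raise ValueError(f"duplicate id {row.id!r} in taxonomy table {path}")
        out[row.id] = parse_lineage(row.taxon, dialect)
    return out


_TAX_HEADER_RE = re.compile(r";tax=([^;]*);?")


def load_reference_db(fasta_path, taxonomy_path=None, dialect: str = "qiime2",
                      source: str = "other", strict: bool = True) -> ReferenceDB:
    """Load a reference database, inner-joining FASTA and taxonomy on id.

    For the ``sintax`` dialect the taxonomy travels in the FASTA headers
    (``;tax=d:...;``) and ``taxonomy_path`` must be omitted.  In strict
    mode (default) an id present in only one file is an error; with
    ``strict=False`` orphans are dropped and logged.
    """
    if dialect == "sintax":
        if taxonomy_path is not None:
            raise ValueError("sintax databases carry taxonomy in FASTA headers; no taxonomy table expected")
        return _load_sintax_db(fasta_path, source=source)
    if taxonomy_path is None:
        raise ValueError(f"dialect {dialect!r} requires a taxonomy table")
    records = read_fasta(fasta_path, source=source)
    taxonomy = read_taxonomy_table(taxonomy_path, dialect)
    fasta_ids = {r.id for r in records}
    orphan_seqs = [r.id for r in records if r.id not in taxonomy]
    orphan_taxa = [i for i in taxonomy if i not in fasta_ids]
    if (orphan_seqs or orphan_taxa) and strict:
        raise ValueError(
            f"FASTA/taxonomy id mismatch: {len(orphan_seqs)} sequences without "
            f"taxonomy {orphan_seqs[:5]}, {len(orphan_taxa)} taxonomy rows without "
            f"sequence {orphan_taxa[:5]}"
        )
    db = ReferenceDB()
    for rec in records:
        if rec.id in taxonomy:
            db.add(rec, taxonomy[rec.id])
    logger.info(
        "loaded %d entries from %s (%d orphan sequences, %d orphan taxonomy rows)",
        len(db), fasta_path, len(orphan_seqs), len(orphan_taxa),
    )
    return db


def _load_sintax_db(fasta_path, source: str = "other") -> ReferenceDB:
    db = ReferenceDB()
    for entry in SeqIO.parse(str(fasta_path), "fasta-pearson"):
        header = entry.description
        m = _TAX_HEADER_RE.search(header)
        if not m:
            raise ValueError(f"record {entry.id!r} lacks a ';tax=' annotation")
        rec_id = entry.id.split(";")[0]
        if rec_id in db:
            raise ValueError(f"duplicate FASTA id {rec_id!r} in {fasta_path}")
        lin = parse_lineage(m.group(1), "sintax")
        db.add(SequenceRecord.from_raw(rec_id, str(entry.seq), source=source), lin)
    return db


def write_reference_db(db: ReferenceDB, out_prefix, style: str = "qiime2",
                       header: str = "") -> List[Path]:
    """Write a database in the ``qiime2`` (FASTA + TSV) or ``sintax`` style.

    Returns the paths written.  ``load_reference_db`` on the output
    reproduces the database exactly (ids, sequences, seven-rank lineages).
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if style == "qiime2":
        fasta_path = Path(str(prefix) + ".fasta")
        tax_path = Path(str(prefix) + ".tax.tsv")
        write_fasta(fasta_path, (rec for rec, _ in db), header=header)
        with open(tax_path, "w") as fh:
            if header:
                fh.write(header)
            for rec, lin in db:
                fh.write(f"{rec.id}\t{format_lineage(lin, 'qiime2')}\n")
        return [fasta_path, tax_path]
    if style == "sintax":
        fasta_path = Path(str(prefix) + ".fasta")
        descriptions = {rec.id: f";{format_lineage(lin, 'sintax')}" for rec, lin in db}
        write_fasta(fasta_path, (rec for rec, _ in db), header=header, descriptions=descriptions)
        return [fasta_path]
    raise ValueError(f"unknown style {style!r}; expected 'qiime2' or 'sintax'")


# --------------------------------------------------------------------------
# NCBI names dump
# --------------------------------------------------------------------------

#: Name classes accepted by default when building a synonym map.
DEFAULT_NAME_CLASSES = frozenset(
    {"scientific name", "synonym", "equivalent name", "genbank synonym"}
)


def read_names_dump(path, allowed_classes: Iterable[str] = DEFAULT_NAME_CLASSES) -> SynonymMap:
    """Build a :class:`SynonymMap` from an NCBI ``names.dmp``-style file.

    Rows are ``taxid | name | unique name | name class`` with the dump's
    tab-pipe delimiters.  Names whose class is outside ``allowed_classes``
    are ignored.  All names sharing a taxid form one group, represented by
    the scientific name when present.
    """
    allowed = {c.strip().casefold() for c in allowed_classes}
    by_taxid: Dict[str, List[Tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip("\t ") for p in line.rstrip("\n").rstrip("|").split("|")]
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed names-dump row: {line.rstrip()!r}")
            taxid, name, _unique, name_class = parts[0], parts[1], parts[2], parts[3]
            if not taxid or not name:
                raise ValueError(f"{path}:{lineno}: missing taxid or name")
            if name_class.casefold() not in allowed:
                continue
            by_taxid.setdefault(taxid, []).append((name, name_class.casefold()))
    groups: Dict[str, List[str]] = {}
    for taxid, names in by_taxid.items():
        rep = next((n for n, cls in names if cls == "scientific name"), names[0][0])
        groups[rep] = [n for n, _ in names]
    return SynonymMap(groups)


# --------------------------------------------------------------------------
# Classifier outputs
# --------------------------------------------------------------------------

ASSIGNMENT_FORMATS = ("sintax", "qiime2", "mothur", "spingo")

_SINTAX_CONF_RE = re.compile(r"^([a-zA-Z]):([^(]*)\(([-\d.eE]+)\)$")
_MOTHUR_CONF_RE = re.compile(r"^(.*?)\(([-\d.eE]+)\)$")


def read_assignments(path, format: str) -> List[AssignmentResult]:
    """Parse a classifier output table into :class:`AssignmentResult` rows.

    Supported formats: ``sintax`` (per-rank parenthesised confidences),
    ``qiime2`` (one overall confidence, replicated per populated rank),
    ``mothur`` (per-rank bootstrap values, scaled to [0, 1]) and
    ``spingo`` (genus/species columns with scores).  An empty prediction
    field yields an all-empty lineage.
    """
    if format not in ASSIGNMENT_FORMATS:
        raise ValueError(f"unknown assignment format {format!r}; expected one of {ASSIGNMENT_FORMATS}")
    parser = {
        "sintax": _parse_sintax_line,
        "qiime2": _parse_qiime2_line,
        "mothur": _parse_mothur_line,
        "spingo": _parse_spingo_line,
    }[format]
    results: List[AssignmentResult] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.rstrip("\n")
            if not text.strip() or text.startswith("#"):
                continue
            if format == "qiime2" and lineno == 1 and text.split("\t")[0] in ("Feature ID", "Feature_ID"):
                continue
            try:
                results.append(parser(text))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return results


def _parse_sintax_line(text: str) -> AssignmentResult:
    fields = text.split("\t")
    if len(fields) < 2:
        raise ValueError(f"expected at least 2 tab-separated fields, got {len(fields)}")
    seq_id = fields[0].split(";")[0]
    body = fields[1].strip()
    names = [""] * N_RANKS
    confs: List[Optional[float]] = [None] * N_RANKS
    if body:
        for token in body.split(","):
            token = token.strip()
            m = _SINTAX_CONF_RE.match(token)
            if m:
                letter, name, conf = m.group(1).lower(), m.group(2), float(m.group(3))
            else:
                m2 = _SINTAX_FIELD_RE.match(token)
                if not m2:
                    raise ValueError(f"unparseable sintax field {token!r}")
                letter, name, conf = m2.group(1).lower(), m2.group(2), None
            if letter not in _SINTAX_RANK_SLOT:
                raise ValueError(f"unknown sintax rank letter {letter!r}")
            slot = _SINTAX_RANK_SLOT[letter]
            names[slot] = _canon_token(name)
            confs[slot] = conf
    lin = Lineage(ranks=tuple(names), raw=body, dialect="sintax")
    has_conf = any(c is not None for c in confs)
    return AssignmentResult(seq_id=seq_id, predicted=lin,
                            confidences=tuple(confs) if has_conf else None)


def _parse_qiime2_line(text: str) -> AssignmentResult:
    fields = text.split("\t")
    if len(fields) < 2:
        raise ValueError(f"expected at least 2 tab-separated fields, got {len(fields)}")
    seq_id = fields[0]
    lin = parse_lineage(fields[1], "qiime2") if fields[1].strip() else Lineage.empty()
    confs = None
    if len(fields) >= 3 and fields[2].strip():
        overall = float(fields[2])
        # The format carries a single confidence; replicate it at populated ranks.
        confs = tuple(overall if name else None for name in lin.ranks)
    return AssignmentResult(seq_id=seq_id, predicted=lin, confidences=confs)


def _parse_mothur_line(text: str) -> AssignmentResult:
    fields = text.split("\t")
    if len(fields) < 2:
        raise ValueError(f"expected at least 2 tab-separated fields, got {len(fields)}")
    seq_id = fields[0]
    body = fields[-1].strip().rstrip(";")
    names = [""] * N_RANKS
    confs: List[Optional[float]] = [None] * N_RANKS
    if body:
        parts = body.split(";")
        if len(parts) > N_RANKS:
            raise ValueError(f"more than {N_RANKS} taxonomy fields in {body!r}")
        for i, token in enumerate(parts):
            token = token.strip()
            m = _MOTHUR_CONF_RE.match(token)
            if m:
                name, conf = m.group(1), float(m.group(2))
                if conf > 1.0:  # bootstrap percentages
                    conf /= 100.0
            else:
                name, conf = token, None
            names[i] = _canon_token(name)
            confs[i] = conf
    lin = Lineage(ranks=tuple(names), raw=body, dialect="rdp")
    has_conf = any(c is not None for c in confs)
    return AssignmentResult(seq_id=seq_id, predicted=lin,
                            confidences=tuple(confs) if has_conf else None)


def _parse_spingo_line(text: str) -> AssignmentResult:
    # SPINGO-style row: id, similarity, genus, genus score, species, species score.
    fields = text.split("\t")
    if len(fields) < 6:
        raise ValueError(f"expected 6 tab-separated fields, got {len(fields)}")
    seq_id = fields[0]
    genus = _canon_token(fields[2]) if fields[2].strip().upper() != "AMBIGUOUS" else ""
    species = _canon_token(fields[4]) if fields[4].strip().upper() != "AMBIGUOUS" else ""
    names = [""] * N_RANKS
    names[5], names[6] = genus, species
    confs: List[Optional[float]] = [None] * N_RANKS
    if genus and fields[3].strip():
        confs[5] = float(fields[3])
    if species and fields[5].strip():
        confs[6] = float(fields[5])
    lin = Lineage(ranks=tuple(names), raw=text, dialect="rdp")
    has_conf = any(c is not None for c in confs)
    return AssignmentResult(seq_id=seq_id, predicted=lin,
                            confidences=tuple(confs) if has_conf else None)
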