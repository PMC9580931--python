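import random

import pytest
from hypothesis import settings

from itgdb.model import Lineage, ReferenceDB, SequenceRecord

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_lineage(species="", genus="", kingdom="Bacteria", phylum="Proteobacteria",
                 klass="Alphaproteobacteria", order="Order1", family="Family1"):
    if species and not genus:
        genus = species.split("_")[0]
    return Lineage(ranks=(kingdom, phylum, klass, order, family, genus, species))


def make_db(entries, source="other"):
    """Build a ReferenceDB from (id, seq, species-or-Lineage) tuples."""
    db = ReferenceDB()
    for entry_id, seq, tax in entries:
        lin = tax if isinstance(tax, Lineage) else make_lineage(tax)
        db.add(SequenceRecord(id=entry_id, seq=seq, source=source), lin)
    return db


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(42)
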