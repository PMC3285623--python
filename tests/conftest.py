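"""Shared fixtures: synthetic GenBank records built through Biopython."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO


def make_genbank(path, sequence: str, features: list[dict], name="SYNTH01",
                 organism="Synthetica testensis", topology="circular") -> str:
    """Write a synthetic GenBank flat file and return its path."""
    rec = SeqRecord(Seq(sequence), id=name, name=name, description="synthetic")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = topology
    rec.annotations["organism"] = organism
    for f in features:
        loc = f["location"]
        feat = SeqFeature(loc, type=f["type"])
        feat.qualifiers.update(f.get("qualifiers", {}))
        rec.features.append(feat)
    SeqIO.write(rec, str(path), "genbank")
    return str(path)


@pytest.fixture
def tiny_genome(tmp_path):
    """100 bp circular genome: forward CDS, reverse rRNA, origin-wrapping CDS."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    # forward CDS at [0, 9): ATGTTTTAA
    seq = "ATGTTTTAA" + seq[9:]
    features = [
        {"type": "CDS", "location": SimpleLocation(0, 9, strand=1),
         "qualifiers": {"gene": ["nad3"]}},
        {"type": "rRNA", "location": SimpleLocation(20, 50, strand=-1),
         "qualifiers": {"product": ["16S ribosomal RNA"]}},
        {"type": "CDS",
         "location": CompoundLocation([SimpleLocation(94, 100, strand=1),
                                       SimpleLocation(0, 9, strand=1)]),
         "qualifiers": {"gene": ["ND1"]}},
        {"type": "tRNA", "location": SimpleLocation(60, 80, strand=1),
         "qualifiers": {"product": ["tRNA-Leu"],
                        "anticodon": ["(pos:67..69,aa:Leu,seq:taa)"]}},
    ]
    return make_genbank(tmp_path / "tiny.gb", seq, features)


@pytest.fixture
def fixture_tables():
    import mitocomp as mc

    return mc.load_fixtures()
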