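"""Packaged regression fixtures: printed composition, per-gene and
breakpoint tables plus the published recoding partitions.

The composition fixture stores the *printed* (rounded) proportions.  The
printed AT%/skew columns were computed by the original authors from
unrounded counts, so a handful of cells cannot be re-derived exactly from
the 3-decimal proportions; those cells are enumerated verbatim in the
fixture metadata and the integrity check verifies every derived cell lies
within the interval implied by +/-0.0005 rounding boxes on the proportions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .heterogeneity import BinPartition, DAYHOFF_GROUPS, MINMAX6_GROUPS, MINMAX9_GROUPS

#: phylum -> superclade used for the clade summaries
SUPERCLADES = {
    "Hemichordata": "Deuterostomia",
    "Echinodermata": "Deuterostomia",
    "Chordata": "Deuterostomia",
    "Priapulida": "Ecdysozoa",
    "Nematoda": "Ecdysozoa",
    "Onychophora": "Ecdysozoa",
    "Arthropoda": "Ecdysozoa",
    "Platyhelminthes": "Lophotrochozoa",
    "Entoprocta": "Lophotrochozoa",
    "Ectoprocta": "Lophotrochozoa",
    "Phoronida": "Lophotrochozoa",
    "Brachiopoda": "Lophotrochozoa",
    "Nemertea": "Lophotrochozoa",
    "Annelida": "Lophotrochozoa",
    "Mollusca": "Lophotrochozoa",
    "Chaetognatha": "Chaetognatha",
    "Cnidaria": "Cnidaria",
}


@dataclass
class FixtureTables:
    table1: pd.DataFrame  # 10x10 breakpoint distance matrix
    table2: pd.DataFrame  # 50 genome composition rows
    table3: pd.DataFrame  # per-gene/per-position composition of one genome
    dayhoff: BinPartition
    minmax9: BinPartition
    minmax6: BinPartition
    superclades: dict[str, str]
    non_reproducible_cells: list[list]

    def genome_row(self, taxon: str) -> pd.Series:
        hit = self.table2[self.table2.taxon == taxon]
        if hit.empty:
            raise KeyError(taxon)
        return hit.iloc[0]


def _read(name: str) -> str:
    return resources.files("mitocomp.data").joinpath(name).read_text()


def load_fixtures() -> FixtureTables:
    """Load and checksum-verify the packaged tables."""
    meta = json.loads(_read("fixture_metadata.json"))
    frames = {}
    for name, digest in meta["sha256"].items():
        text = _read(name)
        actual = hashlib.sha256(text.encode()).hexdigest()
        if actual != digest:
            raise ValueError(f"fixture {name} checksum mismatch: {actual}")
        frames[name] = text
    t1 = pd.read_csv(
        resources.files("mitocomp.data") / "table1_breakpoints.tsv",
        sep="\t", index_col=0,
    )
    t2 = pd.read_csv(resources.files("mitocomp.data") / "table2_genomes.tsv", sep="\t")
    t3 = pd.read_csv(
        resources.files("mitocomp.data") / "table3_flustra_genes.tsv", sep="\t"
    )
    return FixtureTables(
        table1=t1,
        table2=t2,
        table3=t3,
        dayhoff=BinPartition(DAYHOFF_GROUPS),
        minmax9=BinPartition(MINMAX9_GROUPS),
        minmax6=BinPartition(MINMAX6_GROUPS),
        superclades=dict(SUPERCLADES),
        non_reproducible_cells=[list(c) for c in meta["non_reproducible_cells"]],
    )


def fixture_consistency(fx: FixtureTables) -> list[list]:
    """Cells whose printed derived value differs from the re-derived one at
    printed precision.  Every deviation must fall inside the +/-0.0005
    rounding interval of the proportions; anything worse raises.
    """
    bad = []
    for df, label_col in ((fx.table2, "taxon"), (fx.table3, "unit")):
        for _, row in df.iterrows():
            a, c, g, t = (float(row[s]) for s in "ACGT")
            derived = {
                "at_percent": (100 * (a + t), 1),
                "at_skew": ((a - t) / (a + t), 3),
                "gc_skew": ((g - c) / (g + c), 3),
            }
            for col, (calc, dp) in derived.items():
                printed = float(row[col])
                s = 10 ** dp
                exact = min(
                    abs(np.floor(calc * s) / s - printed),
                    abs(np.ceil(calc * s) / s - printed),
                ) <= 1e-9
                if exact:
                    continue
                # interval bound from proportion rounding (+/-0.0005 per state)
                if col == "at_percent":
                    lo, hi = 100 * (a + t - 0.001), 100 * (a + t + 0.001)
                else:
                    x, y = (a, t) if col == "at_skew" else (g, c)
                    corners = [
                        (x + dx - y - dy) / (x + dx + y + dy)
                        for dx in (-0.0005, 0.0005)
                        for dy in (-0.0005, 0.0005)
                    ]
                    lo, hi = min(corners), max(corners)
                if not lo - 10 ** -dp / 2 <= printed <= hi + 10 ** -dp / 2:
                    raise ValueError(
                        f"{row[label_col]} {col}: printed {printed} outside "
                        f"rounding interval [{lo:.5f}, {hi:.5f}]"
                    )
                bad.append([row[label_col], col, round(calc, 5), printed])
    return bad
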