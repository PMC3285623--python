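"""Multiple-alignment container and FASTA/TSV input-output.

The in-memory container is deliberately thin: taxa labels plus a numpy
character matrix with a declared alphabet.  Statistics modules index the
matrix directly; Biopython does the FASTA parsing and writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_STATES = "ACGT"
AA_STATES = "ACDEFGHIKLMNPQRSTVWY"

#: characters treated as missing data (excluded from all counts) per alphabet
MISSING = {"DNA4": "N", "AA20": "X"}


def states_for(alphabet: str) -> str:
    """Counted character states for a declared alphabet name."""
    if alphabet == "DNA4":
        return DNA_STATES
    if alphabet == "AA20":
        return AA_STATES
    if alphabet.startswith("RECODED-"):
        k = int(alphabet.split("-", 1)[1])
        return "0123456789ABCDEFGHIJ"[:k]
    raise ValueError(f"unknown alphabet {alphabet!r}")


@dataclass
class MultipleAlignment:
    """Taxa x columns character matrix over a declared alphabet.

    Parameters
    ----------
    taxa:
        Row labels, unique.
    matrix:
        ``(n_taxa, n_columns)`` array of single characters.
    alphabet:
        ``"DNA4"``, ``"AA20"`` or ``"RECODED-k"``.
    gap:
        Gap symbol, default ``"-"``.
    meta:
        Free-form provenance (e.g. the recoding partition).
    """

    taxa: list[str]
    matrix: np.ndarray
    alphabet: str = "DNA4"
    gap: str = "-"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-dimensional")
        if len(self.taxa) != self.matrix.shape[0]:
            raise ValueError("taxa count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        allowed = set(states_for(self.alphabet)) | {self.gap}
        allowed.add(MISSING.get(self.alphabet, "?"))
        allowed.add("?")
        present = set(np.unique(self.matrix))
        bad = present - allowed
        if bad:
            raise ValueError(
                f"characters {sorted(bad)} not in alphabet {self.alphabet} "
                f"(allowed: {sorted(allowed)})"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def states(self) -> str:
        return states_for(self.alphabet)

    def row(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    @classmethod
    def from_rows(
        cls,
        rows: Mapping[str, str] | Sequence[tuple[str, str]],
        alphabet: str = "DNA4",
        gap: str = "-",
    ) -> "MultipleAlignment":
        items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
        if not items:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise ValueError(f"ragged rows: lengths {sorted(lengths)}")
        mat = np.array([list(str(s).upper()) for _, s in items], dtype="<U1")
        return cls([t for t, _ in items], mat, alphabet=alphabet, gap=gap)

    # -- column selections ----------------------------------------------
    def take_columns(self, index: Iterable[int]) -> "MultipleAlignment":
        idx = np.asarray(list(index), dtype=int)
        return MultipleAlignment(
            list(self.taxa), self.matrix[:, idx], self.alphabet, self.gap,
            dict(self.meta),
        )

    def codon_positions(self, positions: Iterable[int]) -> "MultipleAlignment":
        """Columns belonging to the given codon positions (1, 2 and/or 3).

        Assumes the alignment starts in frame, as produced by
        back-translation of an amino-acid alignment.
        """
        wanted = sorted(set(positions))
        if not wanted or any(p not in (1, 2, 3) for p in wanted):
            raise ValueError("positions must be a non-empty subset of {1,2,3}")
        keep = [i for i in range(self.n_columns) if (i % 3) + 1 in wanted]
        return self.take_columns(keep)


def read_alignment(path: str | Path, alphabet: str = "DNA4") -> MultipleAlignment:
    """Read an aligned FASTA file.  Rows must all have the same length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return MultipleAlignment.from_rows(
        [(r.id, str(r.seq).upper()) for r in records], alphabet=alphabet
    )


def write_alignment(al: MultipleAlignment, path: str | Path, wrap: int = 70) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=taxon, description="")
        for taxon, row in zip(al.taxa, al.matrix)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def write_table(df, path: str | Path) -> None:
    """Write a report table as TSV with a single header row."""
    df.to_csv(path, sep="\t", index=False)
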