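"""Annotated mitogenome records: GenBank reading, gene-name normalization,
CDS extraction and gene orders.

Coordinates are 0-based half-open internally; the GenBank boundary (1-based
inclusive) is crossed only inside :func:`read_genbank`.  Features annotated
with a ``join()`` across the origin of a circular genome get
``wraps_origin=True`` and keep ``start > end``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .alignment import MultipleAlignment

#: protein-coding and rRNA tokens of a standard metazoan mitogenome
PROTEIN_RRNA_TOKENS = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "rrnS", "rrnL",
)

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# anticodon -> ordinal suffix for the isoacceptor families the field
# distinguishes: L1 = Leu(CUN), L2 = Leu(UUR), S1 = Ser(AGN), S2 = Ser(UCN)
_ANTICODON_CLASS = {
    "L": {"TAG": "L1", "GAG": "L1", "TAA": "L2"},
    "S": {"TCT": "S1", "GCT": "S1", "TGA": "S2"},
}


def _load_synonyms() -> dict[str, str]:
    table = {}
    src = resources.files("mitocomp.data").joinpath("gene_synonyms.tsv")
    with src.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row["raw"].lower()] = row["token"]
    return table


_SYNONYMS = _load_synonyms()


def normalize_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Map a GenBank gene/product name onto the controlled vocabulary.

    tRNA names resolve to single-letter tokens; leucine and serine tRNAs
    additionally need the ``anticodon`` to pick L1/L2 or S1/S2.  Tryptophan
    tRNAs return the bare token ``W``; duplicate copies are given ordinal
    suffixes (W1, W2) by :func:`read_genbank` in genomic order.
    """
    key = raw.strip().lower().replace("_", " ")
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    # tRNA spellings: "tRNA-Leu", "trnL", "trnL(uaa)", "tRNA-Ser (UCN)"
    aa = None
    if key.startswith("trna-") or key.startswith("trna "):
        name = key[5:].strip()
        aa = _AA3_TO_1.get(name[:3])
    elif key.startswith("trn") and len(key) >= 4:
        ch = raw.strip()[3]
        if ch.upper() in _AA3_TO_1.values():
            aa = ch.upper()
    if aa is None:
        vocab = sorted(set(_SYNONYMS.values())) + ["trnX (single-letter)"]
        raise ValueError(f"cannot normalize gene name {raw!r}; vocabulary: {vocab}")
    if aa in ("L", "S"):
        if not anticodon:
            raise ValueError(f"{raw!r}: leucine/serine tRNA requires an anticodon")
        ac = anticodon.strip().upper().replace("U", "T")
        cls = _ANTICODON_CLASS[aa]
        if ac in cls:
            return cls[ac]
        # fall back on the codon family encoded in the name, e.g. "(CUN)"
        fam = key[key.find("(") + 1:key.find(")")] if "(" in key else ""
        fam = fam.upper().replace("U", "T")
        by_family = {"CTN": "L1", "TTR": "L2", "AGN": "S1", "TCN": "S2"}
        if fam in by_family:
            return by_family[fam]
        raise ValueError(f"{raw!r}: unrecognized anticodon {anticodon!r}")
    return aa


@dataclass
class GeneFeature:
    """One annotated feature on the linearized genome."""

    name: str
    start: int
    end: int
    strand: int
    kind: str  # cds | rrna | trna | noncoding
    wraps_origin: bool = False
    incomplete_stop_len: int = 0

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")
        if not self.wraps_origin and not self.start < self.end:
            raise ValueError(f"{self.name}: start must precede end unless wrapping")
        if self.incomplete_stop_len and self.kind != "cds":
            raise ValueError("incomplete_stop_len only applies to CDS features")

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass
class MitoGenome:
    accession: str
    taxon: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.accession}: ambiguity characters {sorted(bad)} not supported "
                "(only A,C,G,T,N)"
            )
        self.features.sort(key=lambda f: f.start)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Nucleotides of a feature on its coding strand."""
        if feat.wraps_origin:
            nt = self.sequence[feat.start:] + self.sequence[:feat.end]
        else:
            nt = self.sequence[feat.start:feat.end]
        if feat.strand == -1:
            nt = str(Seq(nt).reverse_complement())
        return nt

    def feature(self, token: str) -> GeneFeature:
        for f in self.features:
            if f.name == token:
                return f
        raise KeyError(f"no feature named {token!r} in {self.accession}")


def _feature_kind(ftype: str) -> str | None:
    return {
        "CDS": "cds", "rRNA": "rrna", "tRNA": "trna",
        "D-loop": "noncoding", "misc_feature": "noncoding",
    }.get(ftype)


def _raw_name(feat) -> str:
    for key in ("gene", "product", "standard_name", "note"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    raise ValueError(f"feature at {feat.location} has no name qualifier")


def _anticodon(feat) -> str | None:
    q = feat.qualifiers
    if "anticodon" in q:
        val = q["anticodon"][0]
        # formats like "(pos:...,aa:Leu,seq:taa)" or a bare triplet
        if "seq:" in val:
            return val.split("seq:")[1].strip(") ").upper()
        if len(val.strip()) == 3:
            return val.strip().upper()
    for note in q.get("note", []):
        for word in note.replace("(", " ").replace(")", " ").split():
            if len(word) == 3 and set(word.upper()) <= set("ACGUT"):
                return word.upper()
    return None


def read_genbank(path: str | Path) -> MitoGenome:
    """Read one annotated mitogenome from a GenBank flat file."""
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not record.seq or len(record.seq) == 0:
        raise ValueError(f"{path}: record has no sequence")
    length = len(record.seq)
    circular = record.annotations.get("topology", "circular") == "circular"

    features: list[GeneFeature] = []
    for feat in record.features:
        kind = _feature_kind(feat.type)
        if kind is None:
            continue
        parts = feat.location.parts
        strand = int(feat.location.strand or 1)
        start = int(parts[0].start)
        end = int(parts[-1].end)
        wraps = len(parts) > 1 and int(parts[0].end) == length and int(parts[-1].start) == 0
        raw = _raw_name(feat)
        if kind == "trna":
            name = normalize_gene_name(raw, anticodon=_anticodon(feat))
        else:
            name = normalize_gene_name(raw)
        nt_len = (length - start + end) if wraps else (end - start)
        stop_len = nt_len % 3 if kind == "cds" else 0
        features.append(
            GeneFeature(name, start, end, strand, kind,
                        wraps_origin=wraps, incomplete_stop_len=stop_len)
        )
    if not any(f.kind in ("cds", "rrna") for f in features):
        raise ValueError(f"{path}: no CDS or rRNA features found")

    # ordinal suffixes for duplicated tRNA tokens (second tryptophan etc.)
    counts: dict[str, int] = {}
    for f in sorted(features, key=lambda f: f.start):
        if f.kind == "trna":
            counts[f.name] = counts.get(f.name, 0) + 1
    seen: dict[str, int] = {}
    for f in sorted(features, key=lambda f: f.start):
        if f.kind == "trna" and counts[f.name] > 1:
            seen[f.name] = seen.get(f.name, 0) + 1
            f.name = f"{f.name}{seen[f.name]}"

    taxon = record.annotations.get("organism", record.id)
    return MitoGenome(record.id, taxon, str(record.seq), circular, features)


def extract_cds(
    genome: MitoGenome, token: str, code: int = 5
) -> tuple[list[str], str, bool]:
    """In-frame codons and conceptual translation of one CDS.

    Returns ``(codons, translation, incomplete_stop)``.  A trailing
    incomplete termination codon (1-2 bases, completed by polyadenylation
    in vivo) is excluded from the codon list and signalled by the flag.
    """
    feat = genome.feature(token)
    if feat.kind != "cds":
        raise ValueError(f"{token} is not a CDS feature")
    nt = genome.feature_sequence(feat)
    rem = len(nt) % 3
    if rem and feat.incomplete_stop_len != rem:
        raise ValueError(
            f"{token}: length {len(nt)} not a codon multiple and "
            f"incomplete_stop_len={feat.incomplete_stop_len} does not explain it"
        )
    if rem:
        nt = nt[:-rem]
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    aa = str(Seq(nt).translate(table=code))
    table = CodonTable.unambiguous_dna_by_id[code]
    internal = [i for i, c in enumerate(codons[:-1]) if c in table.stop_codons]
    if internal:
        warnings.warn(
            f"{genome.accession}:{token}: internal stop codon(s) at codon "
            f"index {internal}", stacklevel=2,
        )
    return codons, aa, bool(rem)


def extract_gene_order(genome: MitoGenome, include: set[str] | None = None):
    """Signed gene order over the selected feature kinds (default cds+rrna)."""
    from .gene_order import GeneOrder  # local import avoids a cycle

    if include is None:
        include = {"cds", "rrna"}
    feats = [f for f in genome.features if f.kind in include]
    feats.sort(key=lambda f: f.start)
    tokens = [f.name for f in feats]
    dups = {t for t in tokens if tokens.count(t) > 1}
    if dups:
        raise ValueError(
            f"{genome.accession}: duplicated gene tokens {sorted(dups)}; "
            "disambiguate before building a gene order"
        )
    return GeneOrder(
        taxon=genome.taxon,
        genes=[(f.name, f.strand) for f in feats],
        circular=genome.circular,
    )


def backtranslate_alignment(
    aa_alignment: MultipleAlignment, cds_by_taxon: dict[str, list[str]]
) -> MultipleAlignment:
    """Expand an amino-acid alignment to codons using each taxon's CDS.

    Each residue column becomes three nucleotide columns; gaps become
    triple gaps.  The supplied codons must match the ungapped residues of
    each row in number and order.
    """
    rows = {}
    for ti, taxon in enumerate(aa_alignment.taxa):
        if taxon not in cds_by_taxon:
            raise ValueError(f"no codons supplied for taxon {taxon!r}")
        codons = cds_by_taxon[taxon]
        out = []
        k = 0
        for j in range(aa_alignment.n_columns):
            ch = aa_alignment.matrix[ti, j]
            if ch == aa_alignment.gap:
                out.append("---")
                continue
            if k >= len(codons):
                raise ValueError(
                    f"{taxon}: ran out of codons at alignment column {j} "
                    f"({len(codons)} codons supplied)"
                )
            out.append(codons[k])
            k += 1
        if k != len(codons):
            raise ValueError(
                f"{taxon}: {len(codons)} codons supplied but only {k} residues "
                "in the alignment row"
            )
        rows[taxon] = "".join(out)
    return MultipleAlignment.from_rows(rows, alphabet="DNA4")
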