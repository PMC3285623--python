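"""Base composition, Perna-Kocher strand skews, codon usage and p-distances.

The strand-asymmetry skews are

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed from base proportions on the plus strand for whole genomes and on
the coding strand for genes.  Codon usage is tallied per isoacceptor codon
family (Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN, one family per
remaining amino acid plus the termination codons).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .alignment import DNA_STATES


@dataclass
class CompositionProfile:
    """Counts and proportions over A,C,G,T plus AT% and both skews."""

    unit: str
    counts: dict[str, int]
    proportions: dict[str, float] = field(init=False)
    at_percent: float = field(init=False)
    at_skew: float = field(init=False)
    gc_skew: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.get(s, 0) for s in DNA_STATES)
        if total == 0:
            raise ValueError(f"{self.unit}: no countable characters")
        self.proportions = {s: self.counts.get(s, 0) / total for s in DNA_STATES}
        p = self.proportions
        self.at_percent = 100.0 * (p["A"] + p["T"])
        self.at_skew, self.gc_skew = compute_skews(p["A"], p["C"], p["G"], p["T"])


def compute_skews(p_a: float, p_c: float, p_g: float, p_t: float) -> tuple[float, float]:
    """AT- and GC-skew from base proportions.

    A zero denominator yields ``nan`` (undefined skew), not an exception.
    """
    at = (p_a - p_t) / (p_a + p_t) if p_a + p_t > 0 else math.nan
    gc = (p_g - p_c) / (p_g + p_c) if p_g + p_c > 0 else math.nan
    return at, gc


def base_composition(seq: str, unit: str = "genome") -> CompositionProfile:
    """Composition profile of a nucleotide sequence; N and gaps excluded."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    return CompositionProfile(unit, {s: counts.get(s, 0) for s in DNA_STATES})


def codon_position_composition(
    cds_set: list[list[str]],
) -> tuple[CompositionProfile, CompositionProfile, CompositionProfile, CompositionProfile]:
    """Per-codon-position profiles pooled over genes, plus the pooled profile.

    Returns ``(pos1, pos2, pos3, pooled)``.
    """
    if not cds_set or all(len(c) == 0 for c in cds_set):
        raise ValueError("no codons supplied")
    pos_counts = [Counter(), Counter(), Counter()]
    for codons in cds_set:
        for codon in codons:
            for i, ch in enumerate(codon.upper()):
                pos_counts[i][ch] += 1
    profiles = [
        CompositionProfile(f"codon position {i + 1}",
                           {s: pos_counts[i].get(s, 0) for s in DNA_STATES})
        for i in range(3)
    ]
    pooled = CompositionProfile(
        "protein coding sequences",
        {s: sum(pc.get(s, 0) for pc in pos_counts) for s in DNA_STATES},
    )
    return profiles[0], profiles[1], profiles[2], pooled


def codon_families(code: int = 5) -> dict[str, str]:
    """Map codon -> family label under the given translation table.

    Leucine and serine are split into their two isoacceptor families; every
    other amino acid is one family; termination codons form the Stop family.
    """
    table = CodonTable.unambiguous_dna_by_id[code]
    aa3 = {v: k.capitalize() for k, v in
           (("Ala", "A"), ("Arg", "R"), ("Asn", "N"), ("Asp", "D"), ("Cys", "C"),
            ("Gln", "Q"), ("Glu", "E"), ("Gly", "G"), ("His", "H"), ("Ile", "I"),
            ("Leu", "L"), ("Lys", "K"), ("Met", "M"), ("Phe", "F"), ("Pro", "P"),
            ("Ser", "S"), ("Thr", "T"), ("Trp", "W"), ("Tyr", "Y"), ("Val", "V"))}
    fam = {}
    for codon in table.stop_codons:
        fam[codon] = "Stop"
    for codon, aa in table.forward_table.items():
        if aa == "L":
            fam[codon] = "Leu1" if codon.startswith("CT") else "Leu2"
        elif aa == "S":
            fam[codon] = "Ser1" if codon.startswith("AG") else "Ser2"
        else:
            fam[codon] = aa3[aa]
    return fam


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    family_counts: dict[str, int]
    family_fractions: dict[str, float]
    total_codons: int
    excluded: int = 0  # codons containing N, tallied separately


def codon_usage(cds_set: list[list[str]], code: int = 5) -> CodonUsageTable:
    """64-codon usage over a set of coding sequences.

    Complete termination codons are counted (Stop family); codons containing
    N are excluded and tallied separately.
    """
    fam_of = codon_families(code)
    counts: Counter = Counter()
    excluded = 0
    for codons in cds_set:
        for codon in codons:
            codon = codon.upper()
            if codon in fam_of:
                counts[codon] += 1
            else:
                excluded += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable codons")
    fam_counts: Counter = Counter()
    for codon, n in counts.items():
        fam_counts[fam_of[codon]] += n
    return CodonUsageTable(
        counts=dict(counts),
        family_counts=dict(fam_counts),
        family_fractions={f: n / total for f, n in fam_counts.items()},
        total_codons=total,
        excluded=excluded,
    )


def p_distance(row_a: str, row_b: str, missing: str = "N", gap: str = "-") -> float:
    """Proportion of differing sites; gap/missing columns are skipped."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    skip = {gap, missing, "?"}
    kept = diff = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a in skip or b in skip:
            continue
        kept += 1
        diff += a != b
    if kept == 0:
        raise ValueError("no comparable columns")
    return diff / kept


def group_summary(
    at_percent_by_taxon: dict[str, float], grouping: dict[str, str]
) -> dict:
    """Unweighted per-clade mean/min/max AT% plus the global summary.

    ``grouping`` maps each taxon to exactly one clade; taxa missing from the
    grouping raise, empty clades are omitted.
    """
    missing = [t for t in at_percent_by_taxon if t not in grouping]
    if missing:
        raise ValueError(f"taxa without clade assignment: {missing}")
    clades: dict[str, list[float]] = {}
    for taxon, at in at_percent_by_taxon.items():
        clades.setdefault(grouping[taxon], []).append(at)
    per_clade = {
        clade: {"n": len(vals), "mean": float(np.mean(vals)),
                "min": float(np.min(vals)), "max": float(np.max(vals))}
        for clade, vals in clades.items()
    }
    taxa = list(at_percent_by_taxon)
    vals = np.array([at_percent_by_taxon[t] for t in taxa])
    overall = {
        "n": len(taxa),
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "argmin": taxa[int(vals.argmin())],
        "argmax": taxa[int(vals.argmax())],
    }
    return {"clades": per_clade, "overall": overall}


def composition_table(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """Report table mirroring the composition summaries (one row per unit)."""
    rows = []
    for p in profiles:
        rows.append({
            "unit": p.unit,
            **{s: round(p.proportions[s], 3) for s in DNA_STATES},
            "at_percent": round(p.at_percent, 1),
            "at_skew": round(p.at_skew, 3),
            "gc_skew": round(p.gc_skew, 3),
        })
    return pd.DataFrame(rows)
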