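"""Breakpoint distances and conserved blocks between signed circular gene orders.

A gene order is a circular (or linear) list of ``(token, sign)`` pairs.  Its
adjacency set contains every consecutive oriented pair, canonicalized under
the reading-direction identification ``(x, y) == (-y, -x)``.  The breakpoint
distance between two orders over the same genes is the number of adjacencies
of one absent from the other; for circular orders of n unique genes both
sets have size n, so the count is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

Signed = tuple[str, int]


@dataclass(frozen=True)
class GeneOrder:
    taxon: str
    genes: tuple[Signed, ...]
    circular: bool = True

    def __init__(self, taxon: str, genes, circular: bool = True):
        genes = tuple((str(t), int(s)) for t, s in genes)
        tokens = [t for t, _ in genes]
        dups = {t for t in tokens if tokens.count(t) > 1}
        if dups:
            raise ValueError(f"{taxon}: duplicate gene tokens {sorted(dups)}")
        if any(s not in (1, -1) for _, s in genes):
            raise ValueError("signs must be +1 or -1")
        object.__setattr__(self, "taxon", taxon)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "circular", circular)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def tokens(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.genes)

    def rotated(self, k: int) -> "GeneOrder":
        if not self.circular:
            raise ValueError("cannot rotate a linear order")
        k %= len(self.genes)
        return GeneOrder(self.taxon, self.genes[k:] + self.genes[:k], True)

    def reversed_order(self) -> "GeneOrder":
        """The same molecule read from the other strand."""
        return GeneOrder(
            self.taxon, tuple((t, -s) for t, s in reversed(self.genes)), self.circular
        )

    def equivalent(self, other: "GeneOrder") -> bool:
        """Equality up to rotation (and strand flip) for circular orders."""
        if self.tokens != other.tokens:
            return False
        candidates = [other]
        if other.circular:
            candidates += [other.rotated(k) for k in range(1, len(other))]
            rev = other.reversed_order()
            candidates += [rev.rotated(k) for k in range(len(rev))]
        return any(self.genes == c.genes for c in candidates)


def _canonical(pair: tuple[Signed, Signed]) -> tuple[Signed, Signed]:
    (xt, xs), (yt, ys) = pair
    mirrored = ((yt, -ys), (xt, -xs))
    return min(pair, mirrored)


@dataclass(frozen=True)
class AdjacencySet:
    adjacencies: frozenset[tuple[Signed, Signed]]
    circular: bool


def adjacency_set(order: GeneOrder) -> AdjacencySet:
    """Canonical oriented adjacencies of a gene order."""
    n = len(order)
    genes = order.genes
    pairs = []
    last = n if order.circular else n - 1
    for i in range(last):
        pairs.append(_canonical((genes[i], genes[(i + 1) % n])))
    return AdjacencySet(frozenset(pairs), order.circular)


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b``."""
    if a.tokens != b.tokens:
        diff = sorted(a.tokens ^ b.tokens)
        raise ValueError(f"gene sets differ between {a.taxon} and {b.taxon}: {diff}")
    sa = adjacency_set(a).adjacencies
    sb = adjacency_set(b).adjacencies
    return len(sa - sb)


def breakpoint_matrix(orders: list[GeneOrder]) -> pd.DataFrame:
    """Symmetric pairwise breakpoint-distance matrix (zero diagonal)."""
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    taxa = [o.taxon for o in orders]
    n = len(orders)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = breakpoint_distance(orders[i], orders[j])
            except ValueError as exc:
                raise ValueError(f"{taxa[i]} vs {taxa[j]}: {exc}") from exc
            m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=taxa, columns=taxa)


def _runs_of(order: GeneOrder, length: int) -> list[tuple[int, tuple[Signed, ...]]]:
    n = len(order)
    starts = range(n) if order.circular else range(n - length + 1)
    out = []
    for s in starts:
        if not order.circular and s + length > n:
            continue
        run = tuple(order.genes[(s + k) % n] for k in range(length))
        out.append((s, run))
    return out


def _occurs(run: tuple[Signed, ...], other: GeneOrder) -> bool:
    n = len(other)
    rev = tuple((t, -s) for t, s in reversed(run))
    for cand in (run, rev):
        starts = range(n) if other.circular else range(n - len(run) + 1)
        for s in starts:
            if all(other.genes[(s + k) % n] == cand[k] for k in range(len(run))):
                return True
    return False


def shared_blocks(
    a: GeneOrder, b: GeneOrder, min_len: int = 2
) -> list[list[Signed]]:
    """Maximal gene runs shared by two orders, same or fully reversed orientation.

    Runs are reported in ``a``'s reading direction; a reversed occurrence in
    ``b`` (order flipped, signs negated) counts as shared.  Brute force over
    all runs of ``a`` — n is 15 for mitogenome orders.
    """
    if a.tokens != b.tokens:
        raise ValueError("gene sets differ")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    n = len(a)
    max_len = n if (a.circular and b.circular) else n
    covered: list[tuple[int, int]] = []  # (start, length) of reported blocks
    blocks: list[list[Signed]] = []
    for length in range(max_len, min_len - 1, -1):
        runs = _runs_of(a, length)
        if length == n and a.circular:
            runs = runs[:1]  # all n rotations are the same circular run
        for start, run in runs:
            inside = any(
                (start - s) % n + length <= fl
                for s, fl in covered
            ) if a.circular else any(
                s <= start and start + length <= s + fl for s, fl in covered
            )
            if inside:
                continue
            if _occurs(run, b):
                covered.append((start, length))
                blocks.append(list(run))
        if length == n and blocks:
            break  # the full order is shared; nothing longer to report
    return blocks


def read_gene_orders(path: str | Path, circular: bool = True) -> list[GeneOrder]:
    """Plain-text orders: one taxon per line, tab-separated signed tokens."""
    orders = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            taxon, toks = fields[0], fields[1:]
            genes = [
                (t.lstrip("-"), -1 if t.startswith("-") else 1) for t in toks
            ]
            orders.append(GeneOrder(taxon, genes, circular))
    if not orders:
        raise ValueError(f"no gene orders in {path}")
    return orders


def write_gene_orders(orders: list[GeneOrder], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in orders:
            toks = [("-" if s < 0 else "") + t for t, s in o.genes]
            fh.write("\t".join([o.taxon] + toks) + "\n")
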