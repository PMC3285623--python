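"""Synthetic data generators: scrambled gene orders, tree-simulated
sequences with stationary or breakpoint-shifted composition, and codon
streams with prescribed usage.

The sequence simulator mirrors the nonstationary breakpoint mechanism used
for compositional-bias modelling: along any branch the stationary
composition may switch at a breakpoint, the generator is rebuilt from the
shared exchangeabilities and the new frequencies, and descendants inherit
the shifted regime.  Substitution along a branch segment uses the exact
matrix exponential of the current generator, so a stationary configuration
really is stationary — the property the calibration tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import MultipleAlignment
from .composition import codon_families
from .gene_order import GeneOrder
from .models import SubstitutionModel
from .site_rates import read_tree

# ---------------------------------------------------------------------------
# gene-order scrambling


@dataclass(frozen=True)
class Inversion:
    start: int
    length: int


@dataclass(frozen=True)
class Transposition:
    start: int
    length: int
    dest: int


def apply_operation(order: GeneOrder, op) -> GeneOrder:
    genes = list(order.genes)
    n = len(genes)
    idx = [(op.start + k) % n for k in range(op.length)]
    segment = [genes[i] for i in idx]
    if isinstance(op, Inversion):
        flipped = [(t, -s) for t, s in reversed(segment)]
        for i, g in zip(idx, flipped):
            genes[i] = g
        return GeneOrder(order.taxon, genes, order.circular)
    if isinstance(op, Transposition):
        rest = [g for i, g in enumerate(genes) if i not in set(idx)]
        dest = op.dest % (len(rest) + 1)
        new = rest[:dest] + segment + rest[dest:]
        return GeneOrder(order.taxon, new, order.circular)
    raise TypeError(f"unknown operation {op!r}")


@dataclass
class ScrambleLog:
    seed: int
    source: GeneOrder
    operations: list
    result: GeneOrder

    def replay(self) -> GeneOrder:
        order = self.source
        for op in self.operations:
            order = apply_operation(order, op)
        return order


def scramble_gene_order(
    order: GeneOrder,
    n_ops: int,
    seed: int = 0,
    op_mix: tuple[float, float] = (0.5, 0.5),
) -> ScrambleLog:
    """Apply ``n_ops`` random inversions/transpositions, logging each.

    ``op_mix`` gives (inversion, transposition) probabilities.  Operations
    never span the whole circle (a full-circle operation is a rotation or
    strand flip, i.e. the identity for circular comparison).
    """
    rng = np.random.default_rng(seed)
    n = len(order)
    ops = []
    current = order
    for _ in range(n_ops):
        for _attempt in range(100):
            kind = rng.choice(2, p=np.asarray(op_mix) / sum(op_mix))
            if kind == 0 or n < 3:
                op = Inversion(int(rng.integers(n)), int(rng.integers(1, n)))
            else:
                length = int(rng.integers(1, n - 1))
                op = Transposition(int(rng.integers(n)), length,
                                   int(rng.integers(n - length + 1)))
            moved = apply_operation(current, op)
            if not (order.circular and moved.equivalent(current)):
                break  # skip no-op transpositions (rotations of the circle)
        current = moved
        ops.append(op)
    return ScrambleLog(seed, order, ops, current)


# ---------------------------------------------------------------------------
# tree-structured sequence simulation


@dataclass(frozen=True)
class CompositionShift:
    """A composition breakpoint on the branch above the named node.

    ``edge`` is a leaf taxon label or an internal node label; ``position``
    is the fraction of the branch (from the parent) at which the stationary
    composition switches to ``frequencies``.  Descendants inherit the new
    regime.
    """

    edge: str
    position: float
    frequencies: tuple[float, ...]


@dataclass
class SimulationConfig:
    tree: str | dendropy.Tree
    states: str
    root_frequencies: tuple[float, ...]
    n_sites: int
    exchangeabilities: np.ndarray | None = None  # default: all-equal (F81-like)
    shifts: list[CompositionShift] = field(default_factory=list)
    gamma_shape: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.root_frequencies, float)
        if f.shape != (len(self.states),) or np.any(f < 0) or not np.isclose(f.sum(), 1):
            raise ValueError("root composition must be a simplex point over the states")
        for sh in self.shifts:
            g = np.asarray(sh.frequencies, float)
            if g.shape != (len(self.states),) or np.any(g < 0) or not np.isclose(g.sum(), 1):
                raise ValueError(f"shift on {sh.edge!r}: invalid simplex point")
            if not 0 <= sh.position <= 1:
                raise ValueError(f"shift on {sh.edge!r}: position outside [0, 1]")


def _node_key(node: dendropy.Node) -> str | None:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return node.label


def _evolve(
    states: np.ndarray,
    model: SubstitutionModel,
    durations: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample child states site-by-site given per-site branch durations."""
    lam, right, left = model._eigen()
    w = right[states, :] * np.exp(np.outer(durations, lam))
    probs = np.clip(w @ left, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(len(states))
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.intp)


def simulate_alignment(cfg: SimulationConfig) -> tuple[MultipleAlignment, np.ndarray]:
    """Simulate an alignment down a tree; returns it with the true site rates.

    Root states are drawn from the root composition; each branch evolves under
    the current regime's reversible generator, switching at configured
    breakpoints.  With ``gamma_shape`` set, per-site rates are i.i.d.
    gamma(shape, mean 1) draws scaling every branch.
    """
    tree = read_tree(cfg.tree)
    rng = np.random.default_rng(cfg.seed)
    n = len(cfg.states)
    exch = cfg.exchangeabilities
    if exch is None:
        exch = np.ones((n, n)) - np.eye(n)

    models: dict[tuple, SubstitutionModel] = {}

    def model_for(freqs: tuple[float, ...]) -> SubstitutionModel:
        if freqs not in models:
            models[freqs] = SubstitutionModel(cfg.states, exch, np.asarray(freqs))
        return models[freqs]

    shifts_by_edge: dict[str, list[CompositionShift]] = {}
    for sh in cfg.shifts:
        shifts_by_edge.setdefault(sh.edge, []).append(sh)
    for lst in shifts_by_edge.values():
        lst.sort(key=lambda s: s.position)
    known = {_node_key(nd) for nd in tree.preorder_node_iter()}
    unknown = set(shifts_by_edge) - known
    if unknown:
        raise ValueError(f"shift edges not present in the tree: {sorted(unknown)}")

    if cfg.gamma_shape is not None:
        rates = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape, size=cfg.n_sites)
    else:
        rates = np.ones(cfg.n_sites)

    root = tree.seed_node
    root_freqs = tuple(float(x) for x in cfg.root_frequencies)
    root_states = rng.choice(n, size=cfg.n_sites, p=np.asarray(root_freqs))
    states_at = {id(root): root_states}
    regime_at = {id(root): root_freqs}

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        cur = states_at[id(parent)]
        freqs = regime_at[id(parent)]
        t = node.edge.length or 0.0
        key = _node_key(node)
        prev = 0.0
        for sh in shifts_by_edge.get(key, []):
            seg = (sh.position - prev) * t
            if seg > 0:
                cur = _evolve(cur, model_for(freqs), rates * seg, rng)
            freqs = tuple(float(x) for x in sh.frequencies)
            prev = sh.position
        seg = (1.0 - prev) * t
        if seg > 0:
            cur = _evolve(cur, model_for(freqs), rates * seg, rng)
        states_at[id(node)] = cur
        regime_at[id(node)] = freqs

    chars = np.array(list(cfg.states))
    taxa, rows = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append(chars[states_at[id(leaf)]])
    alphabet = "DNA4" if cfg.states == "ACGT" else (
        "AA20" if len(cfg.states) == 20 else f"RECODED-{n}"
    )
    al = MultipleAlignment(taxa, np.array(rows), alphabet=alphabet)
    return al, rates


# ---------------------------------------------------------------------------
# codon streams


def simulate_cds(
    usage: dict[str, float],
    n_codons: int,
    seed: int = 0,
    allow_stops: bool = False,
    code: int = 5,
) -> list[str]:
    """I.i.d. codon draws from target usage fractions over sense codons."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    fam = codon_families(code)
    codons = [c for c, w in usage.items() if w > 0]
    if not allow_stops:
        codons = [c for c in codons if fam.get(c) != "Stop"]
    weights = np.array([usage[c] for c in codons], dtype=float)
    if not codons or weights.sum() <= 0:
        raise ValueError("codon usage has zero total mass")
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(codons), size=n_codons, p=weights)
    return [codons[i] for i in draws]
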