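"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import itertools

import numpy as np

import mitocomp as mc
from mitocomp.gene_order import GeneOrder


def balanced_newick(n: int, term: float = 0.3, inner: float = 0.1) -> str:
    labels = [f"t{i}" for i in range(n)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{labels[lo]}:{term}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{inner}"

    return build(0, n) + ";"


def breakpoint_oracle(a: GeneOrder, b: GeneOrder) -> int:
    """Count a's consecutive pairs absent from b by explicit double loop."""
    na, nb = len(a.genes), len(b.genes)
    apairs = [(a.genes[i], a.genes[(i + 1) % na])
              for i in range(na if a.circular else na - 1)]
    bpairs = [(b.genes[i], b.genes[(i + 1) % nb])
              for i in range(nb if b.circular else nb - 1)]
    missing = 0
    for x, y in apairs:
        found = False
        for u, v in bpairs:
            if (x, y) == (u, v) or (x, y) == ((v[0], -v[1]), (u[0], -u[1])):
                found = True
                break
        missing += not found
    return missing


def random_signed_order(rng: np.random.Generator, n: int, taxon: str) -> GeneOrder:
    perm = rng.permutation(n)
    signs = rng.choice([1, -1], size=n)
    return GeneOrder(taxon, [(str(p), int(s)) for p, s in zip(perm, signs)], True)


def brute_force_loglik(al, tree, model, rate: float = 1.0) -> np.ndarray:
    """Site log-likelihood by explicit summation over ancestral states."""
    tree = mc.read_tree(tree)
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    idx = {s: i for i, s in enumerate(model.states)}
    n = model.n_states
    p_of = {id(nd): model.transition_matrix((nd.edge.length or 0.0) * rate)
            for nd in nodes}
    out = np.zeros(al.n_columns)
    for site in range(al.n_columns):
        leaf_state = {
            t: idx.get(al.matrix[al.taxa.index(t), site]) for t in al.taxa
        }
        total = 0.0
        for assign in itertools.product(range(n), repeat=len(internals)):
            amap = {id(nd): a for nd, a in zip(internals, assign)}
            pr = model.frequencies[amap[id(tree.seed_node)]]
            for nd in nodes:
                if nd is tree.seed_node:
                    continue
                parent = amap[id(nd.parent_node)]
                if nd.is_leaf():
                    s = leaf_state[nd.taxon.label]
                    pr *= 1.0 if s is None else p_of[id(nd)][parent, s]
                else:
                    pr *= p_of[id(nd)][parent, amap[id(nd)]]
            total += pr
        out[site] = np.log(total)
    return out


def set_partitions_into_k(states: list[str], k: int):
    """All partitions of ``states`` into exactly ``k`` non-empty groups."""

    def rec(i: int, max_group: int, assign: list[int]):
        if i == len(states):
            if max_group + 1 == k:
                yield tuple(assign)
            return
        for g in range(min(max_group + 1, k - 1) + 1):
            assign.append(g)
            yield from rec(i + 1, max(max_group, g), assign)
            assign.pop()

    for assign in rec(0, -1, []):
        yield tuple(sorted(
            "".join(s for s, a in zip(states, assign) if a == g)
            for g in range(k)
        ))
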