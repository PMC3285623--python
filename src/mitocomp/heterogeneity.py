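"""Compositional-heterogeneity tests and amino-acid recoding.

Four layers:

* an across-taxa chi-square homogeneity test on a taxa x states count matrix
  (expected cell = row total x pooled state frequency, df = (taxa-1)(states-1));
* the matched-pairs test of symmetry (Bowker) on one aligned sequence pair,
  S = sum_{i<j} (N_ij - N_ji)^2 / (N_ij + N_ji), which rejects when the
  divergence matrix is asymmetric, i.e. evolution was not stationary;
* simulation-based deviation statistics: the per-taxon statistic sums
  |taxon frequency - global frequency| over the alphabet, the global
  statistic is its maximum over taxa, and both are calibrated against
  replicate alignments simulated under a stationary reference model
  (Z scores and one-sided smoothed p-values);
* recoding of amino acids into groups: the fixed Dayhoff classes and
  data-driven minmax chi-squared bins that minimize the maximum per-taxon
  binned chi-square statistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import MISSING, MultipleAlignment, states_for

#: the six Dayhoff classes of frequently interchanging amino acids
DAYHOFF_GROUPS = ("AGPST", "C", "DENQ", "FWY", "HKR", "ILMV")

#: published minmax chi-squared bins for mitochondrial protein data
MINMAX9_GROUPS = ("D", "PV", "AIMSY", "GFT", "L", "NH", "W", "RCQK", "E")
MINMAX6_GROUPS = ("GFTW", "AHILMSY", "NPV", "E", "D", "RCQK")


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    detail: pd.DataFrame | None = None
    degenerate: bool = False


def count_matrix(al: MultipleAlignment) -> pd.DataFrame:
    """Taxa x states counts; gaps and missing characters excluded."""
    states = list(al.states)
    missing = {al.gap, MISSING.get(al.alphabet, "?"), "?"}
    rows = []
    for i, taxon in enumerate(al.taxa):
        vals, counts = np.unique(al.matrix[i], return_counts=True)
        d = dict(zip(vals, counts))
        rows.append([int(d.get(s, 0)) for s in states])
        if sum(rows[-1]) == 0:
            raise ValueError(f"{taxon}: row has no countable characters")
        stray = set(d) - set(states) - missing
        if stray:
            raise ValueError(f"{taxon}: unexpected characters {sorted(stray)}")
    return pd.DataFrame(rows, index=list(al.taxa), columns=states)


def chi2_homogeneity(counts: pd.DataFrame) -> TestResult:
    """Across-taxa chi-square test of compositional homogeneity.

    Note this test treats taxa as independent samples; shared phylogenetic
    history makes it conservative on tree-structured data.
    """
    m = counts.to_numpy(dtype=float)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 taxa and 2 states")
    pooled = m.sum(axis=0)
    keep = pooled > 0
    if not keep.all():
        dropped = [c for c, k in zip(counts.columns, keep) if not k]
        warnings.warn(f"states with zero pooled count dropped: {dropped}",
                      stacklevel=2)
        m = m[:, keep]
        pooled = pooled[keep]
    row_tot = m.sum(axis=1, keepdims=True)
    expected = row_tot * (pooled / pooled.sum())
    cell = (m - expected) ** 2 / expected
    stat = float(cell.sum())
    df = (m.shape[0] - 1) * (m.shape[1] - 1)
    detail = pd.DataFrame(
        {"contribution": cell.sum(axis=1)}, index=counts.index
    )
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)), detail)


def divergence_matrix(
    row_a: str, row_b: str, states: str, skip: set[str]
) -> np.ndarray:
    """Pairwise site-pattern counts N[i, j] over columns where both rows
    carry plain states."""
    idx = {s: i for i, s in enumerate(states)}
    n = np.zeros((len(states), len(states)), dtype=int)
    for a, b in zip(row_a, row_b):
        if a in skip or b in skip:
            continue
        n[idx[a], idx[b]] += 1
    return n


def matched_pairs_symmetry(
    row_a: str, row_b: str, states: str = "ACGT", gap: str = "-"
) -> TestResult:
    """Bowker matched-pairs test of symmetry for one aligned sequence pair."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    skip = {gap, "?", "N" if set(states) <= set("ACGT") else "X"}
    n = divergence_matrix(row_a.upper(), row_b.upper(), states, skip)
    return bowker_from_divergence(n)


def bowker_from_divergence(n: np.ndarray) -> TestResult:
    s = 0.0
    df = 0
    c = n.shape[0]
    for i in range(c):
        for j in range(i + 1, c):
            tot = n[i, j] + n[j, i]
            if tot > 0:
                s += (n[i, j] - n[j, i]) ** 2 / tot
                df += 1
    if df == 0:
        return TestResult(0.0, 0, 1.0, degenerate=True)
    return TestResult(float(s), df, float(stats.chi2.sf(s, df)))


def pairwise_symmetry_summary(
    al: MultipleAlignment,
    alpha: float = 0.05,
    positions: Iterable[int] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Bowker test over all unordered taxon pairs.

    Returns the fraction of pairs significant at ``alpha`` (degenerate pairs
    count as non-significant and are flagged) and the per-pair table.
    ``positions`` restricts to codon-position column subsets, e.g. ``(1, 2)``.
    """
    if al.n_taxa < 2:
        raise ValueError("need at least two taxa")
    sub = al.codon_positions(positions) if positions is not None else al
    rows = ["".join(r) for r in sub.matrix]
    records = []
    n_sig = 0
    for i, j in itertools.combinations(range(sub.n_taxa), 2):
        res = matched_pairs_symmetry(rows[i], rows[j], sub.states, sub.gap)
        sig = (not res.degenerate) and res.p_value < alpha
        n_sig += sig
        records.append({
            "taxon_a": sub.taxa[i], "taxon_b": sub.taxa[j],
            "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
            "significant": sig, "degenerate": res.degenerate,
        })
    table = pd.DataFrame(records)
    return n_sig / len(records), table


# -- deviation statistics -----------------------------------------------

def _frequencies(al: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(per-taxon, global) state frequencies on non-gap residues."""
    counts = count_matrix(al).to_numpy(dtype=float)
    row_tot = counts.sum(axis=1, keepdims=True)
    return counts / row_tot, counts.sum(axis=0) / counts.sum()


def taxon_deviation(al: MultipleAlignment) -> pd.Series:
    """Per-taxon compositional deviation: sum of absolute differences
    between taxon-specific and global state frequencies."""
    per_taxon, global_f = _frequencies(al)
    d = np.abs(per_taxon - global_f).sum(axis=1)
    return pd.Series(d, index=list(al.taxa), name="deviation")


def global_deviation(al: MultipleAlignment) -> float:
    """Maximum taxon deviation — the global heterogeneity statistic."""
    return float(taxon_deviation(al).max())


@dataclass
class DeviationReport:
    per_taxon: pd.DataFrame
    global_observed: float
    global_z: float
    global_p: float
    n_deviating: int
    alpha: float
    n_reps: int


def posterior_predictive(
    al: MultipleAlignment,
    replicate_source: Callable[[int], MultipleAlignment] | Iterable[MultipleAlignment],
    n_reps: int = 100,
    alpha: float = 0.05,
) -> DeviationReport:
    """Posterior-predictive-style deviation test against simulated replicates.

    ``replicate_source`` either yields alignments or is called with the
    replicate index; replicates must cover the same taxa (order-insensitive)
    and stand in for draws from a fitted reference model.  One-sided
    p-values use (r+1)/(n+1) smoothing; Z = (obs - mean) / sd.
    """
    if n_reps < 20:
        raise ValueError("n_reps < 20 gives unstable replicate standard deviations")
    obs = taxon_deviation(al)
    obs_global = float(obs.max())
    taxa = list(al.taxa)

    if callable(replicate_source):
        reps_iter = (replicate_source(i) for i in range(n_reps))
    else:
        reps_iter = iter(replicate_source)

    rep_stats = np.empty((n_reps, len(taxa)))
    rep_global = np.empty(n_reps)
    for r in range(n_reps):
        try:
            rep = next(reps_iter)
        except StopIteration as exc:
            raise ValueError(f"replicate source exhausted after {r} draws") from exc
        if set(rep.taxa) != set(taxa):
            raise ValueError("replicate taxa differ from the observed alignment")
        d = taxon_deviation(rep)
        rep_stats[r] = d.reindex(taxa).to_numpy()
        rep_global[r] = d.max()

    mean = rep_stats.mean(axis=0)
    sd = rep_stats.std(axis=0, ddof=1)
    degenerate = sd == 0
    z = np.full(len(taxa), np.nan)
    z[~degenerate] = (obs.to_numpy()[~degenerate] - mean[~degenerate]) / sd[~degenerate]
    p = ((rep_stats >= obs.to_numpy()).sum(axis=0) + 1) / (n_reps + 1)
    flag = (p < alpha) & ~degenerate
    per_taxon = pd.DataFrame({
        "observed": obs.to_numpy(), "rep_mean": mean, "rep_sd": sd,
        "z_score": z, "p_value": p, "deviating": flag, "degenerate": degenerate,
    }, index=taxa)

    g_sd = rep_global.std(ddof=1)
    g_z = (obs_global - rep_global.mean()) / g_sd if g_sd > 0 else float("nan")
    g_p = float(((rep_global >= obs_global).sum() + 1) / (n_reps + 1))
    return DeviationReport(
        per_taxon=per_taxon,
        global_observed=obs_global,
        global_z=float(g_z),
        global_p=g_p,
        n_deviating=int(flag.sum()),
        alpha=alpha,
        n_reps=n_reps,
    )


# -- recoding ------------------------------------------------------------

@dataclass(frozen=True)
class BinPartition:
    """Disjoint state groups covering an alphabet, with the minmax p-value."""

    groups: tuple[str, ...]
    min_p: float = float("nan")

    def __post_init__(self) -> None:
        flat = "".join(self.groups)
        if len(set(flat)) != len(flat):
            raise ValueError("groups overlap")
        if any(not g for g in self.groups):
            raise ValueError("empty group")

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset("".join(self.groups))

    def canonical(self) -> tuple[str, ...]:
        return tuple(sorted("".join(sorted(g)) for g in self.groups))

    def serialize(self) -> str:
        return ",".join("".join(sorted(g)) for g in self.groups)

    @classmethod
    def parse(cls, text: str) -> "BinPartition":
        return cls(tuple(text.replace(" ", "").split(",")))


def recode(al: MultipleAlignment, partition: BinPartition) -> MultipleAlignment:
    """Replace each residue by its group symbol; gaps/missing preserved.

    Group symbols follow the canonical (sorted) group order; the mapping is
    stored in the result's ``meta['recoding']``.
    """
    groups = partition.canonical()
    if not set(al.states) <= set("".join(groups)):
        missing = set(al.states) - set("".join(groups))
        raise ValueError(f"partition does not cover residues {sorted(missing)}")
    symbols = states_for(f"RECODED-{len(groups)}")
    mapping = {}
    for sym, grp in zip(symbols, groups):
        for ch in grp:
            mapping[ch] = sym
    mapping[al.gap] = al.gap
    mapping[MISSING.get(al.alphabet, "?")] = "?"
    mapping["?"] = "?"
    out = np.vectorize(mapping.__getitem__)(al.matrix)
    return MultipleAlignment(
        list(al.taxa), out, alphabet=f"RECODED-{len(groups)}", gap=al.gap,
        meta={**al.meta, "recoding": dict(zip(groups, symbols))},
    )


def binned_counts(counts: pd.DataFrame, groups: tuple[str, ...]) -> np.ndarray:
    m = counts.to_numpy(dtype=float)
    cols = {s: i for i, s in enumerate(counts.columns)}
    out = np.zeros((m.shape[0], len(groups)))
    for g, grp in enumerate(groups):
        for ch in grp:
            out[:, g] += m[:, cols[ch]]
    return out


def max_taxon_chi2(counts: pd.DataFrame, groups: tuple[str, ...]) -> tuple[float, float]:
    """(max per-taxon binned chi-square, min over taxa of its p-value).

    Each taxon's binned counts are tested against the pooled binned
    frequencies with df = k - 1.
    """
    b = binned_counts(counts, groups)
    pooled = b.sum(axis=0)
    pooled_f = pooled / pooled.sum()
    row_tot = b.sum(axis=1, keepdims=True)
    expected = row_tot * pooled_f
    with np.errstate(divide="ignore", invalid="ignore"):
        cell = np.where(expected > 0, (b - expected) ** 2 / expected, 0.0)
    per_taxon = cell.sum(axis=1)
    stat = float(per_taxon.max())
    return stat, float(stats.chi2.sf(stat, len(groups) - 1))


def _greedy_descent(
    counts: pd.DataFrame, assign: np.ndarray, k: int
) -> tuple[float, np.ndarray]:
    states = list(counts.columns)
    groups = lambda a: tuple(  # noqa: E731
        "".join(states[i] for i in np.where(a == g)[0]) for g in range(k)
    )
    best, _ = max_taxon_chi2(counts, groups(assign))
    improved = True
    while improved:
        improved = False
        for i in range(len(states)):
            src = assign[i]
            if (assign == src).sum() == 1:
                continue  # moving would empty the source group
            for dst in range(k):
                if dst == src:
                    continue
                assign[i] = dst
                stat, _ = max_taxon_chi2(counts, groups(assign))
                if stat < best - 1e-12:
                    best = stat
                    src = dst
                    improved = True
                else:
                    assign[i] = src
    return best, assign


def find_minmax_bins(
    al: MultipleAlignment,
    k: int,
    seed: int = 0,
    restarts: int = 50,
) -> BinPartition:
    """Heuristic minmax chi-squared binning of the alignment alphabet.

    Steepest-descent single-residue moves from ``restarts`` random seeded
    starting partitions; ties broken by the lexicographically smallest
    canonical partition.  ``k`` equal to the alphabet size returns the
    identity partition.
    """
    counts = count_matrix(al)
    states = list(counts.columns)
    if not 2 <= k <= len(states):
        raise ValueError(f"k must be in [2, {len(states)}]")
    if k == len(states):
        part = tuple(sorted(states))
        _, min_p = max_taxon_chi2(counts, part)
        return BinPartition(part, min_p)

    rng = np.random.default_rng(seed)
    best_stat = np.inf
    best_groups: tuple[str, ...] | None = None
    for _ in range(restarts):
        # random assignment guaranteed to populate all k groups
        assign = np.concatenate([
            np.arange(k), rng.integers(0, k, size=len(states) - k)
        ])
        rng.shuffle(assign)
        stat, assign = _greedy_descent(counts, assign, k)
        groups = tuple(sorted(
            "".join(states[i] for i in np.where(assign == g)[0])
            for g in range(k)
        ))
        if stat < best_stat - 1e-12 or (
            abs(stat - best_stat) <= 1e-12
            and best_groups is not None
            and groups < best_groups
        ):
            best_stat = stat
            best_groups = groups
    assert best_groups is not None
    _, min_p = max_taxon_chi2(counts, best_groups)
    return BinPartition(best_groups, min_p)


def select_bin_count(
    al: MultipleAlignment,
    k_max: int,
    alpha: float = 0.05,
    seed: int = 0,
    restarts: int = 50,
) -> tuple[int, dict[int, BinPartition]]:
    """Largest bin count whose minmax partition has min p-value above alpha.

    Scans k from ``k_max`` down to 2 and returns ``(k*, partitions_by_k)``;
    if no k qualifies, returns 1 with a warning (all states in one bin).
    """
    results: dict[int, BinPartition] = {}
    for k in range(k_max, 1, -1):
        part = find_minmax_bins(al, k, seed=seed, restarts=restarts)
        results[k] = part
        if part.min_p > alpha:
            return k, results
    warnings.warn(
        f"no bin count in [2, {k_max}] attains min p-value > {alpha}; "
        "returning a single bin", stacklevel=2,
    )
    return 1, results
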