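"""Sitewise rate estimation on a fixed tree and fast-site removal.

Per-site likelihoods come from Felsenstein's pruning algorithm run once per
discrete-gamma category; the sitewise rate is the posterior mean of the
category rates,

    r_hat(s) = sum_g r_g w_g L(s|g) / sum_g w_g L(s|g).

Saturation reduction removes the round(q * L) highest-rate columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MISSING, MultipleAlignment
from .models import SubstitutionModel


def read_tree(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    """Newick tree with branch lengths (expected substitutions/site)."""
    if isinstance(source, dendropy.Tree):
        return source
    text = str(source)
    if "(" in text and ";" in text:
        return dendropy.Tree.get(data=text, schema="newick")
    return dendropy.Tree.get(path=text, schema="newick")


def _leaf_partials(al: MultipleAlignment, model: SubstitutionModel) -> dict[str, np.ndarray]:
    """Per-taxon (n_sites x n_states) indicator partials; gap/missing -> all ones."""
    idx = {s: i for i, s in enumerate(model.states)}
    out = {}
    for t, row in zip(al.taxa, al.matrix):
        p = np.zeros((al.n_columns, model.n_states))
        for j, ch in enumerate(row):
            if ch in idx:
                p[j, idx[ch]] = 1.0
            else:
                p[j, :] = 1.0
        out[t] = p
    return out


@dataclass
class SiteRateProfile:
    """Per-site per-category log-likelihoods plus the model that made them."""

    log_likelihoods: np.ndarray  # (n_sites, n_categories)
    model: SubstitutionModel
    all_gap: np.ndarray          # boolean mask of uninformative columns


def site_likelihoods(
    al: MultipleAlignment,
    tree: dendropy.Tree | str | Path,
    model: SubstitutionModel,
) -> SiteRateProfile:
    """Pruning-algorithm likelihood of every site under every rate category.

    The tree's leaves must cover the alignment taxa; the root is the tree's
    seed node with the model's stationary frequencies (re-rooting does not
    change the likelihood for a reversible model).  Computation is in
    linear space with per-node log scaling, stable for long trees.
    """
    tree = read_tree(tree)
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(al.taxa) - leaf_names
    if missing:
        raise ValueError(f"tree lacks leaves for taxa: {sorted(missing)}")
    partials = _leaf_partials(al, model)
    n_sites = al.n_columns
    rates = model.category_rates
    loglik = np.empty((n_sites, len(rates)))
    all_gap = np.array([
        all(ch not in model.states for ch in al.matrix[:, j])
        for j in range(n_sites)
    ])

    for g, r in enumerate(rates):
        node_partial: dict[int, np.ndarray] = {}
        node_scale: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node_partial[id(node)] = partials[node.taxon.label]
                node_scale[id(node)] = np.zeros(n_sites)
                continue
            prod = np.ones((n_sites, model.n_states))
            scale = np.zeros(n_sites)
            for child in node.child_nodes():
                t = (child.edge.length or 0.0) * r
                p = model.transition_matrix(t)
                prod *= node_partial[id(child)] @ p.T
                scale += node_scale[id(child)]
            mx = prod.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            node_partial[id(node)] = prod / mx[:, None]
            node_scale[id(node)] = scale + np.log(mx)
        root = tree.seed_node
        site_l = node_partial[id(root)] @ model.frequencies
        loglik[:, g] = np.log(np.where(site_l > 0, site_l, 1e-300)) + node_scale[id(root)]
    return SiteRateProfile(loglik, model, all_gap)


def posterior_mean_rates(profile: SiteRateProfile) -> np.ndarray:
    """Posterior-mean site rates; all-gap columns are NaN (undefined)."""
    model = profile.model
    ll = profile.log_likelihoods
    w = np.log(model.category_weights)
    post = ll + w[None, :]
    post -= post.max(axis=1, keepdims=True)
    post = np.exp(post)
    post /= post.sum(axis=1, keepdims=True)
    rates = post @ model.category_rates
    rates[profile.all_gap] = np.nan
    return rates


def ml_category_rates(profile: SiteRateProfile) -> np.ndarray:
    """Alternative estimator: the single best-supported category rate per site."""
    ll = profile.log_likelihoods + np.log(profile.model.category_weights)[None, :]
    rates = profile.model.category_rates[np.argmax(ll, axis=1)]
    rates = rates.astype(float)
    rates[profile.all_gap] = np.nan
    return rates


def remove_fast_sites(
    al: MultipleAlignment, rates: np.ndarray, fraction: float
) -> tuple[MultipleAlignment, list[int]]:
    """Drop the round(q * L) highest-rate columns; survivors keep their order.

    Ties at the cutoff are broken by keeping the leftmost columns; undefined
    (NaN) rates are treated as slowest and never preferentially removed.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (al.n_columns,):
        raise ValueError("need exactly one rate per alignment column")
    n_remove = int(round(fraction * al.n_columns))
    if n_remove == 0:
        return al, []
    key = np.where(np.isnan(rates), -np.inf, rates)
    # sort by descending rate, rightmost first among ties -> leftmost kept
    order = sorted(range(al.n_columns), key=lambda i: (-key[i], -i))
    removed = sorted(order[:n_remove])
    keep = sorted(set(range(al.n_columns)) - set(removed))
    return al.take_columns(keep), removed


def estimate_gamma_shape(
    al: MultipleAlignment,
    tree: dendropy.Tree | str | Path,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.05, 20.0),
) -> float:
    """Direct-search ML estimate of the gamma shape on a fixed tree."""
    tree = read_tree(tree)

    def neg_loglik(alpha: float) -> float:
        m = SubstitutionModel(
            model.states, model.exchangeabilities, model.frequencies,
            alpha=alpha, n_categories=model.n_categories,
        )
        prof = site_likelihoods(al, tree, m)
        w = np.log(m.category_weights)
        site = prof.log_likelihoods + w[None, :]
        mx = site.max(axis=1, keepdims=True)
        return -float((np.log(np.exp(site - mx).sum(axis=1)) + mx[:, 0]).sum())

    res = minimize_scalar(neg_loglik, bounds=bounds, method="bounded")
    return float(res.x)
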