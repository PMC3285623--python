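"""Reversible substitution models with discrete-gamma rate variation.

A model is an exchangeability matrix S (symmetric, zero diagonal) and
stationary frequencies pi; the generator is Q_ij = S_ij * pi_j with rows
summing to zero, scaled so the mean substitution rate at stationarity is 1.
Among-site rate variation uses G equiprobable gamma categories represented
by their category means (shape alpha, mean 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Category-mean rates of the discretized gamma(alpha) distribution.

    Boundaries are the i/G quantiles of gamma(shape=alpha, mean 1); each
    category rate is the conditional mean within its interval, so the
    weighted mean rate is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    g = n_categories
    if g == 1:
        return np.ones(1)
    bounds = stats.gamma.ppf(np.arange(1, g) / g, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([special.gammainc(alpha + 1, alpha * bounds), [1.0]])
    lower = np.concatenate([[0.0], special.gammainc(alpha + 1, alpha * bounds)])
    return g * (upper - lower)


@dataclass
class SubstitutionModel:
    """Reversible rate matrix over ``states`` plus discrete-gamma categories."""

    states: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = None
    n_categories: int = 1
    _decomp: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.states)
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (n, n):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if pi.shape != (n,) or np.any(pi < 0):
            raise ValueError("invalid stationary frequencies")
        if not np.isclose(pi.sum(), 1.0):
            raise ValueError("stationary frequencies must sum to 1")
        self.exchangeabilities = s
        self.frequencies = pi

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def category_rates(self) -> np.ndarray:
        if self.n_categories == 1 or self.alpha is None:
            return np.ones(max(self.n_categories, 1))
        return discrete_gamma_rates(self.alpha, self.n_categories)

    @property
    def category_weights(self) -> np.ndarray:
        g = max(self.n_categories, 1)
        return np.full(g, 1.0 / g)

    def rate_matrix(self) -> np.ndarray:
        """Generator Q, calibrated to one expected substitution per unit time."""
        pi = self.frequencies
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        return q / scale

    def _eigen(self):
        # reversible Q is similar to a symmetric matrix via diag(sqrt(pi))
        if self._decomp is None:
            pi = np.where(self.frequencies > 0, self.frequencies, 1e-300)
            q = self.rate_matrix()
            d = np.sqrt(pi)
            b = (q * d[:, None]) / d[None, :]
            lam, u = np.linalg.eigh((b + b.T) / 2.0)
            left = u.T * d[None, :]      # U^T diag(d)
            right = u / d[:, None]       # diag(1/d) U
            self._decomp = (lam, right, left)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the symmetric eigendecomposition."""
        lam, right, left = self._eigen()
        p = (right * np.exp(lam * t)[None, :]) @ left
        return np.clip(p, 0.0, None)

    # -- constructors ----------------------------------------------------
    @classmethod
    def jukes_cantor(cls, states: str = "ACGT", **kw) -> "SubstitutionModel":
        n = len(states)
        s = np.ones((n, n)) - np.eye(n)
        return cls(states, s, np.full(n, 1.0 / n), **kw)

    @classmethod
    def gtr(
        cls,
        frequencies,
        rates=None,
        states: str = "ACGT",
        **kw,
    ) -> "SubstitutionModel":
        """General time-reversible model; ``rates`` are the 6 upper-triangle
        exchangeabilities in order (AC, AG, AT, CG, CT, GT), default all 1."""
        n = len(states)
        s = np.zeros((n, n))
        vals = np.ones(n * (n - 1) // 2) if rates is None else np.asarray(rates, float)
        iu = np.triu_indices(n, 1)
        s[iu] = vals
        s += s.T
        return cls(states, s, np.asarray(frequencies, float), **kw)

    @classmethod
    def from_config(cls, path, states: str = "ACGT") -> "SubstitutionModel":
        """Plain-text key=value model file: freqs, rates, alpha, categories."""
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
        freqs = [float(x) for x in kv["freqs"].split(",")]
        rates = [float(x) for x in kv["rates"].split(",")] if "rates" in kv else None
        alpha = float(kv["alpha"]) if "alpha" in kv else None
        g = int(kv.get("categories", 1))
        return cls.gtr(freqs, rates, states=states, alpha=alpha, n_categories=g)
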