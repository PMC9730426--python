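"""Time-reversible substitution models with discrete-Γ (+I) rate mixtures.

The model family is GTR+Γ(+I) for nucleotides and a fixed-exchangeability
(default Poisson) +Γ(+I) model for amino acids. The rate matrix is built
from exchangeabilities and stationary frequencies, scaled to one expected
substitution per site at stationarity, and exponentiated through the
symmetrised eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from plastconflict.core import Alphabet


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete-Γ categories (mean 1).

    Category boundaries are the i/k quantiles of Γ(α, scale=1/α); the mean
    within each bin follows from the incomplete-gamma identity
    E[X·1{X<b}] = P(α+1, αb) for X ~ Γ(α, 1/α).
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k == 1 or alpha >= 1e5:
        # relative rate spread < 0.5%: numerically rate-homogeneous
        return np.ones(k)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * bounds)])
    rates = k * (upper - lower)
    # guard against ppf round-off at extreme alpha
    rates = np.clip(rates, 1e-12, None)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible S-state model: exchangeabilities × frequencies, Γ(+I) rates.

    ``exchangeabilities`` is a symmetric S×S matrix with positive
    off-diagonal entries (the diagonal is ignored); ``frequencies`` sum to
    one. ``alpha`` is the Γ shape with ``n_categories`` discrete categories;
    ``p_inv`` an invariant-site proportion in [0, 1).
    """

    alphabet: Alphabet
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    n_categories: int = 4
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        s = self.n_states
        if self.exchangeabilities.shape != (s, s):
            raise ValueError("exchangeability matrix has wrong shape")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeability matrix must be symmetric")
        off = self.exchangeabilities[~np.eye(s, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal exchangeabilities must be positive")
        if self.frequencies.shape != (s,) or np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        self.frequencies = self.frequencies / self.frequencies.sum()
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")

    # ------------------------------------------------------------- builders

    @classmethod
    def jc(cls, alpha: float = 1.0, n_categories: int = 1, p_inv: float = 0.0):
        return cls(
            alphabet=Alphabet.NT,
            exchangeabilities=np.ones((4, 4)),
            frequencies=np.full(4, 0.25),
            alpha=alpha,
            n_categories=n_categories,
            p_inv=p_inv,
        )

    @classmethod
    def gtr(
        cls,
        rates,
        frequencies,
        alpha: float = 1.0,
        n_categories: int = 4,
        p_inv: float = 0.0,
    ):
        """GTR from the 6 upper-triangle rates (AC, AG, AT, CG, CT, GT)."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (6,):
            raise ValueError("GTR needs 6 exchangeability rates")
        ex = np.zeros((4, 4))
        ex[np.triu_indices(4, 1)] = rates
        ex = ex + ex.T
        return cls(
            alphabet=Alphabet.NT,
            exchangeabilities=ex,
            frequencies=frequencies,
            alpha=alpha,
            n_categories=n_categories,
            p_inv=p_inv,
        )

    @classmethod
    def poisson_aa(
        cls,
        frequencies=None,
        alpha: float = 1.0,
        n_categories: int = 4,
        p_inv: float = 0.0,
    ):
        """Equal-exchangeability amino-acid model with optional frequencies."""
        if frequencies is None:
            frequencies = np.full(20, 0.05)
        return cls(
            alphabet=Alphabet.AA,
            exchangeabilities=np.ones((20, 20)),
            frequencies=frequencies,
            alpha=alpha,
            n_categories=n_categories,
            p_inv=p_inv,
        )

    @classmethod
    def aa_from_paml(cls, path, alpha: float = 1.0, n_categories: int = 4):
        """Load a PAML-format empirical AA rate file (190 rates + 20 freqs)."""
        values: list[float] = []
        with open(path) as fh:
            for line in fh:
                values.extend(float(x) for x in line.split())
        if len(values) < 210:
            raise ValueError("PAML rate file needs 190 exchangeabilities + 20 frequencies")
        ex = np.zeros((20, 20))
        k = 0
        for i in range(1, 20):
            for j in range(i):
                ex[i, j] = ex[j, i] = values[k]
                k += 1
        freqs = np.asarray(values[190:210])
        return cls(
            alphabet=Alphabet.AA,
            exchangeabilities=ex,
            frequencies=freqs / freqs.sum(),
            alpha=alpha,
            n_categories=n_categories,
        )

    # ------------------------------------------------------------ structure

    @property
    def n_states(self) -> int:
        return 4 if self.alphabet == Alphabet.NT else 20

    def q_matrix(self) -> np.ndarray:
        """Scaled rate matrix: rows sum to zero, mean rate 1 at stationarity."""
        q = self.exchangeabilities * self.frequencies[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.frequencies, np.diag(q))
        return q / mu

    @cached_property
    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, A, B) with P(t) = A @ diag(exp(λt)) @ B."""
        pi = self.frequencies
        sqrt_pi = np.sqrt(pi)
        q = self.q_matrix()
        sym = sqrt_pi[:, None] * q / sqrt_pi[None, :]
        vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
        a = vecs / sqrt_pi[:, None]
        b = vecs.T * sqrt_pi[None, :]
        return vals, a, b

    @cached_property
    def category_rates(self) -> np.ndarray:
        """Mixture rates including the invariant category when p_inv > 0.

        Γ means are divided by (1 − p_inv) so the weighted mean rate is 1.
        """
        g = discrete_gamma_rates(self.alpha, self.n_categories)
        if self.p_inv > 0:
            return np.concatenate([[0.0], g / (1.0 - self.p_inv)])
        return g

    @cached_property
    def category_weights(self) -> np.ndarray:
        w = np.full(self.n_categories, 1.0 / self.n_categories)
        if self.p_inv > 0:
            return np.concatenate([[self.p_inv], (1.0 - self.p_inv) * w])
        return w

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t·r_k) for every mixture category; shape (K, S, S)."""
        vals, a, b = self._eigen
        rates = self.category_rates
        s = self.n_states
        out = np.empty((len(rates), s, s))
        for k, r in enumerate(rates):
            if r == 0.0 or t == 0.0:
                out[k] = np.eye(s)
            else:
                out[k] = (a * np.exp(vals * t * r)[None, :]) @ b
        np.clip(out, 0.0, 1.0, out=out)
        return out

    def replace(self, **kwargs) -> "SubstitutionModel":
        params = dict(
            alphabet=self.alphabet,
            exchangeabilities=self.exchangeabilities,
            frequencies=self.frequencies,
            alpha=self.alpha,
            n_categories=self.n_categories,
            p_inv=self.p_inv,
        )
        params.update(kwargs)
        return SubstitutionModel(**params)

    def gtr_rates(self) -> np.ndarray:
        """Upper-triangle exchangeabilities, normalised so the last is 1."""
        s = self.n_states
        r = self.exchangeabilities[np.triu_indices(s, 1)]
        return r / r[-1]
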