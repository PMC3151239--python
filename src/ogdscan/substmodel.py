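"""JTT amino-acid substitution model with discrete-gamma rate heterogeneity.

The rate matrix Q is the reversible matrix built from the published JTT
exchangeabilities S and stationary frequencies pi (Q_ij = S_ij * pi_j),
normalised so that one unit of branch length equals one expected
substitution per site at stationarity: -sum_i pi_i Q_ii = 1.

Frequencies are either the model's own published values or empirical
("+F") frequencies counted from the alignment; empirical counting is the
default for per-family scans, matching common practice for protein data.
Rate heterogeneity across sites uses Yang's discrete-gamma scheme: ncat
equal-probability categories, each represented by its conditional mean
rate, with overall mean rate 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._jtt_data import AA_ORDER, JTT_FREQUENCIES, JTT_LOWER_TRIANGLE

__all__ = [
    "AA_ORDER",
    "SubstitutionModel",
    "RateModel",
    "jtt_model",
    "discrete_gamma",
    "transition_probabilities",
    "empirical_frequencies",
]

N_STATES = 20
FREQ_FLOOR = 1e-6  # pseudo-count floor keeping Q irreducible under "+F"


def _exchangeabilities() -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(JTT_LOWER_TRIANGLE, start=1):
        for j, val in enumerate(row):
            s[i, j] = s[j, i] = val
    return s


@dataclass
class SubstitutionModel:
    """Normalised reversible rate matrix and its spectral decomposition."""

    q: np.ndarray
    pi: np.ndarray
    # eigendecomposition of the symmetrised generator, for fast P(t)
    _evals: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)  # pi^-1/2 U
    _left: np.ndarray = field(repr=False, default=None)  # U^T pi^1/2

    def __post_init__(self) -> None:
        if self._evals is None:
            sqrt_pi = np.sqrt(self.pi)
            # D^{1/2} Q D^{-1/2} is symmetric by detailed balance
            sym = (self.q * sqrt_pi[:, None]) / sqrt_pi[None, :]
            sym = (sym + sym.T) / 2.0  # enforce exact symmetry against round-off
            evals, u = np.linalg.eigh(sym)
            self._evals = evals
            self._right = u / sqrt_pi[:, None]
            self._left = u.T * sqrt_pi[None, :]

    def p_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); clipped to [0, 1] against round-off."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        p = (self._right * np.exp(self._evals * t)[None, :]) @ self._left
        np.clip(p, 0.0, 1.0, out=p)
        return p


@dataclass
class RateModel:
    """Discrete-gamma site-rate categories (equal probability, mean rate 1)."""

    alpha: Optional[float]
    rates: np.ndarray

    @property
    def ncat(self) -> int:
        return len(self.rates)


def jtt_model(frequencies: Union[str, Sequence[float]] = "model") -> SubstitutionModel:
    """Build the normalised JTT rate matrix.

    ``frequencies`` is either ``"model"`` (published JTT frequencies) or a
    length-20 vector of empirical frequencies in :data:`AA_ORDER` order.
    """
    if isinstance(frequencies, str):
        if frequencies != "model":
            raise ValueError("frequencies must be 'model' or a 20-vector")
        pi = np.asarray(JTT_FREQUENCIES, dtype=float)
    else:
        pi = np.asarray(frequencies, dtype=float)
        if pi.shape != (N_STATES,):
            raise ValueError("empirical frequencies must have 20 entries")
        if np.any(pi <= 0):
            raise ValueError("frequencies must be strictly positive")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError("frequencies must sum to 1")
    pi = pi / pi.sum()
    s = _exchangeabilities()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    q = q / scale
    return SubstitutionModel(q=q, pi=pi)


def discrete_gamma(alpha: float, ncat: int) -> RateModel:
    """Yang-style mean-per-category discretisation of Gamma(alpha, 1/alpha)."""
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return RateModel(alpha=alpha, rates=np.ones(1))
    probs = np.arange(1, ncat) / ncat
    cut = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cut, [np.inf]])
    # mean rate within each category: ncat * [I(alpha+1, b*alpha) - I(alpha+1, a*alpha)]
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    rates = ncat * (upper - lower)
    rates = rates / rates.mean()  # guard against ppf round-off; analytically 1
    return RateModel(alpha=alpha, rates=rates)


def uniform_rates() -> RateModel:
    """Single-category (no heterogeneity) rate model."""
    return RateModel(alpha=None, rates=np.ones(1))


def transition_probabilities(
    model: SubstitutionModel, t: float, rate: float = 1.0
) -> np.ndarray:
    """P = exp(Q * t * rate); rows sum to 1, entries nonnegative."""
    return model.p_matrix(t * rate)


def empirical_frequencies(alignment, floor: float = FREQ_FLOOR) -> np.ndarray:
    """Observed amino-acid proportions, gaps/ambiguities excluded.

    Zero counts are floored at a small pseudo-frequency and the vector is
    renormalised, so the resulting "+F" model stays irreducible.
    ``alignment`` is an :class:`ogdscan.likelihood.AlignmentMatrix` or any
    object with a ``state_matrix`` attribute of integer states (20 = missing).
    """
    states = np.asarray(alignment.state_matrix)
    counts = np.bincount(states[states < N_STATES].ravel(), minlength=N_STATES).astype(
        float
    )
    if counts.sum() == 0:
        raise ValueError("alignment has no unambiguous residues")
    pi = counts / counts.sum()
    pi = np.maximum(pi, floor)
    return pi / pi.sum()
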