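"""General time-reversible (GTR) nucleotide substitution model.

The model is parameterised by six symmetric exchangeability rates
(AC, AG, AT, CG, CT, GT; GT fixed to 1 as the reference rate) and the
equilibrium base frequencies pi.  The rate matrix is normalised to one
expected substitution per unit branch length, so branch lengths are in
substitutions/site.  Transition probabilities are obtained from the
eigendecomposition of the similarity-transformed symmetric matrix, which is
numerically stable and lets P(t) be written as ``sum_k A[:,:,k] exp(lam_k t)``
— the form the placement kernels exploit.

States are encoded A=0, C=1, G=2, T=3; code 4 means missing data (gaps,
N and other ambiguity codes), which contributes a flat partial likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NSTATES = 4
MISSING = 4
_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_TO_BASE = "ACGT"

# (i, j) index pairs for the exchangeability vector order AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 state codes (missing = 4)."""
    out = np.full(len(seq), MISSING, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _BASE_TO_CODE.get(ch, MISSING)
    return out


@dataclass
class GTRModel:
    rates: np.ndarray  # (6,) AC, AG, AT, CG, CT, GT
    pi: np.ndarray     # (4,)
    # eigendecomposition of the normalised rate matrix, filled in __post_init__
    eigvals: np.ndarray = field(init=False, repr=False)   # (4,)
    basis: np.ndarray = field(init=False, repr=False)     # (4,4,4): P(t) = basis @ exp(eig t)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates < 0):
            raise ValueError("rates must be six non-negative exchangeabilities")
        if self.pi.shape != (4,) or np.any(self.pi <= 0):
            raise ValueError("pi must be four positive frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-12:  # keep normalisation idempotent
            self.pi = self.pi / self.pi.sum()
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _PAIRS):
            Q[i, j] = r * self.pi[j]
            Q[j, i] = r * self.pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(self.pi, np.diag(Q))
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        Q /= scale
        self._Q = Q
        # symmetrise: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sq = np.sqrt(self.pi)
        B = (Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self.eigvals = lam
        # P(t)[x,y] = sum_k basis[x,y,k] exp(lam_k t)
        left = V / sq[:, None]          # (x, k)
        right = V * sq[:, None]         # (y, k)
        self.basis = np.einsum("xk,yk->xyk", left, right)

    @classmethod
    def jukes_cantor(cls) -> "GTRModel":
        return cls(rates=np.ones(6), pi=np.full(4, 0.25))

    @property
    def Q(self) -> np.ndarray:
        return self._Q

    def transition(self, t: float) -> np.ndarray:
        """Transition probability matrix P(t); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = self.basis @ np.exp(self.eigvals * t)
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def to_dict(self) -> dict:
        return {"rates": self.rates.tolist(), "pi": self.pi.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GTRModel":
        return cls(rates=np.array(d["rates"]), pi=np.array(d["pi"]))


def empirical_frequencies(encoded_rows: np.ndarray) -> np.ndarray:
    """Base frequencies over all non-missing cells, with a small floor."""
    counts = np.bincount(
        encoded_rows[encoded_rows < NSTATES].ravel(), minlength=NSTATES
    ).astype(float)
    counts = np.maximum(counts, 1.0)
    return counts / counts.sum()


def tip_partials(states: np.ndarray) -> np.ndarray:
    """(ncols, 4) partial likelihoods for one encoded sequence."""
    ncols = states.shape[0]
    F = np.zeros((ncols, NSTATES))
    obs = states < NSTATES
    F[obs, states[obs]] = 1.0
    F[~obs, :] = 1.0
    return F


def pairwise_loglik(sa: np.ndarray, sb: np.ndarray, t: float, model: GTRModel) -> float:
    """Log-likelihood of two aligned sequences at divergence t."""
    P = model.transition(t)
    Fa = tip_partials(sa)
    Fb = tip_partials(sb)
    site = np.einsum("x,cx,xy,cy->c", model.pi, Fa, P, Fb)
    return float(np.sum(np.log(np.maximum(site, 1e-300))))


def ml_pairwise_distance(
    sa: np.ndarray, sb: np.ndarray, model: GTRModel, t_max: float = 10.0
) -> float:
    """Maximum-likelihood divergence between two aligned encoded sequences."""
    from scipy.optimize import minimize_scalar

    both = (sa < NSTATES) & (sb < NSTATES)
    if not np.any(both) or np.all(sa[both] == sb[both]):
        return 0.0
    res = minimize_scalar(
        lambda t: -pairwise_loglik(sa, sb, t, model),
        bounds=(1e-9, t_max),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
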