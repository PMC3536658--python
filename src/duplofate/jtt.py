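"""Jones-Taylor-Thornton (JTT) empirical amino-acid substitution model.

The JTT model is a time-reversible Markov model on the 20 amino acids,
parameterized by a symmetric exchangeability matrix (observed accepted
point mutation counts) and the equilibrium amino-acid frequencies
published with the model.  The instantaneous rate matrix is

    Q[i, j] = s[i, j] * pi[j]   (i != j),

with rows rescaled so that the expected number of substitutions per
site per unit time equals one (-sum_i pi_i Q_ii = 1).  Distances are
therefore expressed in expected substitutions per site.

Transition probabilities P(t) = expm(Q t) are computed once per call via
the symmetric eigendecomposition of pi^(1/2) Q pi^(-1/2), which is exact
and cheap for a 20-state chain.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Amino acids in the conventional order of the published model tables.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Published JTT equilibrium frequencies (same order as AMINO_ACIDS).
_JTT_FREQS = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803,
    0.040752, 0.061830, 0.073152, 0.022944, 0.053761,
    0.091904, 0.058676, 0.023826, 0.040126, 0.050901,
    0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])
_JTT_FREQS = _JTT_FREQS / _JTT_FREQS.sum()

# Published JTT exchangeability counts, lower triangle in column-major
# order: s(2,1), s(3,1), ..., s(20,1), s(3,2), s(4,2), ...
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475,
    9, 11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74,
    101, 64, 126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10,
    15, 503, 232, 8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15,
    59, 38, 4, 46, 31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115,
    209, 62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20,
    119, 26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14,
    5, 24, 201, 33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573,
    11, 229, 21, 479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59,
    25, 52, 24, 180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24,
    18, 323, 17, 92, 12, 53, 536, 62, 285, 118, 6, 10, 23, 477, 35, 63,
    38, 12, 21, 112, 71, 25, 16,
]


def equilibrium_frequencies() -> np.ndarray:
    """Return a copy of the JTT equilibrium frequency vector pi."""
    return _JTT_FREQS.copy()


def rate_matrix() -> np.ndarray:
    """Build the normalized JTT instantaneous rate matrix Q (20 x 20)."""
    n = 20
    s = np.zeros((n, n))
    k = 0
    for j in range(n - 1):
        for i in range(j + 1, n):
            s[i, j] = s[j, i] = _JTT_LOWER[k]
            k += 1
    q = s * _JTT_FREQS[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # one expected substitution per site per unit time
    scale = -(_JTT_FREQS * np.diag(q)).sum()
    return q / scale


@lru_cache(maxsize=1)
def _eigendecomposition() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition of Q for exact matrix exponentials.

    For a reversible chain, B = D Q D^-1 with D = diag(sqrt(pi)) is
    symmetric; expm(Q t) = D^-1 U exp(L t) U' D.
    """
    q = rate_matrix()
    d = np.sqrt(_JTT_FREQS)
    b = (d[:, None] * q) / d[None, :]
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    left = eigvec / d[:, None]      # D^-1 U
    right = eigvec.T * d[None, :]   # U' D
    return eigval, left, right


def transition_matrix(t: float) -> np.ndarray:
    """Transition probabilities P(t) = expm(Q t) for branch length t >= 0."""
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    eigval, left, right = _eigendecomposition()
    p = (left * np.exp(eigval * t)[None, :]) @ right
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


def encode(sequence: str) -> np.ndarray:
    """Map an amino-acid string to integer states; -1 marks gaps/unknowns."""
    return np.array([_AA_INDEX.get(ch, -1) for ch in sequence.upper()],
                    dtype=np.int64)


def decode(states: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in states)


def sample_equilibrium(length: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an ancestral sequence (integer states) from pi."""
    return rng.choice(20, size=length, p=_JTT_FREQS)


def evolve(states: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve integer states along a branch of length t substitutions/site."""
    p = transition_matrix(t)
    cum = np.cumsum(p, axis=1)
    u = rng.random(states.shape[0])
    return (u[:, None] > cum[states]).sum(axis=1)
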