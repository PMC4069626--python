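"""Codon substitution model: genetic code, frequencies, rate matrix, P(t).

The model is the one-ratio (M0) codon model: substitution between sense
codons happens one nucleotide at a time, at a rate proportional to the
target codon's equilibrium frequency, multiplied by the
transition/transversion rate ratio ``kappa`` when the nucleotide change is
a transition and by the nonsynonymous/synonymous rate ratio ``omega`` when
the codon change alters the encoded amino acid.  Stop codons are excluded,
so the state space has 61 codons under the standard genetic code.

The generator Q is scaled so that the total substitution rate at
equilibrium is one, i.e. the divergence ``t`` between two sequences counts
expected nucleotide substitutions per codon.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if a != b and the pair is A<->G or C<->T."""
    if a == b:
        return False
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


class GeneticCode:
    """The standard nuclear genetic code over the 61 sense codons.

    Codons are ordered by position-wise TCAG rank (the conventional codon
    table order) with the three stop codons removed.
    """

    def __init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[1]
        self.stop_codons = tuple(sorted(table.stop_codons))
        self.sense_codons: tuple[str, ...] = tuple(
            "".join(c)
            for c in itertools.product(NUCLEOTIDES, repeat=3)
            if "".join(c) not in table.stop_codons
        )
        self.aa_of: dict[str, str] = {c: table.forward_table[c] for c in self.sense_codons}
        self.index: dict[str, int] = {c: k for k, c in enumerate(self.sense_codons)}
        self.n_states = len(self.sense_codons)
        self._build_neighbor_arrays()

    is_transition = staticmethod(is_transition)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_synonymous(self, c1: str, c2: str) -> bool:
        return self.aa_of[c1] == self.aa_of[c2]

    def _build_neighbor_arrays(self) -> None:
        # Precompute all ordered sense-codon pairs that differ at exactly
        # one position; these are the only nonzero off-diagonal rates.
        rows, cols, ts, syn = [], [], [], []
        for i, ci in enumerate(self.sense_codons):
            for j, cj in enumerate(self.sense_codons):
                if i == j:
                    continue
                diff = [p for p in range(3) if ci[p] != cj[p]]
                if len(diff) != 1:
                    continue
                p = diff[0]
                rows.append(i)
                cols.append(j)
                ts.append(is_transition(ci[p], cj[p]))
                syn.append(self.aa_of[ci] == self.aa_of[cj])
        self._nbr_i = np.asarray(rows, dtype=np.intp)
        self._nbr_j = np.asarray(cols, dtype=np.intp)
        self._nbr_ts = np.asarray(ts, dtype=bool)
        self._nbr_syn = np.asarray(syn, dtype=bool)


# Module-level singleton: the model is specified for the standard code only.
STANDARD_CODE = GeneticCode()


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium codon frequencies pi over the 61 sense codons."""

    pi: np.ndarray
    model_tag: str  # "Fequal" or "F61"

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (STANDARD_CODE.n_states,):
            raise ValueError(f"pi must have {STANDARD_CODE.n_states} entries")
        if np.any(pi < 0) or not np.isfinite(pi).all():
            raise ValueError("codon frequencies must be finite and nonnegative")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must sum to 1")

    @classmethod
    def equal(cls) -> "CodonFrequencies":
        n = STANDARD_CODE.n_states
        return cls(np.full(n, 1.0 / n), "Fequal")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "CodonFrequencies":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("no codon counts")
        return cls(counts / total, "F61")


class SpectralDecomposition:
    """Eigendecomposition of a reversible codon rate matrix.

    Reversibility lets Q be symmetrized as ``Pi^(1/2) Q Pi^(-1/2)``, giving
    a real symmetric eigenproblem.  When some pi entries are zero (F61 with
    unobserved codons) the decomposition is restricted to the support of
    pi; states outside the support never occur in the data.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray) -> None:
        self.support = np.flatnonzero(pi > 0)
        s = self.support
        sqrt_pi = np.sqrt(pi[s])
        A = Q[np.ix_(s, s)] * (sqrt_pi[:, None] / sqrt_pi[None, :])
        A = 0.5 * (A + A.T)
        lam, U = np.linalg.eigh(A)
        self.eigenvalues = lam
        self._U = U
        self._sqrt_pi = sqrt_pi
        self._pi = pi
        self._n_full = Q.shape[0]
        # B[i, k] = sqrt(pi_i) U_ik, so pi_i P_ij(t) = sum_k B_ik B_jk e^(lam_k t)
        self.B = sqrt_pi[:, None] * U

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) on the full state space (identity off-support)."""
        if t < 0:
            raise ValueError("t must be nonnegative")
        s = self.support
        elam = np.exp(self.eigenvalues * t)
        core = (self._U * elam) @ self._U.T
        P_s = core * (self._sqrt_pi[None, :] / self._sqrt_pi[:, None])
        P = np.eye(self._n_full)
        P[np.ix_(s, s)] = P_s
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def joint_probabilities(self, t: float) -> np.ndarray:
        """Symmetric matrix pi_i P_ij(t) on the support."""
        elam = np.exp(self.eigenvalues * t)
        return (self.B * elam) @ self.B.T


@dataclass
class CodonModel:
    """A parameterized, scaled codon rate matrix."""

    code: GeneticCode
    freqs: CodonFrequencies
    kappa: float
    omega: float
    Q: np.ndarray
    scale: float
    _decomp: SpectralDecomposition | None = field(default=None, repr=False)

    @property
    def pi(self) -> np.ndarray:
        return self.freqs.pi

    @property
    def decomposition(self) -> SpectralDecomposition:
        if self._decomp is None:
            self._decomp = spectral_decompose(self)
        return self._decomp


def build_rate_matrix(
    freqs: CodonFrequencies, kappa: float, omega: float
) -> CodonModel:
    """Construct the scaled 61x61 codon rate matrix.

    Off-diagonal rates: 0 for codon pairs differing at more than one
    position; otherwise pi_j, times kappa for a transition and times omega
    for a nonsynonymous change.  Rows sum to zero and the matrix is divided
    by the mean rate so that -sum_i pi_i q_ii = 1.
    """
    if not np.isfinite(kappa) or kappa < 0:
        raise ValueError(f"kappa must be finite and nonnegative, got {kappa}")
    if not np.isfinite(omega) or omega < 0:
        raise ValueError(f"omega must be finite and nonnegative, got {omega}")
    code = STANDARD_CODE
    pi = freqs.pi
    n = code.n_states
    Q = np.zeros((n, n))
    rate = pi[code._nbr_j].copy()
    rate[code._nbr_ts] *= kappa
    rate[~code._nbr_syn] *= omega
    Q[code._nbr_i, code._nbr_j] = rate
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    scale = -float(pi @ np.diag(Q))
    if scale <= 0:
        # Degenerate corner (e.g. omega = kappa = 0 leaves no permitted
        # change); keep the unscaled zero matrix.
        scale = 1.0
    Q /= scale
    return CodonModel(code=code, freqs=freqs, kappa=kappa, omega=omega, Q=Q, scale=scale)


def spectral_decompose(model: CodonModel) -> SpectralDecomposition:
    """Eigendecomposition of the model's rate matrix for fast exp(Qt)."""
    decomp = SpectralDecomposition(model.Q, model.pi)
    # Verify the decomposition reproduces Q on its support; fall back to
    # direct exponentiation only if the eigensolver misbehaved.
    s = decomp.support
    rebuild = (
        (decomp._U * decomp.eigenvalues) @ decomp._U.T
    ) * (decomp._sqrt_pi[None, :] / decomp._sqrt_pi[:, None])
    if not np.allclose(rebuild, model.Q[np.ix_(s, s)], atol=1e-8):
        warnings.warn(
            "spectral decomposition numerically defective; "
            "falling back to direct matrix exponentials",
            RuntimeWarning,
        )
        return None  # caller should use transition_probabilities(..., direct=True)
    return decomp


def transition_probabilities(model: CodonModel, t: float) -> np.ndarray:
    """Transition probability matrix P(t) = exp(Qt).

    Uses the cached spectral decomposition when pi is strictly positive,
    otherwise direct Pade exponentiation on the full matrix (so rows of
    zero-frequency states are still proper distributions).
    """
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"t must be finite and nonnegative, got {t}")
    if np.all(model.pi > 0):
        decomp = model.decomposition
        if decomp is not None:
            return decomp.transition_matrix(t)
    P = scipy.linalg.expm(model.Q * t)
    np.clip(P, 0.0, 1.0, out=P)
    return P
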