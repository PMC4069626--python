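"""Nei–Gojobori (1986) counting estimates of dN, dS and their variances.

These heuristic estimates serve two roles: quick descriptive statistics
reported alongside the likelihood results, and — more importantly — the
source of the location/scale parameters of the logistic change of
variables used by the Bayesian quadrature.  Only orders of magnitude
matter for the latter, so the plain (unweighted-pathway) method suffices.

Sites: each codon position contributes the fraction of its possible
single-nucleotide changes that are synonymous, with changes into stop
codons excluded from the tally.  Differences: codon pairs differing at k
positions are resolved by averaging the synonymous/nonsynonymous split
over all k! orderings of the single-nucleotide steps, skipping pathways
that pass through a stop codon.  Proportions are corrected for multiple
hits with the one-parameter (JC69) formula d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .alignment_io import PairAlignment
from .codon_model import STANDARD_CODE, GeneticCode

#: p-distances at or above this are treated as saturated for variance
#: purposes; the JC69 variance explodes as p approaches 3/4.
SATURATION_GUARD = 0.74


@dataclass
class NGResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # nan when saturated
    dN: float
    var_dS: float
    var_dN: float
    t_hat: float  # expected substitutions per codon implied by (dS, dN)
    omega_hat: float  # dN/dS; nan when undefined
    var_t_hat: float
    var_omega_hat: float  # nan when dS or dN is 0

    @property
    def saturated(self) -> bool:
        return not (math.isfinite(self.dS) and math.isfinite(self.dN))

    @property
    def usable_for_transform(self) -> bool:
        """True when the counting variances can parameterize the logistic
        change of variables: unsaturated, with both distance classes > 0."""
        return (
            self.pS < SATURATION_GUARD
            and self.pN < SATURATION_GUARD
            and math.isfinite(self.dS)
            and math.isfinite(self.dN)
            and self.dS > 0
            and self.dN > 0
        )


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> float:
    """Synonymous site count of one codon (0..3)."""
    code = STANDARD_CODE
    s = 0.0
    for pos in range(3):
        syn = 0
        total = 0
        for nuc in "TCAG":
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if code.is_stop(alt):
                continue
            total += 1
            if code.aa_of[alt] == code.aa_of[codon]:
                syn += 1
        if total:
            s += syn / total
    return s


@lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) contribution of one codon pair, averaged over pathways."""
    if c1 == c2:
        return (0.0, 0.0)
    code = STANDARD_CODE
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    path_results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        valid = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if code.is_stop(nxt):
                valid = False
                break
            if code.aa_of[cur] == code.aa_of[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            path_results.append((sd, nd))
    if not path_results:
        # Every pathway crosses a stop codon (possible only for some 2-3
        # step pairs); fall back to counting steps through stops too.
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0.0
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                aa_cur = code.aa_of.get(cur, "*")
                aa_nxt = code.aa_of.get(nxt, "*")
                if aa_cur == aa_nxt:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            path_results.append((sd, nd))
    k = len(path_results)
    return (
        sum(r[0] for r in path_results) / k,
        sum(r[1] for r in path_results) / k,
    )


def ng_site_counts(aln: PairAlignment, code: GeneticCode = STANDARD_CODE) -> tuple[float, float]:
    """(S, N): synonymous and nonsynonymous site counts, averaged over the
    two sequences.  S + N = 3 L_c."""
    if aln.L_c == 0:
        raise ValueError("empty alignment")
    s1 = s2 = 0.0
    for (a, b), n in aln.patterns.items():
        s1 += n * _codon_site_counts(a)
        s2 += n * _codon_site_counts(b)
    S = 0.5 * (s1 + s2)
    return S, 3.0 * aln.L_c - S


def ng_difference_counts(
    aln: PairAlignment, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """(Sd, Nd): pathway-averaged synonymous/nonsynonymous differences."""
    Sd = Nd = 0.0
    for (a, b), n in aln.patterns.items():
        sd, nd = _codon_pair_differences(a, b)
        Sd += n * sd
        Nd += n * nd
    return Sd, Nd


def jc69_correct(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns nan for p >= 3/4 (saturated; the correction is undefined).
    """
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc69_variance(p: float, sites: float) -> float:
    """Sampling variance of the JC69 distance: 9p(1-p) / ((3-4p)^2 sites)."""
    if sites <= 0 or p >= 0.75:
        return math.nan
    return 9.0 * p * (1.0 - p) / ((3.0 - 4.0 * p) ** 2 * sites)


def ng_variances(ng: NGResult) -> tuple[float, float, float, float]:
    """(var_dS, var_dN, var_t_hat, var_omega_hat) of a counting analysis.

    The distance variances are the JC69 sampling variances; the composite
    variances come from the delta method, treating dS and dN as
    independent.  The composite entries are nan when dS or dN is zero or
    saturated (callers must then use the mode/Hessian route).
    """
    return (ng.var_dS, ng.var_dN, ng.var_t_hat, ng.var_omega_hat)


def ng_estimate(aln: PairAlignment, code: GeneticCode = STANDARD_CODE) -> NGResult:
    """Full Nei–Gojobori analysis of one pairwise alignment."""
    S, N = ng_site_counts(aln, code)
    Sd, Nd = ng_difference_counts(aln, code)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jc69_correct(pS)
    dN = jc69_correct(pN)
    var_dS = jc69_variance(pS, S)
    var_dN = jc69_variance(pN, N)
    total = S + N
    if math.isfinite(dS) and math.isfinite(dN):
        # Per-codon substitutions implied by (dS, dN): dS is per synonymous
        # site and dN per nonsynonymous site, so the total per codon is
        # 3 (S dS + N dN) / (S + N).
        t_hat = 3.0 * (S * dS + N * dN) / total
        var_t_hat = (3.0 * S / total) ** 2 * var_dS + (3.0 * N / total) ** 2 * var_dN
    else:
        t_hat = math.nan
        var_t_hat = math.nan
    if math.isfinite(dS) and math.isfinite(dN) and dS > 0 and dN > 0:
        omega_hat = dN / dS
        var_omega_hat = omega_hat**2 * (var_dN / dN**2 + var_dS / dS**2)
    else:
        omega_hat = (dN / dS) if (dS and dS > 0 and math.isfinite(dS)) else math.nan
        var_omega_hat = math.nan
    return NGResult(
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        var_dS=var_dS,
        var_dN=var_dN,
        t_hat=t_hat,
        omega_hat=omega_hat,
        var_t_hat=var_t_hat,
        var_omega_hat=var_omega_hat,
    )
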