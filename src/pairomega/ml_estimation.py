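"""Maximum-likelihood estimation of (t, omega, kappa) for a codon pair.

The likelihood of an unrooted two-sequence alignment under a reversible
codon model is

    L(t, omega, kappa) = prod_h pi_{i_h} P_{i_h j_h}(t),

taken over codon sites h (equivalently over compressed site patterns).
The MLEs of omega and t can sit on the boundary of the parameter space:
identical sequences give t_hat = 0 (omega unidentifiable), synonymous-only
differences give omega_hat = 0, nonsynonymous-only differences give
omega_hat = infinity, and near-random sequences push t_hat (and often
omega_hat) to infinity.  These boundary cases are detected and reported
with explicit sentinels so that downstream summaries can account for them.

Positive selection is tested with the one-sided likelihood ratio test of
H0: omega = 1, using the critical value 2.71 (5% level), and only called
significant when omega_hat > 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .alignment_io import PairAlignment
from .codon_model import CodonFrequencies, CodonModel, SpectralDecomposition, build_rate_matrix
from .counting_ng import NGResult, ng_estimate

# Optimization box (natural scale); the optimizer works in log coordinates.
T_BOUNDS = (1e-6, 50.0)
OMEGA_BOUNDS = (1e-6, 99.0)
KAPPA_BOUNDS = (0.01, 99.0)

#: One-sided chi-square critical value for the LRT at the 5% level.
LRT_CRITICAL_5PCT = 2.71

#: kappa used when the sequences are identical and kappa is unidentifiable.
KAPPA_IDENTICAL = 2.0

_LOWER_TOL = 1e-4  # MLE within this of the lower bound -> 0 sentinel
_UPPER_FRAC = 0.98  # MLE above this fraction of the upper bound -> inf sentinel


class PairLikelihood:
    """Caching likelihood evaluator for one alignment.

    Site patterns are fixed, so for given (omega, kappa) the quantities
    pi_i P_ij(t) for all observed patterns reduce to W @ exp(lambda * t)
    with a pattern-by-eigenvalue matrix W precomputed from the spectral
    decomposition.  Evaluating a whole grid of t values then costs one
    small matrix product.
    """

    def __init__(self, aln: PairAlignment, freqs: CodonFrequencies) -> None:
        self.aln = aln
        self.freqs = freqs
        self.i_idx, self.j_idx, self.counts = aln.pattern_arrays()
        self._cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}

    def _pattern_basis(self, omega: float, kappa: float) -> tuple[np.ndarray, np.ndarray]:
        key = (omega, kappa)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        model = build_rate_matrix(self.freqs, kappa=kappa, omega=omega)
        decomp = SpectralDecomposition(model.Q, model.pi)
        # Map full-space codon indices to support-local ones.
        pos = np.full(model.pi.shape[0], -1, dtype=np.intp)
        pos[decomp.support] = np.arange(decomp.support.size)
        B = decomp.B
        W = B[pos[self.i_idx]] * B[pos[self.j_idx]]
        lam = decomp.eigenvalues
        if len(self._cache) > 256:
            self._cache.clear()
        self._cache[key] = (W, lam)
        return W, lam

    def loglik_t_grid(self, ts: np.ndarray, omega: float, kappa: float) -> np.ndarray:
        """log-likelihood at each t in ``ts`` for fixed (omega, kappa)."""
        if self.aln.L_c == 0:
            return np.zeros(np.shape(ts))
        W, lam = self._pattern_basis(omega, kappa)
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        f = W @ np.exp(np.outer(lam, ts))  # pattern x t: pi_i P_ij(t)
        np.clip(f, 1e-300, None, out=f)
        return self.counts @ np.log(f)

    def loglik(self, t: float, omega: float, kappa: float) -> float:
        return float(self.loglik_t_grid(np.array([t]), omega, kappa)[0])


def log_likelihood(
    aln: PairAlignment, model: CodonModel, t: float
) -> float:
    """log L = sum over patterns n_ij log(pi_i P_ij(t))."""
    if t < 0 or not np.isfinite(t):
        raise ValueError(f"t must be finite and nonnegative, got {t}")
    engine = PairLikelihood(aln, model.freqs)
    return engine.loglik(t, model.omega, model.kappa)


@dataclass
class MLResult:
    t_hat: float
    omega_hat: float  # nan when unidentifiable (identical sequences)
    kappa_hat: float
    logL: float
    boundary: str  # interior | t_zero | omega_zero | omega_inf | t_inf
    se_t: float = math.nan
    se_omega: float = math.nan
    logL0: float = math.nan  # max log-likelihood under omega = 1
    lrt_stat: float = math.nan
    significant_5pct: bool = False

    @property
    def interior(self) -> bool:
        return self.boundary == "interior"


def _classify(value: float, bounds: tuple[float, float]) -> str:
    lo, hi = bounds
    if value <= lo + _LOWER_TOL:
        return "low"
    if value >= _UPPER_FRAC * hi:
        return "high"
    return "mid"


def _start_points(ng: NGResult) -> list[np.ndarray]:
    """Multi-start points in (log t, log omega, log kappa)."""

    def clip_log(x, bounds, default):
        if not (x is not None and math.isfinite(x) and x > 0):
            x = default
        return math.log(min(max(x, bounds[0] * 1.5), bounds[1] / 1.5))

    t0 = clip_log(ng.t_hat if ng else None, T_BOUNDS, 0.3)
    w0 = clip_log(ng.omega_hat if ng else None, OMEGA_BOUNDS, 0.3)
    k0 = math.log(2.0)
    base = np.array([t0, w0, k0])
    return [base, base + np.array([1.0, 1.0, 0.5]), base - np.array([1.0, 1.0, 0.5])]


def maximize_likelihood(
    aln: PairAlignment,
    freqs: CodonFrequencies,
    fix_omega: float | None = None,
    ng: NGResult | None = None,
) -> MLResult:
    """Maximize the pairwise likelihood over (t, omega, kappa).

    With ``fix_omega`` given, only (t, kappa) are free (used for the
    omega = 1 null of the LRT).  Identical sequences short-circuit to the
    t = 0 boundary with kappa fixed at 2 and omega unidentifiable.
    """
    if aln.L_c == 0:
        raise ValueError("cannot fit an empty alignment")
    engine = PairLikelihood(aln, freqs)
    if aln.is_identical:
        pi = freqs.pi
        i_idx, _, counts = aln.pattern_arrays()
        logL = float(counts @ np.log(pi[i_idx]))
        return MLResult(
            t_hat=0.0,
            omega_hat=fix_omega if fix_omega is not None else math.nan,
            kappa_hat=KAPPA_IDENTICAL,
            logL=logL,
            boundary="t_zero",
        )
    if ng is None:
        ng = ng_estimate(aln)

    if fix_omega is None:

        def negloglik(x):
            return -engine.loglik(math.exp(x[0]), math.exp(x[1]), math.exp(x[2]))

        bounds = [
            tuple(np.log(T_BOUNDS)),
            tuple(np.log(OMEGA_BOUNDS)),
            tuple(np.log(KAPPA_BOUNDS)),
        ]
        starts = _start_points(ng)
    else:

        def negloglik(x):
            return -engine.loglik(math.exp(x[0]), fix_omega, math.exp(x[1]))

        bounds = [tuple(np.log(T_BOUNDS)), tuple(np.log(KAPPA_BOUNDS))]
        starts = [s[[0, 2]] for s in _start_points(ng)]

    best = None
    for x0 in starts:
        res = minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"likelihood optimization failed: {best}")

    x = best.x
    t_hat = math.exp(x[0])
    if fix_omega is None:
        omega_hat, kappa_hat = math.exp(x[1]), math.exp(x[2])
    else:
        omega_hat, kappa_hat = fix_omega, math.exp(x[1])
    logL = -float(best.fun)

    boundary = "interior"
    t_cls = _classify(t_hat, T_BOUNDS)
    w_cls = _classify(omega_hat, OMEGA_BOUNDS) if fix_omega is None else "mid"
    if t_cls == "low":
        boundary = "t_zero"
        t_hat = 0.0
    elif t_cls == "high":
        boundary = "t_inf"
        t_hat = math.inf
    elif w_cls == "low":
        boundary = "omega_zero"
        omega_hat = 0.0
    elif w_cls == "high":
        boundary = "omega_inf"
        omega_hat = math.inf

    result = MLResult(
        t_hat=t_hat, omega_hat=omega_hat, kappa_hat=kappa_hat,
        logL=logL, boundary=boundary,
    )
    if boundary == "interior" and fix_omega is None:
        se_t, se_omega = _asymptotic_se(engine, t_hat, omega_hat, kappa_hat)
        result.se_t, result.se_omega = se_t, se_omega
    return result


def _asymptotic_se(
    engine: PairLikelihood, t: float, omega: float, kappa: float
) -> tuple[float, float]:
    """SEs of (t_hat, omega_hat) from the observed information.

    The Hessian of log L is taken in (log t, log omega, log kappa) by
    central second differences and mapped back by the delta method.
    """
    x0 = np.log([t, omega, kappa])
    h = 1e-3

    def f(x):
        return engine.loglik(math.exp(x[0]), math.exp(x[1]), math.exp(x[2]))

    n = 3
    H = np.empty((n, n))
    f0 = f(x0)
    for a in range(n):
        for b in range(a, n):
            ea = np.eye(n)[a] * h
            eb = np.eye(n)[b] * h
            if a == b:
                H[a, a] = (f(x0 + ea) - 2 * f0 + f(x0 - ea)) / h**2
            else:
                H[a, b] = H[b, a] = (
                    f(x0 + ea + eb) - f(x0 + ea - eb) - f(x0 - ea + eb) + f(x0 - ea - eb)
                ) / (4 * h**2)
    try:
        cov = np.linalg.inv(-H)
        var_log = np.diag(cov)
        if np.any(var_log[:2] <= 0):
            raise np.linalg.LinAlgError
        return t * math.sqrt(var_log[0]), omega * math.sqrt(var_log[1])
    except np.linalg.LinAlgError:
        warnings.warn("observed information not positive definite", RuntimeWarning)
        return math.nan, math.nan


def lrt_positive_selection(
    aln: PairAlignment,
    freqs: CodonFrequencies,
    ml: MLResult | None = None,
    ng: NGResult | None = None,
) -> MLResult:
    """One-sided LRT of omega = 1; fills the LRT fields of the MLResult.

    Significance requires both 2*(logL1 - logL0) > 2.71 and omega_hat > 1;
    identical sequences carry no information and are never significant.
    """
    if ml is None:
        ml = maximize_likelihood(aln, freqs, ng=ng)
    if ml.boundary == "t_zero":
        ml.logL0 = ml.logL
        ml.lrt_stat = 0.0
        ml.significant_5pct = False
        return ml
    null = maximize_likelihood(aln, freqs, fix_omega=1.0, ng=ng)
    ml.logL0 = null.logL
    ml.lrt_stat = max(0.0, 2.0 * (ml.logL - null.logL))
    omega_gt1 = (ml.omega_hat > 1.0) or ml.boundary == "omega_inf"
    ml.significant_5pct = bool(ml.lrt_stat > LRT_CRITICAL_5PCT and omega_gt1)
    return ml


def dn_ds_from_mle(model: CodonModel, t_hat: float) -> tuple[float, float]:
    """(dN, dS) implied by an interior MLE.

    Substitution flow through the rate matrix is split into nonsynonymous
    and synonymous parts; per-site distances divide each flow by the
    model-implied proportion of sites of that class (the flow proportions
    under the same model with omega = 1, the mutational opportunity).
    """
    if not (np.isfinite(t_hat) and t_hat >= 0):
        raise ValueError("dn_ds_from_mle requires a finite interior t_hat")
    code = model.code
    pi = model.pi

    def flows(m: CodonModel) -> tuple[float, float]:
        rates = m.pi[code._nbr_i] * m.Q[code._nbr_i, code._nbr_j]
        syn = float(rates[code._nbr_syn].sum())
        nonsyn = float(rates[~code._nbr_syn].sum())
        return syn, nonsyn

    rho_s, rho_n = flows(model)
    neutral = build_rate_matrix(model.freqs, kappa=model.kappa, omega=1.0)
    rho_s1, rho_n1 = flows(neutral)
    # Per codon: 3*rho_s1 synonymous sites; t_hat*rho_s synonymous subs.
    dS = t_hat * rho_s / (3.0 * rho_s1) if rho_s1 > 0 else math.nan
    dN = t_hat * rho_n / (3.0 * rho_n1) if rho_n1 > 0 else math.nan
    return dN, dS
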