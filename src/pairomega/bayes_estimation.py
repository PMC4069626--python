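"""Bayesian estimation of (t, omega) by logistic-transformed quadrature.

The posterior f(t, omega | x) is proportional to the likelihood times
independent gamma priors on the divergence t and the rate ratio omega.
Point estimates are the posterior means; posterior variances, the
covariance and the posterior probability of positive selection
P(omega > 1 | x) are computed from the same set of two-dimensional
integrals.  All integrals are evaluated with Gauss-Legendre quadrature
after a change of variables: log t and log omega are mapped through
logistic CDFs whose location and scale are matched to the integrand, so
that a small fixed grid (32 x 32 by default) captures the posterior mass
even when it is sharply concentrated.

The transform parameters come from one of two routes.  When the MLEs are
interior and the sequences are not saturated, the centers are the log
MLEs and the scales derive from Nei-Gojobori counting variances.  In all
other cases (identical, synonymous-only, nonsynonymous-only or
near-random sequences) the posterior kernel is maximized numerically on
the log scale and the scales come from the inverse of a finite-difference
Hessian at the mode — the gamma priors guarantee this mode exists, which
is precisely why the posterior summaries stay finite in every case where
the MLEs do not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln, roots_legendre

from .alignment_io import PairAlignment
from .codon_model import CodonFrequencies
from .counting_ng import NGResult, ng_estimate
from .ml_estimation import KAPPA_IDENTICAL, MLResult, PairLikelihood, maximize_likelihood

#: sqrt(3)/pi: converts a standard deviation into the logistic scale with
#: the same variance (logistic variance is sigma^2 pi^2 / 3).
_SD_TO_LOGISTIC = math.sqrt(3.0) / math.pi

# The logistic surrogate is deliberately over-dispersed relative to the
# delta-method variance.  An under-dispersed surrogate leaves the
# transformed integrand with slowly-decaying (effectively singular)
# behavior at the endpoints of (-1, 1), which destroys Gauss-Legendre
# convergence; a mildly wider one keeps it smooth at negligible cost in
# resolution.  The cap protects heavily skewed prior-dominated posteriors
# (e.g. identical sequences), where a very wide grid would starve the peak
# of nodes.
_NG_SCALE_INFLATION = 1.5
_HESSIAN_SCALE_INFLATION = 2.0
_HESSIAN_SCALE_CAP = 2.6

_HESSIAN_STEP = 1e-3
_DEFAULT_SIGMA = 1.0


@dataclass(frozen=True)
class GammaPrior:
    """Independent gamma priors: t ~ G(alpha_t, beta_t), omega ~ G(alpha_w, beta_w).

    The gamma density G(x | alpha, beta) has mean alpha/beta.  The default
    prior means are 1 for t and 0.5 for omega with shape 1.1, i.e. diffuse
    priors whose density still vanishes at 0 and infinity, penalizing the
    extreme estimates that break ML.
    """

    alpha_t: float = 1.1
    beta_t: float = 1.1
    alpha_omega: float = 1.1
    beta_omega: float = 2.2

    def __post_init__(self) -> None:
        for v in (self.alpha_t, self.beta_t, self.alpha_omega, self.beta_omega):
            if not (v > 0 and math.isfinite(v)):
                raise ValueError("gamma prior parameters must be positive and finite")

    @property
    def mean_t(self) -> float:
        return self.alpha_t / self.beta_t

    @property
    def mean_omega(self) -> float:
        return self.alpha_omega / self.beta_omega

    def log_density_t(self, t):
        a, b = self.alpha_t, self.beta_t
        return a * math.log(b) - gammaln(a) + (a - 1) * np.log(t) - b * np.asarray(t)

    def log_density_omega(self, w):
        a, b = self.alpha_omega, self.beta_omega
        return a * math.log(b) - gammaln(a) + (a - 1) * np.log(w) - b * np.asarray(w)

    def prob_omega_gt1_prior(self) -> float:
        """Prior tail P(omega > 1) = 1 - regularized gamma CDF at beta."""
        return float(1.0 - gammainc(self.alpha_omega, self.beta_omega))


@dataclass
class LogisticTransform:
    """Location/scale of the logistic laws for x1 = log t, x2 = log omega."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    source: str  # "ng_branch" or "hessian_branch"
    mode_log_g: float = math.nan  # log posterior kernel at the located mode

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("logistic scales must be positive")


@dataclass
class QuadratureGrid:
    """Gauss-Legendre grid and scaled integrand evaluations."""

    n: int
    nodes: np.ndarray
    weights: np.ndarray
    t_values: np.ndarray  # n, mapped through the t transform
    omega_values: np.ndarray  # n
    jac1: np.ndarray  # dt/dz1 / t = 2 sigma1 / (1 - z1^2)
    jac2: np.ndarray
    log_g: np.ndarray  # n x n, log posterior kernel
    l_max: float
    r_values: np.ndarray = field(default=None)  # n x n scaled integrand

    def __post_init__(self) -> None:
        if self.r_values is None:
            # r(z1,z2) = g(t,w) t w jac1 jac2 / exp(l_max)
            self.r_values = np.exp(self.log_g - self.l_max) * np.outer(
                self.t_values * self.jac1, self.omega_values * self.jac2
            )


@dataclass
class PosteriorSummary:
    mean_t: float
    mean_omega: float
    var_t: float
    var_omega: float
    cov_t_omega: float
    prob_omega_gt1: float
    norm_const_scaled: float  # A = C exp(-l_max)
    l_max: float
    transform: LogisticTransform | None = None
    n_points: int = 32

    @property
    def sd_t(self) -> float:
        return math.sqrt(self.var_t)

    @property
    def sd_omega(self) -> float:
        return math.sqrt(self.var_omega)


class _PosteriorKernel:
    """log g(t, omega) = log L(x | t, omega, kappa_hat) + log prior."""

    def __init__(
        self,
        aln: PairAlignment | None,
        freqs: CodonFrequencies,
        kappa: float,
        prior: GammaPrior,
    ) -> None:
        self.prior = prior
        self.kappa = kappa
        self.engine = (
            PairLikelihood(aln, freqs) if aln is not None and aln.L_c > 0 else None
        )

    def log_g_grid(self, ts: np.ndarray, omegas: np.ndarray) -> np.ndarray:
        """log g on the outer product grid ts x omegas (len(ts) x len(omegas))."""
        out = np.add.outer(
            np.asarray(self.prior.log_density_t(ts), dtype=float),
            np.asarray(self.prior.log_density_omega(omegas), dtype=float),
        )
        if self.engine is not None:
            for b, w in enumerate(omegas):
                out[:, b] += self.engine.loglik_t_grid(ts, float(w), self.kappa)
        return out

    def log_g(self, t: float, omega: float) -> float:
        return float(self.log_g_grid(np.array([t]), np.array([omega]))[0, 0])


def log_posterior_kernel(
    aln: PairAlignment | None,
    freqs: CodonFrequencies,
    kappa: float,
    prior: GammaPrior,
    t: float,
    omega: float,
) -> float:
    """log of likelihood x prior at (t, omega), with kappa plugged in."""
    if not (t > 0 and omega > 0):
        raise ValueError("t and omega must be positive")
    return _PosteriorKernel(aln, freqs, kappa, prior).log_g(t, omega)


def _find_mode(kernel: _PosteriorKernel, start: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximize log g over x = (log t, log omega)."""

    def neg(x):
        return -kernel.log_g(math.exp(x[0]), math.exp(x[1]))

    best = None
    for x0 in (start, start + 1.0, start - 1.0):
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -float(best.fun)


def _hessian_scales(kernel: _PosteriorKernel, x_mode: np.ndarray) -> tuple[float, float] | None:
    """Logistic scales from the inverse Hessian of log g at the mode.

    Central second differences; returns None if the Hessian is not
    negative definite at any attempted step size.
    """
    h = _HESSIAN_STEP
    for _ in range(4):
        f = lambda x: kernel.log_g(math.exp(x[0]), math.exp(x[1]))
        f0 = f(x_mode)
        e1 = np.array([h, 0.0])
        e2 = np.array([0.0, h])
        H = np.empty((2, 2))
        H[0, 0] = (f(x_mode + e1) - 2 * f0 + f(x_mode - e1)) / h**2
        H[1, 1] = (f(x_mode + e2) - 2 * f0 + f(x_mode - e2)) / h**2
        H[0, 1] = H[1, 0] = (
            f(x_mode + e1 + e2) - f(x_mode + e1 - e2)
            - f(x_mode - e1 + e2) + f(x_mode - e1 - e2)
        ) / (4 * h**2)
        neg_H = -H
        if neg_H[0, 0] > 0 and neg_H[1, 1] > 0 and np.linalg.det(neg_H) > 0:
            cov = np.linalg.inv(neg_H)
            return (
                _SD_TO_LOGISTIC * math.sqrt(cov[0, 0]),
                _SD_TO_LOGISTIC * math.sqrt(cov[1, 1]),
            )
        h *= 2.0
    return None


def choose_transform(
    ml: MLResult | None,
    ng: NGResult | None,
    aln: PairAlignment | None,
    freqs: CodonFrequencies,
    prior: GammaPrior,
    kappa: float | None = None,
) -> LogisticTransform:
    """Pick the logistic change of variables for the quadrature.

    Counting branch: both MLEs interior and p-distances below the 0.74
    saturation guard; centers log t_hat, log omega_hat; scales from the
    delta-method SDs of log t and log omega implied by the counting
    variances.  Otherwise the mode/Hessian branch described in the module
    docstring.
    """
    if kappa is None:
        kappa = ml.kappa_hat if ml is not None else KAPPA_IDENTICAL
    use_ng = (
        ml is not None
        and ng is not None
        and ml.interior
        and ng.usable_for_transform
        and ml.t_hat > 0
        and ml.omega_hat > 0
    )
    if use_ng:
        sd_log_t = math.sqrt(ng.var_t_hat) / ng.t_hat
        sd_log_w = math.sqrt(ng.var_omega_hat) / ng.omega_hat
        factor = _NG_SCALE_INFLATION * _SD_TO_LOGISTIC
        return LogisticTransform(
            mu1=math.log(ml.t_hat),
            sigma1=max(factor * sd_log_t, 1e-3),
            mu2=math.log(ml.omega_hat),
            sigma2=max(factor * sd_log_w, 1e-3),
            source="ng_branch",
        )
    kernel = _PosteriorKernel(aln, freqs, kappa, prior)
    if ng is not None and ng.usable_for_transform:
        start = np.log([ng.t_hat, ng.omega_hat])
    else:
        start = np.log([0.5 * prior.mean_t, 0.5 * prior.mean_omega])
    x_mode, mode_val = _find_mode(kernel, start)
    scales = _hessian_scales(kernel, x_mode)
    if scales is None:
        warnings.warn(
            "posterior-mode Hessian not negative definite; using unit scales",
            RuntimeWarning,
        )
        scales = (_DEFAULT_SIGMA, _DEFAULT_SIGMA)
    return LogisticTransform(
        mu1=float(x_mode[0]),
        sigma1=min(_HESSIAN_SCALE_INFLATION * scales[0], _HESSIAN_SCALE_CAP),
        mu2=float(x_mode[1]),
        sigma2=min(_HESSIAN_SCALE_INFLATION * scales[1], _HESSIAN_SCALE_CAP),
        source="hessian_branch",
        mode_log_g=mode_val,
    )


def _map_nodes(z: np.ndarray, mu: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse logistic-CDF map z in (-1,1) -> theta = exp(x), plus dx/dz.

    x = mu + sigma log((1+z)/(1-z)) is the quantile of Logistic(mu, sigma)
    at (1+z)/2, so d theta / dz = theta * 2 sigma / (1 - z^2).
    """
    x = mu + sigma * (np.log1p(z) - np.log1p(-z))
    return np.exp(x), 2.0 * sigma / (1.0 - z * z)


def _build_grid(
    kernel: _PosteriorKernel,
    transform: LogisticTransform,
    n: int,
    l_max_floor: float = -np.inf,
) -> QuadratureGrid:
    z, w = roots_legendre(n)
    ts, jac1 = _map_nodes(z, transform.mu1, transform.sigma1)
    ws_, jac2 = _map_nodes(z, transform.mu2, transform.sigma2)
    log_g = kernel.log_g_grid(ts, ws_)
    l_max = max(float(np.max(log_g)), l_max_floor)
    if math.isfinite(transform.mode_log_g):
        l_max = max(l_max, transform.mode_log_g)
    return QuadratureGrid(
        n=n, nodes=z, weights=w, t_values=ts, omega_values=ws_,
        jac1=jac1, jac2=jac2, log_g=log_g, l_max=l_max,
    )


def posterior_summaries(
    aln: PairAlignment | None,
    freqs: CodonFrequencies,
    kappa: float,
    prior: GammaPrior,
    transform: LogisticTransform,
    n: int = 32,
) -> PosteriorSummary:
    """All posterior summaries from one n x n evaluation of the kernel.

    The six global integrals (normalizer plus expectations of t, omega,
    t^2, omega^2, t*omega) share the same grid of scaled integrand values;
    the overflow guard exp(-l_max) cancels in every ratio.  The tail
    integral for P(omega > 1 | x) re-runs the quadrature with the omega
    dimension restricted to the image of (1, infinity).
    """
    if n < 8:
        raise ValueError("need at least 8 quadrature points per dimension")
    kernel = _PosteriorKernel(aln, freqs, kappa, prior)
    grid = _build_grid(kernel, transform, n)
    if not np.any(grid.r_values > 0):
        # Catastrophic mis-centering: recenter at the grid argmax once.
        a, b = np.unravel_index(np.argmax(grid.log_g), grid.log_g.shape)
        transform = LogisticTransform(
            mu1=math.log(grid.t_values[a]), sigma1=transform.sigma1,
            mu2=math.log(grid.omega_values[b]), sigma2=transform.sigma2,
            source=transform.source,
        )
        grid = _build_grid(kernel, transform, n)
        if not np.any(grid.r_values > 0):
            raise RuntimeError("posterior quadrature degenerate after recentering")

    w = grid.weights
    t = grid.t_values
    om = grid.omega_values
    r = grid.r_values
    A = float(w @ r @ w)
    E_t = float((w * t) @ r @ w) / A
    E_w = float(w @ r @ (w * om)) / A
    E_t2 = float((w * t * t) @ r @ w) / A
    E_w2 = float(w @ r @ (w * om * om)) / A
    E_tw = float((w * t) @ r @ (w * om)) / A
    var_t = E_t2 - E_t**2
    var_w = E_w2 - E_w**2
    # Round-off guard: tiny negative variances from cancellation.
    var_t = max(var_t, 0.0) if var_t > -1e-10 * max(E_t2, 1.0) else var_t
    var_w = max(var_w, 0.0) if var_w > -1e-10 * max(E_w2, 1.0) else var_w
    cov = E_tw - E_t * E_w

    prob = _tail_probability(kernel, transform, n, grid.l_max, A)
    return PosteriorSummary(
        mean_t=E_t, mean_omega=E_w, var_t=var_t, var_omega=var_w,
        cov_t_omega=cov, prob_omega_gt1=prob, norm_const_scaled=A,
        l_max=grid.l_max, transform=transform, n_points=n,
    )


def _tail_probability(
    kernel: _PosteriorKernel,
    transform: LogisticTransform,
    n: int,
    l_max: float,
    A: float,
) -> float:
    """P(omega > 1 | x): quadrature over z2 restricted to omega > 1."""
    # Image of omega = 1 under the transform: z2* = 2 F(0) - 1.
    z_star = math.tanh(-transform.mu2 / (2.0 * transform.sigma2))
    half_width = (1.0 - z_star) / 2.0
    if half_width <= 1e-15:
        return 0.0
    z, w = roots_legendre(n)
    ts, jac1 = _map_nodes(z, transform.mu1, transform.sigma1)
    z2 = z_star + half_width * (z + 1.0)
    np.clip(z2, -1.0 + 1e-15, 1.0 - 1e-15, out=z2)
    oms, jac2 = _map_nodes(z2, transform.mu2, transform.sigma2)
    log_g = kernel.log_g_grid(ts, oms)
    r = np.exp(log_g - l_max) * np.outer(ts * jac1, oms * jac2)
    num = float(w @ r @ w) * half_width
    return min(max(num / A, 0.0), 1.0)


def posterior_prob_omega_gt1(
    aln: PairAlignment | None,
    freqs: CodonFrequencies,
    kappa: float,
    prior: GammaPrior,
    transform: LogisticTransform,
    n: int = 32,
) -> float:
    """Posterior probability of positive selection, P(omega > 1 | x)."""
    return posterior_summaries(aln, freqs, kappa, prior, transform, n).prob_omega_gt1


def bayes_estimate(
    aln: PairAlignment | None,
    freqs: CodonFrequencies,
    prior: GammaPrior | None = None,
    n: int = 32,
    kappa: float | None = None,
    ml: MLResult | None = None,
    ng: NGResult | None = None,
) -> PosteriorSummary:
    """Convenience driver: ML (for kappa and centering), transform, quadrature."""
    if prior is None:
        prior = GammaPrior()
    have_data = aln is not None and aln.L_c > 0
    if ng is None and have_data:
        ng = ng_estimate(aln)
    if ml is None and have_data:
        ml = maximize_likelihood(aln, freqs, ng=ng)
    if kappa is None:
        kappa = ml.kappa_hat if ml is not None else KAPPA_IDENTICAL
    transform = choose_transform(ml, ng, aln, freqs, prior, kappa=kappa)
    return posterior_summaries(aln, freqs, kappa, prior, transform, n=n)
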