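"""Independent integration oracle for the posterior summaries.

Simpson's rule on a dense uniform grid in (log t, log omega), with the
domain wide enough that the truncated prior tails are negligible relative
to the 1e-4 tolerances being verified, and a separate grid for the
omega > 1 tail starting exactly at log omega = 0.  Completely independent
of the logistic-transformed Gauss-Legendre path used by the package.
"""

import numpy as np
from scipy.integrate import simpson

from pairomega.bayes_estimation import _PosteriorKernel


def dense_grid_summaries(
    aln, freqs, kappa, prior, lo=-25.0, hi=7.0, m=2001, m_tail=1001
):
    kern = _PosteriorKernel(aln, freqs, kappa, prior)
    x = np.linspace(lo, hi, m)
    ts = np.exp(x)
    oms = np.exp(x)
    log_g = kern.log_g_grid(ts, oms)
    l_max = log_g.max()
    # integrand of the normalizer on the log scale: g(t, w) * t * w
    r = np.exp(log_g - l_max) * np.outer(ts, oms)

    def integral(wt, ww, rr=None, xw=None):
        rr = r if rr is None else rr
        xw = x if xw is None else xw
        return simpson(simpson(rr * np.outer(wt, ww), x=xw, axis=1), x=x)

    one_t, one_w = np.ones_like(ts), np.ones_like(oms)
    A = integral(one_t, one_w)
    E_t = integral(ts, one_w) / A
    E_w = integral(one_t, oms) / A
    E_t2 = integral(ts * ts, one_w) / A
    E_w2 = integral(one_t, oms * oms) / A
    E_tw = integral(ts, oms) / A
    x2 = np.linspace(0.0, hi, m_tail)
    om_tail = np.exp(x2)
    log_g_tail = kern.log_g_grid(ts, om_tail)
    r_tail = np.exp(log_g_tail - l_max) * np.outer(ts, om_tail)
    prob = integral(one_t, np.ones_like(om_tail), rr=r_tail, xw=x2) / A
    return {
        "A": A,
        "mean_t": E_t,
        "mean_omega": E_w,
        "E_t2": E_t2,
        "E_omega2": E_w2,
        "E_t_omega": E_tw,
        "var_t": E_t2 - E_t**2,
        "var_omega": E_w2 - E_w**2,
        "cov_t_omega": E_tw - E_t * E_w,
        "prob_omega_gt1": prob,
        "l_max": l_max,
    }
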