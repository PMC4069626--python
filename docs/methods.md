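# Methods

## Model

Codon evolution follows the one-ratio (M0) codon substitution model on the
61 sense codons of the standard genetic code. The instantaneous rate from
codon i to codon j (i ≠ j) is

    q_ij = 0                 if i and j differ at more than one position
         = π_j               synonymous transversion
         = κ π_j             synonymous transition
         = ω π_j             nonsynonymous transversion
         = ω κ π_j           nonsynonymous transition

with diagonal entries making rows sum to zero. Stop codons are excluded
from the state space. The matrix is scaled so that the equilibrium
substitution rate −Σᵢ πᵢ q_ii equals 1, so the divergence t between two
sequences is measured in expected (nucleotide) substitutions per codon.
This calibration is confirmed internally: for L identical codons the
posterior mean of t is ≈ α_t/(β_t + L), and the package reproduces the
reference value 0.011 at L = 100 under the default prior; a
per-nucleotide-site scaling (3× larger rates) would give ≈ 0.004.

Two codon frequency models are supported: Fequal (πⱼ = 1/61, used in the
simulation study) and F61 (πⱼ = observed codon usage pooled over both
sequences). Under F61, unobserved codons keep πⱼ = 0; all matrix work is
restricted to the support of π, which is exact because observed codons
always have positive frequency.

The likelihood of an alignment x with site patterns (i_h, j_h) is
L(t, ω, κ) = Π_h π_{i_h} P_{i_h j_h}(t) with P(t) = exp(Qt). Reversibility
(π_i q_ij = π_j q_ji) makes the likelihood independent of which sequence
is "first" and allows the symmetrized eigendecomposition
Π^{1/2} Q Π^{-1/2} = U Λ Uᵀ, giving π_i P_ij(t) = Σ_k B_ik B_jk e^{λ_k t}
with B = Π^{1/2} U. Site patterns are compressed to counts, and each
(ω, κ) pair requires one 61×61 symmetric eigendecomposition after which a
whole grid of t values costs a single small matrix product. This is what
keeps the 32×32 quadrature grid (32 decompositions, 1,024 likelihood
values) at ~15 ms per gene.

## Maximum likelihood and boundary cases

(t, ω, κ) are maximized by L-BFGS-B in log coordinates within
t ∈ [1e−6, 50], ω ∈ [1e−6, 99], κ ∈ [0.01, 99], multi-started from the
Nei–Gojobori point and two perturbations. Identical sequences
short-circuit to t̂ = 0 with ω unidentifiable (reported as NaN) and κ
fixed at 2, the conventional value when κ cannot be estimated. An MLE
within 1e−4 of a lower bound is reported as the 0 sentinel; within 2% of
an upper bound as the ∞ sentinel. These cases are exactly the regimes
where the sequences contain only synonymous differences (ω̂ = 0), only
nonsynonymous differences (ω̂ = ∞), or are identical/saturated (t̂ = 0/∞).
Standard errors come from the finite-difference observed information at
interior optima only.

Positive selection is tested by the one-sided LRT of H₀: ω = 1 at the 5%
level (critical value 2.71, the one-sided chi-square mixture point), and
is called only when ω̂ > 1. Identical pairs are never significant.

## Bayesian estimation

The posterior kernel is g(t, ω) = L(x | t, ω, κ̂) f(t) f(ω) with κ plugged
in at its MLE. Posterior means, variances, the covariance and
P(ω > 1 | x) are ratios of six double integrals of g against 1, t, ω, t²,
ω², tω. Overflow is avoided by working with exp(log g − l_max), where
l_max is the maximum of log g over the evaluation grid (and the located
mode, when available); the factor exp(l_max) cancels in every ratio.

Integrals are computed by n-point Gauss–Legendre quadrature per dimension
(n = 32 by default) after the change of variables z = 2F(x) − 1, where
x₁ = log t and x₂ = log ω are modeled as Logistic(μ, σ) and F is that
CDF. If the logistic matches the posterior of the log-parameters, the
transformed integrand is nearly flat, so a small fixed grid is accurate
even for sharply peaked posteriors. The location/scale parameters come
from one of two routes:

* **Counting branch** (both MLEs interior, Nei–Gojobori p-distances below
  the 0.74 saturation guard, both counting distances positive):
  μ = log MLE; σ = (√3/π) · SD(log θ̂) with SD(log θ̂) = SD(θ̂)/θ̂ by the
  delta method, using the Nei–Gojobori variances V(dS), V(dN) propagated
  to t̂ = 3(S·dS + N·dN)/(S+N) and ω̂ = dN/dS (dS, dN treated as
  independent).
* **Mode/Hessian branch** (all other cases): log g is maximized over
  (log t, log ω) by Nelder–Mead (multi-started; the gamma priors guarantee
  an interior mode), the Hessian is taken by central second differences
  (step 1e−3 on the log scale, doubled up to 3 times if not negative
  definite, then unit scales as a last resort), and σ is matched to the
  implied variance as above.

**Scale calibration.** The raw variance-matched scales are deliberately
inflated: ×1.5 on the counting branch and ×2.0 (capped at σ = 2.6) on the
mode/Hessian branch. With the raw scales the transformed integrand decays
too slowly at the endpoints of (−1, 1) — effectively an algebraic endpoint
singularity — and Gauss–Legendre convergence stalls near 1e−3 for the
second moments; a mildly over-dispersed surrogate keeps the integrand
smooth at negligible cost in peak resolution. The cap protects strongly
skewed prior-dominated posteriors (identical sequences), where a very wide
grid would starve the peak of nodes. With this calibration, all six
integrals and P(ω > 1 | x) at n = 32 agree with a converged dense-grid
Simpson oracle on (log t, log ω) to better than 1e−4 relative on
informative and on synonymous-only / nonsynonymous-only / random fixtures.
The one residual is the posterior *variances* for identical-sequence
pairs, which converge to ~5e−4 relative at n = 32 (means and tail
probability are within 1e−4): a symmetric logistic cannot fully flatten
the gamma-shaped (shape 1.1) integrand of that case. n is configurable
when more accuracy is wanted.

P(ω > 1 | x) uses the same transform with the z₂ (ω) dimension restricted
to the image of (1, ∞), remapped to a fresh n-point rule, so the tail
integral keeps full resolution near ω = 1 instead of reusing the global
grid with an indicator. The same l_max is used, and the denominator is the
global normalizer.

Degenerate guard: if every scaled integrand value underflows to zero
(catastrophic mis-centering), the transform is recentered once at the grid
argmax of log g and recomputed; a second failure raises an error. In
practice the recentering path is never taken on the tested regimes.

No-data inputs (zero retained codons) are well defined: the likelihood is
identically 1, the posterior equals the prior, and the quadrature
reproduces the prior means and P(ω > 1) = prior gamma tail to better than
1e−5.

## Nei–Gojobori counting

Synonymous site counts per codon are the fraction of the three possible
changes at each position that are synonymous, excluding changes to stop
codons from the denominator. Differences between codons differing at k
positions are averaged over all k! single-step pathways, skipping pathways
through stop codons (if every pathway is blocked — a rare 2–3-step corner
— all pathways are used so that S_d + N_d still equals the number of
differing positions). Proportions p_S = S_d/S and p_N = N_d/N are
corrected for multiple hits with JC69, d = −(3/4) ln(1 − 4p/3), with
variance V(d) = 9p(1−p)/((3−4p)² · sites). The correction saturates at
p ≥ 3/4; p ≥ 0.74 is already treated as saturated when deciding whether
counting variances may parameterize the quadrature transform, because
V(d) explodes as p → 3/4.

## Simulator

Sites are i.i.d.: codon i is drawn from π and codon j from row i of P(t).
For a reversible chain this is exactly the joint law of a pair of
sequences diverged by total path length t from a common ancestor, so no
explicit ancestor is simulated. No indels, no among-site rate variation.
Replicate streams are derived from (seed, cell index, replicate index), so
any single replicate is reproducible in isolation. The defaults mirror
the simulation study the package is validated against: L = 500 codons,
κ = 2, equal codon frequencies, t ∈ {0.1, 0.5, 1, 5}, ω ∈ {0.01, 0.1,
0.5, 2}.

What the simulator does *not* emulate about real data: alignment errors,
indels and frame disruptions, CpG and context effects, selection
heterogeneity among sites and over time, and non-equilibrium codon usage.
Passing the simulation-recovery tests therefore validates the estimators
under the model's own assumptions, not robustness to their violation.

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks run at reduced replicate counts chosen for a
single-CPU workflow: 120–150 replicates per simulation cell in the test
suite and 300 (240 for the power cell) in `scripts/acceptance.py`, versus
10,000 in the reference study. All tolerance bands are 3 Monte-Carlo
standard errors at the replicate count actually used (for proportions at
the boundary of [0, 1], with a 1/R continuity floor), so reduced counts
widen the bands honestly rather than silently.

## Known limitations

* Pairwise comparisons only; no phylogenetic (multi-sequence) inference,
  and correspondingly low power to detect episodic selection.
* κ is plugged in at its MLE rather than integrated over; the posterior
  for (t, ω) is conditional on κ̂.
* Only the plain Nei–Gojobori counting method (no LWL85/YN00 variants),
  used descriptively and for transform calibration.
* F3x4/F1x4 frequency models and non-standard genetic codes are not
  implemented.
* Posterior variances for identical-sequence pairs carry ~5e−4 relative
  quadrature error at n = 32 (see above).
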