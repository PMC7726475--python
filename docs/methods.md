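# Methods

## Model

Every estimator in `dcgnet` treats an m-channel recording as a lag-1 vector
autoregression with correlated Gaussian errors,

    y_t = c + Γ y_{t−1} + u_t,      u_t ~ N(0, Σ),  Ω = Σ⁻¹,

and reads two graphs off the parameters: the directed *effective* graph from
the nonzero pattern of Γ (an edge j → i means channel j at time t−1 helps
predict channel i at time t; diagonal entries are within-channel
autocorrelation, kept as self-loops), and the undirected *functional* graph
from the off-diagonal nonzeros of the precision Ω (same-time conditional
dependence; edge weights are partial correlations −Ω_ab/√(Ω_aa·Ω_bb)).
We use the precision, not the covariance, for functional edges: covariance
off-diagonals mix direct and indirect dependence, precision off-diagonals
are the conditional (direct) part.

All fits minimize the scaled negative log-likelihood

    L(Γ, c, Ω) = (1/t)·tr(R Ω R′) − log|Ω|,     R = Y − X·[c; Γ′],

plus penalties λ₁·P on Γ entries and λ₂·P on Ω off-diagonals, with P the
l1 norm (the group-lasso penalty with singleton groups reduces to this) or
SCAD in the Fan–Li form with shape a = 3.7: linear λ|x| up to λ, a quadratic
blend on (λ, aλ], constant λ²(a+1)/2 beyond.  SCAD matters here because the
scientific target is "keep strong links, delete weak ones": the l1 penalty
shrinks *all* coefficients, so any λ large enough to delete weak links
biases the strong ones and information criteria then refuse large λ; SCAD's
flat tail leaves strong links nearly unbiased, letting selection pick a λ
that actually removes the weak links.  This contrast is visible in the
benchmark numbers: support-recovery F1 ≈ 0.86–0.90 for the SCAD-based
methods at BIC-selected λ versus ≈ 0.60 for the pure-l1 variants on the
same data.

### Assumptions

Stationarity (spectral radius of Γ below 1), Gaussian errors, lag order
fixed at 1, and time-invariant parameters within a recording period.
Band-filtered narrowband signals violate the "VAR(1) is the true model"
assumption — they are heavily autocorrelated and nearly perfectly
predictable from one lag — so per-band lag fits sit near the unit root (a
warning is logged above spectral radius 0.98).  The contemporaneous
precision remains well-identified in this regime, which is one reason the
condition contrast below is scored on functional edges.

## Estimators

* **var_ols** — equation-by-equation least squares, Σ̂ = R′R/(t−m−1).  The
  dense reference everything else is compared against.  (Penalized fits use
  the maximum-likelihood scaling R′R/t internally; at λ = 0 their precision
  differs from the OLS one by exactly the factor t/(t−m−1).)
* **glasso** — block alternation: given Γ, a weighted graphical-lasso
  precision step (proximal gradient on Ω with off-diagonal soft threshold,
  step initialized at eigmin(Ω)², followed by a fixed-support Newton polish
  to machine-precision stationarity); given Ω, l1-penalized multi-response
  regression by monotone ISTA with the exact Lipschitz constant.  Both
  half-steps run on sufficient statistics (X′X, X′Y, Y′Y), so fit cost is
  independent of recording length.
* **tscgm** — the same alternation with SCAD handled by local linear
  approximation: each outer iteration re-weights the l1 subproblems by the
  SCAD derivative at the current values, the precision first and the lag
  matrix second, which makes the true SCAD objective non-increasing
  (majorize–minimize).
* **tscgm_nl_*** ("non-linear optimization") — joint damped Newton over the
  stacked parameter (Γ, c, and a Cholesky factor of Ω with log-diagonal, so
  iterates are positive definite by construction).  |x| terms are smoothed
  by a pseudo-Huber of half-width 1e−5; the Hessian is a central finite
  difference of the analytic gradient with a backtracking line search
  (simple decrease, at most 30 halvings).  After each accepted step,
  penalized parameters whose magnitude falls below
  τ·σ_max(J)·(normalized Jacobian column norm) are pinned to exactly zero
  and stay pinned (τ = 1e−3 by default; σ_max is computed by power
  iteration through sufficient statistics).  Lag-matrix zeros are exact;
  precision off-diagonal zeros are inherited through the Cholesky factor
  and therefore approximate — a known limitation of this parameterization.
* **tscgm_it_*** ("iterative optimization") — proximal gradient on (Γ, c, Ω)
  jointly: gradient step on the smooth likelihood, exact soft-threshold
  (l1) or three-zone SCAD threshold on the penalized entries, backtracking
  until the precision iterate is positive definite and the objective
  decreases; eigenvalue flooring at 1e−8 is a logged last resort.

Channels are mean-centered and variance-standardized before every fit
(penalties are scale-sensitive) and estimates are rescaled to original units
on return; zero patterns survive that diagonal rescaling unchanged.
Reported `neg_loglik` and objective histories are on the standardized scale,
i.e. the objective actually optimized.

### Tuning parameters

| parameter | default | meaning |
| --- | --- | --- |
| λ₁ | BIC over {0.01, 0.05, 0.1, 0.2} | penalty on lag coefficients (standardized scale) |
| λ₂ | tied to λ₁ by default | penalty on precision off-diagonals |
| a (SCAD) | 3.7 | width of the unbiased tail; conventional value |
| τ | 1e−3 | Newton-fit zeroing threshold; values above 0.1 trigger a logged caution (they can change the model's behavior, very small values merely restrict the search) |
| tol | 1e−6 relative objective change | convergence of alternating/proximal loops (max 500 iterations) and Newton loops (max 100) |
| q | 0.5 | strong/weak quantile for the VAR reference: links below the median nonzero magnitude count as weak |

λ is selected by BIC = t·L + log(t)·k with k the number of nonzero
parameters (lag entries + intercepts + precision diagonal + off-diagonal
pairs); ties break toward the sparser model, then the smaller λ₁.  The grid
was sized so that the BIC optimum is interior, not at an edge.

## Band decomposition

Recordings are split into theta (0.01–4 Hz), delta (4–8), alpha (8–16),
beta (16–32) and gamma (32–49) components — this five-band table follows
the source convention of the pipeline, which swaps the usual theta/delta
naming; pass a custom band list to rename.  Filters are Hamming
windowed-sinc band-passes with odd, symmetric (linear-phase) taps; the
automatic order is 2·⌈1.65·fs/Δf⌉+1 taps with transition width
Δf = max(1 Hz, 10% of the lower edge), capped at 4001 taps.  A lower edge
within 0.02% of Nyquist of DC (theta's 0.01 Hz at 500 Hz) cannot be
realized at sane filter lengths and becomes a low-pass at the upper edge
(logged).  Application is forward–reverse with reflect padding of 3·order
samples: phase response identically zero, magnitude response |H|².
Designed responses give ≈ 60 dB attenuation one transition width beyond the
band edges and unit gain at band midpoints.  Bandpower is the mean squared
amplitude per tiling window (trailing partial window dropped).

## Synthetic data generator

The generator emulates the study protocol the pipeline targets: two
recording periods ("baseline", "post_stim"), 500 Hz, 5 minutes each
(150,000 samples per period, 300,000 total), 7 channels.  Ground truth is a
stationary sparse VAR(1): off-diagonal lag links placed uniformly at random
at the requested density with magnitudes in [0.2, 0.45] and random sign
(defaults chosen to be well inside detectability at the protocol sample
sizes), diagonal drawn in [0.2, 0.6] for realistic autocorrelation, spectral
radius rescaled to 0.9 if it reaches 0.95.  The error precision is identity
plus a sparse symmetric perturbation; positive definiteness is enforced by
*shrinking the perturbation* until the smallest eigenvalue is ≥ 0.05 rather
than by eigenvalue flooring, because flooring would perturb every entry and
break the generator's support-honesty guarantee (declared nonzero pattern =
actual pattern), which the recovery benchmarks rely on.

On top of the VAR background, each band contributes a per-channel sinusoid
at its center frequency (2/6/12/24/40 Hz, 2% frequency jitter, random
phase) scaled by a per-condition amplitude table; the post-stimulation
period doubles the theta- and gamma-band amplitudes and injects *shared*
oscillators into selected channel pairs (defaults: two gamma pairs, one
theta pair).  A shared oscillator creates contemporaneous dependence
confined to one band — the mechanism by which "the post period gains
gamma-band edges" is made true by construction, without touching the
VAR matrix (which would leak into every band).  Conditions share the same
noise realization (a paired design), so they differ only through amplitudes
and couplings; with all amplitudes zero the output equals the plain VAR
simulation for the same seed, bit for bit.

What the generator does **not** emulate: volume conduction and electrode
geometry, 1/f spectral shape, artifacts (blinks, muscle), non-stationarity
within a period, and non-Gaussian noise.  Passing tests therefore
demonstrate correctness of the estimation machinery under the stated model,
not robustness to real-EEG pathologies.

## Benchmarks and their definitions

* **Recovery suite** (m = 5, density 0.2, t = 2000, 20 seeds): F1 of the
  estimated off-diagonal lag support against truth at BIC-selected λ.  The
  diagonal is excluded because it is always present in both.
* **Strong/weak suite**: 3 strong links with |coef| in [0.4, 0.5] and 3
  weak links with |coef| in [0.01, 0.03].  "Weak" is defined as the
  estimation noise floor — the OLS standard error at t = 2000 is
  1/√t ≈ 0.022 — since links comfortably above that floor are genuine
  signal that a well-calibrated selector *should* keep.  The benchmark
  records the fraction of strong links retained and weak links zeroed by
  the Newton SCAD fit (median over 20 seeds), and the fraction of seeds in
  which a competing method reports at least one link absent from the true
  support (a spurious, "created" link).
* **Condition contrast** (20 seeds, 60-second demo periods): the full
  band-filter → fit → multilayer → compare chain, scored as the number of
  *functional* edges gained post-stimulation per band.  Functional edges
  are the right readout here because the injected couplings are
  contemporaneous and because near-unit-root lag fits on narrowband signals
  have unstable effective-edge support.  The 60-second demo length keeps
  the benchmark quick; fits operate on sufficient statistics, so longer
  recordings change runtime only in the filtering stage.

## Networks and comparisons

An estimate becomes a chain-graph layer at nonzero tolerance 1e−8 (exact
zeros exist only for the thresholding/proximal/pinning methods; the
tolerance makes "≠ 0" well-defined for the rest).  Layers stack into a
multiplex network with a shared node set; the supra-adjacency matrix is
(N·L)×(N·L) with per-layer adjacencies on the diagonal blocks and
coupling·I elsewhere.  Inter-layer replica coupling defaults to 0 because
each band is fit independently — the layers are displayed jointly, not
dynamically coupled.  Edge weights are retained in exports; comparisons use
support sets only.

`compare_methods` scores candidates against a VAR reference split by
`threshold_weak_links` (quantile q of nonzero magnitudes, strictly-below
removal so ties survive): strong links preserved, weak links removed,
links created (absent from the unthresholded reference support).  Note that
against a *dense* reference the created set is empty by construction; the
spurious-link benchmark above therefore scores candidates against known
synthetic ground truth, where "created" is a false positive in the usual
sense.

## Degenerate inputs and numerical edges

Rank-deficient designs raise a `SingularDesignError` naming constant
channels; zero-variance channels get unit scale during standardization so
the error message, not a division, surfaces the problem.  Singular residual
covariances (noiseless data) are ridge-floored at 1e−10 before inversion.
Non-PD intermediates in the proximal fit are first handled by step
halving, then by logged eigenvalue flooring.  Thresholding a precision can
in principle break positive definiteness; `threshold_weak_links` repairs by
flooring and re-inverts so Σ̂·Ω̂ = I always holds on returned estimates.

## Known limitations

Lag order is fixed at 1; no time-varying or hierarchical parameters; no
statistical tests on edges (sparsity itself is the selection mechanism); no
artifact rejection or source localization; EDF files can be read (via mne)
but not written; the Newton variant's precision sparsity is approximate, as
described above.
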