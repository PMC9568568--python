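# Methods

## Model

A complex carries `n_sat` equivalent binding sites, each occupied
independently with probability `p` at the working concentration, so the
occupancy is `K ~ Bin(n_sat, p)` and the expected count per complex is
`E[K] = n_sat * p`. A fraction `f_l` of the component pool carries the
rare B label; given `K = k` the number of B-labelled molecules is
`Bin(k, f_l)`. The observable is the binary state
`S = 1(at least one B molecule)`, a Bernoulli variable whose success
probability marginalises to

```
q = 1 - (1 - p * f_l) ** n_sat
```

(the explicit sum over k collapses by the binomial theorem applied to
`(1-p) + p(1-f_l)`). A sample of `V` scored complexes with `V_plus`
positives contributes the Bernoulli likelihood
`q**V_plus * (1-q)**(V - V_plus)`; only the sufficient statistic
`(V, V_plus)` is stored. Across `m` experiments the likelihood is the
product of per-sample terms with sample-specific `p_j` and one shared
`n_sat` — `m + 1` parameters in total. Concentration is metadata only; it
never enters the likelihood.

Key assumptions: sites fill independently (no steric interaction between
bound molecules, no bivalent bridging), complexes are scored
independently, and `f_l` is known exactly up to pipetting error (whose
effect is quantified separately, below). Independence is an approximation
for densely packed complexes where bound molecules can clash; the method
tolerates the resulting mild non-independence because only the marginal
positive fraction enters the data.

## Numerical evaluation of q

`q` is computed in log space as `-expm1(n_sat * log1p(-p * f_l))`, which
is exact at the boundaries (`q = 0` at `p*f_l = 0` or `n_sat = 0`,
`q = 1` at `p*f_l = 1` with `n_sat >= 1`) and does not underflow at large
`n_sat`. The explicit occupancy sum with exact binomial coefficients is
retained only as a test oracle; the two agree to better than 1e-10 over
randomized grids up to `n_sat = 500` (in practice, to ~4e-16).

## Inference

Posterior sampling is Metropolis-within-Gibbs, written for this model:

* every `p_j` takes a Gaussian random-walk step on the logit scale
  (default SD 0.2), accepted against the joint posterior. Given `n_sat`
  the full conditional factorises over samples, so all `p_j` update
  simultaneously with componentwise accept/reject. The Beta prior
  (default Beta(1,1)) is applied with the logit Jacobian, so a chain can
  never stick at the boundaries 0 or 1.
* `n_sat` is an **integer** parameter with a discrete-uniform prior
  (default support 0..1000) and a symmetric integer random-walk proposal
  (± Uniform{1..10}); proposals outside the support are rejected. The
  integer treatment follows from the binomial model, where `n_sat` is a
  site count; a continuous relaxation (real `n_sat` in the closed form,
  Gaussian proposal) is available behind `SamplerConfig(continuous_nsat=
  True)` for comparison and lands on the same posterior location on
  well-identified data.

Defaults are 4 chains x 20 000 draws after 5 000 burn-in, with per-chain
generators seeded `seed + chain` so runs are bit-reproducible and chains
differ only by seed. Initial states are drawn from the priors and
re-drawn (up to 100 times) if the log-posterior is not finite.

Chains start from a uniform draw over the `n_sat` prior support, far from
the posterior mode, and the posterior couples `n_sat` to every `p_j`
along a `p_j * n_sat ~ const` ridge. Joint fits therefore need a longer
burn-in than the single-parameter fits: the parameter-recovery studies
and the acceptance script use 20 000 burn-in iterations for joint fits,
which brings every R-hat below 1.05 on the study designs used here.
Convergence is gated quantitatively at R-hat < 1.1 on every parameter
(`PosteriorResult.converged()`), replacing visual trace inspection;
summaries (MAP, central 95% credible interval, R-hat, lag-1
autocorrelation, acceptance rates) are computed for every parameter and
serialised by `molcount fit`, and raw draws can be dumped for plotting.

Point and interval summaries: the MAP of an integer parameter is the most
frequent sampled value (ties toward the smallest); for a real parameter
it is the midpoint of the tallest bin of a 200-bin histogram over the
sample range. Credible intervals are central equal-tailed sample
quantiles, not HPD. The R-hat implementation is the standard potential
scale reduction `sqrt(V_hat / W)` with `V_hat = (n-1)/n * W +
(1 + 1/m) * B/n`; for identical chains this is `sqrt((n-1)/n)`, i.e. 1 up
to O(1/n).

Identifiability: with a single sample, `p` and `n_sat` are confounded
(only `q` is observed), so single-sample fits hold `n_sat` fixed. In the
joint model the shared `n_sat` becomes identifiable chiefly through
samples near saturation (`p` close to 1), where the ceiling `p <= 1`
bounds `n_sat` from below and the accumulated `1/n`-scaling of the `p_j`
posteriors penalises larger values; with few samples the upper tail of
the `n_sat` posterior is genuinely heavy, and it tightens as `m` grows.

An exact (to grid resolution) quadrature of the single-sample posterior
over `p` (`grid_posterior_p`, 2001 points) serves as an independent
oracle: MCMC marginals agree with it to Kolmogorov–Smirnov distance
< 0.05 in the test suite.

## Design verification and error robustness

`run_grid` simulates one experiment per cell of a (`p`, `f_l`, `V`)
design grid at a fixed `n_sat` (default 205, an upper-limit stoichiometry
for the adenovirus–antibody validation system), re-estimates `p` blind,
and records the posterior bias (posterior mean minus truth), SD, and
R-hat; non-converged cells are flagged, never dropped. The default grids
are 11 evenly spaced values per axis over `p` in [0.1, 0.99], `f_l` in
[0.01, 0.9] and `V` in [100, 4000] — 1331 cells; the step values are a
reconstruction, as only the ranges and total count are fixed by the
study design. The qualitative landscape: rare labelling
(`f_l <= ~0.1`) with `V >= ~500` estimates `p` with |bias| and SD below
0.05, while `f_l` near 1 saturates the positive fraction and leaves `p`
unidentified.

`pipetting_error_sim` perturbs the true label fraction per replicate as
`f_l * (1 + d_sys) * (1 + d_rand)` — one systematic draw per batch, one
random draw per mixture — and analyses at the nominal `f_l`. Bounds
default to 2.5% systematic and 1.2% random (typical 10 µl manual-pipette
tolerances); the error distribution is Uniform within the bound
(maximum-entropy choice given only a bound), with a Gaussian alternative
(bound read as 2 SD) behind a flag. At `f_l = 0.01`, `V = 4000` the mean
absolute bias changes by well under 0.02 relative to error-free runs.

## Fisher information

The per-particle information about `p` is the Bernoulli information
under reparameterisation,

```
I(p) = (dq/dp)^2 / (q (1 - q)),   dq/dp = n_sat * f_l * (1 - p*f_l)^(n_sat - 1)
```

multiplied by `V` for a full experiment; the design landscape is reported
as inverse information `1/(V*I)`, where low values mark precise designs.
At `n_sat = 1, f_l = 1` it reduces exactly to the textbook `1/(p(1-p))`.
Degenerate designs (`q` of 0 or 1) carry no information and are recorded
as `+inf` in landscapes. The landscape default `p = 0.5` is a
representative mid-occupancy choice. Information about `n_sat` itself is
out of scope. The qualitative conclusion the landscape supports: as
`n_sat` grows the set of usable `f_l` values narrows and the optimum
shifts downward (roughly as `1/(n_sat * p)`), so small `f_l` is the safe
choice when `n_sat` is unknown — at the price of needing larger `V` when
`n_sat` is small.

## Calibration and heterogeneity

`calibrate` anchors the **median** A-channel intensity of a sample to the
model's expected count for that sample and scales every particle's
intensity by the same factor, so the median inferred count equals the
estimate by construction and the conversion is scale-equivariant.
Heterogeneity is summarised by a log-normal fit to the inferred counts —
by maximum likelihood on the counts, not least squares on binned
frequencies, because MLE is bin-independent and reproducible; an R² of
the fitted density against a histogram (Freedman–Diaconis bins by
default) is still reported for comparability with graphing-software
fits. Non-positive counts are excluded from the log fit and their number
reported. Mean counts across a titration are fitted with the one-site
binding curve `n(c) = n_max * c / (K_half + c)` by least squares.

## Synthetic data

The generator realises the hierarchical model exactly: `K ~ Bin(n_sat,
p)`, `B ~ Bin(K, f_l)`, positive iff `B >= 1`, A intensity
`gain * (K - B) * exp(eps)` with log-normal multiplicative noise at a
configurable CV (default 10%), and a fixed log-normal reference channel.
The A intensity tracks the A-labelled molecules `K - B` rather than
`K`; at operating `f_l <= 0.07` the difference is at most 7% and in
practice A intensity is treated as the total-occupancy proxy. The
binding probability of a titration sample follows the Langmuir map
`p(c) = c / (c + K_half)` — a generative convenience for realistic test
data; the inference model never sees concentration. `generate_study`
bundles four titrations over a >100-fold concentration range
(`f_l` 0.007/0.015/0.03/0.07, 1500 particles per sample, 24 samples) as
a realistic full-study design with a known ground truth.

What the simulator deliberately omits: optical blur and segmentation
error, background fluorescence and spectral bleed-through, day-to-day
staining variability, and any non-independence of binding. Passing tests
therefore validate the statistical machinery under the model's own
assumptions — they do not certify performance on real images, where the
upstream scoring pipeline must deliver clean binary calls.

## Problem sizes and tolerances

Simulation-based checks run at deliberately chosen sizes: design-regime
checks use `V = 4000` and 2 chains x 5000 draws (posterior SDs of ~0.01
make Monte-Carlo error negligible at that budget); joint recovery uses
`m = 6` or `m = 24` samples at 4 chains x 20 000 draws with 20 000
burn-in; stochastic recovery criteria use three seeds with a majority
verdict, reflecting that any single simulated dataset can be an outlier.
Numerical tolerances: closed-form agreement 1e-10; derivative checks
1e-5 relative against central differences, restricted to designs with
`q < 0.999` (beyond that the difference quotient is float cancellation
noise); KS < 0.05 for sampler-vs-quadrature agreement.

## Known limitations

* `n_sat` inference needs near-saturating samples; titrations that stop
  well short of saturation leave its posterior upper tail heavy, and the
  sampler mixes slowly along the `p_j * n_sat` ridge (mitigate with
  longer burn-in, or by fixing `n_sat` when it is known).
* The independence assumption biases counts for complexes with strong
  steric interactions; the binary readout is only mildly sensitive to
  this, but it is not corrected for.
* Calibration inherits any nonlinearity between fluorescence and
  occupancy (quenching, self-absorption); the median anchor removes only
  the overall gain.
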