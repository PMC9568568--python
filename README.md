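# molcount

Molecular counting from **binary differential labelling**: estimate the
absolute number of copies of a component within a molecular complex
(its stoichiometry) from simple positive/negative fluorescence scores.

## The problem and the model

Counting molecules inside a complex — say, antibodies bound to a virus
particle — usually needs carefully calibrated intensity measurements or
single-molecule localisation tricks. Binary differential labelling avoids
both: split the component of interest into two batches carrying spectrally
distinct dyes (A and B), mix them so that B is rare (a fraction
*f<sub>l</sub>* of the pool, typically 1–7%), and score each complex only
for whether it carries *any* B label. The fraction of B-positive complexes
then encodes the stoichiometry.

With *n*<sub>sat</sub> binding sites per complex, each occupied
independently with probability *p*, the number of bound molecules is
*K* ~ Bin(*n*<sub>sat</sub>, *p*) and the B-label count given *K* is
Bin(*K*, *f<sub>l</sub>*). Marginalising *K*, the probability a complex is
B-positive has the closed form

> *q* = 1 − (1 − *p·f<sub>l</sub>*)<sup>*n*<sub>sat</sub></sup>

A sample of *V* complexes with *V*<sub>+</sub> positives contributes a
Bernoulli likelihood *q*<sup>*V*<sub>+</sub></sup>(1 −
*q*)<sup>*V*−*V*<sub>+</sub></sup>. Across *m* experiments at different
concentrations the model estimates one *p<sub>j</sub>* per sample and a
**single shared *n*<sub>sat</sub>** (the complex's saturation count does
not depend on concentration), by Metropolis-within-Gibbs MCMC with
Beta(1,1) priors on the *p<sub>j</sub>* and a discrete-uniform prior on
*n*<sub>sat</sub>. The expected count per complex is then
E[*K*] = *n*<sub>sat</sub>·*p<sub>j</sub>*, and the per-sample estimates
calibrate raw A-channel intensities into per-particle molecule counts,
recovering population heterogeneity from an ensemble measurement.

The package also ships the design tools that make the method usable on a
new system: bias/SD verification simulations over (*p*, *f<sub>l</sub>*,
*V*) grids, a pipetting-error robustness study, and Fisher-information
landscapes that identify informative (*f<sub>l</sub>*, *V*) designs across
hypothetical *n*<sub>sat</sub> values from 10 to 1000.

## Worked example

Fit a four-titration study (24 samples, label fractions 0.7–7%, ~1500
particles per sample) simulated at a true saturation count of 133:

```python
from molcount import SamplerConfig, fit_joint, generate_study

scores = generate_study(n_sat=133, seed=7)
res = fit_joint(scores, config=SamplerConfig(n_chains=4, n_draws=20_000,
                                             n_burnin=20_000, seed=7))
lo, hi = res.ci["n_sat"]
print(f"MAP(n_sat) = {res.map['n_sat']:.0f}, 95% CI = [{lo:.0f}, {hi:.0f}], "
      f"max R-hat = {max(res.rhat.values()):.3f}")
j = 5  # highest concentration of the first titration
print(f"sample {scores[j].condition.sample_id}: "
      f"p MAP = {res.map[f'p[{j}]']:.3f}, "
      f"expected count = {res.map['n_sat'] * res.map[f'p[{j}]']:.1f}")
```

prints

```
MAP(n_sat) = 132, 95% CI = [126, 148], max R-hat = 1.005
sample t0s05: p MAP = 0.947, expected count = 125.0
```

The joint fit recovers the generative saturation count (132 vs 133) with a
converged sampler, and the near-saturated sample carries an expected
occupancy of 125 molecules. The same workflow runs from the shell:

```sh
molcount simulate --nsat 133 --fl 0.01 --v 2000 \
    --concentrations 0.15,0.6,2.5,10,20 --seed 7 --out-prefix sim
molcount fit --scores sim_scores.csv --seed 7 --out posterior.json
molcount calibrate --particles sim_particles.csv \
    --estimates posterior.json --out calibrated.csv
molcount verify-grid --nsat 205 --out grid.csv
molcount fisher --p 0.5 --v 1000 --out fisher.csv
```

Real data drop into the same commands: binary scores as a CSV with header
`sample_id,concentration_ug_ml,f_l,n_particles,n_positive`, per-particle
intensities as `sample_id,particle_id,ref_intensity,a_intensity,b_value`.

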