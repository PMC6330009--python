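# pathway-uq

Uncertainty quantification, propagation and global sensitivity analysis for
mass-action models of intracellular signalling pathways.

Dynamical models of pathways such as the CaMKII/calmodulin/PP2B system that
governs synaptic plasticity are usually over-parameterized with respect to
the available dose-response data: many parameter combinations fit equally
well, so point estimates are misleading.  `pathway-uq` treats calibration
as inverse uncertainty quantification and asks three questions that matter
for experimental design and model building:

1. **Which parameter sets are viable?**  Approximate Bayesian computation
   (ABC) samples the approximate posterior
   f(θ | ρ(y_sim, y_exp) ≤ δ) — parameter draws whose simulated curves lie
   within distance δ of the data.  ABC-MCMC uses an adaptive threshold that
   shrinks to δ within a single run, and multiple datasets are merged
   sequentially: the posterior after each dataset is compressed into an
   R-vine copula (KDE marginals + pair copulas) and used as the prior for
   the next.
2. **How uncertain are the predictions?**  The posterior sample is pushed
   through the model to a prediction ensemble; uncertainty is the
   per-input-point variance V(Y_pred).
3. **Which parameters drive that uncertainty?**  First-order sensitivity
   indices S_i = V(E(Y|Θ_i))/V(Y), estimated by binning the *dependent*
   posterior sample (no independence assumption), plus Monte Carlo
   filtering: classify the predictions qualitatively, split the sample by
   class, and rank parameters by Kolmogorov-Smirnov distance and parameter
   pairs by symmetrized Kullback-Leibler divergence.

The supporting machinery handles the thermodynamic structure of reversible
mass-action networks: moiety conservation laws, Wegscheider cycle
conditions that split the dissociation constants into free and constrained
sets (Σ_j z_j log10 Kd_j = 0 around every cycle), and a detailed-balance
equilibrium solver in log-concentration space, so steady-state phenotypes
depend only on the Kd = kr/kf parameters.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Fit the bundled six-species demo network (ligand-binding protein L, ligand
X, partner P; one thermodynamic cycle, so Kd4 is constrained to
Kd1·Kd2/Kd3) to synthetic titration data with 2% noise, sequentially
through the copula chain:

```python
from pathway_uq import ABCConfig, credible_intervals, default_prior, sequential_fit
from pathway_uq.synthetic import (
    SyntheticSpec, demo_network, demo_setups, demo_theta_true, synth_data,
)

net = demo_network()
truth = demo_theta_true()          # log10: Kd1=0.30, Kd2=0.10, Kd3=-0.20
spec = SyntheticSpec(theta_true=truth, noise="additive_gaussian",
                     sigma=0.02, seed=7)
setups = synth_data(net, spec, demo_setups())
cfg = ABCConfig(delta_target=0.05, n_iterations=1500,
                proposal_step=0.25, adapt_block=100, seed=7)
post = sequential_fit(net, [[setups[0]], [setups[1]]],
                      default_prior(net), cfg)
print(credible_intervals(post.matrix, 0.95, names=post.names))
```

Output:

```
parameter     lower    median     upper  level
      Kd1  0.125372  0.309177  0.490207   0.95
      Kd2 -0.023546  0.110197  0.249329   0.95
      Kd3 -0.302412 -0.209904 -0.108461   0.95
```

Each 95% credibility interval covers its generating value (0.30, 0.10,
−0.20): after conditioning on both titration curves the three free
dissociation constants are pinned to within roughly ±0.2 log10 units,
compared with the ±3 log10-unit prior.  The corresponding entropy
reductions (H_diff = H_prior − H_post, in nats) quantify the same gain per
parameter: the prior histograms sit at H_prior ≈ ln 6 ≈ 1.77 nats, the
posterior marginals concentrate enough that H_post turns negative, and
H_diff reaches 2.5–3.0 nats for all three parameters.

The same pipeline is scriptable from the shell:

```bash
pathway-uq synth --noise 0.02 --seed 7 --out fixtures/
pathway-uq model validate fixtures/model.tsv
```

```
species: 6
reactions: 4
  mass-action reversible: 4
  custom: 0
thermodynamic constraints: 1
  free Kd: 3
  constrained Kd: Kd4
conservation laws:
  total L: L + LX + LP + LXP
  total X: X + LX + LXP
  total P: P + LP + LXP
```

`pathway-uq fit / copula / characterize / propagate / gsa / filter` expose
the remaining stages; a 25-species synthetic reconstruction of the
CaMKII/CaM/PP2B/PP1 network ships as
`src/pathway_uq/data/camkii_synthetic.tsv` for structural testing.

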