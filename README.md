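# salience-dcm

Spectral dynamic causal modeling of the salience network (dorsal anterior
cingulate cortex, dACC, and anterior insula, AI) with metabolite-informed
group analysis — built for studying how glutamate (GLU) and glutathione
(GSH) levels measured by 7T MRS in the dACC relate to effective connectivity
in first-episode schizophrenia (FES) versus healthy controls (HC).

The scientific question the toolchain addresses: does inhibitory
(GABAergic) activity within the dACC–AI circuit *decrease* with glutamate
and *increase* with glutathione in patients — i.e. can an antioxidative
state counteract glutamate-driven disinhibition?  Since the clinical data
of such studies are typically available only on request, the package frames
the question as a parameter-recovery experiment: a synthetic study
generator emulates the design (n = 20 HC / 19 FES, 360 resting-state
volumes at TR 1 s, group-shifted metabolite levels coupled to inhibitory
connectivity), and the full inference chain must recover what was planted.

The chain has three stages, each usable on its own:

1. **Hierarchical Bayesian metabolite comparison** — per metabolite,
   `y_i = β0 + β_group(i)`, Gaussian residual σ_i, data-scaled priors, a
   gamma hyperprior on the deflection SD σ_β so the groups regularize each
   other; Metropolis-within-Gibbs, 11,000 retained draws (thin 10); reports
   posterior mean/median/mode, 95% HDI, posterior proportion (PP) of the
   directional claim and the standardized effect size `(β_FES − β_HC)/σ_i`.
2. **Subject-level spectral DCM** — each region is a two-state (E/I) node;
   free parameters are log scaling factors on the between-region E→E
   connections (default +1/8 Hz) and within-region I→E connections
   (default −1/8 Hz).  The model predicts the complex BOLD cross-spectral
   density through a linearized balloon model, and a variational-Laplace
   scheme (Gauss–Newton, Levenberg–Marquardt damping) fits it to the Welch
   CSD of the prepared ROI pair, returning a Gaussian posterior and its
   free energy F.
3. **Parametric empirical Bayes (PEB)** — subject posteriors enter a
   hierarchical GLM with design (group ±1, centred GLU, GLU×group, centred
   GSH, GSH×group, constant).  Bayesian model reduction scores the
   "only-group" model analytically from the full fit, and fixed-effects
   model comparison uses `PP_i = softmax(F_i)` with PP > 0.95 as the
   decision rule (a Bayes factor of 20 ↔ PP 20/21 ≈ 0.952).

## Worked example

```python
import numpy as np
from salience_dcm import (StudyConfig, simulate_metabolites, simulate_bold,
                          DCMParams, estimate_csd, variational_laplace)
from salience_dcm import metabolite_bayes, prep

# metabolite stage on a synthetic cohort
cfg = StudyConfig(seed=7)
table = simulate_metabolites(cfg)
post = metabolite_bayes.fit_group_model(table, "gsh", seed=11)
diff = post.difference
print(metabolite_bayes.summarize(diff).mode,
      metabolite_bayes.posterior_proportion(diff))
# 0.246 0.975   -> GSH higher in FES: mode of the difference 0.25 mM, PP 0.97

# subject stage: simulate one subject with weakened inhibition and invert
params = DCMParams().with_connectivity(np.array([0.0, 0.0, -0.3, -0.7]))
bold = simulate_bold(params, n_vol=360, tr=1.0, seed=3)
clean = prep.remove_confounds(prep.TimeseriesPair(tr=1.0, data=bold))
fit = variational_laplace(estimate_csd(clean.data, tr=1.0))
print(fit.mean[:4].round(2))
# [ 0.27  0.01 -0.24 -0.39]  -> inhibitory log-scalings recovered with the
# correct ordering (dACC -0.3, AI -0.7); E->E scalings are weakly
# identified at this record length and stay near their prior
```

The end-to-end pipeline and the replicated recovery experiment are a single
call (or `salience-dcm run` / `salience-dcm recover` from the shell):

```python
from salience_dcm import run_study, recovery_experiment
manifest, report = run_study(StudyConfig(seed=1), out_dir="runs/demo")
# report["model_comparison"]["winner"] -> "two_metabolite"
# report["peb"]["effects"]["gsh_by_group:ie_ai"] -> sign +1, PP ...
```

A `salience-dcm` console script exposes `simulate`, `prep`, `fit-dcm`,
`peb`, `fit-metabolites`, `run` and `recover` subcommands; every stage
writes plain CSV/JSON/YAML artifacts.

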