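# cattlernm

Pedigree-based reaction-norm animal models for genotype-by-environment
interaction (GxE) under prenatal drought and heat stress in beef
cattle.

Growth of a calf depends on the environment its dam experienced before
its birth: cumulative rainfall over the year, gestation, or last
trimester before birth (`sumPrec365`, `sumPrec280`, `sumPrec90`, mm)
and heat load as the mean temperature-humidity index over the last 90
days (`meanTHI90`). This package asks how much of the *genetic* control
of birth weight (BW) and weaning weight (WW) changes along those
environmental gradients — the question a breeder in a drought-prone
system needs answered before selecting bulls on records from good
years.

The core model is a bivariate maternal reaction-norm animal model: for
each trait, fixed effects (sex × birth type, parity, vegetation zone,
weaning age for WW, fixed EC regression) plus random contemporary-group
and maternal-permanent-environment effects (2×2 across traits) and
direct + maternal additive-genetic random regressions on the scaled EC,

    y_t = X_t a_t + Q_t b_t + R_t c_t + Z_t u_t + W_t v_t + e_t ,

with the stacked 8-vector of per-animal coefficients
(u<sub>bw0</sub>, u<sub>bw1</sub>, u<sub>ww0</sub>, u<sub>ww1</sub>,
v<sub>bw0</sub>, v<sub>bw1</sub>, v<sub>ww0</sub>, v<sub>ww1</sub>)
distributed as A ⊗ G8 over the pedigree. Components are estimated by
accelerated EM-REML on the sparse mixed-model equations (a hand-written
LDL' factorization with a Takahashi selected inverse supplies the exact
prediction-error-variance traces the EM updates need). Downstream the
package computes gradient-wise heritabilities, cross-gradient and
cross-trait genetic correlations, intercept-slope statistics,
gradient-specific EBVs, plasticity classes (robust / plastic /
extremely plastic by |slope| against the population slope SD) and elite
sire re-ranking. A synthetic-herdbook generator (pedigree, weather,
phenotypes drawn under the exact model) makes the whole chain testable
without any proprietary data.

## Worked example

Run the analysis scripts in order (each prints what it found and
writes its tables under `results/`):

```sh
python analysis/01_simulate.py
python analysis/02_covariates.py
python analysis/03_qc.py
python analysis/04_screen.py
python analysis/05_fit_rnm.py
python analysis/06_genetic_params.py
python analysis/07_ebv_plasticity.py
```

On the default desk-scale herd (~1,900 animals, 6 farms, seeded, with
the reaction norm driven by `sumPrec365`), the run prints, among other
things:

```
records:  1909 (BW 1909, WW 1635)
BW mean 37.3 kg (sd 5.4); WW mean 230.3 kg (sd 26.5)
...
 sumPrec365 ww: b = +0.0126 (se 0.0054), p = 1.90e-02, n = 1198
 sumPrec280 ww: b = +0.0044 (se 0.0059), p = 4.62e-01, n = 1198
...
 sumPrec365 bw: h2_direct 0.13-0.37, h2_maternal 0.05-0.10
 sumPrec365 ww: h2_direct 0.33-0.38, h2_maternal 0.13-0.19
...
 sumPrec365 ww: 35 elite sires, rank corr(-1,+1) = 0.94, robust/plastic/extreme = 51%/34%/14%
  sumPrec90 bw: 35 elite sires, rank corr(-1,+1) = 0.83, robust/plastic/extreme = 34%/40%/26%
```

Read: a wetter year before birth adds ~12.6 g of weaning weight per mm
of cumulative rainfall at the phenotypic scale (the mid-gestation
window shows no effect, as simulated); direct heritabilities for BW
vary almost three-fold along the rainfall gradient; and ranking the 35
elite sires at the dry versus wet extreme gives rank correlations of
0.83–0.98 — mild but real re-ranking — with roughly half of them
classified robust and the rest plastic or extremely plastic. All
numbers are deterministic for the configured seed.

The same chain is available as one call:

```python
from cattlernm.pipeline import RunConfig, run_pipeline
from cattlernm.simulate import SimScenario

result = run_pipeline(RunConfig(out_dir="out", scenario=SimScenario(seed=7),
                                ec_names=("sumPrec365", "meanTHI90")))
```

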