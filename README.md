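# climniche

Phylogenetic comparative analysis of climatic-niche evolution for
species-level molecular datasets — built for the question "how have the
climatic preferences of a clade (for example the lichen photobiont
*Trebouxia*) evolved, and how fast?". The inputs are an ultrametric,
time-scaled phylogeny (optionally with a sample of posterior trees to
integrate over dating and topology uncertainty) and an accession-level
table of bioclimatic values (BIO1–BIO19) per operational taxonomic unit
(OTU). The package is aimed at researchers in phylogenetics, lichenology,
and macroevolution who want a scripted, reproducible version of the
standard R comparative-methods workflow in Python.

## What it computes

For each climate variable, on the MCC tree and every posterior tree:

- **Phylogenetic signal** — Blomberg's *K* with per-OTU sampling error and
  a tip-randomization test. With shared-ancestry matrix *C* (entries =
  root-to-MRCA path length, Myr), GLS mean *â* and error-inflated
  structure *C̃ = C + E/σ̂²* (E = diag(se²), σ̂² the ML Brownian rate):

  *K* = (MSE₀/MSE) / E[MSE₀/MSE]₍BM₎, where MSE₀ = (x−â)ᵀ(x−â)/(n−1),
  MSE = (x−â)ᵀC̃⁻¹(x−â)/(n−1), and E[MSE₀/MSE]₍BM₎ =
  [tr(C̃) − n/(1ᵀC̃⁻¹1)]/(n−1). *K* = 1 is the Brownian-drift expectation;
  *K* → 0 means phylogeny-independent trait values.

- **Disparity through time (DTT)** — mean relative subclade disparity
  (average squared pairwise difference) traced from root to present, the
  **MDI** statistic (signed area between the observed curve and the median
  of Brownian simulations), and its one-sided simulation p-value.

- **Trait-evolution model selection** — ML fits of Brownian motion
  (V = σ²C), single-optimum Ornstein–Uhlenbeck
  (V = σ²/(2α)·e^(−2α(T−C))·(1−e^(−2αC)), root state free), and early
  burst (rate ∝ e^(at), a ≤ 0), all with known sampling error as a fixed
  diagonal, compared by small-sample Akaike weights (AICc_w). On an
  ultrametric tree the OU fit is likelihood-identical to exponentially
  accelerating rates, and the package exposes that equivalence.

- **Rates** — diffusion-rate (σ²) contrasts between paired variables
  (defaults: BIO5 vs BIO6, BIO16 vs BIO17) with 95% HPD intervals over the
  posterior trees, and absolute per-tip rates of niche change:
  |tip value − GLS-reconstructed parent state| / branch duration, in trait
  units per Myr, under the best-fit model's covariance, for per-OTU mean,
  minimum, and maximum values.

A first-class synthetic-data module generates birth–death chronograms,
jittered pseudo-posterior ensembles, correlated 19-variable climate
tables, and accession tables with the heavy-tailed count structure real
sequence archives produce (min 1, mean ≈ 29, max 454 accessions/OTU), so
every analysis is testable end-to-end without downloads.

## Worked example

```python
import numpy as np
from climniche import (SimulationConfig, make_fixture_study, load_ensemble,
                       read_accessions, summarize_all, trait_vector,
                       k_randomization_test, dtt_test, fit_all_models,
                       absolute_tip_rates)

paths = make_fixture_study("toy_study",
                           SimulationConfig(n_tips=81, n_posterior=20, seed=42))
ens = load_ensemble(paths["mcc"], paths["posterior"])
summary = summarize_all(read_accessions(paths["accessions"]))
x, se = trait_vector(summary, "BIO1", ens.mcc.tip_labels)

print(k_randomization_test(ens.mcc, x, se, n_rand=1000, seed=1).summary())
print(dtt_test(ens.mcc, x, n_sim=1000, seed=2).summary())
comp = fit_all_models(ens.mcc, x, se)
print(comp.summary())
rates = absolute_tip_rates(ens.mcc, x, comp.best, se=se)
print(f"mean |rate| = {np.nanmean(rates['rate']):.4f} trait units/Myr")
```

prints

```
Blomberg's K = 1.1192  (sigma2_hat = 0.0387)
randomization p = 0  (1000 permutations)
MDI = -0.0033   p(MDI as negative) = 0.457   p(MDI as positive) = 0.543   [1000 BM simulations, sigma2_hat = 0.09776]
model            lnL          AICc    weight        sigma2       shape
BM         -137.1582      278.4702    0.5912      0.038703
OU         -137.1582      280.6280    0.2010      0.038703       1e-08
EB         -137.1249      280.5614    0.2078     0.0485603   -0.003049
best: BM
mean |rate| = 0.1197 trait units/Myr
```

BIO1 in this toy study evolves by Brownian drift: *K* sits near (here just
above) the Brownian expectation of 1 and no permutation reaches it
(p = 0); the DTT curve tracks the simulated Brownian envelope (MDI ≈ 0);
the BM model carries the largest AICc weight, with OU collapsing onto it
(α at its lower bound); and tips changed by ≈ 0.12 trait units per Myr on
average.

The same analyses run from the shell over all variables and trees, writing
tidy CSV reports:

```bash
climniche make-fixtures --outdir toy_study --seed 42 --n-posterior 20
climniche all --mcc toy_study/mcc.nwk --posterior toy_study/posterior.nwk \
    --accessions toy_study/accessions.csv --groups toy_study/groups.yaml \
    --seed 1 --n-rand 1000 --n-sim 1000 --outdir toy_out
```

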