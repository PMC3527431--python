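# grnevo

Individual-based simulation of evolving gene regulatory networks under
colored environmental noise, with assays for mutational robustness,
directional epistasis and evolvability.

## The scientific problem

Whether a population's capacity to adapt ("evolvability") can itself evolve
depends on how its genetic system turns mutations into heritable phenotypic
variation — and on the temporal structure of the environment doing the
selecting. Positively autocorrelated (red) environmental fluctuations change
slowly enough for populations to track them, which can maintain genetic
variation and select for genotypes that buffer lethal mutational effects
while still producing variant phenotypes. Randomly varying (white)
environments provide no such opportunity. `grnevo` implements a gene-network
model to study this: it is aimed at evolutionary systems biologists who want
a reproducible, scriptable engine for fluctuating-selection experiments on
regulatory networks.

## The model

A genotype is an `N x N` matrix `A` of regulatory effects among `N = 10`
genes with fixed topology (connectance `c = 0.75`, i.e. 75 interactions).
Development iterates

    s_i(t+1) = f( Σ_j a_ij s_j(t) ),   f(x) = 2/(1+e^(-a x)) - 1,

for 100 steps; a genotype is viable iff expression settles
(`V = (1/10) Σ_t D(S(t), S_ave) < 1e-4` over the last 10 states, with
`D(S,S') = Σ_i (Δs_i)^2 / 4N`). Populations of 250 evolve through pools of
1000 viable offspring produced by row-wise recombination (or cloning) and
per-element mutation at genomic rate `mu = 0.1`; the 250 offspring closest
to the current optimum `S_opt(t)` survive (fitness `F = e^(-D/σ)`,
`σ = 0.05`, rank truncation). `S_opt(t)` is constant (stabilizing), a fixed
displaced target (directional), or the founding phenotype shifted by red
noise `E(t) = Σ_f f^(-γ) sin(2π f t/n + θ_f)` or by its white (permuted)
control. Robustness and epistasis of evolved networks are summarized by
power-law fits `ln(W_m) = -α m^β + ln(100)` (viability) and `W_m = α m^β`
(phenotypic distance) over `m = 1..6` accumulated mutations; evolvability is
the rate of decline of ln distance to novel random targets over four
generations of selection. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from grnevo import (SimConfig, random_stable_seed, mutation_accumulation,
                    fit_viability_powerlaw, fit_distance_powerlaw,
                    evolvability_assay, run_simulation)
from grnevo.metrics import time_average

rng = np.random.default_rng(7)
net, s0 = random_stable_seed(10, 0.75, rng)    # rejection-sample a stable founder

resp = mutation_accumulation(net, s0, rng=rng)  # m = 1..6, 50 replicates each
fv = fit_viability_powerlaw(resp)
fd = fit_distance_powerlaw(resp)
ev = evolvability_assay(net, s0, rng=np.random.default_rng(1), n_targets=10)

cfg = SimConfig(regime="red", period=50, generations=500, assay_every=250)
res = run_simulation(cfg, seed=3)
```

Output for this founder and these seeds:

```
W_m  : [94. 90. 76. 72. 70. 60.]
dist : [0.213 0.299 0.448 0.536 0.819 0.851]
viability fit: alpha=0.058 beta=1.202 W1=94.3 r2=0.960
distance fit : alpha=0.193 beta=0.813 1/W1=5.195 r2=0.961
evolvability : rate=0.0362 variation=0.0802
```

Reading: one mutation leaves ~94% of this founder's mutants viable
(`W1 = 94.3`, high viability robustness), and lethality accelerates mildly
with load (`beta = 1.20 > 1`, weak synergistic epistasis). Each mutation
moves the phenotype ~0.19 Euclidean units (`1/W1 = 5.2` phenotypic
robustness), with sub-linear accumulation (`beta = 0.81`). Under directional
selection toward random targets, the cloned population closes ~3.6% of its
log distance per generation while producing a distance SD of ~0.08.

The 500-generation red-noise run records tidy population metrics at the
assay cadence, e.g. at generation 500 allelic diversity 2.47 alleles/locus,
232 distinct phenotypes among 250 members, 74% of weights changed from the
founder, and survivor mean log fitness -0.07;
`time_average(res.mean_log_fitness, 250)` gives the geometric-mean-fitness
measure (-0.348 here).

The same experiments run from the shell:

```bash
grnevo preset-list
grnevo simulate --preset red-n50-sexual --seed 1 --out runs/red50 --generations 2000
grnevo assay --network runs/red50/founder-r0.json --s0 runs/red50/s0-r0.json \
             --mode mutation --seed 1 --out robustness.csv
```

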