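# tmaze

Chemotactic cell sorting in a microfluidic T-maze: transport models,
phenotype heterogeneity, and sorting-index analysis.

## The problem

Swimming bacteria such as *Escherichia coli* climb chemical gradients by
biasing a run-and-tumble random walk. Within a clonal population, expression
noise makes individual cells differ in two key traits: the **tumble bias**
T_B (probability of being in the tumbling state, which sets the run time and
hence the random-motility diffusivity D) and the **pathway gain** g = N·H
(receptor-cluster cooperativity N times motor amplification H, which sets
how strongly a sensed gradient is amplified). Both feed into the chemotactic
sensitivity coefficient χ and the drift speed up a gradient,

    v_c = χ₀ (K_A − K_I) ∇C / [(K_A + C)(K_I + C)],
    χ₀ = ½ v² (1 − a₀) g τ_t / T_B,

which reduces to linear sensing (v_c = χ_G ∇C) at low attractant and log
sensing (v_c = χ_L ∇C/C) for K_I ≪ C ≪ K_A.

A branching microfluidic maze — a series of T-junctions overlaid on a steady
linear attractant gradient — turns this into a sequence of binary decisions:
at every junction a cell migrates into the up- or down-gradient branch.
Because the steady accumulation slope v_c/D is independent of swimming
speed, the maze sorts cells by *sensitivity*, not motility: stronger
chemotaxers are progressively enriched at deeper junctions. Comparing the
junction-resolved cell counts with a chemotactically homogeneous model
population quantifies the heterogeneity of χ within a clonal population.

This package implements, for that assay:

* the reconstructed device geometry and steady linear attractant field
  (`tmaze.geometry`);
* single-phenotype chemotaxis relations (`tmaze.chemotaxis`);
* a mass-conserving 2-D advection–diffusion solver on the masked channel
  network (`tmaze.transport`);
* the 1-D analytical navigation model — branch-split diffusion counts B_n,
  sorting indices S_n, navigation performance P_n — validated against the
  2-D solver (`tmaze.navigation`);
* the phenotype-heterogeneity model: Beta tumble bias, the compound
  pathway-gain density h_g (Poisson cluster size × Gamma Tar/Tsr ratio ×
  Gaussian motor gain), joint and chemotactic-velocity densities, and
  Monte-Carlo sampling (`tmaze.population`);
* the analysis pipeline: heterogeneous counts N_B(n,t), heterogeneous
  sorting index H_n, junction marginals and velocity distributions, the χ
  and σ fits, log-profile slopes, choice factor and empirical sorting index
  (`tmaze.heterogeneity`);
* a synthetic-data generator (stochastic agents with per-phenotype drift and
  diffusivity, Poisson counting noise, two-strain and sorted/unsorted
  experiment layouts) standing in for microscopy observations
  (`tmaze.synthetic`);
* a thin CLI: `tmaze simulate-2d | simulate-agents | analyze-profiles |
  fit-heterogeneity | reproduce` (`tmaze.cli`).

## Worked example

```python
from tmaze import (MazeGeometry, linear_regime_field,
                   PopulationHyperparameters, MazeHeterogeneityModel)

geom = MazeGeometry()                      # reconstructed 4-junction device
field = linear_regime_field(geom)          # 0-5 uM attractant, linear sensing
hyper = PopulationHyperparameters()        # alpha=5, beta=17, ..., sigma=7.8

model = MazeHeterogeneityModel(hyper, geom, field)
print(f"gradient          : {field.gradient*1e3:.3f} nM/um")
print(f"mean phenotype    : g = {model.gbar:.1f}, T_B = {model.tbar:.3f}")
print(f"mean drift speed  : {model.vbar_i[0]:.2f} um/s (chi_G * dC/dy)")
for n in range(1, 5):
    H = model.heterogeneous_sorting_index(n)
    v = model.anchor_epsilon(1.1, 2400.0).junction_mean_velocity(n, 2400.0)
    print(f"junction {n}: H_n = {H:5.2f}   mean v_c = {v:.2f} um/s")
```

prints

```
gradient          : 1.407 nM/um
mean phenotype    : g = 76.2, T_B = 0.227
mean drift speed  : 0.90 um/s (chi_G * dC/dy)
junction 1: H_n =  1.04   mean v_c = 1.10 um/s
junction 2: H_n =  1.31   mean v_c = 1.42 um/s
junction 3: H_n =  2.36   mean v_c = 2.09 um/s
junction 4: H_n =  6.65   mean v_c = 3.13 um/s
```

`H_n` is the heterogeneous sorting index — how many times more cells of the
heterogeneous population reach junction n than a homogeneous population
carrying the mean phenotype would. It grows junction by junction because the
right-skewed gain distribution lets high-gain cells dominate deep in the
maze (H₄ ≈ 6.6 in the linear regime; ≈ 2.9 in the log regime, where the
decreasing relative gradient weakens selection). The mean chemotactic
velocity of the cells present at each junction rises from 1.1 to ~3.1 µm/s:
the maze progressively selects low-tumble-bias, high-gain phenotypes.

## Layout

```
src/tmaze/        library (geometry, chemotaxis, transport, navigation,
                  population, heterogeneity, synthetic, config, cli)
tests/            pytest suite, including end-to-end acceptance checks
docs/methods.md   model description, conventions, and limitations
scripts/          acceptance script
```
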