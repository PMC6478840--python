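# Methods

This note documents the models implemented in `tmaze`, the conventions and
numerical choices behind them, and what the synthetic data do and do not
emulate.

## Device reconstruction

The maze is a series of `n_junctions = 4` T-junctions on a steady linear
attractant gradient. Each junction is a vertical stem of length `2·y_v`
(y_v = 600 µm, the semibranch length) fed horizontally at its midpoint; its
up-gradient end leads to the next junction's feed, its down-gradient end to
a dead-end channel of length `horizontal_len` (default 1000 µm). Consecutive
stems are offset vertically by `y_v`, so the maze spans
`(n_junctions + 1)·y_v = 3000 µm` along the gradient.

Exact fabrication dimensions are not available; the defaults are fixed by
internal consistency with the quantities the assay reports:

* the slope-fitting window [750, 1100] µm along a stem implies a stem length
  of 1200 µm (y_v = 600);
* in the high-attractant (0–500 µM) configuration the test channel spans
  47–469 µM, which over the 3000 µm span gives the gradient
  ∇C = 422/3000 ≈ 0.1407 µM/µm; the low-attractant (0–5 µM) configuration is
  the same field divided by 100;
* the field is parameterized by the fractional band (0.094, 0.938) of the
  source–sink gap that the maze occupies (47/500 and 469/500), so arbitrary
  source/sink pairs scale correctly;
* the nominal inlet position (`inlet_y` = 661 µm) is where the field equals
  the reported inlet concentration (140 µM at 0–500 µM); the 2-D mask
  attaches the inlet channel at the junction-1 feed (600 µm), and the 61 µm
  offset enters only the inlet concentration `C_0` and the path distances.

Path distances from the inlet port to the up-gradient end of junction n are
`d_n = inlet_len + |inlet_y − feed_1| + (n−1)(y_v + horizontal_len) + y_v`
(defaults: 961, 2561, 4161, 5761 µm). All dimensions are configurable.

## Single-phenotype chemotaxis

A phenotype is (g, T_B): pathway gain and tumble bias. With run speed
`v = v_r (1 − T_B)`, tumble duration τ_t = 0.2 s and mean reorientation
cosine ⟨cos θ⟩ = 1/3:

* sensitivity χ₀ = ½ v² (1 − a₀) g τ_t / T_B,
* diffusivity D = v² τ_t / [3 T_B (1 − ⟨cos θ⟩)],
* drift v_c = χ₀ (K_A − K_I) ∇C / [(K_A + C)(K_I + C)], with Tar
  dissociation constants K_I = 18 µM, K_A = 2.9 mM.

Since χ₀ and D share the v² factor, the steady accumulation slope v_c/D is
independent of swimming speed — the property that makes the maze a
sensitivity sorter. The kinase steady-state activity a₀ (default 1/3) and
run speed v_r (default 25 µm/s) are not separately identifiable from maze
data; they only enter through the grouped constant ε (below), which is
calibrated, so these defaults cancel out of every pipeline result.

The low-concentration limit gives linear sensing v_c = χ_G ∇C and the
window K_I ≪ C ≪ K_A gives log sensing v_c = χ_L ∇C/C. Note the 1/C form's
relative error against the full response is (1 + C/K_A)(1 + K_I/C) − 1,
which for these dissociation constants is never below ≈ 16%; the regime
limit is therefore meaningful as a *shape* statement (within 10% across
[5 K_I, K_A/5] once matched at the window center), not as a pointwise one.
The population-average sensitivities fitted to junction-1 profiles are
χ_G = 6.4×10² µm²s⁻¹µM⁻¹ and χ_L = 1.4×10³ µm²s⁻¹, and the population
diffusivity is D = 330 µm²/s.

## 2-D transport solver

∂B/∂t = D∇²B − ∇·(v_c B) on the rasterized channel mask with reflecting
walls. Operator splitting per step: explicit first-order upwind advection in
y (monotone; CFL-checked) followed by backward-Euler diffusion with a
pre-factorized sparse operator (unconditionally stable). Both half-steps
conserve mass exactly on the masked grid (relative drift ~1e-13 over 1000
steps) and keep the density non-negative. Drift acts only inside stems
(where the channel is parallel to the gradient); in a horizontal channel an
upward drift only biases the cross-channel profile and does not transport,
so omitting it is equivalent at the resolutions used. Defaults: grid 10 µm,
step 1 s. The initial condition is a unit-density disc of radius
`port_radius` (default: the channel width) at the inlet port, emulating the
seeded droplet.

The discrete steady profile of the upwind scheme in a closed stem has slope
`ln(1 + v_c dx/D)/dx`, within 1.4% of v_c/D at dx = 10 µm; slope tests use
interior windows away from the feed and branch mouths, where weak steady
circulation loops through channel crossings perturb the profile locally.

## 1-D navigation model

Unfolding the maze along the swimming path, a purely diffusive population
halves at each junction and arrives with the branch-split Gaussian

    B_n(t) = (B_0/2ⁿ) exp[−d_n²/(4Dt)] / √(4πDt).

Chemotaxis multiplies B_n by a sorting index S_n built from the per-junction
drift speeds v_c,i over the semibranch y_v. Two closed exponential forms are
provided, differing only in sign:

* **growth** (default in `tmaze.navigation`):
  S_n = exp[+Σ_{i≤n} i y_v v_c,i/(4D)] — larger than 1 and exponentially
  increasing with junction number, the qualitative behavior of the
  advective-to-diffusive arrival ratio;
* **transit**: the same magnitude with a damped exponent, the compact form
  obtained when the two-Gaussian ratio is evaluated at the chemotactic
  transit time t_n* = Σ i y_v/v_c,i, where the quadratic displacement cost
  (d − v t)² dominates the linear gain for n ≥ 3.

Neither closed form matches a brute-force 1-D advection–diffusion solution
quantitatively for deep junctions: at v_c = 0.9 µm/s the brute-force
arrival-density ratios at the junction ends (at t_n*) are ≈ 1.9, 3.5, 6.1,
10.5 for n = 1…4, which the growth form brackets from above (1.5, 3.4, 12,
60) and the transit form from below. The package therefore treats the
exponential forms as model *definitions* (they are what the heterogeneity
quantification is defined through), exposes both, and validates transport
behavior against the brute-force solver (`solve_path_1d`) and the 2-D
code: normalized last-junction occupancy time-courses of the 1-D path model
and the 2-D solver agree within 4–10% for drift speeds 0–2.5 µm/s.

## Phenotype heterogeneity

* Tumble bias: Beta(α = 5, β = 17); mean T̄_B = 5/22 ≈ 0.227.
* Pathway gain g = N·H compounds cluster size N_tot ~ Poisson(λ = 9)
  (conditioned on N_tot ≥ 2), Tar/Tsr ratio r ~ Gamma(γ = 2.2, δ = 0.7)
  with N = r N_tot/(r + 1) (integer N from 1 to N_tot − 1; the composition
  weight diverges at N = N_tot, which is excluded), and motor gain
  H ~ Normal(µ = 15, σ) truncated at zero. σ is the model's only free
  parameter; its fitted value 7.8 is the default.
* g and T_B are independent; the joint density factorizes.

The compound gain density is tabulated by a truncated double sum
(k ≤ max(40, λ + 8√λ), grid up to 3µλ with ~3000 points) and normalized
numerically; the raw truncated mass (≈ 0.97 at σ = 7.8, the deficit mostly
from the zero-truncation of the motor-gain Gaussian) is kept as a
diagnostic. The mean gain is ḡ ≈ 76. Because of the truncation the mean is
not exactly σ-independent: E[g] = E[N]·E[H_trunc], with E[H_trunc] rising
above µ once σ/µ is appreciable (+3% at σ = 7.8, +16% at σ = 12). Analytic
densities agree with 10⁶-draw Monte-Carlo samples to Kolmogorov–Smirnov
distance < 0.01.

Under the grouped-constant convention the drift of a phenotype is
`v_c = g ε / T_B`, and its diffusivity is `D(T_B) = D_ref T̄_B / T_B`
(all diffusivity variation carried by the tumble bias, normalized so the
mean phenotype has the measured population diffusivity D_ref = 330 µm²/s).
ε is calibrated so the mean phenotype reproduces the fitted population
velocity: ε = χ_G ∇C T̄_B/ḡ in the linear regime, and per junction
ε_i = χ_L (∇C/C_i) T̄_B/ḡ in the log regime, with C_i the concentration at
the midpoint of junction i's up-gradient semibranch — the mean concentration
along the segment the drift acts on (defaults: 173, 258, 342, 427 µM).
Velocity densities are integrated over the tumble bias at fixed v (the
change of variables g = vT_B/ε), which keeps the quadrature
well-conditioned at small velocities; normalizations hold to 1e-3.

## Junction-resolved observables and conventions

The navigation weight of a phenotype to junction n at time t has two
factors: the **arrival** factor B_n(D(T_B)) (a tumble-bias selection that
favors low T_B, strongest at early times and deep junctions) and the
**sensitivity** factor S_n(g) (a pathway-gain weight). Under the
slope-invariance convention the sensitivity exponent is proportional to g
alone. Three deliberate conventions, each exposed as an option:

1. **Sensitivity weight sign.** The pipeline default is the transit-damped
   form e^{−s_n g}. Its population average exceeds the mean-phenotype value
   by Jensen's inequality (the weight is convex in g), so the heterogeneous
   sorting index H_n is finite, larger than 1, and increasing with n. The
   growth form e^{+s_n g} is available but numerically fragile as a
   population weight: averaged over the gain distribution's Gaussian
   motor-gain tail it is dominated by the far tail (values of order 1e4–1e5
   at junction 4), making every derived quantity truncation-dominated.

2. **Arrival factor in H_n.** H_n = N_B/[B_n(T̄_B) S_n(ḡ, T̄_B)] by default
   evaluates the arrival Gaussian of both populations at the common
   reference diffusivity, so H_n isolates sensitivity heterogeneity from
   motility and is time-independent (H₄ ≈ 6.6 linear, ≈ 2.9 log at σ = 7.8).
   The fully phenotype-resolved arrival variant (`arrival="phenotype"`) is
   strongly time-dependent (dominated at early times by low-tumble-bias
   outliers that have already arrived where the mean phenotype has not) and
   is reported as a diagnostic alongside.

3. **Junction velocity distributions.** The tumble-bias marginal at
   junction n is the Beta refit (moment matching, closed form) of the
   arrival-tilted initial Beta; the velocity distribution at junction n uses
   this refit marginal with the inlet gain distribution by default, i.e. it
   describes the motility selection of arrivals. Junction means are
   evaluated at the first observation time (40 min), where arrival
   selection is sharpest; with ε anchored so the junction-1 mean is
   1.1 µm/s, the junction 1–4 means are 1.10, 1.42, 2.09, 3.13 µm/s. The
   sensitivity-weighted gain marginal (`gain="junction"`) is available; note
   that under the damped weight it shifts the gain marginal *down* with n,
   while the growth weight shifts it up.

Observation times default to 40, 80, 120, 160 min (the assay's window).

## Fits

* `fit_chi`: bounded scalar minimization (in log χ) of the squared misfit
  between peak-normalized junction-1 profiles of the 2-D model and the
  observation, at the observation's time. Self-consistency: a profile
  generated at χ = 640 with 5% multiplicative noise is recovered within
  ~2%; flat or zero-gradient inputs raise an unidentifiability error.
* `fit_sigma`: bounded scalar least squares of log H_n between model and
  observation. Exact model-generated H_n recover σ to <1%; with 10%
  multiplicative noise on H₁…H₄ the mean recovery bias over 20 replicates
  is ~7%. H ≡ 1 observations drive σ to the lower bound (homogeneous
  limit).

## Synthetic data

Agents follow Euler–Maruyama drift–diffusion (the same abstraction as the
transport PDE, independently implemented): isotropic diffusion with the
phenotype's D, drift v_c along +y inside stems only, reflecting walls via
per-axis rejection (which preserves the uniform equilibrium), all
randomness from one seeded generator. Step size is bounded by half the
channel width and adapted downward for heavy-tailed heterogeneous
populations. Junction decisions are tracked during stepping: the first
semibranch end reached after arriving at a feed is the cell's choice, so a
non-chemotactic population halves per junction by construction of an
unbiased first-passage — the measured dilution factors are 2.0 within
Monte-Carlo error. Ensemble junction profiles agree with the PDE to
KS < 0.05 at 10⁴ agents.

Rendered observations are 25 µm-binned junction counts with optional
Poisson resampling (counting noise; no image-level noise model is
attempted). The heterogeneous-experiment generator also produces the
matched single-junction control (a one-junction device whose stem spans the
last junction's concentration range — the "unsorted" reference) and a
sorting-index observation table drawn from the navigation model with
multiplicative noise, which is the input the σ fit expects. What passing
tests on these data show is internal consistency of the pipeline at the
drift–diffusion level of description; they cannot validate run-and-tumble
kinematics, cell–cell interactions, growth, or imaging artifacts, none of
which are modeled.

## Known limitations

* The homogeneous 2-D simulation does not hold a near-zero log-profile
  slope at the last junction across the whole observation window: once
  cells arrive, a junction's profile relaxes to the local steady exponential
  within ~20 min, so the junction-1/junction-4 slope ratio averaged over
  the window is O(1) rather than large. Large, stable slope ratios would
  require the last junction to stay flux-dominated for hours, which no
  variant of the reconstructed geometry (connector/inlet lengths, seeding
  reservoir size, outlet channels or reservoirs) achieves; the early-window
  ordering (last junction far less skewed than the first) is the robust
  form of this behavior here.
* The exponential sorting-index forms are definitions, not asymptotics: the
  brute-force 1-D ratio lies strictly between them for n ≥ 1 and neither is
  quantitatively correct for deep junctions.
* Zero-count bins are excluded (not pseudo-counted) in log-slope fits;
  at low counts this is unbiased only in expectation.
* The Beta refit of junction tumble-bias marginals matches the first two
  moments; E[1/T_B]-type functionals computed from the refit differ from
  the exact tilted marginal by <1% in the regimes exercised.
* Branch re-entry is neglected by the 1-D model (branches treated as
  effectively infinite); dead-end lengths ≥ 1000 µm keep re-entry small but
  non-zero over 160 min, visible as a weak down-gradient bias in the
  diffusive choice factor at late times.
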