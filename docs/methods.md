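# Methods

## Model

A cell in steady-state exponential growth is described intensively by its
proteome mass fractions `φ_i`, `Σφ_i = 1`. Protein density homeostasis is
assumed strict, so volume tracks protein mass and `φ_i` doubles as the
concentration of species `i`. The dynamics are

```
dφ_i/dt = π_i − μ φ_i
π_i     = f_i μ_d(φ) + Σ_s w_si N_s
μ       = Σ_i π_i = μ_d(φ) + Σ_s N_s
```

* `f_i` — allocation fraction: the share of metabolic flux routed to
  synthesis of `i`. Dimensionless, `Σf_i = 1`, constant within a growth
  condition (no dynamic regulation). At stationarity the mean composition
  equals the allocation, `φ₀ = f`.
* `μ_d(φ)` — deterministic growth rate (h⁻¹): the growth afforded by a
  composition in the zero-noise limit. It is *intensive* (degree-0
  homogeneous); all provided growth functions evaluate on the normalized
  composition, which enforces intensivity by construction.
* `N_s` — independent zero-mean Ornstein–Uhlenbeck sources,
  `dN = −β N dt + θ dW`, amplitude `θ` (h⁻³ᐟ²), reversion rate `β` (h⁻¹),
  stationary variance `θ²/2β` (h⁻²). Each protein has a private source
  (`w = 1` on itself); proteins in an operon share an additional source
  whose wiring weights sum to one, so every source enters `Σπ` — and hence
  `μ` — exactly once.

Active protein degradation is neglected (it is a small correction to
dilution in growing bacteria), as are cell division and molecule
partitioning: the model describes a lineage-averaged intensive state.

## Growth control

The logarithmic sensitivities `C_i^μ = (φ_i/μ_d) ∂μ_d/∂φ_i` at `φ₀` are
growth-control coefficients. Because `μ_d` is intensive they sum to zero
(Euler's theorem), while the flux-control coefficients of the extensive
biomass flux, `C_i^J = C_i^μ + φ_i`, sum to one. Non-metabolic proteins
have `C^J = 0`, hence `C^μ = −φ`: a sector of mass `φ_H` forces the
metabolic sector to carry `+φ_H` of growth control in aggregate.

Two GCC estimators are exposed and deliberately kept distinct:

* `gcc_numeric` — central difference of `ln μ_d` in log-composition
  (relative step 1e−5) on the degree-0 extension `μ_d(φ/Σφ)`; its result
  sums to zero to differencing accuracy.
* `monod_log_slope` — the one-dimensional slope `φ_half/(φ_half + φ_O)` of
  a Monod dose–response, used to assign the lac operon's GCC from its
  growth curve. On the multivariate extension the same perturbation
  carries an extra factor `(1 − φ_O)`; the one-dimensional slope is the
  estimator that treats the curve as measured (expression in, growth out),
  and it is the one the builder uses.

## Linearization and the reduced system

With `f = φ₀`, the first-order expansion around `φ₀` cancels the
allocation feedback `f_i δμ_d` against the mean-field dilution
`φ₀_i δμ_d` exactly, leaving

```
d(δφ_i)/dt = −μ₀ δφ_i + Σ_s (w_si − φ₀_i) N_s
δμ   = μ₀ Σ_j C_j δφ_j/φ₀_j + Σ_s N_s
δπ_i = φ₀_i μ₀ Σ_j C_j δφ_j/φ₀_j + Σ_s w_si N_s
```

Consequences used throughout: concentration statistics are independent of
the GCC vector; every observable is a linear functional of each source's
raw signal `N_s` and its one-pole filtrate
`F_s(t) = ∫₀^∞ e^{−μ₀r} N_s(t−r) dr`. The three stationary correlator
kernels —

* `⟨N N⟩(τ) ∝ e^{−β|τ|}` (symmetric, "B"),
* `⟨F N⟩(τ)` (asymmetric, peaked where the source leads the filtrate, "A"),
* `⟨F F⟩(τ)` (symmetric mixture of `e^{−μ₀|τ|}` and `e^{−β|τ|}`, "S"),

— are implemented in closed form, with the repeated-root (`β = μ₀`) limits
handled explicitly, and validated in the test suite against numerical
quadrature of their defining integrals.

### Lag convention

All cross-correlations use `r(τ) = corr(x(t+τ), μ(t))`: positive lag means
the expression signal is observed *after* the growth rate. Under this
convention synthesis noise, which enters growth instantly but reaches the
concentration through the slow (rate `μ₀`) filter, produces a
concentration autogenic mode peaking at positive lag, and a production
control mode peaking at negative lag (production must accumulate into
concentration before it can affect growth). These are the orientations in
which the decomposition's asymmetries read naturally.

### Noise modes

`xcorr_analytic` returns the exact Pearson curve together with an
additive decomposition. For concentration–growth: control (focal sources
through the GCC channel; S-shaped), autogenic (focal sources' instant
entry in `μ`; A-shaped), dilution (`−φ₀_i` times every source's growth
channel). For production–growth: control (A-shaped, reversed), autogenic
(B-shaped), transmission (`+φ₀_i` times the GCC-gain-weighted growth
channels). For operon members the control and autogenic modes each split
into an operon-level and a private-reporter instance. The decomposition
sums to the total at machine precision; Pearson normalization divides
curve and modes by the same `σ_x σ_μ`, keeping additivity.

### Stationary CVs, fitting, dual reporters

With `v_s = Var(N_s)/(μ₀(μ₀+β_s))`, the stationary concentration variance
is `Var(δφ_i) = Σ_s (w_si − φ₀_i)² v_s`. `noise_amplitudes_from_cvs`
inverts this linear relation for the `v_s` given target CVs, honoring
equality constraints between amplitudes (e.g. operon source = 1.5 × GFP
source). The system is solved exactly when square and nonsingular and in
the minimum-norm least-squares sense otherwise, with a forward-residual
consistency check; a two-protein cell is the canonical rank-deficient case
(both CV equations carry the same information because `φ_X + φ_Y = 1`), so
its inversion is only determined under the equal-amplitude tie. Negative
solutions raise an infeasibility error naming the protein whose target CV
lies below its extrinsic floor.

The dual-reporter covariance splits into a strictly negative
"transmission between reporters" term,
`−2(1−φ_b)/φ_b · v_b`, and a nonnegative background term `Σ v_j`: reading
the covariance of two identical reporters as extrinsic noise presumes
intrinsic noise does not propagate between them, which this model
violates through shared dilution.

## Growth surfaces for simulation

Mechanistic models carry a Monod function `μ_d = μ_max φ_O/(φ_half+φ_O)`
on the normalized mass of a target set. Models specified phenomenologically
by `(μ₀, C)` need a surface with exactly those sensitivities; two are
provided:

* `LinearizedGrowth` (default): `μ₀(1 + Σ C_j(ψ_j−φ₀_j)/φ₀_j)`,
  `ψ = φ/Σφ`. First-order, intensive, and defined for the transient
  negative-`φ` excursions the integrator tolerates.
* `LogLinearGrowth`: `μ₀ Π(ψ_j/φ₀_j)^{C_j}`. Intensive with the same
  sensitivities, but it collapses (`μ_d → 0`) during deep downward
  excursions of a positively controlling species, which makes long runs at
  moderate noise fragile; kept as an alternative for studying surface
  curvature.

The model class pins `μ_d` only to first order around `φ₀`, so any such
surface is admissible; the linear one is the minimal choice.

## Stochastic integrator

OU sources advance with their exact Gaussian transition
(`N⁺ = N e^{−βΔt} + 𝒩(0, θ²(1−e^{−2βΔt})/2β)`) — the drivers carry no
discretization bias. Mass fractions advance by explicit Euler on the
random ODE; the step must satisfy `Δt ≤ 0.1/max(β, μ₀)` and defaults to
1e−3 h. Initial state: `φ = f`, sources at their stationary law; default
burn-in `20/μ₀`; records every 0.01 h. Recorded `μ` is `Σπ` by
construction, so the growth-equals-total-synthesis identity holds exactly
on the record. After each step `φ` is projected back onto the simplex
(division by `Σφ`), and the largest pre-projection drift is reported as a
diagnostic (≈1e−16 per step at the default step; the simplex is
dynamically invariant, so drift is pure round-off plus `O(Δt²)` local
error). The projection can be disabled. Mild negative-`φ` excursions are
tolerated (the analytics are linear and the surfaces remain defined); a
mass fraction falling below −10 stationary SDs, or a non-positive
composition sum, aborts with an instability error advising a smaller step
or weaker noise. Identical `(seed, dt, duration)` give bit-identical
trajectories.

## Estimators

* Lagged Pearson correlations are computed on the recorded grid; standard
  errors come from a seeded block bootstrap (block length `10/μ₀`, 200
  resamples): lagged cross-products are accumulated within blocks and
  blocks are resampled with replacement, which respects serial dependence
  without splicing artifacts. Block length must exceed twice the largest
  lag.
* Scalar statistics (means, variances, CVs, covariances) get batch-means
  error bars: the statistic per contiguous 20 h block, spread across
  blocks over `√n_blocks`.

## The many-protein cell

`build(condition, seed)` assembles a 1021-species model:

1. **Background proteome** (1018 species): mean abundances log-normal
   (log10 mean 1.5, SD 1.0) truncated to 0.1–1e4 copies per cell — the
   span covered by genome-scale single-cell abundance surveys; an
   unbounded tail occasionally hands one species tens of percent of the
   proteome mass, which no measured proteome shows. CVs follow
   `η² = a/⟨n⟩ + b` (defaults `a = 1`, `b = 0.01`) with 0.2-dex log-normal
   scatter. The floor `b` sets the proteome-wide noise load
   `Σ φ_j²η_j²` ≈ 1e−4, which in turn fixes the strength of the global
   dilution mode every reporter feels; at a load an order of magnitude
   larger the dilution mode swamps the reporter's own modes and the
   deceptive-correlation regimes (positive correlation with negative
   operon control and vice versa) cannot occur at all — the chosen floor
   (10% CV for abundant proteins, a value in the measured range of
   single-cell studies) places the model in the regime where all four
   modes are visible. Both constants are arguments.
2. **Lac construct**: operon mass `φ_O = {0.3, 1.3, 15} × φ_half` across
   the slow/intermediate/fast conditions on the Monod curve
   (`μ_max = 0.8 /h`, `φ_half = 0.005`), shared equally by LacY, LacZ and
   GFP; background masses rescaled to fill `1 − φ_O` in the table's
   proportions. The shared operon source is weighted 1/3 per member.
3. **GCCs**: background proteins enter the non-metabolic sector in random
   order until its mass first reaches 25% (`C = −φ` each); GFP is
   non-metabolic; LacY and LacZ split `C_O − C_G` equally, with `C_O` from
   the Monod log-slope (0.77 / 0.43 / 0.063). Remaining metabolic proteins
   draw raw scores `mass × Exp(1)` — abundant proteins tend to carry more
   control — then receive a mass-proportional shift making the grand total
   exactly zero. The shift (rather than a pure rescale) is required
   because at slow growth the operon holds more control (0.77) than the
   non-metabolic sector displaces (0.25), so the metabolic background must
   carry net negative control; a nonnegative score vector cannot reach a
   negative sum.
4. **Noise fit**: all reversion rates `β = 4 μ_max = 3.2 h⁻¹`; amplitudes
   solved exactly so that every lac protein has CV 0.15, the operon source
   amplitude is 1.5 × the GFP private amplitude, and all background CVs
   match the table.

All randomness flows from one seed through spawned child streams; the same
seed rebuilds an identical model.

### What the synthetic proteome does and does not emulate

It reproduces a broad, right-skewed abundance spectrum, the
intrinsic-limit-plus-floor CV structure, and realistic mass-fraction
scales for a reporter construct. It does not reproduce any particular
organism's ranked protein identities, correlated abundances between
functional modules, condition-dependent proteome remodeling, or measured
per-protein noise idiosyncrasies. Passing tests therefore demonstrate the
model's internal machinery and its qualitative regime structure, not
agreement with any specific organism's measured correlation curves.

## Problem sizes and numerical tolerances

The verification suite integrates the two-protein toy for 5000 h at
Δt = 1e−3 h (the scale at which bootstrap errors resolve the correlation
curves to a few percent), the dual-reporter cell for 2000 h, and uses
121-point lag grids on ±3 h. Sum rules are enforced and checked to 1e−10;
fit round trips to 1e−10; exact identities (mode additivity,
`μ = Σπ` on records) to machine precision. Equality of simulated and
analytic statistics is asserted at 3 standard errors.

## Known limitations

* **Small-noise validity.** The analytics are first-order. At the toy
  cell's amplitude (θ = 0.5, ≈18% growth-rate CV) the full model shows a
  genuine second-order CV excess of ≈4–9% over the linear formula
  (measured across seeds at 5000 h): off-mean compositions grow slower,
  which weakens restoring dilution and fattens excursion tails.
  Pearson-normalized correlation curves are far less sensitive (bias
  cancels between numerator and denominator; agreement within ≈1 SE).
* Deep excursions make long single-seed records heavy-tailed; scalar
  error bars at fixed duration can understate seed-to-seed spread.
* No cell division, partitioning noise, density fluctuations, dynamic
  allocation (`f(φ)` regulation), or non-protein biomass.
* The GCC raw-score distribution for the metabolic background
  (mass-weighted exponential) is a modeling choice; it is pluggable via
  the assignment step's arguments.
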