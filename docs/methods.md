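# Methods

## Binary-promoter gene model

### State space and master equation

The gene is a two-state (telegraph) promoter coupled to a birth–death
product count. The state is `(m, n)` with `m ∈ {ON, OFF}` and `n ≥ 0`;
`α_n` and `β_n` denote the probabilities of `(ON, n)` and `(OFF, n)`.
Synthesis (rate `k`) occurs only in ON; degradation (`ρ·n`) in both states;
OFF→ON at rate `f`; ON→OFF at propensity `h₁·n` for the self-repressing
gene (SRG: mass-action binding of one of the `n` products to the
regulatory region) or at `h₂ᵉᶠᶠ` for the externally regulated gene (ERG).

Two deliberate modeling choices:

* **Non-sequestering switching (default).** The product that binds the
  SRG's regulatory region is *not* removed from the pool: switching changes
  `m` but leaves `n` untouched, so the switching terms couple `α_n` and
  `β_n` at the same index. A `sequestering=True` variant (bind: `n→n−1`,
  release: `n→n+1`) is provided because both conventions appear in the
  exact-solution literature for this model; all identities below are
  asserted only for the default.
* **The ERG regulator is not a molecule.** Its abundance is folded into the
  single effective rate `h₂ᵉᶠᶠ = h₂ × (regulator abundance)`; simulating it
  explicitly would add a dimension without changing the marginal law of
  `(m, n)`.

### Numerical solution

The count axis is truncated at `n_max`, initialized from the constitutive
envelope `Poisson(k/ρ)` as `⌈k/ρ + 12·√(k/ρ)⌉` (floor 8). The stationary
law solves the sparse linear system `Q p = 0, Σp = 1`, implemented by
replacing one balance row with the normalization row and factorizing with
sparse LU, followed by one step of iterative refinement. Acceptance of a
solution requires

* residual `max|Q p| < 1e−10` relative to the largest outflow rate,
* total mass within `1e−9` of 1,
* boundary mass `α_{n_max} + β_{n_max} < 1e−8`; otherwise `n_max` doubles
  and the solve repeats (hard stop near 10⁶ counts with an explicit error
  naming the parameters).

Transients use Krylov evaluation of the matrix exponential
(`expm_multiply`), which tolerates the stiffness of switching-dominated
regimes; probability conservation is checked to `1e−8`.

The Gillespie sampler implements the same four reaction channels with
exponential waiting times on a counter-based Philox stream, so a seed fully
determines a trajectory. `ssa_sample_states` records states every ~5
relaxation times (`max(1/ρ, 1/switching rate)`) after a 20-relaxation-time
burn-in, producing near-independent draws whose multinomial sampling error
is a valid yardstick against the solver distribution.

### Noise statistics

`F = var(n)/⟨n⟩`; `ξ = cov(g, n)` with the promoter mapped to `g = k/ρ`
(ON) and `0` (OFF). For the non-sequestering model the stationary moment
equations close: `⟨n⟩ = (k/ρ)·P(ON)` and
`E[n²] = (k/ρ)·E[n·1_ON] + ⟨n⟩`, which gives the exact identity
`F = 1 + ξ/⟨n⟩` for *both* SRG and ERG. The test suite asserts it to
`1e−8` on every solved distribution, and the sign law
`sign(ξ) = sign(F−1)` across sweeps. For the ERG the closed form
`F = 1 + k·h/((f+h)(f+h+ρ))` from the two-state transcription literature
serves as an independent oracle of the solver.

**Solver-vs-SSA comparison.** The total-variation distance between the
solver marginal and an empirical histogram of N near-independent SSA
samples has a positive bias of order `√(K/N)` across K occupied bins, so
comparing TV against a bare `3×SE(TV)` would reject a *perfect* simulator.
The acceptance check instead estimates the null TV distribution by
parametric bootstrap (300 multinomial resamples of size N from the solver
marginal) and requires the observed TV to fall below its mean + 3 sd.

## Axis profiles and border noise

Nodes of a 1-D lattice spanning [0, 1] carry independent copies of the gene;
position enters through parametric rate curves. The default positional
input is an activator-like Gaussian `f(x)` peaked at 41.5% of the axis
(the location of the modeled mRNA stripe); a repressor-like `h₂ᵉᶠᶠ(x)` can
be supplied instead, since which rate carries the positional information is
not fixed by the model. Profiles are per-node `⟨n⟩ ± σ` from the
stationary law, or from the transient law at a snapshot time started from
`(OFF, 0)`.

Borders are the half-max crossings of the piecewise-linear mean profile
(half-max level from the node-wise maximum, leftmost node on ties; linear
interpolation between nodes, sides without a crossing reported absent).
The positional-noise band of a border spans the crossings of the
`mean−σ` and `mean+σ` envelopes with the same half-max level, taking on
each side the crossing nearest the mean border; an envelope that never
reaches the level contributes nothing, so bands can be one-sided in
high-noise regimes. Because the half-max level scales with the profile,
borders are invariant under amplitude rescaling.

## Lattice co-culture model

### Update rule (normative)

Types: 1 = melanoma, 2 = normal (keratinocyte). Graph distance is
Manhattan on the 4-neighbor (von Neumann) lattice, toroidal under the
default periodic boundary. The exclusion constraint is the state
invariant: every occupied pair at distance `d` satisfies `d ≥ D(i,j)`,
with defaults `D(1,1)=1`, `D(2,2)=2`, `D(1,2)=max=2` (reciprocal).

One sweep = L² updates of uniformly chosen vertices:

* **Occupied by type i** (normalize by `Q_i = α_i+σ_i+ρ_i+δ_i`):
  quiescence `σ_i/Q_i`; death `ρ_i/Q_i`; migration `δ_i/Q_i` to a uniform
  admissible empty vertex within `r_mig` (default 1), the source being
  ignored in the destination's admissibility check; division `α_i/Q_i`
  onto a uniform admissible empty vertex of the nearest non-empty
  admissible ring `d = 1..D(i,i)`. If a chosen move has no candidate the
  cell stays.
* **Empty vertex x**: stay with weight `R = ρ₁+ρ₂`; become type i by
  division with weight `Π(i)·α_i·n_i(x)` (`n_i(x)` = type-i cells on the
  nearest ring that holds any, `d ≤ D(i,i)`) or by migration with weight
  `Π(i)·δ_i·m_i(x)` (`m_i(x)` = type-i cells within `r_mig`; the chosen
  source is vacated). Weights are normalized by their sum.

Design notes. (a) The division destination must search rings up to
`D(i,i)`: for normal cells the 4-neighbors of a parent are *never*
admissible (distance 1 < D=2), so daughters land on the distance-2 ring —
this is what makes growth under strong contact inhibition possible and
directly produces the factor-2 spacing between the two types' modal
nearest-neighbor distances. (b) Assigning quiescence the weight `σ_i` and
division `α_i` keeps each weight attached to its declared meaning.
(c) The empty-vertex stay weight `R = ρ₁+ρ₂` is a modeling choice that
avoids introducing an extra parameter; alternatives only rescale the empty
vertex's holding time. (d) `r_mig`, the boundary condition, and all
diameters are configurable; the listed values are the defaults used
throughout.

The update is implemented once, as a numba-compiled kernel shared by the
single-step API and the full run loop, with a seeded internal RNG stream
(identical seeds ⇒ identical trajectories). A pure-Python exhaustive
enumeration of the one-step transition law on a 3×3 grid, written
independently of the kernel, is the correctness oracle: empirical one-step
frequencies must match it within four binomial standard errors.

### Default study conditions

Co-culture runs use L=100, periodic boundary, 50 melanoma + 500 normal
cells (the 10:1 seeding of the co-culture experiment, at ~5.5% area
fraction so early growth is exponential), equal division weights for both
types (the fitted early growth rates of the two populations coincide), and
`α=0.8, σ=0.1, ρ=0.05, δ=0.05`. 150 sweeps reach confluence (population
plateau) at this size; 20 replicate seeds are used where replicate spread
matters. These sizes make a full replicate about one second after JIT
compilation, and they are the conditions under which the documented
spatial signatures (minimal melanoma distance 1, modal distance ratio 2,
few large melanoma clusters, ratio decline from 10:1 to ≈3:1) are
asserted.

## Observables

* **Nearest-neighbor histograms**: KD-tree queries under the L1 metric
  (toroidal via box size), self excluded for same-type queries; histogram
  mass equals the number of query cells.
* **Clusters**: connected components of "distance ≤ link_dist" (default:
  the type's self-exclusion diameter). Area = cell count; perimeter =
  exposed unit edges (a 3×3 block scores 12); axis ratio = √(λ₁/λ₂) of the
  member-coordinate covariance (1 for a single cell, ∞ for a perfect
  line); hull area from the planar convex hull of cell centers after
  unwrapping periodic clusters by BFS (degenerate hulls report 0).
* **Density vs. interface**: multi-source BFS gives every vertex's graph
  distance to the nearest melanoma cell; the grid is tiled with
  `window²` squares (default 5×5) binned by mean distance into bands of
  width `window`; the decay rate comes from log-linear least squares on
  positive band means, with zero-count bands excluded and counted.
* **Gompertz fits**: `N(t) = A·exp(−exp(−b(t−c)))` by Levenberg–Marquardt
  with data-driven initial guesses (A from the plateau, c from the `A/e`
  crossing); flat series are fitted but flagged degenerate.

## What the synthetic data does and does not show

All experiments here run on model-generated data: the lattice model's own
trajectories and constructed spatial configurations (e.g., a melanoma wall
with an imposed exponential normal-cell density for the decay-rate
recovery test, labeled synthetic where used). Passing tests demonstrate
internal consistency — solver vs. simulation, kernel vs. enumerated
chain, fits recovering known parameters — and that the *mechanisms*
(negative promoter covariance under self-repression; exclusion-diameter
asymmetry producing clustering and ratio erosion) behave as designed. They
do not calibrate rates to real cultures: absolute experimental quantities
(fluorescence-to-count conversion, the measured final 4:1 ratio, real
micrograph morphology) depend on experimental calibrations outside this
package's scope, so only trends and geometry-driven ratios are asserted.

## Known limitations

* The master-equation solver is dense in `n` per promoter state; genes with
  `k/ρ ≳ 10⁴` become slow (sparse LU on ~2·n_max states).
* The SRG sequestering variant is simulated and solved but the
  `F = 1 + ξ/⟨n⟩` identity is not guaranteed for it.
* Two cell types and 2-D grids only; no phenotype switching; migration
  range defaults to nearest neighbors.
* Cluster hull areas use cell centers, so single-file clusters have zero
  hull area by construction.
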