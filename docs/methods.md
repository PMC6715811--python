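# Methods

## Model

`grmc` treats a chromosome segment as a harmonic bead-spring chain of `N`
loci (backbone spring constant `κ`) with additional harmonic cross-links
(spring constant `ω`) between loop-anchor pairs Σ, e.g. CTCF/cohesin loops
called from a Hi-C map. Excluded volume is deliberately absent — chain
crossing is attributed to topoisomerase activity — which keeps the model
exactly solvable. The connectivity matrix `A` (off-diagonal `κ` for chain
neighbours, `ω` for loop pairs, diagonal fixed by zero row sums) is symmetric
negative semidefinite with one zero eigenvalue for a connected chain.
Diagonalizing `A = VᵀΛV` decouples the dynamics into normal modes with
equilibrium per-axis variances `kT/(−λ_p)`, giving the exact pair statistics

```
σ²_mn = Σ_{λ_p<0} (V_pm − V_pn)² kT/(−λ_p),   ⟨R_mn⟩ = 2√(2/π) σ_mn.
```

The pair distance is chi distributed, so the contact probability at threshold
`r_c` has the closed form `R₀(⟨R⟩)` given in the README. `R₀` is strictly
decreasing, hence invertible: that inversion is the bridge from Hi-C
probabilities to FISH distances.

### Assumptions and their limits

- **Gaussian (phantom) chain**: exact only for zero-rest-length springs. The
  simulator also supports finite rest length `a` (the form used for
  simulation figures); its distance law deviates from chi at short genomic
  separations.
- **Isotropy and equilibrium**: pair vectors are isotropic Gaussians; all
  theory is equilibrium statistics.
- **Heterogeneity as superposition**: a cell population is a weighted
  mixture of Gaussian-chain ensembles. For real chromatin the component law
  is replaced by the Redner–des Cloizeaux (RdC) family with exponents
  `(g, δ) = (1, 5/4)` (from `P ~ ⟨R⟩^−(3+g)` and `δ = 1/(1−ν)`); the chi law
  is `(0, 2)`. The RdC normalization and scale are fixed by the two
  constraints ∫f = 1 and E[r] = ⟨R⟩, which determine the generalized-gamma
  form uniquely given `(g, δ)`; the implementation is validated by the exact
  `(0, 2)` reduction to the chi family.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `r_c` | contact threshold | 0.010 μm (real data); `2a` (simulation) | values ≤ 10 nm give equivalent relative frequencies; 20 nm (used for some published fits) is available by flag. Always explicit, never hard-coded. |
| `(g, δ)` | RdC exponents | (1, 5/4); `chi` = (0, 2) | chromatin-supported values; both families exposed everywhere |
| `κ, ω` | backbone / loop spring constants | 100 kT/a² | stiff springs approximate fixed bond length in `rest_length_mode="a"`. Desk-scale theory-vs-simulation runs use κ = ω = 3 kT/a² so that an N=200 chain spans a wide range of contact probabilities at r_c = 2a; with κ = 100 all pairs of a short chain sit at P ≳ 0.3 and the curve would be probed only near saturation. |
| `ξ` | friction | 0.1 (m = 1) | low friction accelerates conformational sampling of harmonic chains |
| `dt` | time step | 0.01·√(m/max(κ, ω)) | 1% of the stiffest oscillation period; stability margin ≈ 10× |
| `α` | Tikhonov strength | 10⁻² | balances resolution vs noise amplification on ~10³-cell CDFs; noiseless recovery tests use 10⁻³ |
| monomer size | bp per bead | 1200 bp | BEDPE anchors map to beads by floor(start/1200) |

## Numerical choices

- **Inversion of `R₀`**: Brent's method on the bracket
  `[10⁻³ r_c, 10 r_c P^(−1/3)]` (defensively widened); monotonicity
  guarantees a unique bracketed root. Round-trips to better than 10⁻⁸
  relative error over P ∈ [10⁻⁶, 0.99].
- **Mixture fitting**: multi-start least squares on CDF residuals at the
  empirical jump points (right-continuous convention, CDF(r) = #{≤ r}/n),
  with quantile-heuristic starts (R1 near the lower quartile, R2 near the
  upper) plus 10 seeded random restarts; `R` is optimized in log space within
  [1 nm, 100 μm], and results are canonicalized to `R1 ≤ R2` by the
  `(η, R1, R2) ↔ (1−η, R2, R1)` relabeling symmetry. When raw distances are
  available the CDF optimum is polished by Nelder–Mead maximum likelihood:
  CDF residuals weight regions by sample density and therefore localize a
  minority component's mean poorly (with η near 1 the far component
  contributes residuals bounded by 1−η), while the likelihood restores
  efficiency. `refine="none"` gives the pure CDF objective. Data with fewer
  than three distinct distances fall back to a flagged single-population fit.
- **Deconvolution**: the Fredholm CDF equation is discretized on a default
  grid of 100 log-spaced ⟨R⟩ candidates spanning [min(r)/2, 2·max(r)] and
  solved as Lawson–Hanson NNLS on the augmented system `[K; αI] w = [y; 0]`;
  weights are renormalized to sum 1 and residuals are reported against the
  unnormalized solution. Peaks are local maxima with prominence ≥ 5% of the
  largest weight (grid edges padded so boundary modes count). An all-zero
  solution raises a diagnostic error.
- **Langevin integration**: BAOAB splitting, underdamped (m = 1, ξ = 0.1),
  with the numba-compiled force loop over the flat bond list.
  Rest-length-zero runs start from an exact equilibrium draw in normal-mode
  coordinates (so no burn-in is needed); rest-length-`a` runs start from a
  fixed-bond random walk plus an explicit burn-in. Non-finite coordinates
  abort with diagnostics. Same seed → bit-identical trajectories.
- **Estimators**: `P_mn` and `⟨R_mn⟩` are plain snapshot averages over M
  independent trajectories × T snapshots; `σ²_mn` is estimated as ⟨R²⟩/3.
  Standard errors are computed across trajectories (between-trajectory
  variance), which is robust to within-trajectory correlation. Binned
  `E[⟨R_mn⟩]` vs `P_mn` curves use bins of width Δ centered on P; both
  linear and log10 binning are supported, log by default because pair
  probabilities span decades.

## Synthetic data

The generator emulates FISH distance tables (one distance per cell per locus
pair) drawn from a mixture or an arbitrary subpopulation spectrum by exact
inverse-CDF sampling on the incomplete-gamma representation (exact for any
δ, including the heavy-tailed δ < 2 chromatin case), and pseudo-Hi-C counts
as Poisson draws with mean `depth·P_i`, which makes relative contact
frequencies recoverable by construction. Defaults are 2000 cells per pair —
the scale of published loop-resolution FISH datasets — and noise-free
distances; optional Gaussian localization noise (truncated at zero) exists
as an extension but is off by default because the mixture theory itself does
not model measurement error.

What passing tests on these data do **not** show about real experiments:
real FISH has localization error, probe-size effects and detection-efficiency
censoring of short distances; real Hi-C counts carry coverage and ligation
biases that Poisson sampling of true probabilities does not emulate; and real
chromatin is not an equilibrium phantom chain. The package's claims on real
data are therefore limited to what the theory itself asserts: given distance
CDFs measured under conditions comparable to the Hi-C experiment, mixture
fits reproduce relative (not absolute) contact frequencies.

## Problem sizes

Desk-scale defaults keep every analysis on a single CPU: the
theory–simulation comparison uses N = 200 loci, 10 random loops and 10
independent trajectories of 150 saved snapshots (3×10⁶ total steps,
snapshots 11.5 time units apart ≈ half a velocity-decorrelation time);
recovery experiments use 20 seeds × 2000 cells. These sizes give binned-curve
agreement within a few percent and between-trajectory standard errors small
enough for 3-SE tests, and are stated here as the package's chosen study
conditions.

## Known limitations

- No excluded volume, hydrodynamics, or loop-extrusion dynamics; loops are
  static springs.
- The two-population fit cannot distinguish static from dynamic
  heterogeneity — only single-cell time-resolved data can.
- The continuous deconvolution is ill-posed: peak positions are stable but
  peak widths depend on α and on the grid; CV is the robust summary.
- Absolute contact probabilities depend on the unknown experimental `r_c`;
  only relative frequencies `P_i/⟨P⟩` are compared to Hi-C.
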