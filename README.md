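# grmc — reconciling Hi-C contact probabilities with FISH spatial distances

Hi-C measures how often two genomic loci are cross-linked (a *contact
probability* `P_mn`); FISH measures the 3D distance between the same loci in
single cells (a distance distribution with mean `⟨R_mn⟩`). Intuitively a
higher contact probability should mean a shorter distance, yet real data
contain pairs where the locus pair with the **larger** Hi-C signal is also
**farther apart** on average — the FISH–Hi-C paradox. `grmc` implements the
polymer-physics framework that explains and resolves it: the paradox is a
signature of *cell-to-cell heterogeneity* — a contact (for example a
CTCF/cohesin loop) exists in only a fraction `η` of cells.

The package is aimed at chromosome-organization researchers who want to
combine Hi-C contact maps with FISH/imaging distance distributions, and at
polymer physicists studying heterogeneity in chromatin ensembles.

## The model

For a harmonic ("generalized Rouse") chain with extra springs at loop
anchors, the pair vector is an isotropic Gaussian, the scalar distance is chi
distributed, and contact probability and mean distance are linked exactly:

```
P = erf( 2 r_c / (√π ⟨R⟩) ) − (4/π) (r_c/⟨R⟩) exp( −4 r_c² / (π ⟨R⟩²) ) ≡ R₀(⟨R⟩)
```

with `r_c` the contact threshold; for small `P`, `⟨R⟩ ≈ r_c P^(−1/3)`.
Inverting `R₀` turns a Hi-C probability into a FISH-comparable distance — but
only for a homogeneous population. With two subpopulations the distance law
becomes the mixture

```
P(r) = η P(r | ⟨R₁⟩) + (1 − η) P(r | ⟨R₂⟩),
```

whose components are Redner–des Cloizeaux (generalized-gamma) densities
`f(r) ∝ r^(2+g) exp(−(b r)^δ)`; `(g, δ) = (0, 2)` is the Gaussian chain and
`(1, 5/4)` the empirically supported chromatin values (`δ = 1/(1 − ν)`).
Fitting the measured cumulative distance curve CDF(R) recovers
`(η, ⟨R₁⟩, ⟨R₂⟩)`, from which Hi-C contact frequencies follow with no free
parameters. A continuous generalization recovers a full subpopulation
spectrum `P(⟨R⟩)` by nonnegative Tikhonov-regularized inversion, summarized by
the heterogeneity index `CV = σ(⟨R⟩)/μ(⟨R⟩)`.

Modules: `grmc.theory` (closed forms + inversion), `grmc.mixture`
(two-population fits, KS statistics, relative contact frequencies),
`grmc.spectrum` (continuous deconvolution), `grmc.simulate` (loop-anchored
Langevin dynamics and exact normal-mode analytics), `grmc.synth` (synthetic
FISH/Hi-C generators), `grmc.io` + `grmc.cli` (file dialects and the `grmc`
command).

## Worked example

Generate a synthetic FISH experiment for a loop that exists in 42% of cells
(`⟨R₁⟩ = 0.30 μm` looped, `⟨R₂⟩ = 1.21 μm` unlooped), then re-fit it:

```bash
$ grmc synth --eta 0.42 --r1 0.30 --r2 1.21 --n-cells 2000 --seed 7 \
       --pair-id peak4_loop --out fish.csv
wrote 2000 distances for peak4_loop to fish.csv

$ grmc fit --fish fish.csv --rc 0.02
peak4_loop: eta=0.421 R1=0.306 R2=1.197 KS=0.0140 P(rc=0.02)=3.48e-05
```

The fit recovers the generating parameters (η = 0.421 vs 0.42; component
means within 2%); `KS` is the Kolmogorov–Smirnov distance between fitted and
empirical CDF, and `P` is the implied Hi-C contact probability at a 20 nm
threshold. The continuous deconvolution of the same data,

```bash
$ grmc deconvolve --fish fish.csv --alpha 1e-2
peak4_loop: mu=0.847 sigma=0.503 CV=0.594 peaks=3 max|resid|=8.73e-03
```

reports a multimodal spectrum with mean distance 0.85 μm and CV ≈ 0.59 — far
from the ≈0 expected of a homogeneous population, quantifying the
heterogeneity that produces the paradox. In Python the same inversion that
links the two assays is one call:

```python
>>> from grmc import invert_contact_to_mean
>>> invert_contact_to_mean(1e-3, r_c=0.02)   # um
0.20474744475561107
```

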