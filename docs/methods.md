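# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limitations of `lsdpa`.

## Problem and estimators

A multispectral photoacoustic image stack records, at every pixel x, the
initial pressure p₀(λ, x) ∝ μₐ(λ, x) · Γ · φ(λ, x). The Grüneisen
parameter Γ is treated as wavelength-independent; the fluence φ is not.
Two pixel-wise sO₂ estimators are implemented:

* **Linear unmixing (LU).** Assumes p₀ ∝ μₐ and solves
  min‖s − a₁ ε_Hb − a₂ ε_HbO₂‖² with a₁, a₂ ≥ 0 (SLSQP, start (0.5, 0.5),
  tolerance 10⁻¹⁰), reporting sO₂ = a₂/(a₁+a₂). The ratio is invariant to
  positive rescaling of s, and on fluence-free mixtures LU is exact (the
  test suite verifies recovery to 10⁻³ against a brute-force grid search).
  Coefficient non-negativity is imposed because negative chromophore
  amounts are unphysical and would push the ratio outside [0, 1]; an
  unbounded mode is available via a flag.
* **Learned spectral decoloring (LSD).** A fully connected regressor on
  the sum-normalized spectrum. Normalization discards amplitude — the
  deliberate trade that removes device calibration from the problem —
  so the network must infer saturation from spectral *shape*, including
  the depth-dependent coloring imprinted by the fluence.

## Synthetic domains

Training data come from three seeded phantom families on a 256 × 128 voxel
imaging plane (0.1 mm voxels, depth 12.8 mm, surface at z = 0). All blood
compartments use 150 g/L hemoglobin.

* **Generic tissue** (26 wavelengths, 700–950 nm / 10 nm): 1–5 tubular
  vessels (radius U(0.5, 2.5) mm, blood volume fraction 1) in a
  homogeneous background with 0.5% blood volume fraction and μs′ =
  10 cm⁻¹; *all* structures share one sO₂ drawn from U(0, 1). The stated
  "scattering coefficient of 10 cm⁻¹" is read as μs′ (configurable).
* **Flow phantom** (17 acquisition wavelengths, 660–950 nm; pencil beam):
  a single blood tube (radius U(0.5, 2.5) mm, sO₂ U(0, 1)) at a fixed
  6 mm center depth in agar with μs′ = 5 cm⁻¹ and water content
  U(50, 100)%. Only radius, water, and sO₂ are randomized — the physical
  flow-phantom geometry is otherwise fixed.
* **Forearm** (26 wavelengths): gel pad (1 mm, non-absorbing) /
  epidermis (0.15 mm, melanin Gaussian 2.2 ± 1%) / dermis (1.5 mm, blood
  volume 1%, oxygenation Gaussian 80 ± 10%, water 58%) / muscle (blood
  1%, oxygenation 80 ± 10%, water 68%), with 1–5 vessels (sO₂
  U(0, 100)%), one artery (95 ± 5%), one vein (70 ± 10%), and one bone
  (water 19 ± 1%). Gaussian draws are clipped to [0, 1] (no truncation
  rule is documented for these ranges; clipping shifts the artery mean to
  ≈ 0.946). The artery oxygenation range is interpreted as 95 ± 5%,
  consistent with the other tissue ranges. Scattering uses Jacques-style power laws μs′(λ) =
  μs′(800 nm) · (λ/800)⁻ᵇ with per-tissue defaults (skin 20 cm⁻¹, b = 1.5;
  muscle 8 cm⁻¹, b = 0.5; bone 20 cm⁻¹, b = 0.65; blood 10 cm⁻¹; gel pad
  μs′ = 1 cm⁻¹), g = 0.9 everywhere.

The composition laws above are the emulated acquisition conditions;
structure counts, radii ranges, layer thicknesses, and the vessel-count
range U{1..5} are package defaults (configurable).

### Chromophore table

The bundled table (`src/lsdpa/data/chromophores.tsv`, 660–960 nm / 2 nm)
is compiled from the standard literature compilations of tissue optical
properties: Hb/HbO₂ molar extinctions converted to whole-blood μₐ at
150 g/L (MW 64 500 g/mol), Hale & Querry-style water absorption, and the
melanosome power law 519 · (λ/500 nm)⁻³·⁴⁸ cm⁻¹, PCHIP-smoothed onto the
grid. The Hb curve near 800 nm is smoothed so the isosbestic crossing sits
at 800 nm (the package treats 800 nm as the isosbestic anchor throughout;
the raw literature crossing is ~797 nm). Simulator and LU endmembers share
this table by design; an alternative endmember file can be supplied for
sensitivity analysis.

## Optical forward models

* **Layered model** (training-set default): per image column,
  φ(z) = exp(−∫₀ᶻ μ_eff dz′) with μ_eff = √(3 μₐ (μₐ + μs′)) where
  μs′ > 0 and μ_eff = μₐ (Beer–Lambert) where μs′ = 0; φ = 1 at the
  surface, voxel centers at (i + 0.5)Δ. Pencil and slab illumination share
  the column-wise attenuation (the lateral beam profile is not modeled);
  the tags are kept for the Monte Carlo path.
* **Voxel Monte Carlo** (validation oracle, and an optional forward
  model): full 3D hop/drop/spin random walk with Henyey–Greenstein
  scattering, absorbing boundaries, Russian roulette below weight 10⁻⁴
  with survival chance 0.1. Fluence uses a *track-length estimator with
  continuous absorption*: along every voxel-clipped segment the weight
  decays by exp(−μₐ ds) and the voxel accumulates ∫ w dl. This makes the
  non-scattering pencil-beam case deterministic (exact Beer–Lambert, used
  as a tight oracle) and gives a finite fluence in μₐ = 0 voxels. The
  energy ledger closes pathwise — absorbed + escaped + roulette_net +
  residual = injected to ~10⁻¹⁶ relative — where roulette_net is
  killed-minus-gained roulette weight. 2D phantom planes are extruded to a
  thin slab when simulated with MC. The asymptotic decay constant in a
  scattering half-space matches μ_eff to ~1% at 10⁵ photons (the test
  asserts 10%).

Γ is fixed at 1: after sum-to-one normalization the absolute p₀ scale is
irrelevant.

## Dataset construction

Per phantom, Gaussian noise with σ = 0.3% of the stack maximum is added to
the p₀ stack; the ROI is vessel-class pixels whose CNR at the wavelength
nearest 800 nm — computed against the non-vessel background,
CNR = (S − mean_bg)/std_bg — is ≥ 2. Each surviving pixel contributes one
sum-normalized spectrum labeled with its ground-truth sO₂ (and phantom id,
depth, tissue label as metadata). Connected-component filtering uses
4-connectivity in the imaging plane; pixel indexing is 0-based, row-major
(y, z).

**Noise calibration.** The full-scale conditions this package emulates
simulate each wavelength with a 10⁷-photon Monte Carlo run; the effective
noise in such data is MC estimator variance, not an additive floor. We measured the per-voxel MC
noise of this package's own MC on a generic phantom at 800 nm (two
independent 2 × 10⁵-photon runs, ROI = vessel pixels) and extrapolated by
1/√N to 10⁷ photons: the median per-voxel relative noise is ≈ 3.6%,
equivalent to an additive σ of ≈ 0.3% of the stack maximum in the ROI.
That calibrated value, 0.003, is the package default (`noise_sigma_frac`,
configurable). A 1%-of-max floor — a plausible first guess — measurably
over-noises deep-tube and shadowed-vessel pixels and makes every domain
harder than the emulated 10⁷-photon conditions (the generic-domain error
floor rises to ~8–13% median relative error for *any* regressor we tried,
including k-NN and large independently trained MLPs).

## Training

Architecture: input(n) → [dense(2n) → leaky-ReLU(0.01) → dropout(0.2)] × 4
→ dense(1), He initialization, linear output head with estimates clamped
to [0, 1] at reporting time only (the regression target is declared on ℝ).
Loss is MSE on the sO₂ fraction (MAE available). Inputs are standardized
per feature with training-split statistics stored in the trained model; a
trained model is bound to its wavelength grid and rejects spectra on any
other grid, and rejects non-normalized inputs rather than silently
normalizing them.

The step schedule lr = 10⁻² · 0.9^(epoch/2) (updated every two epochs) is
kept in both profiles. The optimizer is Adam (β₁ = 0.9, β₂ = 0.999) with
the schedule rescaled by 0.1 to Adam's customary 10⁻³ starting magnitude;
plain SGD with momentum 0.9 (available via `optimizer="sgd"`) converges an
order of magnitude too slowly at desk scale — with numerically verified gradients it plateaus at
2–3× the error that an independent sklearn MLP reaches on identical data,
while Adam matches the independent fit.

Two profiles exist:

* **full profile** (`lsd_profile="full"`) — 100 epochs × 500 batches ×
  10⁴ samples, the full-scale schedule;
* **desk profile (default)** — 60 epochs × 500 batches × 256 samples
  (3 × 10⁴ updates, versus 5 × 10⁴ in the full schedule), sized to the
  ≈ 10⁵-spectra desk datasets. Batches are drawn with replacement from the
  75% training split; 5% is validation (logged per epoch), 20% the
  held-out test split, touched only at final evaluation.

Seeding: phantom sampling, extraction noise, splits, initialization,
batch and dropout sampling all derive deterministically from the
configured seed; two runs with the same seed agree bit for bit.

## Evaluation

Relative error e = |est − gt| / gt summarized by median and (q25, q75)
with linear percentile interpolation; rows with gt = 0 are excluded from
relative summaries (count logged) and kept in absolute (percentage-point)
summaries. The Severinghaus dissociation curve
sO₂ = (23400/(pO₂³ + 150 pO₂) + 1)⁻¹ uses the standard published
constants (overridable); its numerical inverse round-trips to 10⁻⁶ mmHg.

## Desk-scale study sizes

`scripts/acceptance.py` and the heavyweight tests use ≈ 10⁵ extracted
spectra per domain (≈ 50 generic, ≈ 140 flow, ≈ 70 forearm phantoms), the
layered forward model, the calibrated noise default, and the desk training
profile. The LU baseline is evaluated on a seeded 2500-row subsample of
the test split (SLSQP dominates its cost; medians are stable well below
that size).

## What the synthetic study does and does not show

The phantoms reproduce the *composition laws* and wavelength grids of the
emulated acquisition setups, but not real acoustics: no acoustic forward model, no
reconstruction artifacts, no limited-view geometry, no motion, and a
layered (not MC) fluence for training data, with lateral beam structure
ignored. Passing error bounds therefore demonstrates that the regressor
inverts the simulated coloring on held-out simulated pixels — the
in-silico claim — not performance on any physical device. Train and test
rows share phantoms (the split is a random row split), so
the test split probes interpolation within the domain, not transfer across
domains. Known further limitations: vessels may overlap previously placed
structures (later placements win); the gel pad is assigned a small
non-zero μs′ (1 cm⁻¹) so the layered model is defined there; melanin, fat,
and collagen are absent outside the epidermis term.
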