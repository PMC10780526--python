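# Methods

`mwtomo` builds synthetic training worlds for data-driven 2D electromagnetic
medical imaging: randomized dielectric phantoms, full-wave multistatic
time-domain acquisitions, a fixed preprocessing chain, an encoder–decoder
reconstruction network, and image-quality scoring. This note records the
models, the numerical choices, and what the scaled-down tests do and do not
establish.

## Imaging scenario

A 500 mm × 500 mm square domain is meshed at 2 mm (250×250 cells). Sixteen
idealized Hertzian (2D line-current) antennas sit evenly spaced (22.5°) on a
150 mm-radius ring and take turns transmitting while all sixteen record,
giving 256 traces per scene. Scatterers are confined to a 130 mm-radius
imaging circle; the space between objects and antennas — and everything
beyond, including under the absorbing boundary — is a matching medium with
relative permittivity 40 and conductivity 0.1 S/m, emulating the coupling
liquids used in practice. (The source text is ambiguous between a 130 mm and
a 150 mm imaging circle; 130 mm is the default so objects never touch the
antennas, and it is configurable.)

## Random phantoms

A scene superimposes `n` shapes (6–24 for the database's ten groups, 1–2 for
the "simple scenes" mode; both run through the same code path):

- **Shapes.** Ellipse or convex polygon with probability ½ each. Full axis
  lengths uniform in [50, 120] mm (major = the larger draw), rotation uniform
  in [0°, 360°), centers uniform over the imaging disc (area-uniform:
  r = R√u). Polygons take 3–6 vertices placed at sorted uniform angles on the
  shape's ellipse — convex, with the same size bounds as ellipses.
- **Properties.** Each shape independently draws relative permittivity
  uniform in [10, 80] and conductivity uniform in [0.2, 2.5] S/m — the span
  of human tissues from fat to cerebrospinal fluid.
- **Superposition.** Overlapping shapes add their values; the object-support
  cells are then affinely rescaled, per case and per property, so the support
  minimum and maximum land exactly on the design interval. A single-valued
  support keeps its value (clipped). This is the simplest rule that keeps
  superimposed scenes inside the stated tissue ranges; the original
  procedure's exact arithmetic is not public.
- **Labels.** The 256×256 ground-truth permittivity image is rasterized from
  the analytic shape descriptions over the full square (nearest-neighbour at
  pixel centers, not resampled from the solver grid) using the same affine
  parameters, so label values match the simulated phantom.

Group g (0-based) of the ten database groups uses 6 + 2g shapes, stepping
6 → 24. All sampling is driven by `numpy` `SeedSequence` spawning, so a
database is bit-reproducible from one integer seed and any case can be
regenerated independently.

## FDTD solver

Transverse-magnetic (Ez, Hx, Hy) leapfrog scheme on a staggered Yee grid
with per-cell lossy-dielectric coefficients
Ca = (1 − σΔt/2ε)/(1 + σΔt/2ε), Cb = (Δt/εΔx)/(1 + σΔt/2ε). Defaults:
Δx = 2 mm, Δt = 4.72 ps, 5000 steps (23.6 ns). Antennas are additive
("soft") Ez point sources at the nearest grid cell; receivers sample Ez at
the same cells. Non-magnetic media (μ = μ0).

- **Stability.** The 2D Courant bound Δt ≤ Δx√(ε_min)/(c0√2) is enforced at
  build time against the actual grid minimum. This is why the matching
  medium must fill the space under the boundary layer: with vacuum anywhere
  the limit (4.714 ps) is below the 4.72 ps operating step, while ε_min = 10
  admits it (limit 14.9 ps).
- **Excitation.** Gaussian-modulated sinusoid centered at 1.25 GHz. The
  envelope width is chosen in closed form so the −10 dB *power* points sit at
  0.5 and 2 GHz (σ_f = Δf_half/√(ln 10), τ = 1/2πσ_f); delay 4.5τ keeps the
  start below 10⁻⁴ of the peak. Measured edges land within 0.4% of design.
- **Absorbing boundary.** 10-cell convolutional PML, cubic polynomial
  grading, backed by a PEC wall. Two numerical points matter at this band
  and mesh (≈12 cells/wavelength at 2 GHz):
  (1) the staggered-node profile must be measured from the E-grid walls — a
  half-cell misalignment on one side costs tens of dB;
  (2) the continuum "target reflection 10⁻⁶" conductivity is too strong for
  the discrete transition and measures −46 dB; grading in 0.25× of nominal
  (`pml_sigma_factor`) measures ≈ −70 dB broadband. CPML α is zero: at
  0.5–2 GHz, α/ε0 is comparable to ω even for α = 0.02 S/m, which distorts
  the stretch and costs ≈25 dB. The lossy matching medium handles late-time
  low-frequency energy instead.
- **Validation.** The homogeneous-medium response matches the analytic 2D
  line-current field (frequency-domain Hankel H0⁽²⁾ solution with the
  soft-source current equivalence I = −s·dx²/(Cb·dx·…) derived, not fitted)
  to 1.4% relative L2 at 10 mm range; the error grows roughly linearly with
  distance (grid dispersion), reaching ~7% at 50 mm. Reciprocity of the
  multistatic tensor holds to machine precision. A staggered-time discrete
  energy (E·E paired with consecutive half-step H products) is conserved to
  ~10⁻¹⁰ per step in lossless runs before boundary contact.
- **Measuring boundary reflection honestly.** A single-run, time-gated
  reflection measurement bottoms out near −45 dB — not reflection, but the
  incident pulse's own numerical-dispersion tail (it appears unchanged with
  no wall in reach). Reflection is therefore measured by subtracting a
  larger-domain reference run with identical source–receiver geometry.

## Preprocessing

16×16×n_steps → stack transmitter-major (row = 16·tx + rx) → keep every
20th time sample (pure decimation, phase 0; an averaging mode exists but is
off by default) → append six zero columns → per-row min–max normalization
X' = (X − Xmin)/(Xmax − Xmin), with constant rows mapping to all-zero (the
0/0 convention). At defaults the chain is 16×16×5000 → 256×5000 → 256×250 →
256×256. Normalization equalizes near-pair and far-pair amplitudes, which
differ by orders of magnitude.

## Reconstruction network

U-net-style encoder–decoder, implemented from scratch in NumPy (the
environment provides no autodiff framework): shift-and-accumulate 5×5
same-padded convolutions + ReLU (two per level), 2×2 max-pooling between
the five encoder levels, channels 8→16→32→64→128 (256×256 input reaches a
16×16×128 bottleneck), a decoder of 2×2-stride-2 transposed convolutions
with skip concatenation, and a final linear 1×1 convolution. The stated
"2×1" convolution stride contradicts the printed 256→16 shape chain when
combined with pooling; stride-1 convolutions with 2×2 pooling reproduce the
chain and are used. Training: Adam (lr 5·10⁻⁴), MSE on labels affinely
scaled from [10, 80] to [0, 1], batch 32 (full-batch when the dataset is
smaller). Backpropagation is analytic and verified against central
differences; the ReLU subgradient at exactly 0 is taken as 0 (relevant only
for the measure-zero exact-zero preactivations that zero-initialized biases
produce). Epoch count is a free parameter — the source never states one.

## Metrics

SSIM with the conventional 11×11 Gaussian window (σ 1.5), stabilizers
(0.01L)² and (0.03L)², and a *fixed* dynamic range L = 70 (the permittivity
design span 80 − 10) so scores are comparable across cases; NRMSE = RMSE
divided by the reference's value range; PSNR = 20·log₁₀(range/RMSE) dB,
capped at 100 dB for identical images. Summaries report mean, sample
standard deviation, and the proportions meeting the accepted-quality
baselines (SSIM > 0.9, NRMSE < 0.2, PSNR > 30 dB).

## What the scaled-down tests establish — and what they do not

The full program — 25,000 cases × 2.3 min of FDTD each, plus training on
24,000 cases — is on the order of 10³ CPU-hours and is out of desk scope.
The test suite substitutes:

- exact contracts (time budget, tensor shapes, preprocessing chain, network
  shape arithmetic, pulse band edges);
- solver physics at reduced grids (analytic oracle, reciprocity, boundary
  reflection, energy conservation, stability guard);
- a learning-capacity check: 16 simulated multi-shape cases at a 4 mm mesh,
  fitted at 32×32 with channels 4→64 for 2000 steps — training MSE falls
  ~250×, and the fitted reconstructions' mean SSIM beats an all-background
  prediction;
- a held-out check on simple scenes at the same reduced scale.

A green suite establishes that the machinery is correct and that the
network has the capacity to invert the simulated physics it has seen. It
does **not** establish the generalization levels of the full-scale program:
desk-scale training sets (tens of cases) are far below what the inverse
problem needs, and held-out reconstruction quality at this scale is
reported by the tests as observed, not extrapolated. The synthetic world
also omits real-acquisition effects — antenna feed models, measurement
noise, dispersive (frequency-dependent) tissue properties, and 3D
propagation are all out of scope.
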