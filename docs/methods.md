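# Methods

## FRAP model

Recovery after a line bleach across an elongated intracellular structure
is modelled in one dimension along the structure's long axis. The
observable axial profile is decomposed into two populations at the moment
of the bleach:

* an **immobile** component `(1 − M) · C_post(X)`, which keeps the bleach
  scar indefinitely;
* a **mobile** component `M · C_post(X)`, which relaxes by Fickian
  diffusion, `∂C/∂t = D ∂²C/∂X²`, toward its uniform equilibrium.

This decomposition is the unique one whose center-pixel plateau equals
`M · C_pre + (1 − M) · C_post`, i.e. it is consistent with the endpoint
definition of the mobile fraction
`M = (F_final − F_post) / (F_pre − F_post)`. The cell envelope retains
fluorophores, so both grid ends carry no-flux boundary conditions; with
grid points at pixel centers the ghost point is reflected across the
boundary pixel edge, which makes the discrete Laplacian sum to zero and
total fluorescence exactly conserved. Binding kinetics
(reaction-dominant FRAP), anomalous diffusion, and 2D/3D geometry are out
of scope; for a ~0.3 μm bleach line in a ~3 μm structure the 1D
approximation is the standard treatment.

### Numerics

The engine is explicit Euler on the 3-point Laplacian. Stability requires
`D·Δt/Δx² ≤ 0.25` (half the von Neumann limit, enforced); `evolve()`
subdivides each inter-frame interval into the fewest equal steps meeting
the bound. Because the update is linear, `n` equal steps are applied as
the `n`-th power of the one-step transition matrix (repeated squaring),
which makes even ~10⁶-step evolutions at large `D` cost milliseconds
while remaining the explicit-Euler solution. Against closed forms the
engine matches the Gaussian variance law `σ²(t) = σ₀² + 2Dt` to well
under 2% and the cosine-series solution of the no-flux heat equation to
~1e-5 relative; mass is conserved to rounding (≤1e-9 relative over any
trajectory tested).

The cosine-series solution (DCT-II expansion with continuum eigenvalue
decay) is kept in the package as an independent oracle and as an
alternative forward model for the generator, so estimator round-trips are
not checked purely against the engine that the estimator itself inverts.

## Estimation pipeline

Per cell: Otsu segmentation of the mean prebleach frame (threshold
computed on a 90th-percentile-clipped copy so sparse bright puncta cannot
capture the split), profile extraction by projecting masked pixels onto
the mask's major axis and summing across the short axis at pixel pitch,
per-frame normalization to the prebleach total (compensating acquisition
photobleaching), bleach-center location at the minimum of the
post−pre difference profile (ties broken toward the cell center, then the
lower index), and the recovery curve as the windowed mean (half-width 1 px
by default) at that center relative to prebleach.

`M` is first computed from the endpoint formula with `F_final` taken from
the fitted exponential plateau (robust to end-frame noise; a last-k-frames
mean is available by config). `D` is then matched by minimizing the sum
of squared differences between observed and simulated center curves over
a deterministic log-grid (25 points/decade over 1e-6…1e-1 μm² s⁻¹)
followed by golden-section refinement (relative tolerance 1e-3) — no
stochastic optimizer, so estimates are exactly reproducible.

**Joint refinement (default).** When recovery is slow relative to the
60-min window (e.g. `D ≈ 1e-4 μm² s⁻¹`), the curve has not plateaued and
the single-exponential extrapolation underestimates the plateau by
several percent of amplitude, which biases `M` low and, through the
conditional match, `D` high. The pipeline therefore finishes with a local
joint (M, D) least-squares refinement of the diffusion model against the
full curve, initialized at the two-stage solution. On noiseless fixtures
this recovers (M, D) to better than 0.1% across
D ∈ [1e-4, 4e-3] μm² s⁻¹ × M ∈ [0.25, 1]; the two-stage values (A, τ,
τ½, raw endpoint M) are still reported. Setting
`FrapConfig.joint_fit = False` restores the plain two-stage estimate.

Estimates whose raw endpoint M falls outside [−0.05, 1.05] are flagged as
QC failures (`qc_pass = False`) rather than silently clipped.

## Synthetic data

The generator emulates the study conditions the pipeline targets:
3 × 1 μm rods at 0.05 μm/px, an elongated fluorescent structure filling
the rod, a 0.3 μm line bleach at mid-cell removing 80% of fluorescence,
one frame per minute for 60 min (one prebleach frame), Gaussian detection
noise of 2% of the prebleach level, optional Poisson shot noise, and
presets `cargo_like` (M = 0.83, D = 4.02e-4 μm² s⁻¹) and `shell_like`
(M = 0.06, D = 0.28e-4 μm² s⁻¹) matching the two molecular populations of
interest. Pixel size, bleach width and depth are fixture conventions
(instrument values are rarely published); they are explicit fields of
`SimulationParams`. Colocalization fixtures place Gaussian foci with a
programmed overlap fraction ρ, keeping non-shared foci ≥ 4 PSF widths
from the other channel's foci so ρ = 0 is disjoint by construction.
Birth-event fixtures ramp a focus from 0 to full intensity over two
frames at a scheduled frame and axial position; the biased-position
sampler draws folded positions with a programmable polar-quarter
probability (default 0.704).

What the generator does **not** emulate: optical sectioning and a
realistic 3D PSF (blur is Gaussian), cell growth or division during the
series, bleaching during acquisition beyond the global intensity decay
that normalization removes, motion of the structure, and multi-cell
fields of view. Passing round-trip tests therefore demonstrates that the
estimator correctly inverts its stated physical model under realistic
noise — not that the model captures every property of real confocal data.

All randomness flows from a single integer seed through fixed named
substreams (one per stage), so identical seeds give bit-identical images
and different stages cannot perturb each other.

## Event detection

The study-style scoring of focus appearance is by eye; here it is an
auditable rule: a focus is a connected region (≥ 4 px) of masked pixels
above mean + 3·SD of the masked intensities, and an appearance counts
only if a focus is present in 2 consecutive frames (suppressing
single-frame flickers). With the default settings, flat-noise frames
trigger in < 5% of replicates and programmed appearances are recovered at
the scheduled frame and position (± 1 px). A cell is classified
shell-first or cargo-first when one channel's first appearance precedes
the other's by more than the concomitance window (default 0 frames:
same-frame appearances are concomitant, matching one-frame temporal
resolution). Cell length for position folding is the mask's major-axis
extent; only the first event per cell is scored.

## Problem sizes

Test-suite and acceptance computations use single cells of 60 × 20 px
with 61 frames; noisy recovery statistics use 20 replicates per preset;
event statistics use 50 scheduled time-lapses and 500-draw position
schedules. These sizes give binomial/Monte-Carlo error comfortably inside
the asserted tolerances while keeping the whole suite in seconds.

## Known limitations

* The D match assumes the two-population pure-diffusion model; if real
  recovery is binding-dominated, the fitted D is an effective parameter.
* Only the largest connected component is analyzed per field of view.
* `estimate_D` is bounded to 1e-6…1e-1 μm² s⁻¹; minima at the range edge
  are returned with a warning rather than refined.
* Near-immobile cells (M ≈ 0.05) carry little curve information, so
  per-cell D estimates there scatter by ~15–20% at 2% noise; group means
  remain within a few percent.
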