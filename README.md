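# bmcquant

Quantification of live-cell fluorescence imaging of bacterial
microcompartments (BMCs): FRAP-based mobility estimation, dual-channel
colocalization, and de novo assembly-event statistics, together with a
seeded synthetic-image generator that makes every stage verifiable by
parameter recovery.

## Who this is for

Groups imaging protein organelles in rod-shaped bacteria (Pdu
metabolosomes, carboxysomes and relatives) who need the bespoke
computations behind such studies as tested, reusable code rather than
one-off spreadsheet routines:

* **FRAP of elongated structures.** A line is bleached across the center
  of a fluorescent structure and recovery is imaged (by default every
  1 min for 60 min). Axial intensity profiles are extracted, each frame is
  normalized to the prebleach total fluorescence, and the recovery curve at
  the bleach center yields the **mobile fraction**

  `M = (F_final − F_post) / (F_pre − F_post)`,

  where `F_final` defaults to the fitted plateau of the single-exponential
  recovery `f(t) = A (1 − e^(−τt))` with half-time `τ½ = ln 0.5 / (−τ)`.
  The **diffusion coefficient** `D` is found by matching the observed curve
  against finite-difference simulations of the 1D diffusion equation
  `∂C/∂t = D ∂²C/∂X²` with no-flux boundaries and a two-population
  (mobile + immobile) decomposition of the post-bleach profile. A joint
  (M, D) least-squares refinement then polishes both numbers.

* **Colocalization.** Whole-cell Pearson correlation R between two
  channels within an Otsu-derived cell mask, with the paired-pixel scatter.

* **Assembly events.** First persistent appearance of shell and cargo foci
  in two-channel time-lapses, classification into shell-first /
  cargo-first / concomitant events, and the folded axial position
  (0 = pole, 0.5 = mid-cell) of the first focus, including the fraction of
  events in the polar quarter.

## Worked example

```python
import bmcquant as bq

# simulate a cargo-like FRAP experiment (M = 0.83, D = 4.02e-4 um^2/s)
params = bq.SimulationParams.cargo_like(seed=7)
series, truth = bq.generate_frap_series(params)

est = bq.analyze_cell(series)
print(f"mobile fraction M  = {est.M:.3f}")
print(f"diffusion coeff D  = {est.D:.3e} um^2/s")
print(f"half-time t_1/2    = {est.half_time:.1f} s")
```

prints

```
mobile fraction M  = 0.831
diffusion coeff D  = 4.036e-04 um^2/s
half-time t_1/2    = 72.3 s
```

i.e. from a single noisy simulated cell the pipeline recovers the
generator's mobile fraction to 0.001 and its diffusion coefficient to
within ~0.4%; the ~72 s half-time says the bleached line refills on a
minutes scale, consistent with a liquid-like interior.

The same stages are available from the shell:

```
bmcquant simulate --seed 42 --preset cargo_like --output-dir out/
bmcquant frap --input out/cargo_like.tif --pixel-size 0.05 --interval 60 --output-dir out/
bmcquant coloc --channel-shell shell.tif --channel-cargo cargo.tif
bmcquant events --channel-shell shell.tif --channel-cargo cargo.tif
```

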