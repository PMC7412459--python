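# cmqleaf

Quasi-color modeling of bifacial leaf color from pigment meter readings.

Many leaves — red lettuces are the classic case — carry different colors on
their upper (adaxial) and lower (abaxial) surfaces, because chlorophylls and
anthocyanins distribute unevenly across the blade. Neither surface's CIELab
color alone tracks the leaf's total pigment content. The **conceptual
midpoint quasi-color (CMQ)** resolves this: for CIELab measurements taken at
antipodal points on the two surfaces,

    qL* = (L*_D + L*_B) / 2,   qa* = (a*_D + a*_B) / 2,   qb* = (b*_D + b*_B) / 2

with chroma qC* = √(qa*² + qb*²) and hue qh° = atan2(qb*, qa*), exactly as in
CIELab. The CMQ is not a visible color; it is the notional color that *does*
correlate tightly with pigment content even on strongly bifacial leaves.

The package is for plant phenotyping and breeding workflows that use
transmittance meters — SPAD (chlorophylls) and ACI (anthocyanins) readings,
transformed to SR-S = √SPAD and Lb-A = log₂ ACI. Its core is a small
feed-forward network with one hidden layer of three tanh units,

    H_j = tanh(0.5 (c_j + w_j1 SR-S + w_j2 Lb-A)),    q = d + V H,

shipped with the published coefficients fitted to 604 lettuce leaves, plus
everything around it:

- **colorimetry** — chroma, hue (0–360° and the wraparound −180–180° scale
  used for statistics), ΔE color difference, CMQ from two surfaces;
- **pigments** — SPAD/ACI ↔ SR-S/Lb-A transforms, antipodal averaging,
  calibration-range warnings;
- **network** — the published predictor, forward evaluation, JSON
  serialization;
- **training** — refitting tanh networks (penalized least squares, seeded
  restarts), three nested polynomial baselines (full factorial, quadratic
  polynomial, response surface), and hidden-width selection by repeated
  cross-validated negative log-likelihood;
- **metrics** — R², RMSE, Pearson r, Lin's concordance ρ_c, seeded
  train/test splits, a side-by-side model-comparison table, Monte-Carlo
  total-effect input sensitivity;
- **gamut** — the attainable quasi-color set over the pigment domain, with
  slice and corner summaries;
- **inference** — the color of an unobserved surface via
  hidden = 2·CMQ − known;
- **simulate** — a synthetic leaf-survey generator reproducing the original
  survey's summary statistics, for fully offline testing and benchmarking.

## Worked example

```python
from cmqleaf import (PigmentLevel, SurfaceColor, predict_cmq,
                     estimate_hidden_surface, published_cmq_network)

net = published_cmq_network()
cmq = predict_cmq(net, PigmentLevel(srs=9.7, lba=7.5))   # mondo grass
print(f"qL*={cmq.qL:.1f} qa*={cmq.qa:.1f} qb*={cmq.qb:.1f}")

est = estimate_hidden_surface(SurfaceColor(23.1, 8.1, 5.2),
                              PigmentLevel(srs=5.4, lba=3.9))  # lettuce LS-101
print(f"abaxial estimate: L*={est.L:.1f} a*={est.a:.1f} b*={est.b:.1f}")
```

prints

```
qL*=28.7 qa*=-0.9 qb*=1.7
abaxial estimate: L*=49.2 a*=-3.6 b*=15.2
```

The first line is the quasi-color of a leaf extremely rich in both pigments:
very dark (low qL*) and almost achromatic (qa*, qb* near zero) — such leaves
look nearly black. The second line estimates the unmeasured lower-surface
color of a lettuce leaf from its pigments and measured upper surface; the
actual measured value was (50.3, −4.1, 16.3).

The scripts in `examples/` walk through each capability (prediction, CMQ
from two surfaces, surface inference, gamut mapping, refitting and model
comparison, hidden-width selection) and print the numbers they compute.

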