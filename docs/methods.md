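# Methods

## The quasi-color model

A leaf spot is measured twice, at antipodal points on the adaxial (D) and
abaxial (B) surfaces, in CIELab (D65/10°). The conceptual midpoint
quasi-color (CMQ) is the per-axis mean of the two triples. It is a modeling
construct, not a visible color: when the two surfaces are identical it
coincides with the surface color, and when they differ it is the quantity
that remains predictable from total pigment content.

Pigments enter on transformed scales: SR-S = √SPAD for chlorophylls and
Lb-A = log₂ ACI for anthocyanins, both chosen to normalize the raw meter
distributions. Readings from the two surfaces are averaged per pigment on
the transformed scale — the scale every downstream model consumes — since
the original order of operations is not recorded and transforming first
keeps the training inputs and the prediction inputs on one scale.

The predictor is a 2-H-3 feed-forward network with tanh hidden units and a
fixed pre-activation factor of 0.5:

    H_j = tanh(0.5 (c_j + w_j1 SR-S + w_j2 Lb-A)),   q = d + V H.

The published 3-unit coefficient set ships as a JSON asset, stored at
exactly its printed 4-decimal precision with the 0.5 factor kept explicit
rather than folded into the weights, so the shipped numbers match the
printed equations digit for digit. Inputs are raw SR-S/Lb-A (no internal
standardization); this is confirmed by the model reproducing its documented
worked predictions, e.g. (SR-S 9.7, Lb-A 7.5) → (28.7, −0.9, 1.7).

Because |tanh| ≤ 1, every response is confined to d_r ± Σ_j |V_rj| for any
input whatsoever; the envelope, a Lipschitz bound derived from coefficient
norms, and the monotone decrease of qL* in both pigments over the
calibrated grid are enforced as tests.

### Hue conventions

Hue is the quadrant-aware two-argument arctangent of (a*, b*) — the naive
arctan(b*/a*) is quadrant-ambiguous. Statistics on hues use the wrapped
scale: angles strictly above 180° are shifted by −360°, making purple-red
hues near the 0/360 boundary average correctly. 180° itself is kept
unchanged (half-open convention; cyan/teal hues do not occur in leaves, so
the boundary choice is inconsequential). Summaries convert back to the
conventional 0–360° scale.

ΔE between quasi-colors (ΔqE) is computed with the ordinary CIELab formula
applied to the CMQ triples; the quasi-color is treated as a point in the
same space, which is exactly how model-vs-observation differences are
scored.

## Calibration domain

The model was fitted on lettuce (SR-S 0–8.6, Lb-A 0.1–7.8) and deliberately
applied out to SR-S ≤ 9.7 and 0 ≤ Lb-A ≤ 8.0 across other species. Inputs
outside that domain are accepted — refusing them would forbid the model's
own documented use — but raise a `CalibrationWarning`. Estimated surface
colors whose lightness leaves [0, 100] are never clipped; they carry an
explicit flag.

## Fitting and width selection

Refitting minimizes squared error summed over the three responses with an
L2 penalty on weights (never biases). For conditioning, inputs and
responses are standardized internally (responses to unit variance, so qL*
does not dominate by scale) and the standardization is folded back into the
returned raw-scale weights. Optimization is L-BFGS with analytic gradients,
best of `restarts` seeded random initializations (default 10), relative
loss tolerance 1e−8, iteration cap 2000. A fit with fewer samples than free
parameters (6H + 3) is refused. The default penalty is a light ridge
(1e−4 on the standardized scale); `penalty="auto"` searches the grid
{0, 1e−4, 1e−3, 1e−2, 1e−1} by held-out likelihood on an internal 90/10
split and refits on all data. All randomness descends from one seed.

Model fit is scored by a summed Gaussian negative log-likelihood: per
response, the plug-in variance estimate (mean squared residual, floored at
1e−9 to keep the zero-residual limit finite), per-response NLLs added. The
exact likelihood bookkeeping of the original analysis software is not
documented; this plug-in form is the package's own documented choice, and
only NLL *differences* across candidate widths matter for selection.

Hidden-width selection repeats a seeded 9:1 train/validation split
(`repeats` times, default 20), scores every candidate width per split, and
averages. This mirrors the described procedure, which splits 10:1 per
repetition rather than rotating folds; a true k-fold rotation is available
via `method="rotation"`. The selected width is the smallest whose mean NLL
is within one standard error of the minimum — a standard parsimony
tie-break, adopted because no explicit rule is recorded. On synthetic data
generated from the 3-unit published model (n = 480, realistic noise), this
procedure recovers width 3 (checked over widths 1–8 with 20 repeats; the
full 1–25 sweep adds cost without changing the minimum's location, since
mean validation NLL rises monotonically beyond the optimum in every run we
executed).

### Polynomial baselines

The three classical response designs are fitted per response by exact OLS:
full factorial {1, S, A, S·A}, quadratic polynomial {1, S, A, S², A²}, and
response surface {1, S, A, S·A, S², A²}. The names are standard; the term
sets are the package's explicit definitions and satisfy the nesting that
makes training-error comparisons meaningful (both smaller families are
subsets of the response surface).

## Agreement metrics

R² is 1 − SS_res/SS_tot against the observed series; RMSE is the root mean
squared residual. Pearson r measures linearity; Lin's concordance ρ_c uses
population (divide-by-n) moments — the original estimator — and satisfies
|ρ_c| ≤ |r|, with equality when means and variances match.

Input sensitivity is a Monte-Carlo total-effect (Sobol-type, Jansen
estimator) analysis over independent uniform pigment ranges. The procedure
that produced the originally reported importance percentages is not
documented, so these numbers are a directional characterization — which
pigment dominates which coordinate — not a reproduction; the package's
analysis agrees directionally (anthocyanins dominate qL* and qb*).

## Gamut mapping

The gamut is the network's image of a regular pigment grid (default step
0.1 in both axes over SR-S ∈ [0, 9.7], Lb-A ∈ [0, 8.0]; fine enough that
halving the step changes attainable ranges by far less than the tolerances
used anywhere). Corner summaries average wrapped hue over the single-pigment
corners, defined as the outer 10% of each axis.

A noteworthy model property: the attainable hue set is
(≈352.7°, 360°] ∪ [0°, ≈126.5°]. The anthocyanin-only corner therefore sits
at ≈353° — squarely in the purple-red range but about 13° away from the
≈340° sometimes quoted from figure inspection; 340° is outside the model's
gamut altogether. The chlorophyll-only corner is ≈125–126° (green), as
expected. Peak chroma occurs on single-pigment edges, never the
both-pigments-high corner, where the quasi-color dulls.

## Surface inference

With pigments known and one surface measured, the other surface is the
reflection through the predicted midpoint: hidden = 2·CMQ − known. The
formula is surface-agnostic (the caller labels which side was measured) and
involutive, and the midpoint of (known, estimate) equals the predicted CMQ
to machine precision — both enforced as tests. No plausibility constraint
is imposed beyond the lightness flag.

## Synthetic leaf surveys

The generator emulates the summary structure of the primary lettuce survey
so everything downstream is testable offline:

- **Pigments:** truncated normal marginals on SR-S ∈ [0, 8.6] and
  Lb-A ∈ [0.1, 7.8] with sd = range/4 (only ranges and means are reported;
  range/4 puts the bounds near ±2 sd). The location parameter is solved
  numerically so the *realized* mean equals the reported mean (5.8 / 3.6) —
  asymmetric truncation would otherwise shift it. Pigments are independent
  by default, with a Gaussian-copula correlation knob, since the joint
  distribution is not reported.
- **Observations:** observed CMQ = published-network prediction plus
  independent Gaussian noise per coordinate with sd 1.81 / 1.23 / 1.71
  (the network's training-set RMSE per coordinate) — noise is attached to
  the modeling target, not to each surface, matching the fitting
  assumption.
- **Surfaces:** placed symmetrically about the observed CMQ along a
  uniformly random direction in (L, a, b), oriented so the adaxial side is
  darker (the direction of the reported surface asymmetry), with ΔE
  magnitude drawn from an exponential with mean 10.3 — a heavy right tail
  consistent with a reported maximum of 46.4 against a mean of 10.3. The
  surface midpoint reproduces the observed CMQ exactly by construction.

What passing tests on these data do and do not show: they verify the
machinery — fitting recovers a 3-unit surface, selection recovers its
width, agreement metrics reach survey-like levels — under the reported
noise and pigment distributions. They do not certify performance on real
leaves, whose pigment-asymmetry dependence, measurement error structure,
and species effects the generator deliberately does not model (no optics,
no spectra).

## Problem sizes and numerical choices

Study-style analyses use the survey's own sizes: n = 604 split 480/124 for
refitting quality, n = 480 for width selection with 20 repeated splits over
widths 1–8 and 3 restarts per fit. Comparisons against printed values are
made after rounding to the printed precision (one decimal; nearest degree
for hue). Degenerate inputs fail loudly: hue at the achromatic point,
zero-variance series in correlation metrics, empty record sets, rank
deficiency in OLS, and under-determined network fits all raise errors
rather than returning silent defaults.

## Known limitations

- The package reproduces the published predictor and its documented worked
  examples exactly, but the original raw survey data are not bundled, so
  the historical performance table can only be mirrored in structure (on
  synthetic data), not in its exact numbers.
- The likelihood used for width selection and the sensitivity procedure are
  explicit reconstructions of under-documented steps (see above).
- The published model family is small and smooth by design; nothing here
  targets leaves outside its calibration (thick, waxy, yellow/white, or
  flower tissue), where the model is documented to degrade.
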