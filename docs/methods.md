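# Methods

## Enhancement model

An RGB image is decomposed into hue–saturation–intensity (HSI, Gonzalez
sector convention) with intensity I = (R+G+B)/3. Only the intensity
channel Υ ∈ [0,1]^{P×R} is modified; hue and saturation pass through
unchanged so the recomposed RGB keeps its chromatic content. The stretch
is a local-statistics transform

    Υe(x,y) = [Pδ·μ / (Υσ(x,y) + Pβ + ε)] · (Υ(x,y) − Pγ·Υμ(x,y)) + Υμ(x,y)^Pα

clipped to [0,1]. Υμ and Υσ are sliding-window local mean and
*population* standard deviation with symmetric-reflect border padding;
μ is the global channel mean. Intuition: pixels are re-expressed as a
deviation from (a fraction Pγ of) their local mean, amplified by a gain
that is large where the neighborhood is flat and small where it is
already busy; the additive Υμ^Pα term restores local brightness. The
typeset source formulations of this transform family are ambiguous in
their operator grouping; the grouping above is the classical
statistical-enhancement one (gain × deviation + brightness term), which
is the only reading in which each parameter has its stated role.

Parameters and their box bounds (dimensionless unless noted):

| parameter | role                          | bounds      |
|-----------|-------------------------------|-------------|
| Pα        | local-mean exponent           | [0, 1.6]    |
| Pβ        | gain-denominator offset (intensity units) | [0, 0.5] |
| Pγ        | local-mean subtraction weight | [0, 0.8]    |
| Pδ        | overall gain                  | [0.5, 1.5]  |

The window size w defaults to 3 px (smallest odd neighborhood;
configurable). ε = 1e−6 guards the denominator, since Pβ = 0 is inside
the bounds and Υσ = 0 on flat regions.

## Quality objective

    CF(Υe) = ln(ln(Υs)) · n_edgels(Υe) · H(Υe) / (P·R)

* Υs — sum over all pixels of the Euclidean magnitude of the two 3×3
  Sobel responses (reflect padding). Floored at e + 1e−12 before the
  double log, which is otherwise undefined (≤1) or negative (<e); the
  floor only affects near-constant images, whose CF is 0 anyway through
  the entropy factor.
* n_edgels — pixels whose gradient magnitude strictly exceeds a
  threshold; default threshold = mean magnitude of the field
  (self-scaling across contrast levels), configurable to an absolute
  value.
* H — Shannon entropy in bits of the 256-bin equal-width histogram on
  [0,1] (256 matches the 8-bit provenance of dermoscopy images).
* The double log damps the gradient term so edge intensity cannot
  dominate; natural log there, base-2 entropy. Both choices only
  rescale the objective monotonically in each factor.

CF is deterministic, 0 exactly for constant channels, and increasing in
each factor for Υs > e.

## Hybrid optimizer

Both phases maximize CF over the 4-box; all positions are clipped to the
bounds after every update and all randomness comes from seeded
generators (fixed seed ⇒ bit-identical trajectory).

**Bat phase** (population N=20, T=30 iterations by default; fmin=0,
fmax=2, L0=1, φ0=0.5, ε=0.9, η=0.9 — canonical settings). Per bat and
iteration: frequency f = fmin + U(0,1)(fmax−fmin); velocity
V ← V + f(X − X*); candidate = X + V. With probability 1 − φ the
candidate is replaced by a random walk around the global best,
X* + θ·L̄, with θ a per-component U(−1,1) draw and L̄ the swarm's mean
loudness. The candidate replaces the bat's position only if it improves
the bat's own cost *and* a uniform draw falls below its loudness;
velocity persists either way and is never clipped. The global best is
updated greedily after *every* evaluation. Loudness (L ← εL) and pulse
rate (φ ← φ0(1 − e^{−ητ})) follow per-iteration schedules for every bat,
mirroring simulated-annealing cooling: this makes the walk radius decay
geometrically, which is what lets the swarm refine the optimum —
decaying loudness only on acceptance events leaves the walk radius near
1 and the final precision coarse (measured: known-optimum recovery
within 0.05/component drops from 10/10 seeds to 0/10).

**Bee phase** (colony = hand-over population, limit 20, 30 iterations
by default). The bat phase's final positions become the food sources;
the cross-phase best is carried in (elitism), so the concatenated
best-so-far trace is non-decreasing by construction. Raw costs enter
the fitness map under the minimization convention C = −CF, giving
fitness = 1 + CF for positive CF; without this sign flip the
fitness-proportional onlooker visits would favor the *worst* solutions.
Employed pass: each source spawns a child differing in one random
component, X_u + θ(X_u − X_partner,u), θ ~ U(−1,1), kept only on strict
fitness improvement (ties keep the parent and bump its trial counter).
Onlooker pass: sources are cycled and visited when a uniform draw falls
below Prob_v = 0.1 + 0.9·fitness_v/max fitness, spending one mutation
per visit until colony-size visits are spent (Karaboga's scheme).
Scout pass: at most one source per iteration — the one with the highest
trial count past the limit, ties to the lowest index — is replaced by a
fresh uniform draw with no greedy comparison.

The per-image pipeline computes local statistics once from the original
channel; each objective evaluation is one transform + CF evaluation.
Evaluations are counted (default budget ≈ 1850 per image) so baselines
can be budget-matched exactly. The master seed spawns independent
streams for the two phases and per image in batch mode.

## Synthetic data

Each sample is a skin-toned constant background (default intensity 0.65
with a zero-mean RGB tint (+0.10, 0, −0.10), so R > G > B as in skin), a
darker elliptical lesion (intensity gap 0.12 by default, drawn from
0.10–0.14 across a dataset), Gaussian blur (σ = 2 px), additive Gaussian
noise (σ = 0.02 per channel), and 0–3 dark anti-aliased quadratic hair
streaks. The ground-truth mask is the exact pre-blur ellipse indicator.
128×128 px by default — small enough for fast tests, with a
deliberately small lesion/background gap to emulate poor-contrast
dermoscopy.

What the generator does **not** emulate: the rich multi-scale texture of
real skin and lesions (pigment networks, globules), vignetting and
illumination gradients, color variegation inside the lesion, specular
reflections, and ruler/gel artifacts. This matters for interpreting
results: real dermoscopy has a high local σ nearly everywhere, which
caps the transform's gain term, whereas these synthetics are smooth
(local σ ≈ 0.01), so the same parameter bounds permit gains of 3–5×.
Passing optimizer tests on these fixtures demonstrates the search
machinery, not clinical image quality.

## Evaluation harness

Proxy segmenter: Otsu threshold on the intensity channel, darker class
taken as lesion (synthetic lesions are darker by construction;
polarity is configurable), largest 4-connected component, holes filled.
Scores: Jaccard J = TP/(TP+FP+FN) and Dice D = 2TP/(2TP+FP+FN) =
2J/(1+J). Empty-prediction vs empty-truth is scored 1.0 by convention
with a warning. The harness is a deterministic desk-scale stand-in for
trained neural boundary-estimation models; it tests the *direction* of
the enhancement effect, not absolute benchmark scores.

## Known limitations

* **The objective does not enforce brightness preservation.** CF
  contains no fidelity or brightness term; preservation can only emerge
  from the Υμ^Pα term. On the smooth synthetic fixtures it does not
  emerge: the acceptance script measures per-image mean-intensity shifts
  around +0.2 (reported as `max_brightness_shift`), well above a 0.15
  tolerance, because every high-CF parameter set within the stated
  bounds brightens these images (with Pγ ≤ 0.8 the gain term alone
  contributes ≳ 0.08 to the mean).
* **Enhancement can hurt threshold segmentation on smooth images.** On
  the default synthetic profile, raw Otsu is already near-ceiling
  (mean Dice ≈ 0.97), and maximizing CF amplifies sensor noise (both
  entropy and edgel count rise with noise), degrading the proxy
  segmenter; the acceptance script's `mean_dice_paired_difference` is
  negative under these conditions. Both effects follow from the
  objective's structure, not from the optimizer, which reliably finds
  the CF optimum (grid-oracle ratio ≥ 0.95, random-search wins ≥ 8/10).
* The per-iteration loudness/pulse schedules are one reading of the
  ambiguous schedule description (see above); the acceptance-triggered
  alternative is strictly worse at refinement.
* Hue is undefined at achromatic pixels; a sentinel of 0 is stored, and
  round-trip fidelity is only guaranteed away from S = 0 and the
  intensity extremes.
* The segmentation harness assumes one lesion per image and darker-
  than-background polarity.
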