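# lesionstretch

Brightness-aware contrast stretching for dermoscopy (skin-lesion) images,
driven by a hybrid bat-algorithm / artificial-bee-colony (BA–ABC)
metaheuristic that estimates image-specific enhancement parameters.

Low contrast between a lesion and the surrounding skin degrades automatic
boundary estimation. This package preprocesses an RGB dermoscopy image by
converting it to the HSI color model, stretching only the intensity channel
Υ with a local-statistics transform, and recombining — hue and saturation
pass through untouched. The stretched channel is

```
Υe(x,y) = [Pδ·μ / (Υσ(x,y) + Pβ)] · (Υ(x,y) − Pγ·Υμ(x,y)) + Υμ(x,y)^Pα
```

where Υμ and Υσ are the sliding-window local mean and standard deviation,
μ is the global mean, and the four parameters (Pα, Pβ, Pγ, Pδ) are bounded
by ψl = [0, 0, 0, 0.5] and ψu = [1.6, 0.5, 0.8, 1.5]. They are estimated
**per image** by maximizing an edge/entropy quality objective

```
CF(Υe) = log(log(Υs)) · n_edgels(Υe) · H(Υe) / (P·R)
```

with Υs the summed Sobel gradient magnitude, n_edgels the count of pixels
above the mean gradient magnitude, H the histogram entropy in bits, and
P×R the pixel count. The search runs in two chained phases: a bat
algorithm (frequency-tuned velocity updates toward the global best, a
loudness-scaled random walk, annealing-like loudness/pulse schedules)
followed by an artificial bee colony (employed/onlooker single-component
mutations with strict greedy selection, fitness-proportional visiting, and
scout replacement of stagnant solutions), with the global best carried
across phases.

The package also ships a synthetic low-contrast lesion generator with
ground-truth masks, and an evaluation harness (Otsu-threshold proxy
segmenter, Jaccard/Dice metrics) to quantify the downstream segmentation
effect without any external dataset.

## Worked example

```
$ lesionstretch synth --n 3 --out data --seed 7
wrote 3 image/mask pairs to data

$ lesionstretch enhance data/image_000.png -o enhanced.png --seed 7 --trace trace.csv
best parameters (Pa, Pb, Pg, Pd): [1.6000, 0.2397, 0.8000, 1.0897]
CF original 3.8271 -> enhanced 5.4290 (1847 evaluations)
wrote enhanced.png
```

The optimizer raised the quality objective of this image from 3.83 to 5.43
using 1847 objective evaluations (population 20, 30 bat + 30 colony
iterations); the chosen parameter set applies a gain of about
1.09·μ/(Υσ+0.24), subtracts 80 % of the local mean, and restores local
brightness via Υμ^1.6. `trace.csv` logs the best CF after every iteration,
tagged by phase (`bat` rows then `abc` rows); the trace is non-decreasing
because the global best is retained greedily across both phases.

Batch mode (`lesionstretch enhance <dir>`) processes a directory and
writes a `results.csv` with the per-image parameters and CF values, and
`lesionstretch evaluate --dataset data --out scores.csv` scores the proxy
segmenter on raw versus enhanced images against the ground-truth masks.

The same functionality is available as a library:

```python
from lesionstretch import SyntheticLesionSpec, generate_lesion, enhance_image

sample = generate_lesion(SyntheticLesionSpec(seed=7))
result = enhance_image(sample.image, seed=7)
print(result.best_params, result.cf_original, result.cf_enhanced)
```

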