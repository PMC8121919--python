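# snowmorph

Objective classification of marine snow images into functional
morphotypes, with the particle-export metrics that make the
classification ecologically useful.

Marine snow — the large (>500 µm) composite detrital particles that
carry most of the ocean's vertical carbon export — is imaged in situ by
profiling cameras such as the Underwater Vision Profiler (UVP), which
stores a cut-out greyscale *vignette* of every detected object. Beyond
size, the morphology of these particles (shape, darkness, structural
heterogeneity) carries information about their origin and fate, but has
rarely been quantified. `snowmorph` implements a simple, reproducible
morphotyping pipeline for such vignettes, aimed at particle-flux and
bloom-dynamics studies:

1. **Descriptors** — each vignette is reduced to 24 morphological
   descriptors in four groups: size (area, perimeter, ESD, axes, convex
   area), grey intensity (mean/median/min/max/integrated grey,
   darkness), shape (elongation, circularity, eccentricity, axis
   symmetries, solidity) and structure (grey st.dev./skewness/kurtosis,
   grey range, perimeter/area, boundary index).
2. **Morphospace** — after trimming the 0.1 % most extreme values of
   each descriptor and log-transforming the right-skewed ones, a PCA on
   the correlation structure positions every object by its first 4
   principal coordinates.
3. **Morphotypes** — k-means (k = 5) on the PCA coordinates partitions
   objects into five functional morphotypes, named by deterministic
   rules on cluster medians: *dark* (small, dark, compact), *elongated*,
   *flake* (small, bright, smooth), *fluffy* (medium, bright,
   heterogeneous) and *agglomerated* (large, multielement).
   Classifications from different training sets are compared with
   percent agreement and Cohen's κ after Hungarian label alignment.
4. **Ecology** — morphotyped objects are binned into 5-m concentration
   profiles (ind L⁻¹ = count / sampled volume) from which the package
   derives the slope of the normalized size spectrum
   (ln *n* = ln *a* + *b* ln *d*), the Martin-type attenuation exponent
   (*n_z* = *n*₁₀₀ (z/100)^b), Shannon–Wiener morphotype diversity
   (H = −Σ pᵢ ln pᵢ), and bulk sinking speeds from the deepening of
   concentration peaks through time (type-I regression of peak time on
   peak depth; speed = 1/slope).

A synthetic-data module generates vignettes of the five archetypes and
depth–time concentration fields with known sinking speeds, attenuation
exponents and spectrum slopes, so the whole pipeline is testable
without field data.

## Worked example

```python
import numpy as np, pandas as pd
import snowmorph as sm

vignettes, truth = sm.generate_population([0.2]*5, 1000, seed=11)
features = sm.feature_table(vignettes, threshold=245).table
config = sm.PipelineConfig(pixel_size_mm=0.088, seed=1)
result = sm.run_pipeline(config, features=features)

print("explained variance (4 PCs):",
      np.round(result.morphospace.explained_variance_ratio, 3),
      "->", f"{result.morphospace.explained_variance_ratio.sum():.1%}")
print(result.labels.value_counts().sort_index().to_string())
acc = (result.labels == pd.Series(truth, index=features.index)).mean()
print(f"agreement with generator truth: {acc:.1%}")
print(features.groupby(result.labels)["perimeter"].median().sort_values())
```

prints

```
explained variance (4 PCs): [0.425 0.23  0.163 0.063] -> 88.2%
morphotype
agglomerated    182
dark            208
elongated       219
flake           199
fluffy          192
agreement with generator truth: 100.0%
morphotype
flake            44.0
dark             52.0
fluffy           66.0
elongated        76.0
agglomerated    177.0
```

The first four principal components summarise ~88 % of the descriptor
variance; k-means recovers the five generating archetypes, and the
named clusters reproduce the characteristic perimeter ranking (flake
and dark small, fluffy and elongated intermediate, agglomerated much
larger). `result.profiles` and `result.metrics` (produced when
per-object depths/volumes are supplied) hold the binned concentrations
and the attenuation/diversity metrics per morphotype and time.

A command-line interface mirrors the library:
`snowmorph simulate vignettes`, `extract`, `fit-morphospace`, `assign`,
`profile`, `metrics`, `crossval` — run `snowmorph --help`.

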