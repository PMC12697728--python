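# layerprint

Tools for asking *where in the brain each layer of a convolutional network
lives* — and for building the stimuli that make that question answerable.

When people view natural images, the representational similarity matrices
(RSMs) of successive CNN layers are strongly correlated with one another, so
regressing brain activity on any one layer's RSM tends to light up the same
cortex as every other layer. `layerprint` implements two complementary
remedies and the full searchlight analysis suite around them:

1. **Stimulus synthesis.** Starting from random noise, an image set is
   optimized by gradient descent so that the layer-wise RSMs become mutually
   decorrelated. For `L` layers, each image set induces first-order RSMs
   `C_1 … C_L`; vectorizing each strict upper triangle and correlating the
   vectors gives the second-order matrix `R` with entries
   `R_ij = corr(vec(C_i), vec(C_j))`. The synthesis objective is the
   off-diagonal sum of squares `Σ_{i≠j} R_ij²`, driven to zero through the
   network's input gradients (a diversification phase first pushes each
   image to maximize a distinct feature channel so the RSMs have structure
   worth decorrelating).
2. **Residual method.** For natural images, a layer's *unique*
   representational contribution is isolated by regressing each searchlight
   RSM triangle on the other `L−1` layers' triangles and fitting the
   held-out layer to the residuals.

The analysis suite operates on per-image voxelwise GLM beta maps:

- **Representational stability**: per 7×7×7 searchlight, the mean
  correlation of same-image patterns across runs (448 pairings at 16 images
  × 8 runs) is z-scored against repeatedly subsampled means of the 6,720
  between-image pairings.
- **Layer mapping**: leave-one-participant-out regression of searchlight
  RSM triangles on a layer's RSM triangle, scored by out-of-sample R², and
  z-normalized against a 500-permutation triangle-shuffle null.
- **Group inference**: one-sample t per searchlight with family-wise
  sign-flip max-statistic correction.
- **Overlap**: the asymmetric matrix of significant-voxel sharing ratios
  `|M∩N|/|M|` between layer maps, with bootstrap comparison of mean overlap
  across image regimes.

Because scanner data is not required to develop or validate any of this, the
package ships a ground-truth simulator: designated regions of a synthetic
brain carry the representational geometry of designated layers (multivariate
normal voxel patterns whose covariance equals the target RSM), so every
statistic can be checked against a known answer.

Any convolutional network can be plugged in through a small adapter contract
(named layers, flattened activations, pixel-gradient pullback). A seeded
NumPy CNN with exact hand-written gradients is built in and used throughout
the tests; a GoogLeNet (Inception-V1) adapter exposing the first three
convolutional layers and all nine inception-block outputs is available when
PyTorch/torchvision are installed.

## Worked example

```python
import numpy as np
from layerprint import (SmallCNNAdapter, SynthesisConfig, init_noise,
                        diversify_phase, orthogonalize_phase,
                        orthogonality_cost, mean_offdiagonal, count_pairings)

adapter = SmallCNNAdapter.seeded(0, input_size=64)
config = SynthesisConfig(n_images=8, image_size=(64, 64),
                         phase1_iters=200, phase2_iters=200,
                         step_size=0.05, seed=11, target_layer="conv3")
stimuli = diversify_phase(init_noise(config), adapter, config)
trace = orthogonalize_phase(stimuli, adapter, config)
print("initial cost:", round(orthogonality_cost(trace.initial_som), 4))
print("final cost:  ", round(orthogonality_cost(trace.final_som), 10))
print("mean off-diagonal correlation:",
      round(mean_offdiagonal(trace.initial_som), 4), "->",
      round(mean_offdiagonal(trace.final_som), 10))
print("within/between pairings (16 images, 8 runs):", count_pairings(16, 8))
```

prints

```
initial cost: 1.3309
final cost:   0.0
mean off-diagonal correlation: 0.457 -> -0.0
within/between pairings (16 images, 8 runs): (448, 6720)
```

Noise images evoke layer RSMs whose pairwise second-order correlations
average 0.46 on this network; two hundred joint gradient steps drive the
off-diagonal sum of squares to numerical zero, i.e. the three layers'
representational geometries become fully decorrelated. The pairing counts
are the combinatorics behind the stability statistic: `C(8,2)·16 = 448`
same-image comparisons versus `C(8,2)·16·15 = 6720` different-image
comparisons.

## Command line

The `layerprint` entry point chains the stages from one YAML config
(`synth`, `design`, `simulate`, `stability`, `map`, `residual`, `overlap`,
and `demo` for the whole desk-scale workflow):

```sh
layerprint demo --config config.yaml --seed 1 --out out/
```

Every run writes a `manifest.json` (inputs, outputs, derived seeds, package
version, per-stage wall time) sufficient to reproduce each numeric output
byte-for-byte on one platform. Volumetric outputs are NIfTI, tables CSV,
images PNG plus a lossless float sidecar.

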