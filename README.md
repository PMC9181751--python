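# choroidnet

Segmentation-free ("direct") estimation of choroidal thickness from OCT
B-scans with a patch-based CNN regressor.

The choroid — the vascular layer between retina and sclera — changes
thickness with disease (central serous chorioretinopathy, Vogt–Koyanagi–
Harada, myopic maculopathy), and measuring it normally requires delineating
its two boundaries, Bruch's membrane (BM) and the choroid–sclera interface
(CSI), on every B-scan. Segmentation-based pipelines inherit every boundary
error. `choroidnet` instead regresses mean thickness directly from pixels:

1. **Crop.** A B-scan of height N and width M is divided into K equal-width
   segments (patch width m = M/K). Within each segment an n × m window
   slides from top to bottom with a fixed stride (default 10 px) and the
   placement with maximal summed intensity wins — this lands the window on
   the bright retina/choroid complex and excludes dark vitreous. Adjacent
   patches never overlap.
2. **Regress.** A 7-convolution CNN (3 × 3 kernels, ReLU after every conv,
   2 × 2 max-pool after every second conv, one fully connected head) maps
   each patch x_s to a thickness estimate R_θ(x_s), trained with the MAE
   loss φ(R_θ(x_s), y_s) = |R_θ(x_s) − y_s| under SGD with momentum 0.9,
   weight decay 5·10⁻⁴ and a piecewise learning-rate schedule
   (0.002 → 0.0002 → 0.00002 at epochs 12 and 28; 41 epochs, batch 15).
3. **Average.** The B-scan estimate is the mean of its K patch estimates.
   Because the patches are equal-width and disjoint, the ground-truth
   B-scan label equals the full-width column mean of CSI − BM, and the mean
   signed error (ME) is identical at patch and B-scan level while the MAE
   can only shrink by averaging.

Evaluation reports MAE and ME (± SD of the per-sample errors), the Pearson
correlation coefficient between estimates and ground truth, and the
fraction of samples with absolute error ≤ 5, (5, 10], (10, 15] and > 15
pixels, at both levels.

Clinical OCT volumes cannot be redistributed, so the package ships a
**phantom generator**: layered B-scans with a dark vitreous, a bright BM
line, a speckled choroidal band of known per-column thickness and a dimmer
sclera. Boundaries are generated first and the raster rendered from them,
so ground truth is exact and the whole pipeline — cropping, training,
evaluation — runs end to end offline.

## Worked example

```python
import numpy as np
from choroidnet import (PhantomConfig, CropConfig, TrainConfig,
                        ChoroidThicknessModel, assemble_patches,
                        generate_dataset)

cfg = PhantomConfig(height=128, width=256, channels=1,
                    thickness_range=(20, 100), bm_depth_range=(8, 16),
                    boundary_amplitude=3.0, speckle_sigma=0.02,
                    vessel_contrast=0.05)
crop = CropConfig(k_segments=4, patch_height=64, vertical_stride=10)
samples = assemble_patches(generate_dataset(cfg, 75, 1, seed=11), crop)

model = ChoroidThicknessModel(samples[:240], samples[240:])
results = model.fit(TrainConfig(epochs=10, seed=5), seed=5)
print(results.summary())
```

```
Choroidal thickness CNN regression
==================================================
input patch:      64 x 64 x 1
conv channels:    [16, 16, 32, 32, 64, 64, 64]
parameters:       112,817
epochs trained:   10 (batch size 15)
final train MAE:  7.3923 px
final val MAE:    8.5204 px
best val MAE:     7.0407 px (epoch 7)
==================================================
```

The 60 held-out patches have label SD ≈ 24 px, so a constant predictor
would score ≈ 21 px MAE; the fitted regressor reaches 8.5 px after ten
epochs — it has learned thickness structure, not just the cohort mean.
`results.evaluate(test_patches, patches_per_bscan=4)` then returns the
patch-level and B-scan-level reports (MAE/ME ± SD, PCC, error-interval
fractions), and `choroidnet.scatter_export` writes the agreement
scatterplot data.

The same workflow is scriptable from the shell:

```sh
choroidnet generate --config cfg.yaml --out data/
choroidnet train    --config cfg.yaml --manifest data/manifest.csv --out run/
choroidnet evaluate --checkpoint run/checkpoint.npz \
                    --manifest data/manifest.csv --config cfg.yaml --out eval/
```

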