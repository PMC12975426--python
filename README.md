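# spinegraph

Anatomy-aware two-stage parsing of the spine from volumetric T2-weighted MR
images: every vertebra and every intervertebral disc (IVD) receives its own
label.  For the default thoraco-lumbo-sacral field of view T9…S1 that is 19
structures — 10 vertebral bodies interleaved with 9 discs.

The package is aimed at researchers in medical image analysis who want a
CPU-trainable, fully inspectable implementation of graph-based semantic
segmentation for chain-structured anatomy, together with a synthetic
phantom generator so that every component can be exercised without any
clinical data.

## The model

Plain voxelwise CNNs treat neighbouring vertebrae and discs as independent
classes and confuse them freely.  Here the spine is modeled as a **graph**:
structures are nodes, and edges connect physically contiguous structures
(vertebra ↔ adjacent disc), so the full schema is a path graph with 18
edges.  Graph convolution uses the self-loop-augmented, symmetrically
normalized propagation matrix

```
Â = D^(-1/2) (A + I) D^(-1/2),     H' = σ(Â H W)
```

Stage 1 — the **3D graph-convolutional segmentation network (GCSN)** — is a
residual encoder–decoder over a downsampled volume.  At its bottleneck a
softmax head predicts a soft assignment of voxels to structures; **region
pooling** condenses the dense features into one vector per structure
(`h_k = Σ_v p_kv f_v / Σ_v p_kv`), a stack of graph-convolution layers
propagates information along the vertebra–disc chain, **region unpooling**
redistributes the node features to voxels, and a residual projection fuses
them back into the CNN stream.  Disabling this semantic block yields the
ResUNet ablation — identical in every other parameter.

Stage 2 upsamples the coarse probability maps, fuses each high-resolution
2D slice with its probability slices, and refines boundaries with a 2D
residual network.  Training minimizes soft Dice + cross-entropy with deep
supervision.

Evaluation reports per-structure Dice (DSC), precision and recall, grouped
over vertebrae / IVDs / all structures, plus paired t-tests between
methods.

## Worked example

```python
import numpy as np
import spinegraph as sg
from spinegraph.estimators import CoarseSpineSegmenter
from spinegraph.pipeline import preprocess_pair

cfg = sg.PreprocessConfig.phantom_scale()         # 48x96x48 phantom grid
pairs = [preprocess_pair(*sg.generate_phantom(sg.PhantomSpec(), seed=s), cfg)
         for s in np.random.SeedSequence(42).spawn(4)]
X, y = [p[0] for p in pairs], [p[1] for p in pairs]

est = CoarseSpineSegmenter(base_channels=8, iterations=300, random_state=0)
est.fit(X, y)
print(round(est.score(X, y), 4))
```

This trains the coarse GCSN on four synthetic phantoms and prints the mean
per-structure Dice on the training subjects:

```
0.9927
```

i.e. after 300 iterations the network reproduces ≈ 99 % of every present
structure's voxels on the subjects it was fitted to.  Held-out performance
on fresh phantoms is lower (≈ 0.6–0.8 depending on the split) and is what
the ablation comparison in `scripts/acceptance.py` measures.

A command-line interface mirrors the library:

```bash
spinegraph simulate --n 16 --seed 7 --out cohort/
spinegraph train-coarse --in preprocessed/ --seed 0 --out gcsn.ckpt
spinegraph infer --image sub-000_img.nii.gz --coarse-ckpt gcsn.ckpt --out sub-000_seg.nii.gz
spinegraph evaluate --pred predictions/ --gt cohort/ --out report.csv
```

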