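# lddscp

A compact directional texture descriptor for grayscale image classification,
with the comparison baselines, evaluation protocol and noise-robustness
harness needed to study it end to end — all testable on synthetic imagery.

## The descriptor

Local texture descriptors of the LBP family summarise an image by histograms
of small per-pixel binary codes. The descriptor implemented here codes the
*dominant local direction* instead of raw gray-value differences. The eight
3×3 Kirsch compass masks (weights +5/−3, zero sum; 0° = East, rotating
counter-clockwise in 45° steps) are split into two symmetric groups by
direction — group 1 probes {0°, 45°, 90°, 135°}, group 2 probes
{180°, 225°, 270°, 315°}. At every pixel each group yields four mask
responses `M_ji`, and each group is coded by comparing its responses with
the group mean:

```
code_j = Σ_{i=0..3} S(M_ji − mean_i M_ji) · 2^i ,   S(x) = 1 if x ≥ 0 else 0
```

A set bit marks a direction whose response exceeds the group's average
strength — a *dominant* direction. The words `0000` and `1111` name no
dominant direction and are excluded, leaving `2⁴ − 2 = 14` informative
codes per group (a 94.53 % per-block bin reduction against the 256-bin
basic LBP). Because the responses are compared only with their own mean,
the codes are exactly invariant under affine intensity maps `a·I + b`
(`a > 0`), and small perturbations that flip an LBP bit are absorbed
whenever they stay below the group-mean margin.

The whole-image feature partitions the coded maps into an `N×N` block grid
(default `8×8`; 16×16-pixel blocks at the 128×128 working resolution),
takes each block's two 14-bin histograms, and *stacks* them (element-wise
sum, 14 dims/block — default) or *concatenates* them (28 dims/block). With
the defaults the feature has `64 × 14 = 896` dimensions.

Also included: basic LBP (256 bins/block), centre-symmetric CS-LBP (16
bins/block) and LDP (top-3 |Kirsch response| coding, 256 bins/block)
baselines; leave-one-sample-out KNN evaluation with Euclidean and χ²
histogram distances; inverse-square-distance class-membership profiles
`Ra_i = (1/d_i²)/Σ_j(1/d_j²)`; salt-and-pepper and AWGN corruption with
accuracy-vs-noise sweeps; and a seeded synthetic generator of oriented
sawtooth gratings, crossed gratings and isotropic fields.

## Worked example

```python
import numpy as np
from lddscp import (LabeledFeatures, class_centers, evaluate_dataset,
                    expression_components, extract_matrix, make_dataset)

ds = make_dataset(seed=0)                 # 6 classes x 10 textures, 128x128
feats = extract_matrix(ds.images, "lddscp")
print(feats.shape)                        # (60, 896)

result = evaluate_dataset(ds.images, ds.labels, "lddscp", k=1)
print(result.accuracy)                    # 1.0

data = LabeledFeatures(features=feats, labels=np.asarray(ds.labels))
ra = expression_components(feats[0], class_centers(data))
print((100 * ra).round(2))
```

The feature matrix has one 896-dimensional row of histogram counts per
image. Leave-one-sample-out 1-NN classifies all 60 synthetic textures
correctly (accuracy `1.0`). The membership profile of the first sample
(true class 0, a 0°-oriented grating) concentrates on its own class and
sums to one:

```
0    92.54
1     0.04
2     0.05
3     6.96
4     0.09
5     0.32
```

The same workflow runs from the shell:

```sh
lddscp synth --out data/ --classes 6 --per-class 10 --seed 0
lddscp extract --data data/ --out features.tsv --descriptor lddscp
lddscp evaluate --features features.tsv --k 1 --metric euclidean
lddscp noise-sweep --data data/ --out sweep.tsv --noise sp --levels 0,0.05,0.1,0.2
```

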