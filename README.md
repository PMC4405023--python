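# fsafcm — fast self-adaptive fuzzy C-means segmentation of pulmonary nodules

Pulmonary nodules on chest CT are the most common early sign of lung cancer,
and computer-aided diagnosis needs them segmented quickly and without manual
tuning.  Plain fuzzy C-means (FCM) clusters pixels by gray level alone, so it
fails exactly where nodules are hard: vessels adhering to the nodule at the
same gray level, ground-glass opacities (GGO) at low contrast, smooth
transitions into the pleural wall, and impulse noise.  The classical
spatially regularized variants (FCM_S, EnFCM, FGFCM, FLICM) fix some of this
with a *fixed* neighborhood-strength constant α that cannot adapt across an
image.

This package implements a **self-adaptive** spatially regularized FCM in
which the neighborhood weight is set per pixel from the image's own
statistics, plus the five classical baselines, a lung-parenchyma
preprocessing stage, a synthetic nodule-phantom generator and
segmentation-error evaluation — as a tested library with a thin CLI.

## The model

Each pixel `x_j` is described by the pair `[f(x_j), g(x_j)]` — its gray level
and the mean of its `(2r+1)×(2r+1)` window — and `p_j` is the empirical
frequency of that pair over the image (a 2D histogram).  On top of the
classical FCM memberships

```
μ_ij = 1 / Σ_k (|x_j − v_i| / |x_j − v_k|)^(2/(m−1))
```

each iteration fuses in a spatial function accumulated over the window:

```
λ_j  = p_j · Σ_r (f(x_r) − g(x_j))² / (2r+1)²      per-pixel adaptive factor
ω_r  = exp(−(x_j − x_r)² · λ_j)                    gray-affinity weight
h_ij = Σ_r (μ_ir + ω_r)                            spatial function
μ′_ij = μ_ij^p · h_ij^q / Σ_k μ_kj^p · h_kj^q      fused membership (p=1, q=2)
v_i  = Σ_j μ′_ij^m (x_j + g_j) / (2 Σ_j μ′_ij^m)   center update
```

Smooth tissue has `λ_j ≈ 0` (all ω = 1); edges and rare impulse pixels get a
large `λ_j` that shrinks their own weight while the neighbor-consensus term
pulls them toward the cluster of their surroundings.  The loop stops when the
centers move less than ε = 0.001 (or after 100 iterations); the cluster with
the brighter center is the nodule foreground.  The net effect is fewer
iterations than plain FCM and strong robustness to salt-and-pepper noise,
with no per-image tuning.

## Worked example

Segment a vessel-adhesion phantom (a bright disk with a same-intensity tube
attached) corrupted by 5% salt-and-pepper noise, and compare with plain FCM:

```python
import numpy as np
from fsafcm import (FsafcmConfig, BaselineConfig, baseline_segment, fsafcm_segment,
                    make_phantom, add_salt_pepper, misclassification, error_rate)

phantom = make_phantom("vessel_adhesion", size=96, radius=12, seed=7)
noisy = add_salt_pepper(phantom.image, density=0.05, seed=8)

result = fsafcm_segment(noisy, FsafcmConfig(seed=1))
reference = baseline_segment(noisy, BaselineConfig(algorithm="fcm", seed=1))

print(f"centers:            {np.sort(result.centers).round(2)}")
print(f"iterations:         {result.iterations_run} (plain FCM: {reference.iterations_run})")
mis = misclassification(result.foreground_mask, phantom.truth_mask)
mis_ref = misclassification(reference.foreground_mask, phantom.truth_mask)
print(f"misclassification:  {100*mis:.2f}% (plain FCM: {100*mis_ref:.2f}%)")
rep = error_rate(result.foreground_mask, phantom.truth_mask)
print(f"area error rate:    {rep.rate_percent:+.1f}% ({rep.direction}segmentation)")
```

prints

```
centers:            [ 44.98 155.9 ]
iterations:         9 (plain FCM: 14)
misclassification:  2.16% (plain FCM: 4.44%)
area error rate:    -44.2% (oversegmentation)
```

The two centers recover the parenchyma background (~45) and the bright
tissue (~156, the nodule/vessel level pulled down by rim smoothing and
noise).  The method converges in 9 iterations against 14 for plain FCM and
halves the pixel misclassification; the negative signed error rate says the
segmented area is larger than the true nodule — here because the adhered
vessel shares the nodule's gray level and is picked up with it.

The same pipeline runs from the shell:

```
fsafcm phantom --kind vessel_adhesion --size 96 --seed 7 --out img.png --truth-out truth.png
fsafcm segment --input img.png --output labels.png --mask-out mask.png --seed 1
fsafcm compare --input img.png --truth truth.png --algorithms fcm,fcm_s,enfcm,fgfcm,flicm,fsafcm --report report.csv
fsafcm preprocess --input slice.png --mask-out parenchyma.png --image-out masked.png
```

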