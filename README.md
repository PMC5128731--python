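# lungtrace

Automatic segmentation of the pulmonary parenchyma in thoracic CT, built
around explicit contour geometry rather than region machinery, with a
dedicated correction step for **juxta-pleural nodules** — nodules attached to
the pleural wall whose soft-tissue density makes plain thresholding exclude
them from the lung, leaving a concave bite in the lung border.

The pipeline processes each axial slice in sequence:

1. **Alignment.** The in-plane tilt φ of the scan is estimated as the angle
   between the first principal component μ of the bone-pixel (x, y) cloud and
   the positive x-axis, φ = arctan(μ_y / μ_x); the slice is rotated back only
   when |φ| leaves the ±15° gate, since a mild tilt does not disturb the
   diagonal search below.
2. **Chest mask.** Otsu thresholding, morphological opening, largest
   8-connected component, hole filling.
3. **Contour initialization.** The slice is re-binarized inside the chest
   (lung air = 0). Scanning the major diagonal, the first run of three
   consecutive 0s after chest tissue marks the entry into the image-left
   lung; the minor diagonal finds the right lung. From each entry point the
   border is walked by Moore (8-neighborhood) tracing, stopped when the last
   two points repeat the first two.
4. **Separation.** When both lungs form one component, iterative erosion with
   the diamond B₄ (S = A ⊖ nB₄) splits them and constrained dilation
   (Cⁱ⁺¹ = Cⁱ ∪ p ⊕ B₄, p ∈ A, component count preserved) rebuilds the
   borders, leaving a one-pixel cut; if erosion cannot split, the mask is cut
   along the maximum-cost top-to-bottom intensity path (dynamic programming)
   inside a central column band.
5. **Smoothing.** The contour is resampled by a periodic cubic spline at
   uniform arc-length step L = 0.3 px and each point is replaced by a local
   least-squares polynomial fit x(s), y(s) of degree n = 2 over its 2k + 1 =
   9 neighbors, repeated for up to M = 12 passes or until the perimeter
   change falls below T₂ = 0.01.
6. **Concave correction.** A march with the right-hand rule over the
   clockwise contour finds every concave region, measuring the bridging
   chord width W and maximum depth H; regions with η = H / W above a
   threshold T₁ are replaced by the straight chord, re-including the nodule.
   The detect/replace cycle repeats until the perimeter converges.

A synthetic **chest phantom** generator (elliptical body, two elliptical
lungs, bone blobs for the alignment PCA, optional tilt, noise, fused-lung
bridge and disk-shaped juxta-pleural nodules of 6–17 mm) provides exact
ground-truth masks, so every stage is testable without any scan data. A
**metrics** module computes the standard seven-number evaluation: VD, RVD,
VOE, ASD, RMSD, MSD and the over/under-segmentation call from the sign of
RVD.

## Worked example

```python
import numpy as np
from lungtrace import phantom, segment_slice, dice

spec = phantom.default_spec(
    nodules=(phantom.Nodule(lung=0, angle_deg=170, diameter_mm=12.0),),
    noise_sd=20.0, seed=5,
)
out = phantom.generate_phantom(spec)          # image + exact truth masks
res = segment_slice(out.image)                # full per-slice pipeline

pre  = dice(res.pre_correction_mask, out.truth_lung_mask)
post = dice(res.lung_mask,           out.truth_lung_mask)
nod  = out.truth_lung_mask & ~out.truth_parenchyma_mask
print(f"dice before correction: {pre:.4f}")
print(f"dice after  correction: {post:.4f}")
print(f"nodule area recovered:  {100 * (res.lung_mask & nod).sum() / nod.sum():.1f}%")
print(f"concave regions bridged: {res.log.n_concaves_corrected}")
```

prints

```
dice before correction: 0.9772
dice after  correction: 0.9862
nodule area recovered:  98.3%
concave regions bridged: 1
```

The smoothed-only mask misses the 12 mm nodule entirely (it is excluded by
thresholding); the concave correction bridges the notch and recovers 98% of
the nodule disk, raising the whole-lung Dice accordingly.

The same pipeline is available from the shell:

```bash
lungtrace phantom --out /tmp/ph --slices 20 --seed 1
lungtrace segment --input /tmp/ph_image.nii.gz --output /tmp/seg.nii.gz
lungtrace evaluate --auto /tmp/seg.nii.gz --manual /tmp/ph_truth_lung.nii.gz
lungtrace dump-config        # all stage parameters as YAML
```

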