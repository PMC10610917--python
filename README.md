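# pfseg — plantar-foot segmentation for cold-stressed active thermography

Active (cold-stressed) infrared thermography images the plantar feet while
they rewarm after a cold immersion, at ~1 Hz for 10–15 minutes.  The
resulting sequences are diagnostically rich — pathological regions of a
diabetic foot rewarm differently — but hard to segment: early frames have
almost no foot/background contrast, late frames have a great deal, and a
single fixed preprocessing cannot serve both.  `pfseg` implements a complete
segmentation pipeline for such single-channel radiometric sequences:

1. **Radiometric calibration.**  Two black-body references at known set
   points (28 °C / 36 °C) in the field of view anchor an affine
   count-to-temperature map per frame; a fixed 10 °C temperature window then
   maps temperatures linearly onto gray values in [0, 1], and the
   calibration targets are cropped away.

2. **Two-stage adaptive gamma transform.**  Per image, the empirical CDF
   yields the median x₀ and upper quartile x₁; the contrast ratio
   β = (x₁ − x₀)/x₀ selects one of two reciprocal exponent laws:

   for β ≤ 1: γ = 0.5 + x₀ (x₀ ≤ 0.5), γ = 1/(1.5 − x₀) (x₀ > 0.5);
   for β > 1: the pointwise reciprocal of the above.

   The enhanced image is V_out = V_in^γ.  Both branches meet at γ = 1 when
   x₀ = 0.5, so ordinary mid-keyed images pass through unchanged.

3. **PFSNet**, an attention-gated nested residual-U segmentation network: a
   GoogLeNet-style input stem (7×7/2 convolution + 3×3/2 max pool), five
   encoder stages of residual U-blocks (RSU-L; the deepest stage is the
   dilated RSU-4F variant whose internal maps keep full resolution),
   UNet++-style nested dense skip nodes with a CBAM (channel + spatial)
   attention gate at every fusion point, and multi-side-output fusion (MSOF)
   producing eleven sigmoid saliency maps Y^(i,j) — nine side heads plus the
   fusions Y^(0,5), Y^(5,0) and the final Y^(5,5).

4. **Deep-supervision loss and metrics.**  Training minimizes
   L = Σₘ w_side^(m) e_side^(m) + w_fuse e_fuse with per-map binary
   cross-entropy e = −Σ_(r,c)[P_G log P_S + (1−P_G) log(1−P_S)].
   Evaluation reports Dice (DSC), IoU, and boundary Hausdorff distance
   (raw pixels, plus a normalized 1 − HD/diag convenience score), and the
   enhancement harness reports 256-bin entropy, MSE and PSNR.

No public dataset of cold-stressed plantar thermograms exists, so the
package ships a seeded **phantom generator**: mirror-symmetric foot
silhouettes rewarming exponentially from 18 °C toward 36 °C over a constant
22 °C background, sensor noise at the NETD scale (40 mK), embedded
black-body patches, and optional non-uniform cooling blobs.  Every stage of
the pipeline is exercised end-to-end on these phantoms.

The network and its training loop run on a compact numpy-based reverse-mode
autodiff engine included in the package (`pfseg.autograd`), so there is no
deep-learning-framework dependency; desk-scale configurations
(`NetworkConfig.scaled`) train in minutes on one CPU.

## Worked example

```python
import numpy as np
from pfseg import PhantomConfig, simulate_recovery, enhance_two_stage
from pfseg.synthdata import sample_frames
from pfseg.loss_metrics import entropy

seq = simulate_recovery(PhantomConfig(seed=1, frames=600))
images, masks, idx = sample_frames(seq, stride=10)   # one frame in ten
for k in (16, 59):                                   # a dark and a late frame
    img = images[k]
    out, p = enhance_two_stage(img)
    print(f"frame {idx[k]:3d}: x0={p.x0:.4f} x1={p.x1:.4f} beta={p.beta:.3g} "
          f"gamma={p.gamma:.3f} entropy {entropy(img.values):.3f} -> "
          f"{entropy(out.values):.3f} bits")
```

prints

```
frame 160: x0=0.0039 x1=0.1602 beta=40 gamma=1.984 entropy 1.893 -> 1.483 bits
frame 590: x0=0.0039 x1=0.8320 beta=212 gamma=1.984 entropy 1.587 -> 1.800 bits
```

Frame 160 is an early, low-contrast frame (feet just inside the temperature
window): the transform selects the β > 1 regime, compresses the almost-empty
dark histogram and lowers its entropy by 0.41 bits.  Frame 590 is a late,
high-contrast frame whose bright feet keep the same regime but a very
different quartile spread.

A complete desk-scale run — phantom generation, enhancement, 300 SGD steps
(momentum 0.9, weight decay 1e-4) of a 1/8-width network at 64×64, and
evaluation — is one call:

```python
from pfseg.pipeline import demo_run
r = demo_run(seed=1, stage="mixed")
print(r["train_dsc"])   # 0.9646...
```

## Command line

```bash
pfseg synth --out data/ --subjects 4 --frames 600 --stride 10 --seed 0
pfseg enhance data/train/images --out enhanced/ --method two-stage
pfseg train --data data/ --checkpoint runs/net.npz --batch-size 5 --input-size 64 --width-mult 0.125
pfseg segment data/test/images --checkpoint runs/net.npz --out pred/
pfseg evaluate --pred pred/ --truth data/test/masks
pfseg compare-enhancers data/train/images
```

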