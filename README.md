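# holostain

Lensfree quantitative phase imaging (QPI) reconstruction and GAN-based
virtual histology staining, end to end and fully testable on synthetic
data.

Thin unstained tissue sections are weakly scattering phase objects: they
barely absorb light, but they delay it, and an in-line lensfree
holographic microscope can recover that optical path delay as a
quantitative phase map φ(m,n) (radians). Pathologists, however, read
*stained* brightfield images. `holostain` implements the full
computational chain that bridges the two:

1. **Holographic reconstruction** — angular-spectrum free-space
   propagation; shift-and-add pixel super-resolution fusing 36
   subpixel-shifted sensor frames (1.12 µm Bayer-G1 pitch → 0.37 µm
   effective); Tamura-of-gradient autofocus; multi-height iterative phase
   retrieval from eight holograms recorded 15 µm apart.
2. **Cross-modality registration** — a four-step pipeline (edge-based
   coarse matching, mutual-information similarity alignment, a briefly
   trained rough staining network, block-matching elastic registration)
   that aligns a phase image to the brightfield image of the same tissue
   after staining, to sub-pixel accuracy.
3. **Virtual staining** — a U-net generator G mapping a phase patch to a
   3-channel YCbCr stain patch, trained adversarially against a
   convolutional discriminator D with

       l_D = D(G(x))² + (1 − D(z))²
       l_G = L1{z, G(x)} + λ·TV{G(x)} + α·(1 − D(G(x)))²

   (λ = 0.02, α = 2000, Adam, lr 10⁻⁴/10⁻⁵, an adaptive schedule of
   v = max(5, ⌊7 − w/2⌋) generator steps per discriminator step, and a
   4000-iteration validation-L1 patience rule), plus tiled inference
   that stitches 1792² patches with 7% feathered overlap into a 3456²
   output.
4. **Evaluation** — the 3-channel SSIM and a phase-noise robustness
   protocol that perturbs φ with Gaussian-correlated noise
   δφ = β·(r ⊛ G_L) at fixed phase SNR across kernel widths L.

Since no real tissue data ships with the package, a seeded synthetic
module generates every input the pipeline needs — weak-phase tissue-like
objects, their holograms and PSR frame sets, a deterministic
Beer–Lambert phase→stain forward model (so training has an exactly known
target), and mis-registered pairs with closed-form ground-truth
transforms. The networks run on a small self-contained numpy engine with
hand-written backprop; no GPU or deep-learning framework is required.

## Worked example

```python
import numpy as np
from holostain import synthdata, phase_recovery, stainnet, metrics
from holostain.color import rgb8_to_ycbcr

# simulate: object -> 8 holograms -> recover the phase
cfg = synthdata.SynthConfig(size=256, seed=321)
phi = synthdata.make_phase_object(cfg)                # ground truth, [0,1] rad
stack = synthdata.make_hologram_stack(phi, cfg)       # 8 heights, 15 µm apart
res = phase_recovery.multiheight_recover(stack, n_iter=30)
rec = res.phase - np.mean(res.phase - phi)            # remove global piston
print(f"phase RMSE {np.sqrt(np.mean((rec - phi)**2)):.4f} rad "
      f"after {res.iterations_run} iterations")

# train the desk-scale staining GAN on synthetic pairs
x, y = synthdata.make_gan_patches(600, seed=100)
gen, disc, hist = stainnet.train(x[:500], y[:500], x[500:520], y[500:520],
                                 stainnet.GANConfig.profile("toy", seed=1))

# stain the *recovered* phase and compare with the known target
stained = stainnet.stain_tiled(rec, gen, tile=272, overlap=16,
                               phase_range=(0.0, 1.0))
truth = rgb8_to_ycbcr(synthdata.make_stain_target(phi))
score = metrics.ssim_color(stained, truth, metrics.SSIMConstants(data_range=1.0))
print(f"SSIM vs ground-truth stain: {score:.3f}")
```

Typical output (the training step takes a few CPU minutes):

```
phase RMSE 0.0290 rad after 30 iterations
SSIM vs ground-truth stain: 0.988
```

The first number says multi-height retrieval reproduced the simulated
phase to about 0.03 rad RMS (the weak-phase objects span 1 rad); the
second says the trained generator, fed a *reconstructed* (not
ground-truth) phase image, produced a virtual stain structurally almost
identical to the forward model's true stain.

A command-line interface exposes the same pipeline
(`holostain simulate | reconstruct | psr | register | train | stain |
evaluate`); every run directory is self-describing (resolved config,
seed, provenance JSON).

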