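# wfsan — wavelet-frequency-separation super-resolution for grayscale images

`wfsan` is a lightweight single-image super-resolution tool for 8-bit
grayscale images of the chest-radiograph kind: strong low-frequency
anatomy plus sparse edges.  Instead of mapping a low-resolution (LR)
image directly to a high-resolution (HR) one, it works in the wavelet
domain:

1. the LR image is decomposed with a **1-level 2D stationary (undecimated)
   Haar transform** into four same-sized coefficient planes — approximate
   *A* and details *H*, *V*, *D*.  With the Haar filters this reduces to
   signed half-sums of each 2×2 pixel window (periodic boundaries):

   ```
   A = (a+b+c+d)/2   H = (a+b−c−d)/2   V = (a−b+c−d)/2   D = (a−b−c+d)/2
   ```

2. two **separated convolutional paths** predict the HR coefficients:
   an approximate path (1 channel, ReLU — the A coefficients of a
   non-negative image are non-negative) and a detail path (3 channels,
   Tanh — detail coefficients are signed and sparse).  Both are built
   from **ghost extension blocks**, which produce half their feature
   maps with a dense 3×3 convolution and the other half with a cheap
   depthwise linear map; the detail path's block additionally gates the
   cheap half with a **spatial attention map** σ(f(AvgPool, MaxPool))
   in [0, 1].  Sub-pixel (pixel-shuffle) heads upscale by ×2/×3/×4.

3. the predicted HR sub-bands are merged and the **inverse stationary
   wavelet transform** reconstructs the HR image.

Training minimizes the wavelet-domain L2 loss

```
L = 1/(2N) Σₙ ( ‖HCA − Û_A‖² + ‖HCD − Û_D‖² )
```

with Adam, global-norm gradient clipping and a cosine-decay learning
rate.  By default the network predicts *residual* coefficients on top
of the sub-bands of the bicubic-upscaled LR image, so an untrained
model reproduces bicubic upscaling exactly and training only learns
corrections.

The whole model is small (≈57k parameters at the default 32 filters;
≈4.9k at 8 filters), runs on plain CPU/numpy, and ships with a
synthetic chest-phantom generator so everything is testable without
hospital data.

## Worked example

```python
import numpy as np
from wfsan import (NetworkConfig, TrainConfig, make_dataset,
                   train_model, evaluate_model, evaluate_bicubic)

pairs = make_dataset(25, scale=2, seed=7)[:2000]   # phantom LR/HR 48-px patches
net   = NetworkConfig(scale=2, base_filters=8)     # tiny ×2 model
cfg   = TrainConfig(max_epochs=20, scale=2, seed=1)
model, log = train_model(pairs, net, cfg)

rng = np.random.default_rng(cfg.seed)
order = rng.permutation(len(pairs))
val = [pairs[i] for i in order][len(pairs) - 200:]  # the run's held-out split
print(f"bicubic {evaluate_bicubic(val, 2):.2f} dB")
print(f"wfsan   {evaluate_model(model, val):.2f} dB")
```

On this 20-epoch CPU run the output is

```
bicubic 40.42 dB
wfsan   40.96 dB
```

i.e. the model exceeds plain bicubic upscaling by ≈0.5 dB of PSNR on
held-out phantom patches after ~80 s of training; the per-epoch `log`
carries the learning rate, training loss and validation PSNR.

The same workflow from the shell:

```sh
wfsan synth --n 10 --out-dir phantoms --seed 0         # synthetic images
wfsan train --synthetic 25 --out model.npz --log train.tsv
wfsan sr input.png output.png --ckpt model.npz         # upscale
wfsan eval reference.png output.png                    # MSE / PSNR / SSIM
wfsan stats input.png                                  # per-band SWT statistics
wfsan stats --complexity                               # block parameter/FLOP table
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter choices,
what the phantom generator does and does not emulate, and known
limitations.
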