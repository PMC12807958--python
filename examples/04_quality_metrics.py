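"""Compare reconstructions with SSIM and absolute-difference maps.

Reconstructs one k-space at a low and a high regularization factor and
quantifies what the extra regularization changed: the structural similarity
between the two reconstructions and where the absolute difference lives.
"""

import numpy as np

from csmprage import (AcquisitionParams, abs_difference, apply_sampling_mask,
                      make_bias_field, make_coils, make_phantom,
                      noise_sd_for_target_snr, phyllotaxis_mask,
                      retro_reconstruct, simulate_kspace, ssim3d)

shape = (64, 64, 64)
phantom = make_phantom(shape, n_structures=4, seed=1)
coils = make_coils(shape, 4, seed=2, width=0.35 * 64)
bias = make_bias_field(shape, 0.2, seed=3, brain_mask=phantom.brain_mask())
mask = phyllotaxis_mask(64, 64, R=8, turbo=64, seed=4)
params = AcquisitionParams(matrix=shape,
                           noise_sd=noise_sd_for_target_snr(phantom, 18.0),
                           turbo_factor=64, seed=6)
kspace = apply_sampling_mask(simulate_kspace(phantom, coils, bias, params), mask)

regs = [0.0001, 0.0003, 0.0012]
low, default, high = retro_reconstruct(kspace, mask, coils, regs, tol=0.0,
                                       dtype=np.complex64)
imgs = {rv.lam: rv.volume / bias.field for rv in (low, default, high)}

bm = phantom.brain_mask()
for lam in (0.0003, 0.0012):
    s = ssim3d(imgs[0.0001], imgs[lam]).mean_ssim
    d = abs_difference(imgs[0.0001], imgs[lam])
    print(f"Reg 0.0001 vs {lam:.4f}: SSIM {s:.4f}, "
          f"mean |diff| in brain {d[bm].mean():.4f}")

print("\nAdjacent regularization steps from the same k-space isolate what "
      "the reconstruction added or removed: small SSIM drops and "
      "low-amplitude difference maps mean mostly noise was removed; large "
      "drops mean image structure is being smoothed away.")
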