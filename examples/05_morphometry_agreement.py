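"""Morphometric estimates and their test-retest / between-sequence agreement.

Acquires two repeats of a fully sampled and a CSx8 protocol, estimates
subcortical volumes and regional ribbon thickness from each image, and
computes the agreement statistics used to judge whether an accelerated
protocol can replace the slow reference.
"""

import numpy as np
import pandas as pd

from csmprage import (AcquisitionParams, apply_sampling_mask,
                      between_sequence_r2, cs_recon, estimate_thickness,
                      estimate_volumes, full_mask, make_bias_field,
                      make_coils, make_phantom, noise_sd_for_target_snr,
                      phyllotaxis_mask, repeatability, simulate_kspace,
                      zero_filled_recon)

shape = (96, 96, 96)
phantom = make_phantom(shape, n_structures=5, seed=1)
coils = make_coils(shape, 4, seed=2, width=0.35 * 96)
bias = make_bias_field(shape, 0.2, seed=3, brain_mask=phantom.brain_mask())
noise_sd = noise_sd_for_target_snr(phantom, 18.0)


def acquire(mask, R, noise_seed):
    params = AcquisitionParams(matrix=shape, noise_sd=noise_sd,
                               turbo_factor=64, seed=noise_seed)
    ks = apply_sampling_mask(simulate_kspace(phantom, coils, bias, params), mask)
    if R == 1:
        vol = zero_filled_recon(ks, coils).volume
    else:
        vol = cs_recon(ks, mask, coils, lam=0.0003, tol=0.0,
                       dtype=np.complex64).volume
    img = vol / bias.field
    return pd.concat([estimate_volumes(img, phantom.structures),
                      estimate_thickness(img, phantom)], ignore_index=True)


fm = full_mask(96, 96)
m8 = phyllotaxis_mask(96, 96, 8, turbo=64, seed=21)
ref_1, ref_2 = acquire(fm, 1, 101), acquire(fm, 1, 102)
cs_1, cs_2 = acquire(m8, 8, 201), acquire(m8, 8, 202)

rep = repeatability(cs_1, cs_2)
print("CSx8 within-sequence repeatability (%):")
print(rep[["id", "kind", "repeatability_pct"]].round(2).to_string(index=False))

r2 = between_sequence_r2(ref_1, cs_1)
print("\nBetween-sequence agreement (fully sampled vs CSx8):")
print(r2.round(4).to_string(index=False))

print("\nRepeatability near 100% means repeated accelerated scans give the "
      "same numbers; between-sequence R^2 near 1 means the accelerated "
      "protocol preserves the across-structure ordering measured by the "
      "9-minute reference, which is what morphometric studies rely on.")
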