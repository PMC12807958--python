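"""Build the digital brain phantom and simulate a noisy multi-coil acquisition.

Creates the labeled phantom (WM core, GM ribbon, CSF shell, subcortical
nuclei), coil maps and bias field, then forward-simulates k-space at the
default noise level and reconstructs the fully sampled reference.
"""

import numpy as np

from csmprage import (AcquisitionParams, apply_sampling_mask, full_mask,
                      make_bias_field, make_coils, make_phantom,
                      noise_sd_for_target_snr, simulate_kspace,
                      zero_filled_recon)

shape = (96, 96, 96)
phantom = make_phantom(shape, n_structures=5, seed=1)
coils = make_coils(shape, n_coils=4, seed=2, width=0.35 * 96)
bias = make_bias_field(shape, amplitude=0.2, seed=3,
                       brain_mask=phantom.brain_mask())

print("structure table (ground truth):")
print(phantom.structures[["name", "intensity", "vol_vox", "vol_mm3"]].to_string(index=False))
print("per-region ribbon thickness (mm):", phantom.ribbon_spec["thickness_mm"])

noise_sd = noise_sd_for_target_snr(phantom, target_wm_snr=18.0)
params = AcquisitionParams(matrix=shape, noise_sd=noise_sd, turbo_factor=64, seed=7)
kspace = apply_sampling_mask(simulate_kspace(phantom, coils, bias, params),
                             full_mask(96, 96))
recon = zero_filled_recon(kspace, coils)
img = recon.volume / bias.field  # divide out the known bias field

wm = phantom.tissue_mask(3)
print(f"\nk-space noise sd: {noise_sd:.1f} (per complex component)")
print(f"WM mean intensity in reconstruction: {img[wm].mean():.3f} "
      f"(nominal 1.0); WM mean/sd = {img[wm].mean() / img[wm].std(ddof=1):.1f}")
print("The mean/sd ratio is the measured WM SNR.  It sits below the nominal "
      "target of 18 because the within-tissue texture (5%) adds to the sd "
      "alongside the thermal noise, just as real tissue variation does in "
      "mask-based SNR estimates.")
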