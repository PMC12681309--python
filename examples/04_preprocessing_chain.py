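"""The image-conditioning chain on simulated volumes.

Simulates a noisy phantom acquisition plus a low-resolution transmit (B1+)
map, then runs the conditioning steps a mapping session uses: background
masking, B1+ resampling onto the imaging grid and polynomial smoothing,
nonlocal-means denoising, and the S2 - S3 subtraction image.
"""

import numpy as np

import utemap as u
from utemap.phantom import with_b1_inhomogeneity
from utemap.preprocessing import resample_to_grid, smooth_field_volume

spec = with_b1_inhomogeneity(u.default_t2star_phantom(), amplitude=0.2)
truth = u.render_truth(spec)
_, p2 = u.protocol_pair()
sigma = u.noise_sigma_for_snr(50.0)
scan = u.simulate_scan(truth, p2, noise_sigma=sigma, seed=3)
s2, s3 = scan["echo0"], scan["echo1"]

fg = u.background_mask(s2, rel_threshold=0.1)
print(f"background mask keeps {int(fg.data.sum())} of {s2.data.size} voxels")

# a noisy low-resolution measurement of the smooth B1+ field
rng = np.random.default_rng(4)
low_shape, low_spacing = (24, 24, 8), (64 * 0.8 / 24, 64 * 0.8 / 24, 1.6)
b1_low_true = spec.b1_field.evaluate(low_shape)
b1_low = u.VoxelVolume(b1_low_true + rng.normal(0, 0.02, low_shape), low_spacing)
b1_hi = resample_to_grid(b1_low, s2)
b1_smooth = smooth_field_volume(b1_hi, degree=3)
err_raw = np.abs(b1_hi.data - truth["b1"].data).mean()
err_smooth = np.abs(b1_smooth.data - truth["b1"].data).mean()
print(f"B1+ map error: {err_raw:.4f} resampled only -> {err_smooth:.4f} after "
      "polynomial smoothing (transmit fields are smooth; fitting removes voxel noise)")

den = u.denoise(u.apply_mask(s2, fg), strength=1.0)
tube = truth["label"].data == 1
print(f"tube 1 signal SD: {s2.data[tube].std():.2f} raw -> {den.data[tube].std():.2f} denoised")

sub = u.subtraction_image(s2, s3)
fast = truth["t2star"].data == 1.0
slow = truth["t2star"].data == 20.0
print(
    f"subtraction image S2-S3: mean {sub.data[fast].mean():.1f} in the 1 ms tube vs "
    f"{sub.data[slow].mean():.1f} in the 20 ms tube -> fast-relaxing tissue is bright"
)
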