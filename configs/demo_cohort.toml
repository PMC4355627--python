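# Demo synthetic cohort: 30 control + 30 lesioned volumes at 32^3,
# smoothed-noise backgrounds, 8 interior Gaussian lesions (4 hyper-,
# 4 hypo-intense) of peak amplitude 3x the background SD.
#
#   voxtex simulate --config configs/demo_cohort.toml --seed 1 --out-dir scratch/demo

n_per_group = 30
dims = [32, 32, 32]
smoothing_scale = 2.0   # voxels
mean = 128.0
sd = 24.0

[[lesion]]
center = [8, 8, 8]
sigma = 2.0
support_radius = 4
amplitude = 3.0
sign = 1

[[lesion]]
center = [8, 8, 23]
sigma = 2.0
support_radius = 4
amplitude = 3.0
sign = -1

[[lesion]]
center = [8, 23, 8]
sigma = 2.0
support_radius = 4
amplitude = 3.0
sign = 1

[[lesion]]
center = [8, 23, 23]
sigma = 2.0
support_radius = 4
amplitude = 3.0
sign = -1

[[lesion]]
center = [23, 8, 8]
sigma = 2.0
support_radius = 4
amplitude = 3.0
sign = 1

[[lesion]]
center = [23, 8, 23]
sigma = 2.0
support_radius = 4
amplitude = 3.0
sign = -1

[[lesion]]
center = [23, 23, 8]
sigma = 2.0
support_radius = 4
amplitude = 3.0
sign = 1

[[lesion]]
center = [23, 23, 23]
sigma = 2.0
support_radius = 4
amplitude = 3.0
sign = -1
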