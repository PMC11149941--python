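"""Extract the 215-feature whole-brain radiomics signature of one phantom.

Preprocessing mirrors the clinical chain: scale to the within-brain global
mean, smooth with an isotropic Gaussian, then discretize to 32 gray levels
and compute 79 first-order + 136 texture features.
"""

from petfuse import PhantomConfig, extract_all, generate_control_volume, preprocess_volume

cfg = PhantomConfig(grid_shape=(32, 38, 28), noise_sd=5.0)
volume = preprocess_volume(generate_control_volume(cfg, seed=3), fwhm_mm=8.0)

fv = extract_all(volume)
print(f"extracted {fv.feature_count} features "
      f"(provenance: {fv.provenance['n_bins']} bins, delta={fv.provenance['delta']})")

highlight = [
    "stat_maximum",
    "stat_interquartile_range",
    "ngldm_dependence_count_nonuniformity",
    "ngldm_low_dependence_low_grey_level_emphasis",
]
print("\nThe four features the published selection favored:")
for name in highlight:
    print(f"  {name:<48s} {fv.values[name]:.6g}")
print(
    "\nIntensities are in global-mean units (1.0 = brain average); the NGLDM"
    "\nfeatures summarize how uniformly voxel neighborhoods depend on their"
    "\ncenter gray level."
)
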