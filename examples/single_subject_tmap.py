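"""Compare one demented phantom against a control group voxel by voxel.

Fits y = b0 + b1*group + b2*age at every voxel, thresholds the t-map at
p < 0.01 (hypometabolic tail) and keeps clusters of more than min_size
voxels — the single-subject statistical map used to confirm a dementia
pattern.
"""

from petfuse import (
    PhantomConfig,
    generate_control_volume,
    generate_demented_volume,
    single_subject_tmap,
    threshold_and_cluster,
)

cfg = PhantomConfig(
    grid_shape=(32, 38, 28), noise_sd=2.0, smoothness_mm=4.0, hypometabolism_factor=0.7
)
controls = [generate_control_volume(cfg, seed=i) for i in range(12)]
ages = [55.0 + 2 * i for i in range(12)]
subject = generate_demented_volume(cfg, ["frontal", "temporal_left"], seed=99)

tmap = single_subject_tmap(subject, controls, subject_age=71.0, control_ages=ages)
clusters = threshold_and_cluster(tmap, p_threshold=0.01, min_size=25, tail="hypo")

print(f"degrees of freedom: {tmap.df}, covariates: {tmap.covariates_used}")
print(f"t critical (p<0.01, one-tailed): -{clusters.t_critical:.3f}")
print(clusters.to_table().to_string(index=False))
print(
    "\nEach row is a supra-threshold hypometabolic cluster larger than 25 voxels;"
    "\npeak_t is the most extreme t-score and x,y,z its voxel coordinate."
)
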