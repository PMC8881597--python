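"""Type-I error check: the permutation test on cohorts with no effect.

Simulates null cohorts (effect size d = 0) and verifies that the group
permutation p-value rejects at roughly its nominal rate — the pipeline
leaks no label information through its plumbing.
"""

import numpy as np

from prestim import (
    CohortConfig,
    PipelineConfig,
    SMALL_MONTAGE_16,
    run_pipeline,
)

n_replicates = 5  # increase for a tighter calibration estimate
p_values = []
for rep in range(n_replicates):
    config = PipelineConfig(
        cohort=CohortConfig(n_subjects=4, n_trials_per_condition=15,
                            montage=SMALL_MONTAGE_16, effect_size_d=0.0,
                            seed=100 + rep),
        n_iterations=50,
        permutation_seed=rep,
    )
    group, _ = run_pipeline(config)
    perm = group.permutation[("pre", "full")]
    p_values.append(perm.p_value)
    print(f"replicate {rep}: observed accuracy {perm.observed:.3f}, "
          f"permutation p = {perm.p_value:.3f}, "
          f"null mean {perm.null_distribution.mean():.3f}")

rejections = sum(p < 0.05 for p in p_values)
print(f"\nrejections at alpha = 0.05: {rejections}/{n_replicates} "
      f"(expected about {0.05 * n_replicates:.1f})")
print(f"p-values across replicates: {np.round(p_values, 3).tolist()} — "
      "roughly uniform p-values under the null indicate a calibrated test")
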