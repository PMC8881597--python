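"""End-to-end group analysis on a simulated cohort.

Runs the full pipeline (simulate -> preprocess -> spectra -> per-subject
decoding -> group inference) for 6 subjects and prints the group
statistics: permutation-tested mean accuracy, band attribution of the
classifier weights, the stimulation-site lateralization ANOVA and the
pre/post high-gamma power coupling at FCz.
"""

import numpy as np

from prestim import CohortConfig, PipelineConfig, SMALL_MONTAGE_16, run_pipeline

config = PipelineConfig(
    cohort=CohortConfig(n_subjects=6, n_trials_per_condition=40,
                        montage=SMALL_MONTAGE_16, seed=5),
    n_iterations=100,
)
group, subjects = run_pipeline(config)

perm = group.permutation[("pre", "full")]
print(f"group mean accuracy (pre-stimulus, 4-120 Hz): {perm.observed:.3f}")
print(f"permutation test: p = {perm.p_value:.4f} "
      f"({perm.n_iterations} iterations, null mean {perm.null_distribution.mean():.3f})")
print(f"individually significant subjects: {group.n_significant}/{group.n_subjects}")
print("band attribution of max |weight|:",
      {k: v for k, v in group.band_argmax_counts.items() if v})
if group.anova is not None:
    a = group.anova
    print(f"site x electrode (C5/C6) interaction: "
          f"F({a.df1},{a.df2}) = {a.F:.2f}, p = {a.p:.4f}")
c = group.fcz_gamma_correlation
print(f"FCz high-gamma pre/post power correlation: r = {c.r:.3f} "
      f"(95% CI {np.round(c.ci95, 3)})")

# A cohort with the default planted effect (d = 0.8) shows above-chance
# group accuracy with most significant subjects attributed to high gamma,
# a significant lateralization interaction, and a strong pre/post coupling
# (generator default rho = 0.85).
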