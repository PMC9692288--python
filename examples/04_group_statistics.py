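"""Longitudinal channel statistics and the clinical-scale comparison.

Draws a synthetic cohort whose informative channels (7, 12, 14) gain
activation across sessions, runs the channel-wise Greenhouse-Geisser
RM-ANOVA with Bonferroni-corrected paired-t post-hocs, and the exact
Wilcoxon signed-rank test on the GMFM-88 scores.
"""

import numpy as np

from gaitnirs import (
    CohortSpec,
    channelwise_anova,
    channelwise_posthoc,
    generate_beta_cohort,
    load_brodmann_lookup,
    significance_map,
    shapiro_wilk,
    wilcoxon_exact,
)

spec = CohortSpec(n_subjects=10, seed=7, beta_step=0.4, beta_step_sd=0.05)
beta_df, clinical = generate_beta_cohort(spec, beta_noise_sd=0.05, subject_sd=0.1)

report = significance_map(
    channelwise_anova(beta_df), channelwise_posthoc(beta_df), load_brodmann_lookup()
)
print(report.summary())

gmfm_t0 = np.array([c.gmfm88["T0"] for c in clinical])
gmfm_t2 = np.array([c.gmfm88["T2"] for c in clinical])
w, p_norm = shapiro_wilk(gmfm_t2 - gmfm_t0)
res = wilcoxon_exact(gmfm_t0, gmfm_t2)
print(f"\nGMFM-88 change: Shapiro-Wilk p = {p_norm:.3f}; "
      f"Wilcoxon W+ = {res.w:.0f}, z = {res.z:.3f}, exact p = {res.p_exact:.4f}")
# Channels that survive Bonferroni correction are the planted informative
# ones; the Wilcoxon p confirms a cohort-level motor improvement.
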