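"""Bland–Altman agreement between an intake tool and the DLW reference.

Shows both entry points: internals from published summary moments, and the
full analysis (with normality-gated paired test and MPD split) on paired
per-participant data.
"""

import numpy as np

from dietval import agreement_stats as ag

# --- from summary moments: bias -329.6, SD 599.1, n = 30 -------------------
r = ag.bland_altman_from_moments(bias=-329.6, sd_diff=599.1, n=30)
print("from summary moments (app vs DLW):")
print(f"  bias {r.bias:.1f} kcal/day, 95% CI ({r.bias_ci[0]:.1f}, {r.bias_ci[1]:.1f})")
print(f"  LoA ({r.loa[0]:.1f}, {r.loa[1]:.1f}), SE bias {r.se_bias:.1f}, "
      f"SE LoA {r.se_loa:.1f}")

# --- from paired data ------------------------------------------------------
rng = np.random.default_rng(2)
tdee = rng.normal(2235.2, 456.5, 30)                  # reference expenditure
reported = tdee + rng.normal(-329.6, 599.1, 30)       # tool with bias + spread
pairs = ag.PairedEstimates([f"P{i:02d}" for i in range(30)],
                           reported, tdee, "app", "dlw")

ba = ag.bland_altman(pairs)
test = ag.paired_difference_test(pairs, bonferroni_factor=3)
ou = ag.over_under_summary(pairs)

print("\nfrom paired data (simulated cohort):")
print(f"  bias {ba.bias:.1f} kcal/day, LoA ({ba.loa[0]:.1f}, {ba.loa[1]:.1f})")
print(f"  paired test: {test.test_used}, p_raw {test.p_raw:.4f}, "
      f"p_adj (x3) {test.p_adj:.4f}")
print(f"  {ou.n_over} overestimations (MPD {ou.mpd_over:+.1f}%), "
      f"{ou.n_under} underestimations (MPD {ou.mpd_under:+.1f}%)")
print(f"  overall MPD {ou.mpd_overall:+.1f}%  (mean of individual percentages)")
print("\nThe bias CI uses the t quantile with n-1 df; the LoA keep the fixed")
print("1.96 multiplier. Wide LoA mean poor individual-level agreement even")
print("when the group-level bias looks moderate.")
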