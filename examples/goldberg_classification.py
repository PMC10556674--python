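"""Goldberg cut-off classification of energy-intake misreporting.

Computes the S factor from the literature coefficients for normal-weight
adult women, derives the 95% confidence band around the cohort PAL, and
classifies a small cohort's reported-intake-to-BMR ratios.
"""

import numpy as np

from dietval import energy_goldberg as eg

# pooled variation: within-subject intake CV 26% over 6 assessment days,
# BMR repeatability CV 4.1%, PAL variation CV 16.5%
s = eg.s_factor(cv_wtdei=26.0, d_days=6, cv_wb=4.1, cv_tp=16.5)
print(f"S factor: {s:.2f}%  (pooled CV of intake, BMR, and PAL variation)")

# band around a cohort PAL of 1.66 for n = 30
lower, upper = eg.goldberg_limits(pal_value=1.66, s=s, n=30)
print(f"95% confidence band for TDEI:BMR at n=30: ({lower:.2f}, {upper:.2f})")
print(f"band symmetry check: lower*upper = {lower * upper:.4f} = PAL^2 = {1.66**2:.4f}")

# classify a toy cohort: reported intake vs Mifflin-St Jeor BMR
rng = np.random.default_rng(0)
bmr = np.array([eg.bmr_mifflin(w, h, a)
                for w, h, a in zip(rng.normal(57.8, 6.1, 12),
                                   rng.normal(163, 7, 12),
                                   rng.normal(28.5, 6.7, 12))])
tdee = bmr * 1.66
tdei = tdee + rng.normal(-330, 600, 12)   # under-reporting with spread

cfg = eg.GoldbergConfig(cv_wtdei=26.0, cv_tp=16.5)
res = eg.classify_cohort(tdei, bmr, tdee, cfg)
print(f"\ncohort PAL {res.pal:.2f}, limits ({res.lower_limit:.2f}, {res.upper_limit:.2f})")
print(f"classification: {res.n_under} under / {res.n_plausible} plausible / "
      f"{res.n_over} over of n={len(res.classifications)}")
print("\nA ratio below the band means the participant reported less energy than")
print("is physiologically consistent with their activity level.")
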