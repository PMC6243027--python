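"""Compare continuous resection ratios between surgical-outcome groups.

Generates a 20-patient synthetic cohort whose fast-ripple resection
ratios follow the distributions seen in good (Engel I) and poor
(Engel >= II) outcome groups, then runs the Mann-Whitney comparison and
reports the bootstrap CI of the good-group median — whose lower bound is
the data-driven candidate for the resection threshold.
"""

import hfokit as hk

records, tables = hk.gen_cohort(n_good=10, n_poor=10, seed=3)
cmp = hk.compare_outcomes(records, "fast_ripple", seed=3)

print("patient  group  ratio")
for r in sorted(records, key=lambda r: (r.group, r.patient)):
    print(f"{r.patient:8s} {r.group:5s} {r.ratios['fast_ripple']:.2f}")
print()
print(f"good  (n={cmp.good.n}): median {cmp.good.median:.2f}, "
      f"IQR {cmp.good.iqr[0]:.2f}-{cmp.good.iqr[1]:.2f}, "
      f"95% CI {cmp.good.ci95[0]:.2f}-{cmp.good.ci95[1]:.2f}")
print(f"poor  (n={cmp.poor.n}): median {cmp.poor.median:.2f}, "
      f"IQR {cmp.poor.iqr[0]:.2f}-{cmp.poor.iqr[1]:.2f}")
print(f"Mann-Whitney p = {cmp.p_value:.2g}")
print(f"threshold candidate (good-group lower CI bound): "
      f"{cmp.threshold_candidate:.2f}")
# Good-outcome patients cluster near a complete top-of-ranking resection
# (median ~1); poor-outcome patients near 0.1. The gap is what makes the
# ratio usable as a quantitative EZ-coverage criterion.
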