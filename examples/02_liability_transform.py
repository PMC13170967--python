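"""Transform ordinal respiratory grades to the liability scale.

Uses the observed nostril-stenosis distribution of one breed
(6.2 / 42.6 / 45.2 / 6.0 percent) to show the threshold model: each
category is replaced by the conditional mean of a standard-normal
liability within its slice. The transformed scores average zero and
preserve the category order.
"""

import numpy as np

from kennelquant import grade_to_liability, to_boas_status

rng = np.random.default_rng(0)
grades = rng.choice([0, 1, 2, 3], size=2000, p=[0.062, 0.426, 0.452, 0.060])

lmap, y = grade_to_liability(grades, trait="sten")
print("category  proportion  threshold_z  liability_y")
z = ["-inf"] + [f"{v:.3f}" for v in lmap.z[1:-1]] + ["+inf"]
for j, cat in enumerate(lmap.categories):
    print(f"   {cat}        {lmap.p[j]:.3f}      {z[j]:>6s}       {lmap.y[j]:+.3f}")
print(f"\nweighted mean of transformed scores: {np.sum(lmap.p * lmap.y):+.2e} (zero by construction)")
print(f"weighted variance: {np.sum(lmap.p * lmap.y**2):.3f} (between-category share of the unit liability)")

status = to_boas_status(grades)
print(f"\nclinical status rule (grades 2-3 affected): prevalence {100 * status.mean():.1f}%")
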