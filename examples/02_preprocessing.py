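"""Preprocessing walkthrough: imputation, min-max scaling, SMOTE.

Shows each transform's fitted state and what it does to held-out data.
"""

import numpy as np

import fedstroke as fs
from fedstroke.schema import stroke_schema

schema = stroke_schema()
train = fs.generate_tabular(100, stroke_fraction=0.3, missing_rate=0.2, seed=7)

imp = fs.Imputer("mean").fit(train, schema)
print(f"imputer fill for bmi:      {imp.fill_values['bmi']:.2f}")
print(f"imputer fill for glucose:  {imp.fill_values['avg_glucose_level']:.2f}")

ages = np.array([float(r['age']) for r in imp.transform(train)])
scaler = fs.MinMaxScaler().fit(ages)
print(f"age range fitted:          [{scaler.c_min[0]:.1f}, {scaler.c_max[0]:.1f}]")
print(f"a 50-year-old maps to:     {scaler.transform(np.array([50.0]))[0]:.3f}")

# SMOTE on an imbalanced feature matrix: 950 minority vs 1551 majority
rng = np.random.default_rng(7)
X = rng.normal(size=(2501, 8))
y = np.array([0] * 1551 + [1] * 950)
X_aug, y_aug = fs.smote_oversample(X, y, fs.SmoteConfig(k_neighbors=5, seed=7))
print(f"SMOTE synthetic samples:   {len(y_aug) - len(y)}  "
      f"(minority now {np.sum(y_aug == 1)}, majority {np.sum(y_aug == 0)})")

# Every synthetic sample is a convex combination of a minority point
# and one of its 5 nearest minority neighbors, so the augmented cloud
# never leaves the minority class's convex hull.
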