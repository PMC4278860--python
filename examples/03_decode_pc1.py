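"""Cross-validated linear decoding of the first PC of reach kinematics.

The decoder models the kinematic target as a linear combination of the
nine best lag-aligned features plus an offset, refit in each of five
contiguous folds (selection, normalization and PCA are all training-only).
Accuracy is Pearson's r between observed and predicted traces on the
held-out 20%.
"""

import numpy as np

from ecogkin import SynthConfig, crossvalidate, extract_features, generate_session

session = generate_session(SynthConfig(seed=0))
feats = extract_features(session)

for target in ("pc1", "pc2", "pc3"):
    cv = crossvalidate(feats, n_inputs=9, target=target)
    folds = " ".join(f"{r:.3f}" for r in cv.fold_r)
    print(f"{target}: fold r = [{folds}]  median = {cv.median_r:.3f}")

print("\nPC1 (the encoded movement axis) decodes well; PC2/PC3 sit near zero —")
print("the drive modulating the carriers is one-dimensional.")
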