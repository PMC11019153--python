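"""Train and calibrate the image quality-control classifier.

A balanced labeled set of good images (single complete in-focus nucleus)
and bad ones (out-of-focus, truncated, blank scanner rows, empty frames,
doublets) trains a random forest; the decision threshold is the smallest
out-of-fold probability whose cross-validated precision for the good class
reaches 95%.  The printed held-out precision is the fraction of kept
images that are genuinely good on an independent set.
"""

import numpy as np

from senotex.datasets import make_qc_dataset
from senotex.models import QCParams, apply_qc, train_qc

df_train, labels_train, _ = make_qc_dataset(n_good=120, n_bad=120, seed=11)
model = train_qc(df_train, labels_train, QCParams(n_trees=300, seed=0))
print(f"calibrated threshold: {model.threshold:.3f} "
      f"(target precision {model.target_precision:.0%})")

df_test, labels_test, _ = make_qc_dataset(n_good=120, n_bad=120, seed=12)
keep, proba = apply_qc(model, df_test)
labels_test = np.asarray(labels_test)
print(f"kept {keep.sum()}/{len(keep)} images; "
      f"held-out precision {labels_test[keep].mean():.3f}; "
      f"recall of good images {keep[labels_test].mean():.3f}")
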