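"""Classify drug-treated cells against proliferating/senescent references.

An RBF support vector machine is trained on the texture features of
proliferating and replicatively senescent nuclei only, then applied to
treated groups.  Day-6 treatment shares the senescent generator, so it
should classify almost entirely senescent; day-3 sits midway in parameter
space and should split between the classes (the "ambiguous" call).
"""

from senotex.datasets import make_condition_dataset
from senotex.models import classify_treated, condition_summaries, train_condition

X_train, y_train = make_condition_dataset(30, ("proliferating", "senescent"), seed=21)
model = train_condition(X_train, y_train)
print(f"SVM training accuracy: {model.train_accuracy:.3f}")

groups = {}
for grp in ("treated_d3", "treated_d6"):
    groups[grp], _ = make_condition_dataset(25, (grp,), seed=33)
summary = classify_treated(model, groups)
print(summary.to_frame().to_string(index=False))

print("\nper-condition feature distributions:")
print(condition_summaries(X_train, y_train).to_string(index=False))
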