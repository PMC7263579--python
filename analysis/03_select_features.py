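"""Sequential forward selection of 7 features maximizing 10-fold CV accuracy.

Writes the ordered selection with per-step accuracies to
results/selected_features.json.
"""

import json

from _common import CONFIG, RESULTS, get_dataset, get_features
from t1tex.selection import sfs

subjects, labels = get_dataset()
feats = get_features(subjects)
sel = sfs(feats, labels, k=CONFIG.k, folds=CONFIG.folds, seed=CONFIG.seed)

print("step  feature            CV accuracy")
for i, (name, acc) in enumerate(zip(sel.feature_names, sel.step_accuracies), 1):
    print(f"{i:>4}  {name:<18} {acc:.3f}")

RESULTS.mkdir(exist_ok=True)
(RESULTS / "selected_features.json").write_text(
    json.dumps(
        {
            "ordered_indices": list(sel.ordered_indices),
            "feature_names": list(sel.feature_names),
            "step_accuracies": list(sel.step_accuracies),
        },
        indent=2,
    )
)
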