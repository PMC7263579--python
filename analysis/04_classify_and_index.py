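"""Multiclass evaluation of the selected features vs T1-only baselines.

Compares all four classifiers on the 7 selected features, the
global-T1-only and 30-segment baselines (linear SVM), reports one-vs-all
AUCs with DeLong CIs and a DeLong test of texture vs global T1, fits the
texture index for each one-vs-one cohort pair, and embeds the selected
features in 2-D with t-SNE.

Outputs: results/classification_summary.csv, results/texture_index.csv,
results/tsne_coords.csv.
"""

import json

import numpy as np
import pandas as pd

from _common import CONFIG, RESULTS, get_dataset, get_features
from t1tex.evaluate import (
    CLASSIFIER_NAMES,
    cross_validated_eval,
    delong_test,
    embed_2d,
)
from t1tex.pipeline import global_t1_table, texture_index_comparisons
from t1tex.selection import SelectionResult

subjects, labels = get_dataset()
feats = get_features(subjects)
sel_meta = json.loads((RESULTS / "selected_features.json").read_text())
sel = SelectionResult(
    tuple(sel_meta["ordered_indices"]),
    tuple(sel_meta["step_accuracies"]),
    tuple(sel_meta["feature_names"]),
)
X_sel = feats.iloc[:, list(sel.ordered_indices)]
y = np.asarray(labels)

rows = []
reports = {}
for clf in CLASSIFIER_NAMES:
    rep = cross_validated_eval(X_sel, y, clf, folds=CONFIG.folds, seed=CONFIG.seed)
    reports[clf] = rep
    rows.append({"features": "texture(7)", "classifier": clf, "accuracy": rep.accuracy,
                 **{f"auc_{c}": rep.auc[c][0] for c in rep.classes}})

baselines = global_t1_table(subjects, CONFIG)
for name, cols in (("global_t1(1)", ["global_t1"]),
                   ("segmental_t1(30)", [c for c in baselines if c != "global_t1"])):
    rep = cross_validated_eval(baselines[cols], y, "linear-svm",
                               folds=CONFIG.folds, seed=CONFIG.seed)
    reports[name] = rep
    rows.append({"features": name, "classifier": "linear-svm", "accuracy": rep.accuracy,
                 **{f"auc_{c}": rep.auc[c][0] for c in rep.classes}})

summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "classification_summary.csv", index=False)
print(summary.round(3).to_string(index=False))

# per-class DeLong comparison: texture vs global-T1 decision scores
tex, glob = reports["linear-svm"], reports["global_t1(1)"]
for ci, c in enumerate(tex.classes):
    _, _, delta, p = delong_test(
        tex.scores[:, ci], glob.scores[:, ci], (y == c).astype(int)
    )
    print(f"DeLong texture vs global T1, {c}: dAUC={delta:+.3f}, p={p:.2g}")

tix = texture_index_comparisons(feats, labels, sel)
tix.to_csv(RESULTS / "texture_index.csv")
print(tix.round(2).to_string())

coords = embed_2d(X_sel.to_numpy(), seed=CONFIG.seed)
pd.DataFrame(
    {"subject_id": feats.index, "label": y, "tsne1": coords[:, 0], "tsne2": coords[:, 1]}
).to_csv(RESULTS / "tsne_coords.csv", index=False)
print(f"t-SNE coordinates for {len(y)} subjects -> results/tsne_coords.csv")
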