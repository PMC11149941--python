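"""Train the three classifiers and compare them on a held-out test split.

The combined model concatenates the selected radiomics features onto the
width-50 vector of the CNN's fully connected stage, so its penultimate
layer has width 50 + n_features. Runs on a down-scaled grid for speed.
"""

import numpy as np
import pandas as pd

from petfuse import (
    CohortData,
    ModelConfig,
    PhantomConfig,
    TrainingConfig,
    build_model,
    build_report,
    extract_all,
    generate_control_volume,
    generate_demented_volume,
    predict,
    preprocess_volume,
    select_features,
    train,
)

grid = (16, 16, 16)
cfg = PhantomConfig(grid_shape=grid, noise_sd=5.0, smoothness_mm=4.0)


def subject(i, demented):
    vol = (
        generate_demented_volume(cfg, ["frontal", "parietal"], seed=i)
        if demented
        else generate_control_volume(cfg, seed=i)
    )
    return preprocess_volume(vol, fwhm_mm=4.0)


vols = [subject(i, i >= 20) for i in range(40)] + [subject(100 + i, i >= 8) for i in range(16)]
labels = ["control"] * 20 + ["demented"] * 20 + ["control"] * 8 + ["demented"] * 8
table = pd.DataFrame([extract_all(v).values for v in vols])

sel = select_features(table.iloc[:40], np.array(labels[:40]), fraction=0.10, r_threshold=0.30)
print(f"selected features: {sel.final_features}")

images = np.stack([v.data for v in vols])
feats = table[sel.final_features].to_numpy()
ids = [f"s{i:02d}" for i in range(len(vols))]
cohort = CohortData.from_labels(ids[:40], labels[:40], images[:40], feats[:40])

preds = {}
for kind in ("feature_only", "cnn", "combined"):
    mcfg = ModelConfig(kind=kind, image_shape=grid, n_features=len(sel.final_features))
    net = build_model(mcfg, seed=0)
    if kind == "combined":
        print(f"combined penultimate width: {net.concat_width} (50 + {len(sel.final_features)})")
    model = train(net, cohort, TrainingConfig(seed=0, epochs=60 if kind == "feature_only" else 20))
    print(f"{kind}: validation accuracy {model.val_accuracy:.0f}%")
    preds[kind] = [
        predict(
            model,
            image=images[40 + i] if kind != "feature_only" else None,
            features=feats[40 + i] if kind != "cnn" else None,
            subject_id=ids[40 + i],
        )
        for i in range(16)
    ]

report = build_report(pd.DataFrame({"id": ids[40:], "label": labels[40:]}), preds)
for name, m in report.metrics.items():
    print(f"{name}: sensitivity {m['sensitivity']}%, specificity {m['specificity']}%")
print("\nper-class mean posterior score (percent) of the true class:")
print(report.summary.round(2).to_string(index=False))
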