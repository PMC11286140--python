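"""Supervised call-type classification from features and spectrograms.

Screens the eight repertoire features by Shapley-attribution importance,
tunes a gradient-boosted tree classifier (70/30 split, 5-fold CV random
search), trains the small convolutional network on the prepared
mel-spectrograms (49/21/30 split, early stopping), and writes both
classification reports plus confusion-matrix heatmaps.

Usage: python analysis/04_repertoire_supervised.py [--seed 42]
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from zebrarep import repertoire as rep
from zebrarep.specprep import load_spectrogram_set


def plot_confusion(report, path, title):
    cm = np.asarray(report.confusion_matrix, dtype=float)
    cm = cm / cm.sum(axis=1, keepdims=True)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(cm, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(report.classes)), report.classes, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(report.classes)), report.classes)
    for i in range(len(report.classes)):
        for j in range(len(report.classes)):
            ax.text(j, i, f"{cm[i, j]:.2f}", ha="center", va="center",
                    color="white" if cm[i, j] > 0.5 else "black")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--trials", type=int, default=20)
    ap.add_argument("--screen-threshold", type=float, default=0.1)
    args = ap.parse_args()

    results = Path("results")
    table = pd.read_csv(results / "02_features.csv")
    X = table[list(rep.REPERTOIRE_FEATURES)]
    y = table.call_type.values

    selected, scores = rep.select_features_by_importance(
        X, y, threshold=args.screen_threshold, seed=args.seed)
    scores.to_csv(results / "04_shap_importances.csv", header=["importance"])
    print(f"importance screen kept {len(selected)}/8 features: {selected}")

    model = rep.train_feature_classifier(X[selected], y, n_trials=args.trials,
                                         seed=args.seed)
    print(f"feature-based test accuracy: {model.report.accuracy:.3f} "
          f"(best params {model.best_params})")

    specs = load_spectrogram_set("scratch/spectrograms.npz")
    by_id = dict(zip(table.call_id, table.call_type))
    labels = np.array([by_id[s.call_id] for s in specs])
    cnn = rep.train_spectrogram_classifier(specs, labels, seed=args.seed)
    print(f"spectrogram-based test accuracy: {cnn.report.accuracy:.3f}")

    out = dict(selected_features=selected,
               feature_based=model.report.as_dict(),
               spectrogram_based=cnn.report.as_dict())
    (results / "04_supervised.json").write_text(json.dumps(out, indent=2))
    plot_confusion(model.report, results / "04_confusion_features.png",
                   "feature-based classifier")
    plot_confusion(cnn.report, results / "04_confusion_spectrograms.png",
                   "spectrogram-based classifier")
    for name, r in (("features", model.report), ("spectrograms", cnn.report)):
        f1s = ", ".join(f"{c}: {v:.2f}" for c, v in r.f1.items())
        print(f"  {name} f1 per type -> {f1s}")


if __name__ == "__main__":
    main()
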