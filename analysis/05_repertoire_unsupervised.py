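"""Unsupervised call-type discovery: 2-D embedding, k-means, elbow.

Runs the feature-based route (Euclidean embedding of the screened,
standardized features) and the spectrogram-based route (time-shift
distance matrix as a precomputed metric), picks the cluster count by the
elbow rule, and writes the type-by-cluster tables, the embeddings and the
within/between distance diagnostics.

Usage: python analysis/05_repertoire_unsupervised.py [--seed 42]
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


def plot_embedding(res, types, path, title):
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for t in sorted(set(types)):
        m = types == t
        axes[0].scatter(*res.embedding[m].T, s=6, label=t)
    axes[0].legend(markerscale=2, fontsize=7)
    axes[0].set_title(f"{title}: true types")
    axes[1].scatter(*res.embedding.T, c=res.assignments, s=6, cmap="tab10")
    axes[1].set_title(f"k-means, k={res.k}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_within_between(res, path, title):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(res.within_distances, bins=60, density=True, alpha=0.6,
            color="green", label="within type")
    ax.hist(res.between_distances, bins=60, density=True, alpha=0.6,
            color="red", label="between types")
    ax.set_xlabel("pairwise distance")
    ax.set_title(f"{title} (overlap {res.overlap_coefficient:.2f})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--screen-threshold", type=float, default=0.1)
    args = ap.parse_args()

    results = Path("results")
    table = pd.read_csv(results / "02_features.csv")
    X = table[list(rep.REPERTOIRE_FEATURES)]
    y = table.call_type.values

    selected, _ = rep.select_features_by_importance(
        X, y, threshold=args.screen_threshold, seed=args.seed)
    Xs = ((X[selected] - X[selected].mean()) / X[selected].std()).values
    feat = rep.repertoire_unsupervised(Xs, y, mode="features", seed=args.seed)
    print(f"feature-based clustering: elbow k = {feat.k}, "
          f"within/between overlap = {feat.overlap_coefficient:.3f}")

    specs = load_spectrogram_set("scratch/spectrograms.npz")
    by_id = dict(zip(table.call_id, table.call_type))
    labels = np.array([by_id[s.call_id] for s in specs])
    small = np.stack([rep.downsample_matrix(s.matrix, (32, 64)) for s in specs])
    spec = rep.repertoire_unsupervised(small, labels, mode="spectrogram",
                                       seed=args.seed)
    print(f"spectrogram-based clustering: elbow k = {spec.k}, "
          f"within/between overlap = {spec.overlap_coefficient:.3f}")

    feat.type_cluster_matrix.to_csv(results / "05_clusters_features.csv")
    spec.type_cluster_matrix.to_csv(results / "05_clusters_spectrograms.csv")
    summary = dict(
        feature_based=dict(k=feat.k, overlap=feat.overlap_coefficient,
                           inertia=feat.inertia_by_k.tolist()),
        spectrogram_based=dict(k=spec.k, overlap=spec.overlap_coefficient,
                               inertia=spec.inertia_by_k.tolist()))
    (results / "05_unsupervised.json").write_text(json.dumps(summary, indent=2))
    plot_embedding(feat, y, results / "05_embedding_features.png", "features")
    plot_embedding(spec, labels, results / "05_embedding_spectrograms.png",
                   "spectrograms")
    plot_within_between(feat, results / "05_within_between_features.png",
                        "feature-based")
    plot_within_between(spec, results / "05_within_between_spectrograms.png",
                        "spectrogram-based")
    print("cluster composition (feature-based, rows = true type):")
    print(feat.type_cluster_matrix.round(2))


if __name__ == "__main__":
    main()
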