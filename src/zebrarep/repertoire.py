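"""Call-type classification and clustering (the vocal-repertoire analyses).

Two representations of each call are analyzed in parallel:

- the eight non-F0 acoustic features (screened by Shapley-attribution
  importance, classified with gradient-boosted trees);
- the prepared mel-spectrogram (classified with a small convolutional
  network; clustered via a time-shift-tolerant spectrogram distance).

The unsupervised route reduces either representation to two dimensions,
runs k-means for a range of k and picks the cluster count at the elbow of
the within-cluster sum-of-squares curve, then diagnoses cluster quality
with a true-type-by-cluster confusion table and within- vs between-type
pairwise distance distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold, train_test_split

from zebrarep.cnn import CNNConfig, SmallCNN
from zebrarep.specprep import MelSpectrogram, pairwise_timeshift_distances

REPERTOIRE_FEATURES = ("q25", "q50", "q75", "peak_frequency", "duration",
                       "amplitude_variation", "am_rate", "am_extent")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (validation may be 0) and the seed."""

    train: float = 0.7
    validation: float = 0.0
    test: float = 0.3
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train, self.validation, self.test)
        if any(f < 0 for f in fracs) or self.train <= 0 or self.test <= 0:
            raise ValueError("train and test fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


def split_indices(labels: np.ndarray, spec: SplitSpec
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, covering train/validation/test indices, stratified by label."""
    idx = np.arange(len(labels))
    strat = labels if spec.stratify else None
    train_val, test = train_test_split(idx, test_size=spec.test,
                                       stratify=strat, random_state=spec.seed)
    if spec.validation == 0:
        return train_val, np.array([], dtype=int), test
    val_frac = spec.validation / (spec.train + spec.validation)
    strat2 = labels[train_val] if spec.stratify else None
    train, val = train_test_split(train_val, test_size=val_frac,
                                  stratify=strat2, random_state=spec.seed + 1)
    return train, val, test


@dataclass
class ClassificationReport:
    """Accuracy, per-class precision/recall/f1 and the confusion matrix."""

    classes: list[str]
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion_matrix: np.ndarray  # rows: true class, cols: predicted

    def as_dict(self) -> dict:
        return dict(classes=self.classes, accuracy=self.accuracy,
                    precision=self.precision, recall=self.recall, f1=self.f1,
                    confusion_matrix=self.confusion_matrix.tolist())


def evaluate(pred: np.ndarray, true: np.ndarray,
             classes: list[str] | None = None) -> ClassificationReport:
    """Compute accuracy, precision, recall, f1 and the confusion matrix.

    precision = TP/(TP+FP), recall = TP/(TP+FN), f1 = 2PR/(P+R) (0 when
    P+R = 0), accuracy = trace/total.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ")
    if len(pred) == 0:
        raise ValueError("empty input")
    if classes is None:
        classes = sorted(set(map(str, true)) | set(map(str, pred)))
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        cm[lut[str(t)], lut[str(p)]] += 1
    accuracy = float(np.trace(cm)) / cm.sum()
    precision, recall, f1 = {}, {}, {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        precision[c] = float(p)
        recall[c] = float(r)
        f1[c] = float(2 * p * r / (p + r)) if p + r > 0 else 0.0
    return ClassificationReport(classes=list(classes), accuracy=accuracy,
                                precision=precision, recall=recall, f1=f1,
                                confusion_matrix=cm)


# ---------------------------------------------------------------------------
# Feature-based supervised route


def shap_importances(X: pd.DataFrame, y: np.ndarray,
                     seed: int = 0) -> pd.Series:
    """Mean absolute Shapley attribution per feature.

    A gradient-boosted tree classifier is fit on all data and exact
    TreeSHAP contributions are computed for every sample and class; the
    importance of a feature is the mean absolute contribution.
    """
    classes, y_enc = np.unique(y, return_inverse=True)
    model = xgb.XGBClassifier(n_estimators=100, max_depth=4, learning_rate=0.3,
                              random_state=seed, n_jobs=1, verbosity=0)
    model.fit(X.values, y_enc)
    booster = model.get_booster()
    contribs = booster.predict(xgb.DMatrix(X.values), pred_contribs=True)
    # multiclass: (n, n_class, n_feat + 1); last column is the bias term
    if contribs.ndim == 3:
        imp = np.abs(contribs[:, :, :-1]).mean(axis=(0, 1))
    else:
        imp = np.abs(contribs[:, :-1]).mean(axis=0)
    return pd.Series(imp, index=X.columns).sort_values(ascending=False)


def select_features_by_importance(feature_table: pd.DataFrame, labels: np.ndarray,
                                  threshold: float = 1.0, seed: int = 0
                                  ) -> tuple[list[str], pd.Series]:
    """Keep features whose mean-|SHAP| importance exceeds `threshold`."""
    if feature_table.isna().any().any():
        raise ValueError("candidate features contain missing values")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    scores = shap_importances(feature_table, labels, seed=seed)
    selected = [name for name, score in scores.items() if score > threshold]
    if not selected:
        raise ValueError(
            f"no feature importance exceeds {threshold}; max is "
            f"{scores.max():.3g} — lower the threshold")
    return selected, scores


@dataclass
class TunedModel:
    model: object
    best_params: dict
    report: ClassificationReport
    split: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)


def train_feature_classifier(X: pd.DataFrame, labels: np.ndarray,
                             split: SplitSpec = SplitSpec(0.7, 0.0, 0.3),
                             n_trials: int = 20, seed: int = 0) -> TunedModel:
    """Gradient-boosted tree classifier with random-search tuning.

    Three hyperparameters (learning rate, tree depth, number of trees) are
    tuned by random search with 5-fold cross-validation on the training
    split; the report is computed on the held-out test split only.
    """
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    tr, _, te = split_indices(y, split)
    if len(np.unique(y[tr])) < len(classes):
        raise ValueError("a class is absent from the training split")
    Xv = X.values
    rng = np.random.default_rng(seed)
    best_score, best_params = -np.inf, dict(learning_rate=0.3, max_depth=4,
                                            n_estimators=100)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    for _ in range(n_trials):
        params = dict(
            learning_rate=float(10 ** rng.uniform(-2, -0.3)),
            max_depth=int(rng.integers(2, 9)),
            n_estimators=int(rng.integers(50, 301)),
        )
        scores = []
        for fold_tr, fold_va in cv.split(Xv[tr], y[tr]):
            m = xgb.XGBClassifier(**params, random_state=seed, n_jobs=1, verbosity=0)
            m.fit(Xv[tr][fold_tr], y[tr][fold_tr])
            scores.append(np.mean(m.predict(Xv[tr][fold_va]) == y[tr][fold_va]))
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    model = xgb.XGBClassifier(**best_params, random_state=seed, n_jobs=1, verbosity=0)
    model.fit(Xv[tr], y[tr])
    pred = classes[model.predict(Xv[te])]
    report = evaluate(pred, labels[te], classes=list(map(str, classes)))
    return TunedModel(model=model, best_params=best_params, report=report,
                      split=(tr, np.array([], dtype=int), te))


# ---------------------------------------------------------------------------
# Spectrogram-based supervised route


def downsample_matrix(m: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Block-mean downsampling to a fixed (rows, cols) shape."""
    r, c = out_shape
    rows = np.array_split(np.arange(m.shape[0]), r)
    cols = np.array_split(np.arange(m.shape[1]), c)
    out = np.empty((r, c))
    row_means = np.stack([m[rs].mean(axis=0) for rs in rows])
    for j, cs in enumerate(cols):
        out[:, j] = row_means[:, cs].mean(axis=1)
    return out


def spectrograms_to_inputs(specs: list[MelSpectrogram],
                           input_shape: tuple[int, int] = (32, 32)) -> np.ndarray:
    """Stack prepared spectrograms, downsample, and min-max scale to [0, 1]
    over the whole dataset."""
    shapes = {s.matrix.shape for s in specs}
    if len(shapes) != 1:
        raise ValueError(f"spectrogram shapes differ: {shapes}")
    X = np.stack([downsample_matrix(s.matrix, input_shape) for s in specs])
    lo, hi = X.min(), X.max()
    return (X - lo) / (hi - lo) if hi > lo else np.zeros_like(X)


def train_spectrogram_classifier(specs: list[MelSpectrogram], labels: np.ndarray,
                                 split: SplitSpec = SplitSpec(0.49, 0.21, 0.30),
                                 config: CNNConfig | None = None,
                                 seed: int = 0) -> TunedModel:
    """Small convolutional network on prepared spectrograms.

    Trained with early stopping on the validation split (49/21/30 by
    default); the report is computed on the test split only.
    """
    classes, y = np.unique(labels, return_inverse=True)
    config = config or CNNConfig(n_classes=len(classes), seed=seed)
    X = spectrograms_to_inputs(specs, config.input_shape)
    tr, va, te = split_indices(y, split)
    if len(va) == 0:
        raise ValueError("spectrogram classifier needs a validation split")
    net = SmallCNN(config)
    history = net.fit(X[tr], y[tr], X[va], y[va])
    pred = classes[net.predict(X[te])]
    report = evaluate(pred, labels[te], classes=list(map(str, classes)))
    tuned = TunedModel(model=net, best_params=dict(best_epoch=history.best_epoch),
                       report=report, split=(tr, va, te))
    tuned.history = history
    return tuned


# ---------------------------------------------------------------------------
# Unsupervised route


def embed_2d(X: np.ndarray, mode: str = "features",
             n_neighbors: int = 200, local_connectivity: float = 150.0,
             min_dist: float | None = None, seed: int = 0,
             precomputed: bool = False) -> np.ndarray:
    """2-D embedding via uniform manifold approximation and projection.

    Feature mode uses a Euclidean metric with large-neighborhood
    parameters (n_neighbors 200, local_connectivity 150, both clamped to
    n - 1 for small datasets); spectrogram mode expects a precomputed
    time-shift distance matrix and uses min_dist = 0.
    """
    import umap  # deferred: heavy import

    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 samples to embed")
    nn = min(n_neighbors, n - 1)
    lc = min(local_connectivity, nn - 1) if nn > 1 else 1.0
    if nn < n_neighbors:
        warnings.warn(f"n_neighbors clamped from {n_neighbors} to {nn}")
    if mode == "features":
        kwargs = dict(metric="euclidean", min_dist=0.1 if min_dist is None else min_dist)
        data = X
    elif mode == "spectrogram":
        if not precomputed:
            raise ValueError("spectrogram mode expects a precomputed distance matrix")
        kwargs = dict(metric="precomputed", min_dist=0.0 if min_dist is None else min_dist)
        data = X
    else:
        raise ValueError(f"unknown mode {mode!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=nn,
                            local_connectivity=lc, random_state=seed, **kwargs)
        return reducer.fit_transform(data)


def choose_k_elbow(inertia: np.ndarray, stop_ratio: float = 0.6) -> int:
    """Elbow rule on the within-cluster sum-of-squares curve.

    Keep adding clusters while each step still pays: k grows as long as
    ``inertia[k] / inertia[k-1] <= stop_ratio``, i.e. a new cluster cuts
    the within-cluster sum of squares by at least 40%. Bisecting a single
    isotropic 2-D Gaussian reduces it by only ~32% (the split axis drops
    from 1 to 1 - 2/pi), so an unstructured blob stops at k = 1, while a
    curve with a genuine elbow stops right after it. Robust to the
    hierarchical geometry of embedded call types, where the first split
    (e.g. tonal vs non-tonal) dwarfs later, equally real ones.
    """
    inertia = np.asarray(inertia, dtype=float)
    k = 1
    for j in range(1, len(inertia)):
        if inertia[j - 1] <= 1e-12:
            break  # structure fully explained
        if inertia[j] / inertia[j - 1] <= stop_ratio:
            k = j + 1
        else:
            break
    return k


@dataclass
class ClusteringResult:
    embedding: np.ndarray
    k: int
    assignments: np.ndarray
    inertia_by_k: np.ndarray
    type_cluster_matrix: pd.DataFrame
    within_distances: np.ndarray
    between_distances: np.ndarray
    overlap_coefficient: float


def _sample_pair_distances(points: np.ndarray, same: np.ndarray,
                           rng: np.random.Generator, cap: int = 50_000
                           ) -> tuple[np.ndarray, np.ndarray]:
    n = len(points)
    ii, jj = np.triu_indices(n, k=1)
    is_within = same[ii] == same[jj]
    d = np.linalg.norm(points[ii] - points[jj], axis=1)
    within, between = d[is_within], d[~is_within]
    if len(within) > cap:
        within = rng.choice(within, cap, replace=False)
    if len(between) > cap:
        between = rng.choice(between, cap, replace=False)
    return within, between


def histogram_overlap(a: np.ndarray, b: np.ndarray, bins: int = 60) -> float:
    """Overlap coefficient of two empirical distributions (0 = disjoint)."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    ha, _ = np.histogram(a, bins=bins, range=(lo, hi), density=False)
    hb, _ = np.histogram(b, bins=bins, range=(lo, hi), density=False)
    return float(np.minimum(ha / ha.sum(), hb / hb.sum()).sum())


def cluster_and_diagnose(points: np.ndarray, true_types: np.ndarray,
                         k_max: int = 8, seed: int = 0,
                         embedding: np.ndarray | None = None) -> ClusteringResult:
    """k-means over k = 1..k_max with elbow selection and diagnostics.

    `points` is the representation clustered (by default the 2-D
    embedding); the confusion table gives, per true type, the proportion
    of its calls in each cluster (rows sum to 1); within/between pairwise
    distance samples are drawn in the same representation.
    """
    n = len(points)
    if n <= k_max:
        raise ValueError("need more samples than k_max")
    if np.allclose(points, points[0]):
        k_max = 1  # degenerate identical points
    inertia = []
    models = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(points)
        inertia.append(km.inertia_)
        models[k] = km
    inertia = np.array(inertia)
    k = choose_k_elbow(inertia)
    assignments = models[k].labels_
    types = np.asarray(true_types)
    type_names = sorted(set(map(str, types)))
    mat = np.zeros((len(type_names), k))
    for i, t in enumerate(type_names):
        sel = assignments[types.astype(str) == t]
        for c in range(k):
            mat[i, c] = np.mean(sel == c)
    tcm = pd.DataFrame(mat, index=type_names, columns=[f"cluster{c}" for c in range(k)])
    rng = np.random.default_rng(seed)
    within, between = _sample_pair_distances(points, types, rng)
    overlap = histogram_overlap(within, between) if len(within) and len(between) else np.nan
    return ClusteringResult(
        embedding=embedding if embedding is not None else points,
        k=k, assignments=assignments, inertia_by_k=inertia,
        type_cluster_matrix=tcm, within_distances=within,
        between_distances=between, overlap_coefficient=overlap)


def repertoire_unsupervised(X: np.ndarray, true_types: np.ndarray,
                            mode: str = "features", k_max: int = 8,
                            seed: int = 0, cluster_on: str = "embedding",
                            max_shift: int | None = None) -> ClusteringResult:
    """Full unsupervised route: embed to 2-D, cluster, diagnose.

    In spectrogram mode `X` is a stacked array of prepared spectrogram
    matrices; the time-shift distance matrix is computed first and fed to
    the embedding as a precomputed metric. `cluster_on` selects whether
    k-means runs on the 2-D embedding (default) or the original vectors.
    """
    if mode == "spectrogram":
        D = pairwise_timeshift_distances(X, max_shift=max_shift, symmetrize="min")
        emb = embed_2d(D, mode="spectrogram", precomputed=True, seed=seed)
        base = X.reshape(len(X), -1)
    else:
        emb = embed_2d(X, mode="features", seed=seed)
        base = X
    points = emb if cluster_on == "embedding" else base
    return cluster_and_diagnose(points, true_types, k_max=k_max, seed=seed,
                                embedding=emb)
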