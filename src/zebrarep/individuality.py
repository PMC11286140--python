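"""Individual distinctiveness of call types: KMO -> PCA -> DFA -> nested pDFA.

The chain mirrors standard practice for vocal-individuality studies:

1. Kaiser-Meyer-Olkin screening keeps features whose measure of sampling
   adequacy (MSA) is at least 0.5, i.e. features whose correlations are
   not dominated by partial correlations.
2. PCA on the correlation matrix of the retained features; components
   with eigenvalue > 1 are kept as uncorrelated scores.
3. A linear discriminant function analysis (DFA) with individual identity
   as the grouping factor describes which components carry individuality
   (percent discriminative variance per function; DF-PC correlations).
4. A nested permuted DFA (pDFA) tests whether calls are assigned to the
   correct individual above chance. Balanced derivation sets (an equal
   number of calls per individual) are drawn repeatedly; a DFA fitted on
   each derivation set cross-classifies the withheld calls. The null
   distribution permutes the call-to-individual assignment only among
   individuals sharing a level of a restriction factor (e.g. sex or
   location), so identity effects are tested over and above that factor.
   The observed dataset counts as one permutation, making the smallest
   attainable p-value 1/n_permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg


# ---------------------------------------------------------------------------
# KMO


@dataclass
class KMOResult:
    overall_msa: float
    per_variable_msa: pd.Series
    retained: list[str]
    threshold: float = 0.5


def kmo(X: pd.DataFrame | np.ndarray, threshold: float = 0.5) -> KMOResult:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    MSA_j = sum_{k!=j} r_jk^2 / (sum_{k!=j} r_jk^2 + sum_{k!=j} q_jk^2)
    where r are Pearson correlations and q the anti-image partial
    correlations from the inverse correlation matrix; the overall MSA
    pools the sums over all pairs.
    """
    df = pd.DataFrame(X)
    if df.shape[0] <= df.shape[1]:
        raise ValueError("need more observations than variables")
    R = np.corrcoef(df.values, rowvar=False)
    if np.linalg.cond(R) > 1e10:
        corr = pd.DataFrame(np.abs(R), index=df.columns, columns=df.columns)
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"correlation matrix is singular (near-collinear variables, "
            f"e.g. {worst[0]!r} and {worst[1]!r})")
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d  # anti-image partial correlations (off-diagonal)
    np.fill_diagonal(Q, 0.0)
    R0 = R.copy()
    np.fill_diagonal(R0, 0.0)
    r2 = R0**2
    q2 = Q**2
    msa = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    overall = r2.sum() / (r2.sum() + q2.sum())
    per_var = pd.Series(msa, index=df.columns)
    retained = [c for c in df.columns if per_var[c] >= threshold]
    return KMOResult(overall_msa=float(overall), per_variable_msa=per_var,
                     retained=retained, threshold=threshold)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    loadings: pd.DataFrame        # variables x components (eigenvectors)
    eigenvalues: np.ndarray
    scores: np.ndarray            # n x n_retained
    retained_components: list[str]
    mean: np.ndarray
    scale: np.ndarray


def pca_reduce(X: pd.DataFrame | np.ndarray, eigenvalue_threshold: float = 1.0
               ) -> PCAModel:
    """PCA on the correlation matrix; retain components with eigenvalue > 1.

    Variables are centered and unit-scaled; loading signs are fixed so the
    largest-magnitude entry of each eigenvector is positive.
    """
    df = pd.DataFrame(X)
    if df.shape[1] < 2:
        raise ValueError("need at least two features")
    mean = df.values.mean(axis=0)
    scale = df.values.std(axis=0, ddof=1)
    if np.any(scale == 0):
        raise ValueError("constant feature cannot be standardized")
    Z = (df.values - mean) / scale
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    n_keep = int(np.sum(evals > eigenvalue_threshold))
    if n_keep < 1:
        raise ValueError("no component has eigenvalue above the threshold")
    comp_names = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=df.columns, columns=comp_names)
    scores = Z @ evecs[:, :n_keep]
    return PCAModel(loadings=loadings, eigenvalues=evals, scores=scores,
                    retained_components=comp_names[:n_keep], mean=mean, scale=scale)


# ---------------------------------------------------------------------------
# DFA


@dataclass
class DFAModel:
    coefficients: np.ndarray          # d x n_df discriminant vectors
    percent_variance: np.ndarray      # per discriminant function, sums to 100
    df_scores: np.ndarray             # n x n_df
    df_pc_correlation: pd.DataFrame   # DFs x input variables, with |r|>=0.5 flag
    strong_correlations: pd.DataFrame  # boolean mask |r| >= 0.5
    group_means_df: pd.DataFrame      # group centroids in DF space


def _fit_lda(X: np.ndarray, groups: np.ndarray, ridge: float = 1e-8
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Classical linear discriminants: eigenvectors of Sw^-1 Sb.

    Returns (discriminant vectors, eigenvalues, group labels, group means).
    """
    labels, y = np.unique(groups, return_inverse=True)
    g, d = len(labels), X.shape[1]
    means = np.stack([X[y == i].mean(axis=0) for i in range(g)])
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for i in range(g):
        Xi = X[y == i] - means[i]
        Sw += Xi.T @ Xi
        Sb += (y == i).sum() * np.outer(means[i] - grand, means[i] - grand)
    Sw += ridge * np.eye(d)
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    n_df = min(g - 1, d)
    evals = np.maximum(evals[order][:n_df], 0.0)
    W = evecs[:, order][:, :n_df]
    return W, evals, labels, means


def dfa(scores: np.ndarray, individuals: np.ndarray,
        component_names: list[str] | None = None) -> DFAModel:
    """Linear discriminant function analysis with individual as the group.

    Reports the percent of discriminative variance per function and the
    correlation of each discriminant function with each input component,
    flagged at |r| >= 0.5.
    """
    X = np.asarray(scores, dtype=float)
    individuals = np.asarray(individuals)
    labels, counts = np.unique(individuals, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two individuals")
    if counts.min() < 2:
        bad = labels[counts < 2]
        raise ValueError(f"groups with a single call: {list(bad)}")
    W, evals, glabels, gmeans = _fit_lda(X, individuals)
    total = evals.sum()
    pct = 100 * evals / total if total > 0 else np.full(len(evals), 100.0 / len(evals))
    df_scores = (X - X.mean(axis=0)) @ W
    names = component_names or [f"PC{i + 1}" for i in range(X.shape[1])]
    df_names = [f"DF{i + 1}" for i in range(W.shape[1])]
    corr = np.zeros((W.shape[1], X.shape[1]))
    for i in range(W.shape[1]):
        for j in range(X.shape[1]):
            with np.errstate(invalid="ignore"):
                corr[i, j] = np.corrcoef(df_scores[:, i], X[:, j])[0, 1]
    corr_df = pd.DataFrame(corr, index=df_names, columns=names)
    gm = pd.DataFrame((gmeans - X.mean(axis=0)) @ W, index=glabels, columns=df_names)
    return DFAModel(coefficients=W, percent_variance=pct, df_scores=df_scores,
                    df_pc_correlation=corr_df,
                    strong_correlations=corr_df.abs() >= 0.5,
                    group_means_df=gm)


# ---------------------------------------------------------------------------
# Nested pDFA


@dataclass
class PDFAResult:
    """Observed vs chance cross-classification of a nested permuted DFA."""

    observed_correct: float      # mean correct count over balanced selections
    expected_correct: float      # permutation mean of the same quantity
    percent_correct: float       # observed / n cross-classified, in percent
    chance_percent: float        # expected / n cross-classified, in percent
    p_value: float
    n_permutations: int
    n_selections: int
    n_crossclassified: int
    restriction_factor: str
    seed: int


def _mahalanobis_classify(X_train: np.ndarray, y_train: np.ndarray,
                          X_test: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Classify with pooled within-group covariance (equal priors).

    Equivalent to linear-DFA cross-classification: Mahalanobis distance to
    each group centroid under the pooled covariance; ties broken by the
    lowest group index.
    """
    labels = np.unique(y_train)
    d = X_train.shape[1]
    means = np.stack([X_train[y_train == g].mean(axis=0) for g in labels])
    Sw = np.zeros((d, d))
    for i, g in enumerate(labels):
        Xi = X_train[y_train == g] - means[i]
        Sw += Xi.T @ Xi
    Sw /= max(len(X_train) - len(labels), 1)
    Sw += ridge * np.eye(d)
    L = np.linalg.cholesky(Sw)
    Zt = linalg.solve_triangular(L, X_test.T, lower=True).T       # n x d
    Zm = linalg.solve_triangular(L, means.T, lower=True).T        # g x d
    d2 = ((Zt[:, None, :] - Zm[None, :, :]) ** 2).sum(axis=2)
    return labels[np.argmin(d2, axis=1)]


def _balanced_selection_correct(X: np.ndarray, index_matrix: np.ndarray,
                                derivation_n: int,
                                rng: np.random.Generator,
                                ridge: float = 1e-8) -> int:
    """One balanced selection on equal-count groups, fully vectorized.

    `index_matrix` is (g, c): row k holds the call indices of group k.
    """
    g, c = index_matrix.shape
    dn = derivation_n
    d = X.shape[1]
    perm = rng.permuted(index_matrix, axis=1)
    train = X[perm[:, :dn].ravel()].reshape(g, dn, d)
    test = X[perm[:, dn:].ravel()]
    means = train.mean(axis=1)
    resid = train - means[:, None, :]
    Sw = np.einsum("gnd,gne->de", resid, resid) / max(g * dn - g, 1)
    Sw += ridge * np.eye(d)
    L = np.linalg.cholesky(Sw)
    Zt = linalg.solve_triangular(L, test.T, lower=True).T
    Zm = linalg.solve_triangular(L, means.T, lower=True).T
    d2 = ((Zt[:, None, :] - Zm[None, :, :]) ** 2).sum(axis=2)
    pred = np.argmin(d2, axis=1)
    true = np.repeat(np.arange(g), c - dn)
    return int(np.sum(pred == true))


def _selection_averaged_correct(X: np.ndarray, individuals: np.ndarray,
                                ind_index: dict, derivation_n: int,
                                n_selections: int,
                                rng: np.random.Generator) -> tuple[float, int]:
    """Mean correct cross-classification count over balanced selections."""
    counts = []
    n_withheld = sum(len(v) - derivation_n for v in ind_index.values())
    sizes = {len(v) for v in ind_index.values()}
    if len(sizes) == 1:
        index_matrix = np.stack(list(ind_index.values()))
        for _ in range(n_selections):
            counts.append(_balanced_selection_correct(
                X, index_matrix, derivation_n, rng))
        return float(np.mean(counts)), n_withheld
    for _ in range(n_selections):
        train_idx, test_idx = [], []
        for ind, idx in ind_index.items():
            sel = rng.choice(idx, size=derivation_n, replace=False)
            train_idx.extend(sel)
            test_idx.extend(np.setdiff1d(idx, sel, assume_unique=True))
        train_idx = np.array(train_idx)
        test_idx = np.array(test_idx)
        pred = _mahalanobis_classify(X[train_idx], individuals[train_idx], X[test_idx])
        counts.append(np.sum(pred == individuals[test_idx]))
    return float(np.mean(counts)), n_withheld


def permute_within_levels(individuals: np.ndarray, restriction: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Shuffle the call-to-individual assignment within each restriction
    level, preserving per-individual call counts. Every permuted call keeps
    its original restriction label."""
    perm_ind = np.asarray(individuals).copy()
    for lev in np.unique(restriction):
        pos = np.where(restriction == lev)[0]
        perm_ind[pos] = perm_ind[pos][rng.permutation(len(pos))]
    return perm_ind


def nested_pdfa(scores: np.ndarray, individuals: np.ndarray,
                restriction: np.ndarray, n_permutations: int = 1000,
                n_selections: int = 100, seed: int = 0,
                derivation_fraction: float = 0.6,
                restriction_name: str = "restriction") -> PDFAResult:
    """Nested permuted discriminant function analysis.

    `restriction` gives each call's level of the restriction factor (every
    individual must map to exactly one level). The permutation null
    shuffles the call-to-individual assignment within each restriction
    level only, preserving per-individual call counts, so the test asks
    whether individual identity explains classification success beyond
    the restriction factor. The observed dataset counts as one of the
    `n_permutations`, so the smallest attainable p is 1/n_permutations.
    """
    X = np.asarray(scores, dtype=float)
    individuals = np.asarray(individuals)
    restriction = np.asarray(restriction)
    rng = np.random.default_rng(seed)

    ind_level: dict = {}
    for ind, lev in zip(individuals, restriction):
        if ind in ind_level and ind_level[ind] != lev:
            raise ValueError(f"individual {ind!r} maps to multiple restriction levels")
        ind_level[ind] = lev
    labels, counts = np.unique(individuals, return_counts=True)
    min_count = counts.min()
    derivation_n = max(2, int(np.floor(derivation_fraction * min_count)))
    if derivation_n >= min_count:
        raise ValueError(
            f"derivation size {derivation_n} leaves no withheld calls for the "
            f"smallest individual ({min_count} calls)")
    for lev in np.unique(restriction):
        inds_here = {i for i, l in ind_level.items() if l == lev}
        if len(inds_here) < 2:
            warnings.warn(f"restriction level {lev!r} has a single individual; "
                          "it contributes nothing to the null")

    def index_by_individual(ind_labels: np.ndarray) -> dict:
        return {g: np.where(ind_labels == g)[0] for g in labels}

    observed, n_cross = _selection_averaged_correct(
        X, individuals, index_by_individual(individuals), derivation_n,
        n_selections, rng)

    permuted_counts = [observed]
    for _ in range(n_permutations - 1):
        perm_ind = permute_within_levels(individuals, restriction, rng)
        count, _ = _selection_averaged_correct(
            X, perm_ind, index_by_individual(perm_ind), derivation_n,
            n_selections, rng)
        permuted_counts.append(count)
    permuted_counts = np.array(permuted_counts)
    p_value = float(np.mean(permuted_counts >= observed - 1e-12))
    # chance level from the true permutations (the observed value is counted
    # in the p-value denominator but would bias the chance estimate)
    expected = float(np.mean(permuted_counts[1:])) if n_permutations > 1 else observed
    return PDFAResult(
        observed_correct=observed, expected_correct=expected,
        percent_correct=100.0 * observed / n_cross,
        chance_percent=100.0 * expected / n_cross,
        p_value=p_value, n_permutations=n_permutations,
        n_selections=n_selections, n_crossclassified=n_cross,
        restriction_factor=restriction_name, seed=seed)
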