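"""Group-discrimination statistics for metabolite matrices.

Implements orthogonal projections to latent structures discriminant
analysis (OPLS-DA) with a single predictive component plus a configurable
number of orthogonal (class-uncorrelated) components, following the NIPALS
formulation: the predictive weight vector is the covariance direction
w = X'y / ||X'y||, orthogonal variation is peeled off as
w_o = p - (w'p) w before the final predictive fit.

Model quality is summarised by R2Y (explained class variance) and Q2
(k-fold cross-validated predictive fraction).  Validation follows the
conventional permutation protocol: the model is refit under random label
permutations and judged sound only if every permuted R2Y and Q2 falls
below the original values and the intercept of the Q2-versus-label-
correlation regression is negative.

Per-feature importance uses the standard VIP (variable importance in
projection) normalisation, mean(VIP^2) = 1, and differential features are
those with VIP > 1 and a Benjamini-Hochberg adjusted nonparametric p-value
(Mann-Whitney for two groups, Kruskal-Wallis for more) below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OplsModel",
    "PermutationReport",
    "oplsda_fit",
    "vip_scores",
    "permutation_test",
    "differential_select",
    "mannwhitney_fdr_select",
    "pca_scores",
]


@dataclass
class OplsModel:
    weights: np.ndarray  # predictive weight vector (p,)
    loadings: np.ndarray  # predictive loading vector (p,)
    scores: np.ndarray  # predictive scores (n,)
    ortho_weights: np.ndarray  # (n_ortho, p)
    ortho_loadings: np.ndarray  # (n_ortho, p)
    ortho_scores: np.ndarray  # (n, n_ortho)
    coef_y: float  # regression of centred y on predictive scores
    r2y: float
    q2: float
    vip: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    feature_names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class score for new samples (decision value)."""
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_scale
        for w_o, p_o in zip(self.ortho_weights, self.ortho_loadings):
            t_o = Xs @ w_o
            Xs = Xs - np.outer(t_o, p_o)
        t = Xs @ self.weights
        return self.y_mean + self.coef_y * t


@dataclass
class PermutationReport:
    n_perm: int
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    label_correlations: np.ndarray
    original_r2y: float
    original_q2: float
    q2_intercept: float
    r2y_intercept: float
    passed: bool


def _prepare(X, y):
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) aligned with y")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels are constant; OPLS-DA needs two classes")
    if classes.size == 2:
        counts = [(y == c).sum() for c in classes]
        if min(counts) < 2:
            raise ValueError("need >= 2 samples per class")
    return X, y


def _fit_core(Xs: np.ndarray, yc: np.ndarray, n_ortho: int):
    """O-PLS decomposition on already centred/scaled data.

    Returns (w, p, t, coef, W_o, P_o, T_o) for one predictive component.
    """
    Xd = Xs.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10:
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("degenerate X: no covariance with labels")
    w /= nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    coef = (t @ yc) / (t @ t)
    return w, p, t, coef, np.array(W_o), np.array(P_o), (
        np.column_stack(T_o) if T_o else np.zeros((Xs.shape[0], 0))
    )


def _scale_params(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return mean, scale


def _q2_cv(X, y, n_ortho: int, k: int, seed: int) -> float:
    n = y.size
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, min(k, n))
    press, tss = 0.0, 0.0
    y_mean_all = y.mean()
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        Xtr, ytr = X[mask], y[mask]
        if np.unique(ytr).size < 2:
            continue
        mean, scale = _scale_params(Xtr)
        Xs = (Xtr - mean) / scale
        yc = ytr - ytr.mean()
        try:
            w, p, t, coef, W_o, P_o, _ = _fit_core(Xs, yc, n_ortho)
        except ValueError:
            continue
        Xte = (X[fold] - mean) / scale
        for w_o, p_o in zip(W_o, P_o):
            t_o = Xte @ w_o
            Xte = Xte - np.outer(t_o, p_o)
        pred = ytr.mean() + coef * (Xte @ w)
        press += float(((y[fold] - pred) ** 2).sum())
        tss += float(((y[fold] - y_mean_all) ** 2).sum())
    return 1.0 - press / tss if tss > 0 else float("nan")


def oplsda_fit(
    X,
    y,
    n_ortho: int | None = 1,
    cv_folds: int = 7,
    seed: int = 0,
    feature_names=None,
) -> OplsModel:
    """Fit an OPLS-DA model with one predictive component.

    ``n_ortho=None`` grows orthogonal components greedily while cross-
    validated Q2 improves by more than 0.01.  Q2 comes from ``cv_folds``-fold
    cross-validation with the preprocessing (centring/scaling) refit inside
    each training fold.
    """
    X, y = _prepare(X, y)
    if n_ortho is None:
        best_k, best_q2 = 1, _q2_cv(X, y, 1, cv_folds, seed)
        for k_try in range(2, min(X.shape[1], 6)):
            q2 = _q2_cv(X, y, k_try, cv_folds, seed)
            if q2 > best_q2 + 0.01:
                best_k, best_q2 = k_try, q2
            else:
                break
        n_ortho = best_k

    mean, scale = _scale_params(X)
    Xs = (X - mean) / scale
    y_mean = y.mean()
    yc = y - y_mean
    w, p, t, coef, W_o, P_o, T_o = _fit_core(Xs, yc, n_ortho)
    fitted = coef * t
    r2y = 1.0 - float(((yc - fitted) ** 2).sum() / (yc**2).sum())
    q2 = _q2_cv(X, y, n_ortho, cv_folds, seed)
    vip = np.sqrt(X.shape[1]) * np.abs(w)  # single predictive component
    return OplsModel(
        weights=w,
        loadings=p,
        scores=t,
        ortho_weights=W_o,
        ortho_loadings=P_o,
        ortho_scores=T_o,
        coef_y=float(coef),
        r2y=r2y,
        q2=q2,
        vip=vip,
        x_mean=mean,
        x_scale=scale,
        y_mean=float(y_mean),
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def vip_scores(model: OplsModel) -> np.ndarray:
    """Variable importance in projection for the predictive component.

    With one predictive component VIP_j = sqrt(p) * |w_j| / ||w||, so the
    mean of squared VIP over features is exactly 1.
    """
    w = model.weights
    return np.sqrt(w.size) * np.abs(w) / np.linalg.norm(w)


def permutation_test(
    X, y, n_perm: int = 1000, seed: int = 0, n_ortho: int = 1, cv_folds: int = 7
) -> PermutationReport:
    """Label-permutation validation of an OPLS-DA model.

    The pass criterion requires every permuted R2Y and Q2 to fall below the
    original values and the intercept of the Q2 vs |label correlation|
    regression line (through the permuted points and the original at
    correlation 1) to be negative.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y = _prepare(X, y)
    rng = np.random.default_rng(seed)
    original = oplsda_fit(X, y, n_ortho=n_ortho, cv_folds=cv_folds, seed=seed)
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    corrs = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        corrs[i] = abs(float(np.corrcoef(y, yp)[0, 1])) if np.std(yp) > 0 else 0.0
        m = oplsda_fit(X, yp, n_ortho=n_ortho, cv_folds=cv_folds, seed=seed + 1 + i)
        r2s[i] = m.r2y
        q2s[i] = m.q2
    xs = np.concatenate([corrs, [1.0]])
    q2_line = np.polyfit(xs, np.concatenate([q2s, [original.q2]]), 1)
    r2_line = np.polyfit(xs, np.concatenate([r2s, [original.r2y]]), 1)
    passed = bool(
        (r2s < original.r2y).all() and (q2s < original.q2).all() and q2_line[1] < 0
    )
    return PermutationReport(
        n_perm=n_perm,
        permuted_r2y=r2s,
        permuted_q2=q2s,
        label_correlations=corrs,
        original_r2y=original.r2y,
        original_q2=original.q2,
        q2_intercept=float(q2_line[1]),
        r2y_intercept=float(r2_line[1]),
        passed=passed,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (delegated)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def _group_pvalues(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    labels = np.unique(groups)
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        samples = [X[groups == g, j] for g in labels]
        if len(labels) == 2:
            res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        else:
            res = stats.kruskal(*samples)
        pvals[j] = res.pvalue
    return pvals


def differential_select(
    X, groups, vip=None, fdr: float = 0.05, vip_cutoff: float = 1.0, feature_names=None
) -> pd.DataFrame:
    """Differential features: VIP > cutoff AND BH-FDR-adjusted nonparametric
    p < fdr.  Returns a frame with p, adjusted p, VIP, log2 fold change and
    its sign (first vs second group level)."""
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    if vip is None:
        y = (groups == np.unique(groups)[-1]).astype(float)
        vip = vip_scores(oplsda_fit(X, y))
    vip = np.asarray(vip, float)
    pvals = _group_pvalues(X, groups)
    _, p_adj, *_ = multipletests(pvals, method="fdr_bh")
    labels = np.unique(groups)
    mean_a = X[groups == labels[0]].mean(axis=0)
    mean_b = X[groups == labels[-1]].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(np.abs(mean_b) / np.abs(mean_a))
    names = (
        list(feature_names) if feature_names is not None else [f"f{j}" for j in range(X.shape[1])]
    )
    out = pd.DataFrame(
        {
            "feature": names,
            "vip": vip,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "log2fc": log2fc,
            "direction": np.sign(mean_b - mean_a),
        }
    )
    out["selected"] = (out.vip > vip_cutoff) & (out.p_adjusted < fdr)
    return out


def mannwhitney_fdr_select(matrix: pd.DataFrame, groups, fdr: float = 0.05) -> list[str]:
    """Normalisation-robustness selection rule: BH-FDR Mann-Whitney only
    (no VIP gate), returning selected feature names."""
    X = matrix.to_numpy(float)
    pvals = _group_pvalues(X, np.asarray(groups))
    _, p_adj, *_ = multipletests(pvals, method="fdr_bh")
    return [c for c, p in zip(matrix.columns, p_adj) if p < fdr]


def pca_scores(X, n_components: int = 2):
    """PCA scores/loadings via SVD on the column-centred matrix (delegated
    linear algebra; provided for score-plot parity with the OPLS-DA view)."""
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    scores = U[:, :k] * S[:k]
    explained = (S**2) / (S**2).sum()
    return scores, Vt[:k], explained[:k]
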