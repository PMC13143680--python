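"""Construction and evaluation of the multi-modal DKD classifier tiers.

Three nested model tiers are compared for discriminating established kidney
disease from diabetes without kidney disease:

* clinical base — age, BMI, HbA1c, systolic blood pressure;
* metabolomics-enhanced — base plus serum-to-urine flux ratios of the
  protein-bound uremic toxins and C8-acylcarnitine;
* fusion — flux ratios plus the digital urine phenotypes (foam half-life,
  yellowness b*) alongside the clinical metrics (eight predictors).

Feature selection (random-forest recursive feature elimination driven by
permutation importance) is embedded strictly inside the training folds of a
repeated stratified cross-validation, so the held-out folds never inform
selection.  Discrimination is summarised by apparent and cross-validated
AUC with fast-DeLong confidence intervals; absolute risk by Hosmer-Lemeshow
goodness of fit, logistic recalibration slope/intercept and the Brier
score; incremental value by category-free NRI and IDI with bootstrap CIs;
and clinical utility by decision-curve net benefit.  A points-based
nomogram is derived from a parallel additive logistic fit on the selected
predictors.  The Riley shrinkage-based minimum-sample-size formula, the
events-per-variable ratio and the Hanley-McNeil AUC standard error round
out the design calculators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

__all__ = [
    "ModelTier",
    "ModelReport",
    "Nomogram",
    "CLINICAL_TIER",
    "METABOLOMICS_TIER",
    "FUSION_TIER",
    "build_feature_table",
    "rfe_select",
    "nested_cv_evaluate",
    "delong_auc",
    "auc_delong_ci",
    "calibration_assess",
    "nri_idi",
    "decision_curve",
    "build_nomogram",
    "fit_logistic_nomogram",
    "epv",
    "riley_min_n",
    "hanley_se_auc",
]


@dataclass(frozen=True)
class ModelTier:
    name: str
    feature_list: tuple[str, ...]

    def __post_init__(self):
        if not self.feature_list:
            raise ValueError("feature list must be non-empty")


CLINICAL_FEATURES = ("age", "bmi", "hba1c_pct", "sbp")
FLUX_FEATURES = (
    "flux_indoxyl_sulfate",
    "flux_c8_carnitine",
    "flux_phenylacetylglutamine",
)
PHYSICALOMICS_FEATURES = ("t_half_s", "b_star")

CLINICAL_TIER = ModelTier("clinical", CLINICAL_FEATURES)
METABOLOMICS_TIER = ModelTier("metabolomics", CLINICAL_FEATURES + FLUX_FEATURES)
FUSION_TIER = ModelTier(
    "fusion", ("bmi", "hba1c_pct", "sbp") + FLUX_FEATURES + PHYSICALOMICS_FEATURES
)


def build_feature_table(cohort: pd.DataFrame, flux_values: pd.DataFrame) -> pd.DataFrame:
    """Merge clinical covariates, measured physicalomics and flux ratios into
    one modelling frame (indexed by subject) with a binary ``label`` column:
    1 = DKD, 0 = diabetes without kidney disease.  Healthy controls are
    excluded from the classification task."""
    sub = cohort[cohort["group"].isin(["T2DM-NoDKD", "DKD"])].set_index("subject_id")
    out = sub[["age", "bmi", "hba1c_pct", "sbp"]].copy()
    # measured (noisy) optical features stand in for the extracted values
    out["t_half_s"] = sub["t_half_s_meas"]
    out["b_star"] = sub["b_star_meas"]
    flux = flux_values.reindex(out.index)
    for met in ("indoxyl_sulfate", "c8_carnitine", "phenylacetylglutamine"):
        if met in flux.columns:
            out[f"flux_{met}"] = flux[met]
    out["label"] = (sub["group"] == "DKD").astype(int)
    return out.dropna()


# --- Feature selection --------------------------------------------------------


def _forest(seed: int, n_estimators: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, min_samples_leaf=2
    )


def rfe_select(
    X: pd.DataFrame,
    y,
    n_keep: int,
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
    drop_frac: float = 0.2,
    perm_repeats: int = 3,
):
    """Recursive feature elimination with a random-forest learner.

    Each round fits forests on the training side of ``cv_folds`` stratified
    inner folds, scores features by permutation importance on the
    corresponding validation side, averages across folds, and drops the
    lowest-scoring ``drop_frac`` of remaining features.  Constant features
    are dropped first with a warning.  Returns ``(ranking, selected)`` where
    ``ranking`` lists all features best-first.
    """
    y = np.asarray(y)
    if n_keep > X.shape[1]:
        raise ValueError("n_keep exceeds the number of features")
    remaining = list(X.columns)
    eliminated: list[str] = []

    const = [c for c in remaining if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant features first: {const}")
        for c in const:
            remaining.remove(c)
        eliminated.extend(const)
        if len(remaining) < n_keep:
            raise ValueError("too few non-constant features for n_keep")

    round_no = 0
    importances = pd.Series(dtype=float)
    while True:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + round_no)
        imp = np.zeros(len(remaining))
        Xr = X[remaining].to_numpy()
        for f, (tr, va) in enumerate(skf.split(Xr, y)):
            rf = _forest(seed * 1000 + round_no * 10 + f, n_estimators)
            rf.fit(Xr[tr], y[tr])
            res = permutation_importance(
                rf, Xr[va], y[va], n_repeats=perm_repeats,
                random_state=seed + round_no * 100 + f, n_jobs=1,
            )
            imp += res.importances_mean
        imp /= cv_folds
        importances = pd.Series(imp, index=remaining)
        if len(remaining) <= n_keep:
            break
        n_drop = min(
            max(1, int(math.floor(drop_frac * len(remaining)))),
            len(remaining) - n_keep,
        )
        order = importances.sort_values(kind="stable")
        victims = list(order.index[:n_drop])
        for v in victims:
            remaining.remove(v)
        eliminated = victims[::-1] + eliminated
        round_no += 1

    ranking = list(importances.sort_values(ascending=False, kind="stable").index)
    ranking += eliminated
    return ranking, list(importances.sort_values(ascending=False, kind="stable").index[:n_keep])


# --- Discrimination -----------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_cov(preds: np.ndarray, y: np.ndarray):
    """Fast DeLong AUCs and covariance matrix for k correlated predictors."""
    pos = preds[:, y == 1]
    neg = preds[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    k = preds.shape[0]
    aucs = np.empty(k)
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


def auc_delong_ci(pred, y, alpha: float = 0.05):
    """AUC with a DeLong confidence interval: ``(auc, (lo, hi))``."""
    pred = np.asarray(pred, float)
    y = np.asarray(y).astype(int)
    aucs, cov = _delong_cov(pred.reshape(1, -1), y)
    se = math.sqrt(max(cov[0, 0], 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(aucs[0]), (
        float(np.clip(aucs[0] - z * se, 0, 1)),
        float(np.clip(aucs[0] + z * se, 0, 1)),
    )


def delong_auc(pred_a, pred_b, y):
    """Compare two correlated AUCs on the same subjects (DeLong test).

    Returns ``(auc_a, auc_b, ci_a, ci_b, p_diff)``.
    """
    pred_a = np.asarray(pred_a, float)
    pred_b = np.asarray(pred_b, float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("need both classes in y")
    aucs, cov = _delong_cov(np.vstack([pred_a, pred_b]), y)
    z975 = stats.norm.ppf(0.975)
    cis = []
    for r in range(2):
        se = math.sqrt(max(cov[r, r], 0.0))
        cis.append(
            (float(np.clip(aucs[r] - z975 * se, 0, 1)), float(np.clip(aucs[r] + z975 * se, 0, 1)))
        )
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-16:
        p = 1.0 if abs(aucs[0] - aucs[1]) < 1e-12 else 0.0
    else:
        zstat = (aucs[0] - aucs[1]) / math.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(zstat)))
    return float(aucs[0]), float(aucs[1]), cis[0], cis[1], p


# --- Calibration --------------------------------------------------------------


def calibration_assess(pred, y, n_groups: int = 10) -> dict:
    """Hosmer-Lemeshow deciles, logistic recalibration slope/intercept and
    Brier score on (out-of-fold) predicted probabilities."""
    pred = np.asarray(pred, float)
    y = np.asarray(y, float)
    if ((pred <= 0) | (pred >= 1)).any():
        pred = np.clip(pred, 1e-6, 1 - 1e-6)
    brier = float(np.mean((pred - y) ** 2))

    df = pd.DataFrame({"pred": pred, "y": y})
    try:
        df["g"] = pd.qcut(df["pred"], q=n_groups, duplicates="drop", labels=False)
    except ValueError:
        df["g"] = 0
    grouped = df.groupby("g")
    sizes = grouped.size()
    if (sizes == 0).any() or len(sizes) < 3:
        hl_chi2, hl_p, dof = 0.0, float("nan"), 0
        if len(sizes) >= 3:
            warnings.warn("degenerate calibration groups merged")
    else:
        obs = grouped["y"].sum()
        exp = grouped["pred"].sum()
        n_g = sizes.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (obs - exp) ** 2 / exp + ((n_g - obs) - (n_g - exp)) ** 2 / (n_g - exp)
        hl_chi2 = float(np.nansum(terms.replace([np.inf, -np.inf], np.nan)))
        dof = max(len(sizes) - 2, 1)
        hl_p = float(stats.chi2.sf(hl_chi2, dof))

    logit_p = np.log(pred / (1 - pred))
    import statsmodels.api as sm

    try:
        fit = sm.Logit(y, sm.add_constant(logit_p)).fit(disp=0)
        intercept, slope = (float(v) for v in fit.params)
    except Exception:  # perfect separation etc.
        intercept, slope = float("nan"), float("nan")
    return {
        "hl_chi2": hl_chi2,
        "hl_p": hl_p,
        "hl_dof": dof,
        "slope": slope,
        "intercept": intercept,
        "brier": brier,
    }


# --- Reclassification & decision curves --------------------------------------


def nri_idi(pred_old, pred_new, y, n_boot: int = 1000, seed: int = 0):
    """Category-free (continuous) NRI and IDI with bootstrap CIs.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)];
    IDI = (mean_new - mean_old | events) - (mean_new - mean_old | nonevents).
    """
    po = np.asarray(pred_old, float)
    pn = np.asarray(pred_new, float)
    y = np.asarray(y).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need both events and nonevents")

    def _stats(po, pn, y):
        ev, ne = y == 1, y == 0
        up, down = pn > po, pn < po
        nri = (up[ev].mean() - down[ev].mean()) + (down[ne].mean() - up[ne].mean())
        idi = (pn[ev] - po[ev]).mean() - (pn[ne] - po[ne]).mean()
        return float(nri), float(idi)

    nri, idi = _stats(po, pn, y)
    rng = np.random.default_rng(seed)
    boots = []
    n = y.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].sum() in (0, n):
            continue
        boots.append(_stats(po[idx], pn[idx], y[idx]))
    boots = np.array(boots) if boots else np.array([[nri, idi]])
    nri_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
    idi_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    return {"nri": nri, "nri_ci": nri_ci, "idi": idi, "idi_ci": idi_ci}


def decision_curve(pred, y, thresholds) -> pd.DataFrame:
    """Net benefit NB(tau) = TP/N - (FP/N) * tau/(1-tau) for the model,
    treat-all and treat-none strategies."""
    pred = np.asarray(pred, float)
    y = np.asarray(y).astype(int)
    thresholds = np.asarray(thresholds, float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie in (0, 1)")
    n = y.size
    prev = y.mean()
    rows = []
    for tau in thresholds:
        treat = pred >= tau
        tp = float((treat & (y == 1)).sum()) / n
        fp = float((treat & (y == 0)).sum()) / n
        w = tau / (1 - tau)
        rows.append(
            {
                "threshold": tau,
                "nb_model": tp - fp * w,
                "nb_all": prev - (1 - prev) * w,
                "nb_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# --- Nested cross-validated evaluation ----------------------------------------


@dataclass
class ModelReport:
    tier: str
    features: list[str]
    apparent_auc: float
    apparent_auc_ci: tuple[float, float]
    cv_auc: float
    cv_auc_ci: tuple[float, float]
    optimism: float
    calibration: dict
    oof_pred: np.ndarray
    apparent_pred: np.ndarray
    y: np.ndarray
    selected_per_fold: list[list[str]] = field(default_factory=list)
    subgroup_aucs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.optimism < -0.02:
            warnings.warn(
                f"negative optimism ({self.optimism:.3f}): apparent AUC below cross-validated"
            )


def nested_cv_evaluate(
    X: pd.DataFrame,
    y,
    tier: ModelTier | None = None,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    n_select: int | None = None,
    n_estimators: int = 500,
    rfe_inner_folds: int = 5,
    subgroups: dict | None = None,
) -> ModelReport:
    """Repeated stratified k-fold evaluation of one model tier.

    Out-of-fold probabilities are pooled (averaged across repeats per
    subject) for the cross-validated AUC and calibration; the apparent AUC
    comes from refitting on the full data.  When ``n_select`` is given,
    RF-RFE feature selection runs inside every outer training fold only.
    """
    y = np.asarray(y).astype(int)
    feats = list(tier.feature_list) if tier is not None else list(X.columns)
    missing = [f for f in feats if f not in X.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    Xt = X[feats].reset_index(drop=True)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError("a class is too small to stratify into the requested folds")

    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    oof_sum = np.zeros(y.size)
    oof_cnt = np.zeros(y.size)
    selected_per_fold = []
    for f, (tr, te) in enumerate(rskf.split(Xt, y)):
        cols = feats
        if n_select is not None and n_select < len(feats):
            _, cols = rfe_select(
                Xt.iloc[tr], y[tr], n_select, cv_folds=rfe_inner_folds,
                seed=seed + 7919 * f, n_estimators=n_estimators,
            )
            selected_per_fold.append(cols)
        rf = _forest(seed + f, n_estimators)
        rf.fit(Xt.iloc[tr][cols], y[tr])
        oof_sum[te] += rf.predict_proba(Xt.iloc[te][cols])[:, 1]
        oof_cnt[te] += 1
    oof = oof_sum / np.maximum(oof_cnt, 1)

    cols = feats
    if n_select is not None and n_select < len(feats):
        _, cols = rfe_select(
            Xt, y, n_select, cv_folds=rfe_inner_folds, seed=seed, n_estimators=n_estimators
        )
    rf_full = _forest(seed, n_estimators)
    rf_full.fit(Xt[cols], y)
    apparent = rf_full.predict_proba(Xt[cols])[:, 1]

    app_auc, app_ci = auc_delong_ci(apparent, y)
    cv_auc, cv_ci = auc_delong_ci(oof, y)
    calib = calibration_assess(oof, y)
    sub_aucs = {}
    if subgroups:
        for name, mask in subgroups.items():
            mask = np.asarray(mask, bool)
            if np.unique(y[mask]).size == 2:
                sub_aucs[name] = auc_delong_ci(oof[mask], y[mask])[0]
    return ModelReport(
        tier=tier.name if tier else "custom",
        features=feats,
        apparent_auc=app_auc,
        apparent_auc_ci=app_ci,
        cv_auc=cv_auc,
        cv_auc_ci=cv_ci,
        optimism=app_auc - cv_auc,
        calibration=calib,
        oof_pred=oof,
        apparent_pred=apparent,
        y=y,
        selected_per_fold=selected_per_fold,
        subgroup_aucs=sub_aucs,
    )


# --- Nomogram -----------------------------------------------------------------


@dataclass
class Nomogram:
    """Points-based rendering of an additive logistic model.

    Each feature earns ``scale * beta_j * (value - ref_j)`` points, with the
    reference at the minimum (positive coefficient) or maximum (negative) of
    the training range so points are non-negative; the widest-range feature
    spans 100 points.  Total points map back to probability through the
    linear predictor, so the round trip to the direct logistic prediction is
    exact up to floating point.
    """

    intercept: float
    coefs: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    scale: float
    base_lp: float

    def points(self, feature: str, value: float) -> float:
        beta = self.coefs[feature]
        lo, hi = self.ranges[feature]
        ref = lo if beta >= 0 else hi
        return self.scale * beta * (value - ref)

    def total_points(self, x: dict | pd.Series) -> float:
        return float(sum(self.points(f, x[f]) for f in self.coefs))

    def probability(self, total_points: float) -> float:
        lp = self.base_lp + total_points / self.scale
        return float(1.0 / (1.0 + math.exp(-lp)))

    def predict(self, x: dict | pd.Series) -> float:
        return self.probability(self.total_points(x))


def fit_logistic_nomogram(X: pd.DataFrame, y):
    """Additive logistic fit (statsmodels, L-BFGS fallback to regularised)
    returning ``(results, Nomogram)``."""
    import statsmodels.api as sm

    exog = sm.add_constant(X.astype(float))
    model = sm.Logit(np.asarray(y, float), exog)
    try:
        res = model.fit(disp=0, maxiter=200)
        params = res.params
    except Exception:
        res = model.fit_regularized(alpha=1e-4, disp=0)
        params = res.params
    coefs = {c: float(params[c]) for c in X.columns}
    ranges = {c: (float(X[c].min()), float(X[c].max())) for c in X.columns}
    return res, build_nomogram(float(params["const"]), coefs, ranges)


def build_nomogram(intercept: float, coefs: dict, ranges: dict) -> Nomogram:
    """Map an additive logistic model to a 0-100 point scale."""
    spans = {}
    for f, beta in coefs.items():
        lo, hi = ranges[f]
        if hi <= lo:
            raise ValueError(f"zero-range feature {f!r}")
        spans[f] = abs(beta) * (hi - lo)
    widest = max(spans.values())
    if widest <= 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    scale = 100.0 / widest
    base_lp = intercept + sum(
        beta * (ranges[f][0] if beta >= 0 else ranges[f][1]) for f, beta in coefs.items()
    )
    return Nomogram(intercept=intercept, coefs=dict(coefs), ranges=dict(ranges),
                    scale=scale, base_lp=base_lp)


def plot_nomogram(nomogram: Nomogram, path):
    """Render the point scales to a PNG (reporting plumbing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = list(nomogram.coefs)
    fig, ax = plt.subplots(figsize=(7, 0.6 * len(feats) + 1.5))
    for i, f in enumerate(feats):
        lo, hi = nomogram.ranges[f]
        pts = sorted([nomogram.points(f, lo), nomogram.points(f, hi)])
        ax.plot(pts, [i, i], lw=2)
        ax.annotate(f"{lo:g}", (pts[0], i), textcoords="offset points", xytext=(0, 4))
        ax.annotate(f"{hi:g}", (pts[1], i), textcoords="offset points", xytext=(0, 4))
    ax.set_yticks(range(len(feats)), feats)
    ax.set_xlabel("points")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --- Sample-size calculators --------------------------------------------------


def epv(n_events: int, n_predictors: int) -> float:
    """Events per variable."""
    if n_predictors <= 0:
        raise ValueError("n_predictors must be > 0")
    return n_events / n_predictors


def riley_min_n(p: int, r2cs: float, s: float) -> int:
    """Minimum sample size for a target global shrinkage factor ``s``:
    n = p / ((s - 1) * ln(1 - r2cs / s)), rounded up."""
    if not 0 < s < 1:
        raise ValueError("shrinkage target s must lie in (0, 1)")
    if not 0 < r2cs < s:
        raise ValueError("need 0 < r2cs < s")
    n = p / ((s - 1.0) * math.log(1.0 - r2cs / s))
    return int(math.ceil(n))


def hanley_se_auc(auc: float, n1: int, n2: int) -> float:
    """Hanley-McNeil standard error of an AUC with n1 cases / n2 controls."""
    if not 0 < auc < 1:
        raise ValueError("auc must lie in (0, 1)")
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one case and one control")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)
    ) / (n1 * n2)
    return math.sqrt(var)
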