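"""Serum-to-urine metabolic flux ratios.

Transforms paired serum/urine concentration panels into a matrix of
log10 double-creatinine-normalised flux ratios,

    flux = log10( (C_serum_met / C_serum_creat) / (C_urine_met / C_urine_creat) ),

a dimensionless readout of renal secretory handling: high values mean a
metabolite accumulates systemically while its urinary excretion lags
(tubular secretory failure), independently of hydration status because
uniform dilution of either fluid cancels exactly.

The preprocessing contract mirrors common targeted-metabolomics practice:
metabolites missing in >20% of samples in either fluid are dropped,
missing-at-random values are KNN-imputed, and below-LOD (censored) values
are set to LOD/2 so the log transform stays finite.  Censoring and
missingness are tracked separately throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PairedPanel",
    "FluxRatioMatrix",
    "filter_missingness",
    "knn_impute",
    "impute_lod",
    "flux_ratio",
    "pqn_normalize",
    "tus_normalize",
    "normalization_concordance",
]


@dataclass
class PairedPanel:
    """Per-subject serum + urine metabolite concentrations (umol/L).

    ``serum`` / ``urine`` are subjects x metabolites frames; NaN entries are
    either missing-at-random (censored flag False) or below-LOD censored
    (censored flag True).  Creatinine is carried separately and must be
    observed and strictly positive for every subject.
    """

    serum: pd.DataFrame
    urine: pd.DataFrame
    serum_censored: pd.DataFrame
    urine_censored: pd.DataFrame
    serum_creatinine: pd.Series
    urine_creatinine: pd.Series
    lod: pd.DataFrame  # index: metabolite, columns: ["serum", "urine"]

    def __post_init__(self) -> None:
        if not self.serum.columns.equals(self.urine.columns):
            raise ValueError("serum and urine panels must share metabolites")
        if not self.serum.index.equals(self.urine.index):
            raise ValueError("serum and urine panels must share subjects")
        for creat in (self.serum_creatinine, self.urine_creatinine):
            if creat.isna().any() or (creat <= 0).any():
                raise ValueError("creatinine must be present and > 0 for every subject")

    @property
    def metabolites(self) -> list[str]:
        return list(self.serum.columns)

    @property
    def subjects(self) -> pd.Index:
        return self.serum.index

    def copy(self) -> "PairedPanel":
        return PairedPanel(
            self.serum.copy(),
            self.urine.copy(),
            self.serum_censored.copy(),
            self.urine_censored.copy(),
            self.serum_creatinine.copy(),
            self.urine_creatinine.copy(),
            self.lod.copy(),
        )


@dataclass
class FluxRatioMatrix:
    """Subjects x metabolites log10 flux ratios with imputation provenance."""

    values: pd.DataFrame
    lod_imputed: pd.DataFrame = field(default_factory=pd.DataFrame)
    knn_imputed: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("flux ratio matrix must contain finite entries only")


def _missing_mask(values: pd.DataFrame, censored: pd.DataFrame) -> pd.DataFrame:
    # NaN and not censored => missing at random; censored NaNs are handled by LOD/2
    return values.isna() & ~censored.astype(bool)


def filter_missingness(panel: PairedPanel, threshold: float = 0.20):
    """Drop metabolites whose MAR-missing fraction strictly exceeds ``threshold``
    in either biofluid.  Returns ``(filtered_panel, dropped_names)``.
    """
    frac_serum = _missing_mask(panel.serum, panel.serum_censored).mean(axis=0)
    frac_urine = _missing_mask(panel.urine, panel.urine_censored).mean(axis=0)
    dropped = [
        m
        for m in panel.metabolites
        if frac_serum[m] > threshold or frac_urine[m] > threshold
    ]
    keep = [m for m in panel.metabolites if m not in dropped]
    filtered = PairedPanel(
        panel.serum[keep].copy(),
        panel.urine[keep].copy(),
        panel.serum_censored[keep].copy(),
        panel.urine_censored[keep].copy(),
        panel.serum_creatinine.copy(),
        panel.urine_creatinine.copy(),
        panel.lod.loc[panel.lod.index.intersection(keep)].copy(),
    )
    return filtered, dropped


def _knn_impute_fluid(
    values: pd.DataFrame, censored: pd.DataFrame, k: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute MAR-missing entries of one fluid by the mean of the k nearest
    subjects (Euclidean distance on log10, z-scored features observed in both
    subjects).  Ties in distance break by subject order for determinism.
    """
    out = values.copy()
    missing = _missing_mask(values, censored)
    if not missing.to_numpy().any():
        return out, missing

    logv = np.log10(values.where(values > 0))
    z = (logv - logv.mean(axis=0)) / logv.std(axis=0, ddof=0).replace(0.0, 1.0)
    zmat = z.to_numpy()
    n = len(values)
    obs = ~np.isnan(zmat)

    for j, met in enumerate(values.columns):
        targets = np.flatnonzero(missing[met].to_numpy())
        if targets.size == 0:
            continue
        donors = np.flatnonzero(obs[:, j] & values[met].notna().to_numpy())
        if donors.size == 0:
            raise ValueError(f"no complete neighbours available for {met!r}")
        for i in targets:
            # distance over features observed in both subject i and each donor
            diffs = zmat[donors] - zmat[i]
            shared = obs[donors] & obs[i]
            shared[:, j] = False  # the target feature itself never enters
            with np.errstate(invalid="ignore"):
                sq = np.where(shared, diffs**2, 0.0)
            counts = shared.sum(axis=1)
            dist = np.sqrt(np.where(counts > 0, sq.sum(axis=1) / counts, np.inf))
            order = np.lexsort((donors, dist))
            chosen = donors[order][: min(k, donors.size)]
            out.iloc[i, j] = float(values[met].to_numpy()[chosen].mean())
    return out, missing


def knn_impute(panel: PairedPanel, k: int = 5):
    """KNN-impute missing-at-random entries per fluid.

    Returns ``(panel, knn_flags)`` where ``knn_flags`` is a dict with boolean
    frames per fluid marking imputed cells.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    serum, flag_s = _knn_impute_fluid(panel.serum, panel.serum_censored, k)
    urine, flag_u = _knn_impute_fluid(panel.urine, panel.urine_censored, k)
    new = panel.copy()
    new.serum, new.urine = serum, urine
    return new, {"serum": flag_s, "urine": flag_u}


def impute_lod(panel: PairedPanel):
    """Replace below-LOD censored entries with LOD/2, flagging them.

    Returns ``(panel, lod_flags)``; raises if a censored entry has no LOD.
    """
    new = panel.copy()
    flags = {}
    for fluid in ("serum", "urine"):
        values: pd.DataFrame = getattr(new, fluid)
        censored: pd.DataFrame = getattr(new, f"{fluid}_censored").astype(bool)
        for met in values.columns:
            col_cens = censored[met]
            if col_cens.any():
                if met not in new.lod.index or not np.isfinite(new.lod.loc[met, fluid]):
                    raise ValueError(f"censored entries of {met!r} ({fluid}) have no LOD")
                values.loc[col_cens, met] = new.lod.loc[met, fluid] / 2.0
        flags[fluid] = censored.copy()
    return new, flags


def flux_ratio(panel: PairedPanel) -> FluxRatioMatrix:
    """Compute the log10 double-creatinine-normalised serum-to-urine flux ratio.

    Requires a fully imputed panel (no missing, no censored NaNs).
    """
    for fluid in ("serum", "urine"):
        values: pd.DataFrame = getattr(panel, fluid)
        if values.isna().to_numpy().any():
            raise ValueError("panel must be imputed before computing flux ratios")
        if (values <= 0).to_numpy().any():
            raise ValueError("zero/negative concentration encountered post-imputation")
    serum_q = panel.serum.div(panel.serum_creatinine, axis=0)
    urine_q = panel.urine.div(panel.urine_creatinine, axis=0)
    values = np.log10(serum_q / urine_q)
    return FluxRatioMatrix(
        values=values,
        lod_imputed=(panel.serum_censored.astype(bool) | panel.urine_censored.astype(bool)),
        knn_imputed=pd.DataFrame(False, index=values.index, columns=values.columns),
    )


def flux_pipeline(panel: PairedPanel, missing_threshold: float = 0.20, k: int = 5):
    """Full preprocessing chain: missingness filter -> KNN -> LOD/2 -> ratio.

    Returns ``(FluxRatioMatrix, dropped_metabolites)``.
    """
    filtered, dropped = filter_missingness(panel, missing_threshold)
    imputed, knn_flags = knn_impute(filtered, k=k)
    complete, lod_flags = impute_lod(imputed)
    matrix = flux_ratio(complete)
    matrix.knn_imputed = knn_flags["serum"] | knn_flags["urine"]
    matrix.lod_imputed = lod_flags["serum"] | lod_flags["urine"]
    return matrix, dropped


def pqn_normalize(matrix: pd.DataFrame, reference: pd.Series | None = None):
    """Probabilistic quotient normalisation.

    ``reference`` defaults to the per-feature median spectrum of the matrix
    itself (the QC-pool stand-in).  Each sample is divided by the median of
    its feature-wise quotients against the reference.

    Returns ``(normalised, dilution_factors)``.
    """
    if reference is None:
        reference = matrix.median(axis=0)
    reference = reference.reindex(matrix.columns)
    usable = reference > 0
    if not usable.any():
        raise ValueError("reference spectrum must be strictly positive somewhere")
    quotients = matrix.loc[:, usable].div(reference[usable], axis=1)
    factors = quotients.median(axis=1)
    if (factors <= 0).any() or factors.isna().any():
        raise ValueError("all-zero or invalid sample encountered in PQN")
    return matrix.div(factors, axis=0), factors


def tus_normalize(matrix: pd.DataFrame, urine_creatinine: pd.Series) -> pd.DataFrame:
    """Creatinine-adjusted total-useful-signal normalisation.

    The per-sample dilution factor is the geometric mean of two dilution
    estimates — total retained-feature signal and urinary creatinine, each
    relative to its cohort median — so a uniformly diluted sample (signal and
    creatinine jointly scaled by k) normalises identically to the undiluted
    one.
    """
    creat = urine_creatinine.reindex(matrix.index)
    if (creat <= 0).any() or creat.isna().any():
        raise ValueError("urinary creatinine must be > 0 for every sample")
    total = matrix.sum(axis=1)
    if (total <= 0).any():
        raise ValueError("zero total signal encountered")
    factor = np.sqrt((total / total.median()) * (creat / creat.median()))
    return matrix.div(factor, axis=0)


def normalization_concordance(mat_a: pd.DataFrame, mat_b: pd.DataFrame, groups, selector=None):
    """Feature-selection overlap between two normalisations of the same matrix.

    Runs the differential-selection rule (Mann-Whitney + BH-FDR < 0.05 by
    default) on both matrices and returns
    ``(jaccard, overlap_vs_a, overlap_vs_b, selected_a, selected_b)``.
    """
    if not mat_a.columns.equals(mat_b.columns):
        raise ValueError("matrices must share the same feature universe")
    if selector is None:
        from .multivariate import mannwhitney_fdr_select

        selector = mannwhitney_fdr_select
    sel_a = set(selector(mat_a, groups))
    sel_b = set(selector(mat_b, groups))
    union = sel_a | sel_b
    if not union:
        raise ValueError("empty selection under both normalisations; overlap undefined")
    inter = sel_a & sel_b
    jacc = len(inter) / len(union)
    ov_a = len(inter) / len(sel_a) if sel_a else float("nan")
    ov_b = len(inter) / len(sel_b) if sel_b else float("nan")
    return jacc, ov_a, ov_b, sorted(sel_a), sorted(sel_b)
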