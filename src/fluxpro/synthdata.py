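"""Synthetic cohorts, paired metabolite panels and outcome histories.

The generator emulates a three-group diabetic-kidney-disease study design
(healthy controls, type-2 diabetes without kidney disease, established DKD)
so that every downstream operator — image feature extraction, flux-ratio
preprocessing, multivariate statistics, model evaluation, prognosis — can be
tested against known ground truth without any external data.

Marginals follow the published baseline table of the emulated design: normal
for symmetric variables (mean +- SD), log-normal for skewed ones (median and
IQR, with the IQR assumed symmetric on the log scale).  Cross-variable
structure is induced through a Gaussian copula on latent normals; correlation
targets are therefore defined — and reproduced exactly, up to sampling noise
— on the latent scale, i.e. on log-transformed values for the log-normal
variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fluxomics import PairedPanel

__all__ = [
    "GROUPS",
    "Marginal",
    "CorrelationTarget",
    "CohortConfig",
    "FluxEffectConfig",
    "MetaboliteParams",
    "OutcomeConfig",
    "default_cohort_config",
    "default_flux_effects",
    "default_outcome_config",
    "generate_cohort",
    "generate_metabolite_panel",
    "generate_outcomes",
    "group_location_summary",
    "attained_latent_correlations",
]

GROUPS = ("HC", "T2DM-NoDKD", "DKD")

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


@dataclass(frozen=True)
class Marginal:
    """One variable's marginal distribution for a single group.

    ``dist`` is "normal" (loc=mean, scale=SD) or "lognormal" (loc=median,
    with ``iqr`` = (q1, q3) setting the log-scale SD).
    """

    dist: str
    loc: float
    scale: float = 0.0
    iqr: tuple[float, float] | None = None

    def __post_init__(self):
        if self.dist not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.dist == "normal" and self.scale <= 0:
            raise ValueError("normal marginal needs SD > 0")
        if self.dist == "lognormal":
            if self.loc <= 0:
                raise ValueError("lognormal median must be > 0")
            if self.iqr is None or not (0 < self.iqr[0] < self.iqr[1]):
                raise ValueError("lognormal marginal needs a valid (q1, q3) IQR")

    @property
    def sigma_log(self) -> float:
        assert self.iqr is not None
        return (math.log(self.iqr[1]) - math.log(self.iqr[0])) / (2 * _Z75)

    def transform(self, z: np.ndarray) -> np.ndarray:
        if self.dist == "normal":
            return self.loc + self.scale * z
        return self.loc * np.exp(self.sigma_log * z)

    @property
    def location(self) -> float:
        """Mean for normal marginals, median for lognormal ones."""
        return self.loc


@dataclass(frozen=True)
class CorrelationTarget:
    var_a: str
    var_b: str
    r: float
    kind: str = "pearson"  # or "spearman"

    def __post_init__(self):
        if not -1 < self.r < 1:
            raise ValueError("correlation targets must lie in (-1, 1)")
        if self.kind not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation kind {self.kind!r}")

    @property
    def latent_r(self) -> float:
        """Latent Gaussian correlation reproducing the target.

        Pearson targets are taken verbatim on the latent/log scale; a
        Spearman target rho converts through r = 2 sin(pi * rho / 6).
        """
        if self.kind == "pearson":
            return self.r
        return 2.0 * math.sin(math.pi * self.r / 6.0)


# --- Published-design defaults ------------------------------------------------

_N = Marginal  # terse aliases for the tables below


def _ln(median, q1, q3):
    return Marginal("lognormal", median, iqr=(q1, q3))


#: Per-group marginals for the baseline variables of the emulated design
#: (HC, T2DM-NoDKD, DKD order).
DEFAULT_GROUP_PARAMS: dict[str, dict[str, Marginal]] = {
    "age": {
        "HC": _N("normal", 54.2, 8.5),
        "T2DM-NoDKD": _N("normal", 58.1, 9.2),
        "DKD": _N("normal", 61.4, 8.8),
    },
    "bmi": {
        "HC": _N("normal", 23.1, 2.8),
        "T2DM-NoDKD": _N("normal", 26.4, 3.5),
        "DKD": _N("normal", 27.1, 3.9),
    },
    "sbp": {
        "HC": _N("normal", 118.2, 12.4),
        "T2DM-NoDKD": _N("normal", 129.7, 15.0),
        "DKD": _N("normal", 142.3, 18.6),
    },
    "dbp": {
        "HC": _N("normal", 76.3, 8.6),
        "T2DM-NoDKD": _N("normal", 80.2, 9.3),
        "DKD": _N("normal", 84.4, 10.2),
    },
    "hba1c_pct": {
        "HC": _N("normal", 5.4, 0.4),
        "T2DM-NoDKD": _N("normal", 7.2, 1.1),
        "DKD": _N("normal", 8.1, 1.5),
    },
    "egfr": {
        "HC": _N("normal", 112.5, 11.3),
        "T2DM-NoDKD": _N("normal", 96.2, 14.7),
        "DKD": _N("normal", 54.1, 18.2),
    },
    "uacr_mg_g": {
        "HC": _ln(6.2, 4.1, 8.5),
        "T2DM-NoDKD": _ln(14.5, 8.2, 22.1),
        "DKD": _ln(482.5, 156.4, 1250.2),
    },
    "serum_creatinine_umol_L": {
        "HC": _ln(68.2, 59.3, 77.2),
        "T2DM-NoDKD": _ln(74.0, 62.4, 85.3),
        "DKD": _ln(112.1, 88.6, 145.7),
    },
    "urine_osmolality_mosm": {
        "HC": _N("normal", 650.2, 120.6),
        "T2DM-NoDKD": _N("normal", 680.1, 145.4),
        "DKD": _N("normal", 420.3, 110.6),
    },
    "chroma_C": {
        "HC": _N("normal", 45.2, 5.6),
        "T2DM-NoDKD": _N("normal", 38.4, 6.1),
        "DKD": _N("normal", 28.5, 7.2),
    },
    "b_star": {
        "HC": _N("normal", 42.1, 5.1),
        "T2DM-NoDKD": _N("normal", 35.2, 5.8),
        "DKD": _N("normal", 24.6, 6.5),
    },
    "t_half_s": {
        "HC": _ln(4.2, 2.5, 6.1),
        "T2DM-NoDKD": _ln(8.5, 5.2, 12.4),
        "DKD": _ln(45.8, 22.5, 98.2),
    },
    "mbi_pct": {
        "HC": _N("normal", 2.1, 0.8),
        "T2DM-NoDKD": _N("normal", 5.4, 1.9),
        "DKD": _N("normal", 18.2, 6.5),
    },
    # equilibrium surface tension (mN/m); no published marginal — chosen in the
    # physiological urine range, decreasing with proteinuria severity
    "surface_tension_mN_m": {
        "HC": _N("normal", 68.0, 4.0),
        "T2DM-NoDKD": _N("normal", 64.0, 4.0),
        "DKD": _N("normal", 52.0, 6.0),
    },
}

DEFAULT_MALE_FRACTION = {"HC": 42 / 80, "T2DM-NoDKD": 55 / 102, "DKD": 58 / 100}

DEFAULT_CORRELATIONS = (
    CorrelationTarget("uacr_mg_g", "t_half_s", 0.78),
    CorrelationTarget("b_star", "urine_osmolality_mosm", 0.78),
    CorrelationTarget("uacr_mg_g", "mbi_pct", 0.85),
    CorrelationTarget("t_half_s", "surface_tension_mN_m", -0.88, kind="spearman"),
)

#: intercepts of the latent risk-score link, tuned so the stratum split within
#: the diabetic-without-DKD group matches the emulated design (~17% high risk)
_RISK_INTERCEPT = {"HC": -4.0, "T2DM-NoDKD": -1.45, "DKD": 1.5}
_RISK_SLOPE = 1.5

#: coefficient of variation of the simulated repeat-measurement noise applied
#: to the physicalomics ground truth (within the published precision bound)
MEASUREMENT_CV = 0.03


@dataclass
class CohortConfig:
    n_per_group: dict[str, int]
    group_params: dict[str, dict[str, Marginal]]
    male_fraction: dict[str, float]
    target_correlations: tuple[CorrelationTarget, ...] = DEFAULT_CORRELATIONS
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError("counts must be >= 2 per group")
        for var, per_group in self.group_params.items():
            for g in self.n_per_group:
                if g not in per_group:
                    raise ValueError(f"variable {var!r} missing marginal for group {g!r}")

    @property
    def variables(self) -> list[str]:
        return list(self.group_params)


def default_cohort_config(
    seed: int = 0, n_per_group: tuple[int, int, int] = (80, 102, 100)
) -> CohortConfig:
    """Study-condition defaults: group sizes, marginals and correlation
    targets of the emulated three-group design."""
    return CohortConfig(
        n_per_group=dict(zip(GROUPS, n_per_group)),
        group_params={k: dict(v) for k, v in DEFAULT_GROUP_PARAMS.items()},
        male_fraction=dict(DEFAULT_MALE_FRACTION),
        seed=seed,
    )


def _latent_correlation_matrix(variables, targets) -> np.ndarray:
    """Latent copula correlation matrix: targets verbatim, unspecified pairs
    filled by transitive products along specified links (a one-factor-style
    completion), then validated positive definite.
    """
    idx = {v: i for i, v in enumerate(variables)}
    p = len(variables)
    R = np.eye(p)
    specified = np.zeros((p, p), bool)
    for t in targets:
        if t.var_a not in idx or t.var_b not in idx:
            raise ValueError(f"correlation target references unknown variable: {t}")
        i, j = idx[t.var_a], idx[t.var_b]
        R[i, j] = R[j, i] = t.latent_r
        specified[i, j] = specified[j, i] = True

    # transitive completion: iterate until no unspecified linked pair remains
    known = specified.copy()
    for _ in range(p):
        changed = False
        for i in range(p):
            for j in range(i + 1, p):
                if known[i, j]:
                    continue
                via = [k for k in range(p) if k not in (i, j) and known[i, k] and known[k, j]]
                if via:
                    k = max(via, key=lambda k: abs(R[i, k] * R[k, j]))
                    R[i, j] = R[j, i] = R[i, k] * R[k, j]
                    known[i, j] = known[j, i] = True
                    changed = True
        if not changed:
            break

    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin < 1e-10:
        # clip-eigenvalue repair; renormalise the diagonal
        w, V = np.linalg.eigh(R)
        R = V @ np.diag(np.clip(w, 1e-8, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one row per subject with group label, clinical covariates,
    physicalomics ground truth and noisy derived measurements.

    Identical seed => identical table.  Cross-variable correlation structure
    is induced by a per-group Gaussian copula on latent normals.
    """
    rng = np.random.default_rng(config.seed)
    variables = config.variables
    R = _latent_correlation_matrix(variables, config.target_correlations)
    L = np.linalg.cholesky(R)

    frames = []
    offset = 0
    for group in GROUPS:
        if group not in config.n_per_group:
            continue
        n = config.n_per_group[group]
        z = rng.standard_normal((n, len(variables))) @ L.T
        cols = {
            "subject_id": [f"S{offset + i:04d}" for i in range(n)],
            "group": group,
        }
        latent = {}
        for j, var in enumerate(variables):
            marg = config.group_params[var][group]
            vals = marg.transform(z[:, j])
            if marg.dist == "lognormal" or var in ("mbi_pct", "chroma_C"):
                vals = np.maximum(vals, 1e-6)
            cols[var] = vals
            latent[var] = z[:, j]
        cols["sex_male"] = (
            rng.random(n) < config.male_fraction.get(group, 0.5)
        ).astype(int)
        df = pd.DataFrame(cols)
        df["log10_uacr"] = np.log10(df["uacr_mg_g"])
        df["b_adj"] = df["b_star"] * (650.0 / df["urine_osmolality_mosm"].clip(lower=1.0))
        # latent risk score on [0,1]; threshold 0.5 defines the high stratum
        z_sev = latent["uacr_mg_g"]
        score = 1.0 / (1.0 + np.exp(-(_RISK_INTERCEPT[group] + _RISK_SLOPE * z_sev)))
        df["risk_score"] = score
        df["risk_stratum"] = np.where(score >= 0.5, "high", "low")
        # noisy repeat-style measurements of the optical features
        for var in ("chroma_C", "b_star", "t_half_s", "mbi_pct"):
            noise = rng.normal(0.0, MEASUREMENT_CV, n)
            df[f"{var}_meas"] = df[var] * (1.0 + noise)
        frames.append(df)
        offset += n
    out = pd.concat(frames, ignore_index=True)
    return out


def group_location_summary(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Observed vs configured location per group and variable.

    Uses the mean for normal marginals and the median for log-normal ones
    (the configured location of a skewed variable is its median).
    """
    rows = []
    for var in config.variables:
        for group, sub in cohort.groupby("group"):
            marg = config.group_params[var][group]
            obs = sub[var].mean() if marg.dist == "normal" else sub[var].median()
            rows.append(
                {
                    "variable": var,
                    "group": group,
                    "observed": obs,
                    "configured": marg.location,
                }
            )
    return pd.DataFrame(rows)


def attained_latent_correlations(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Per-group sample correlations on the copula (latent) scale for each
    configured target: Pearson on log-transformed values for log-normal
    variables, Spearman where the target is a Spearman rho."""
    rows = []
    for t in config.target_correlations:
        for group, sub in cohort.groupby("group"):
            cols = {}
            for var in (t.var_a, t.var_b):
                marg = config.group_params[var][group]
                v = sub[var].to_numpy(float)
                cols[var] = np.log(v) if marg.dist == "lognormal" else v
            a, b = cols[t.var_a], cols[t.var_b]
            if t.kind == "spearman":
                from scipy.stats import spearmanr

                r = float(spearmanr(a, b).statistic)
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            rows.append(
                {"var_a": t.var_a, "var_b": t.var_b, "group": group, "kind": t.kind,
                 "target": t.r, "r_observed": r}
            )
    return pd.DataFrame(rows)


# --- Paired metabolite panels -------------------------------------------------


@dataclass(frozen=True)
class MetaboliteParams:
    """Generative parameters for one metabolite."""

    serum_median: float  # umol/L in the non-DKD baseline
    urine_median: float  # umol/L at reference osmolality (650 mOsm/kg)
    sigma_log: float = 0.47  # geometric SD ~1.6
    serum_log2fc: float = 0.0  # DKD vs T2DM effect
    urine_log2fc: float = 0.0
    lod_serum: float = 1e-4
    lod_urine: float = 1e-4
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.lod_serum <= 0 or self.lod_urine <= 0:
            raise ValueError("lod must be > 0")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")


@dataclass
class FluxEffectConfig:
    metabolites: dict[str, MetaboliteParams]
    seed: int = 0

    @property
    def toxin_names(self) -> list[str]:
        return list(self.metabolites)


def default_flux_effects(seed: int = 0) -> FluxEffectConfig:
    """The 'High Serum / Low Urine' flux-mismatch conditions: protein-bound
    uremic toxins and acylcarnitines accumulate in DKD serum while their
    urinary excretion falls; TCA intermediates deplete in urine."""
    m = MetaboliteParams
    return FluxEffectConfig(
        metabolites={
            "indoxyl_sulfate": m(2.0, 20.0, serum_log2fc=1.5, urine_log2fc=-1.0,
                                 lod_serum=0.0152, lod_urine=0.0152, missing_rate=0.05),
            "p_cresyl_sulfate": m(10.0, 30.0, serum_log2fc=1.3, urine_log2fc=-0.8,
                                  lod_serum=0.0224, lod_urine=0.0224, missing_rate=0.05),
            "phenylacetylglutamine": m(5.0, 50.0, serum_log2fc=1.0, urine_log2fc=-0.7,
                                       lod_serum=0.01, lod_urine=0.01, missing_rate=0.05),
            "c8_carnitine": m(0.15, 0.4, serum_log2fc=0.8, urine_log2fc=-0.5,
                              lod_serum=0.005, lod_urine=0.005, missing_rate=0.08),
            "c16_carnitine": m(0.10, 0.05, serum_log2fc=1.0, urine_log2fc=-0.4,
                               lod_serum=0.005, lod_urine=0.005, missing_rate=0.08),
            "c18_carnitine": m(0.08, 0.03, serum_log2fc=0.9, urine_log2fc=-0.4,
                               lod_serum=0.005, lod_urine=0.005, missing_rate=0.08),
            "succinate": m(5.0, 30.0, serum_log2fc=-0.3, urine_log2fc=-0.8,
                           lod_serum=0.05, lod_urine=0.05, missing_rate=0.05),
            "citrate": m(100.0, 300.0, serum_log2fc=-0.2, urine_log2fc=-0.7,
                         lod_serum=0.05, lod_urine=0.05, missing_rate=0.05),
            "kynurenine": m(2.5, 4.0, serum_log2fc=0.6, urine_log2fc=0.2,
                            lod_serum=0.01, lod_urine=0.01, missing_rate=0.05),
            "tryptophan": m(60.0, 50.0, serum_log2fc=-0.3, urine_log2fc=-0.2,
                            lod_serum=0.05, lod_urine=0.05, missing_rate=0.05),
        },
        seed=seed,
    )


#: urinary creatinine at reference osmolality (umol/L); scaled by dilution
URINE_CREATININE_REF = 9000.0


def generate_metabolite_panel(cohort: pd.DataFrame, effects: FluxEffectConfig) -> PairedPanel:
    """Serum + urine concentration panel for each cohort subject.

    DKD subjects' concentrations are shifted by the configured log2
    fold-changes; urinary analytes (and creatinine) scale with each subject's
    dilution state (osmolality / 650); values below LOD are recorded as
    censored; a configured fraction is set missing completely at random.
    """
    if cohort.empty:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(effects.seed)
    subjects = pd.Index(cohort["subject_id"], name="subject_id")
    n = len(subjects)
    is_dkd = (cohort["group"] == "DKD").to_numpy()
    dilution = (cohort["urine_osmolality_mosm"].to_numpy(float) / 650.0).clip(0.1, None)

    serum = {}
    urine = {}
    lod_rows = []
    for name, p in effects.metabolites.items():
        zs = rng.standard_normal(n)
        zu = rng.standard_normal(n)
        s = p.serum_median * np.exp(p.sigma_log * zs)
        u = p.urine_median * np.exp(p.sigma_log * zu) * dilution
        s = s * np.where(is_dkd, 2.0 ** p.serum_log2fc, 1.0)
        u = u * np.where(is_dkd, 2.0 ** p.urine_log2fc, 1.0)
        serum[name] = s
        urine[name] = u
        lod_rows.append({"metabolite": name, "serum": p.lod_serum, "urine": p.lod_urine})

    serum = pd.DataFrame(serum, index=subjects)
    urine = pd.DataFrame(urine, index=subjects)
    lod = pd.DataFrame(lod_rows).set_index("metabolite")

    serum_cens = pd.DataFrame(False, index=subjects, columns=serum.columns)
    urine_cens = pd.DataFrame(False, index=subjects, columns=urine.columns)
    for name, p in effects.metabolites.items():
        serum_cens[name] = serum[name] < p.lod_serum
        urine_cens[name] = urine[name] < p.lod_urine
    serum = serum.mask(serum_cens)
    urine = urine.mask(urine_cens)

    for name, p in effects.metabolites.items():
        if p.missing_rate > 0:
            for frame in (serum, urine):
                drop = rng.random(n) < p.missing_rate
                frame.loc[drop & frame[name].notna().to_numpy(), name] = np.nan

    urine_creat = (
        URINE_CREATININE_REF
        * dilution
        * np.exp(0.15 * rng.standard_normal(n))
    )
    return PairedPanel(
        serum=serum,
        urine=urine,
        serum_censored=serum_cens,
        urine_censored=urine_cens,
        serum_creatinine=pd.Series(
            cohort["serum_creatinine_umol_L"].to_numpy(float), index=subjects
        ),
        urine_creatinine=pd.Series(urine_creat, index=subjects),
        lod=lod,
    )


# --- Outcome histories --------------------------------------------------------


@dataclass
class OutcomeConfig:
    """Exponential event-time model over a fixed horizon.

    ``group_hazards`` are annual hazards of the primary renal composite for
    the *low-risk* stratum of each group; within the diabetic-without-DKD
    group the high-risk stratum multiplies the hazard by ``hr_high_vs_low``.
    Death from non-renal causes competes with the primary event.
    """

    horizon_years: float = 3.0
    group_hazards: dict[str, float] = field(
        default_factory=lambda: {
            "HC": 0.0,
            # 3-year low-risk event probability 2.3% => annual hazard
            "T2DM-NoDKD": -math.log(1 - 0.023) / 3.0,
            # 3-year composite probability 34% in established disease
            "DKD": -math.log(1 - 0.34) / 3.0,
        }
    )
    hr_high_vs_low: float = 12.5
    competing_mortality_hazard: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.horizon_years <= 0:
            raise ValueError("horizon must be > 0")
        if any(h < 0 for h in self.group_hazards.values()):
            raise ValueError("hazards must be >= 0")
        if self.competing_mortality_hazard < 0:
            raise ValueError("hazards must be >= 0")


def default_outcome_config(seed: int = 0) -> OutcomeConfig:
    return OutcomeConfig(seed=seed)


def _exponential_times(rng, hazard: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(
            hazard > 0, rng.exponential(1.0, hazard.size) / np.where(hazard > 0, hazard, 1.0),
            np.inf,
        )


def generate_outcomes(cohort: pd.DataFrame, config: OutcomeConfig) -> pd.DataFrame:
    """Per subject: event indicator, type (mare / death / censored) and time.

    Event times are exponential with group- and stratum-specific hazards;
    non-renal death is an independent exponential competing process; everyone
    still event-free at the horizon is administratively censored.
    """
    if "risk_stratum" not in cohort.columns:
        raise ValueError("cohort must carry a risk-stratum column")
    rng = np.random.default_rng(config.seed)
    hazard = cohort["group"].map(config.group_hazards).to_numpy(float)
    if np.isnan(hazard).any():
        raise ValueError("every cohort group needs a hazard")
    high = (
        (cohort["risk_stratum"] == "high") & (cohort["group"] == "T2DM-NoDKD")
    ).to_numpy()
    hazard = hazard * np.where(high, config.hr_high_vs_low, 1.0)

    t_event = _exponential_times(rng, hazard)
    t_death = _exponential_times(
        rng, np.full(len(cohort), config.competing_mortality_hazard)
    )
    t = np.minimum.reduce([t_event, t_death, np.full(len(cohort), config.horizon_years)])
    event_type = np.where(
        (t_event <= t_death) & (t_event <= config.horizon_years),
        "mare",
        np.where((t_death < t_event) & (t_death <= config.horizon_years), "death", "censored"),
    )
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "group": cohort["group"].to_numpy(),
            "risk_stratum": cohort["risk_stratum"].to_numpy(),
            "time_years": t,
            "event_type": event_type,
            "event": event_type == "mare",
        }
    )
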