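"""Association battery linking light-exposure metrics to blood lipids.

Three model tiers over pooled subject-season rows:

* ``simple``             - Pearson correlation r per (predictor, outcome);
* ``photoperiod_adjusted`` - OLS of the z-scored outcome on the z-scored
  predictor plus photoperiod duration (coded 1/12/23 h for winter solstice,
  equinox, summer solstice);
* ``fully_adjusted``     - ANCOVA-style OLS additionally adjusting for age,
  sex (female=0/male=1) and indigeneity (native N=0 / non-native NN=1),
  reporting the predictor's standardized beta and Type III partial eta^2
  = SS_predictor / (SS_predictor + SS_residual).

Multiplicity is controlled with the Benjamini-Hochberg step-up rule at
FDR q = 0.1 across the predictor x outcome family; multicollinearity is
screened with variance inflation factors.  Circular predictors (acrophases,
window onsets) are linearized by unwrapping to a +/-12 h interval around the
cohort circular mean before entering any linear model.

All subject-season rows are treated as independent (no subject random
effect) - a deliberate simplification matching pooled "overall data"
regression reporting; see the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CircalipidError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)
from .metrics import (CosinorEstimate, NonparametricMetrics,
                      circular_mean_clock)

SEASON_PHOTOPERIOD_H = {"WS": 1, "SE": 12, "SS": 23}

#: metric columns measured on the 24 h clock, unwrapped before modelling
CIRCULAR_COLUMNS = (
    "ble_acrophase_h", "le_acrophase_h", "ble_m10_onset_h",
    "ble_l5_onset_h", "melatonin_acrophase_h",
)

LIPID_COLUMNS = ("tc", "ldl", "hdl", "tg", "tg_hdl")

#: Table-1-style predictor family (14 predictors per lipid)
DEFAULT_PREDICTORS = (
    "photoperiod_h",
    "le_mesor", "le_amplitude", "le_acrophase_h",
    "ble_mesor", "ble_amplitude", "ble_acrophase_h",
    "ble_m10", "ble_m10_onset_h", "ble_l5", "ble_l5_onset_h",
    "ble_ra", "ble_na",
    "melatonin_acrophase_h",
)

DEMOGRAPHIC_COVARIATES = ("photoperiod_h", "age", "male", "nn")


# ---------------------------------------------------------------------------
# row containers
# ---------------------------------------------------------------------------

@dataclass
class ParticipantSeason:
    """One subject-season row: demographics, lipid panel and derived metrics."""

    subject: str
    age: float
    sex: str                      # "female" | "male"
    indigeneity: str              # "N" | "NN"
    season: str                   # "WS" | "SE" | "SS"
    tc: float
    ldl: float
    hdl: float
    tg: float
    meq: Optional[float] = None
    metrics: dict = field(default_factory=dict)   # channel -> (CosinorEstimate, NonparametricMetrics)
    melatonin_acrophase_h: Optional[float] = None
    melatonin_profile: Optional[object] = None    # raw MelatoninProfile
    ble_epochs: Optional[np.ndarray] = None       # 48-epoch composite day
    series: Optional[dict] = None                 # channel -> EpochSeries (optional)

    def __post_init__(self) -> None:
        if self.season not in SEASON_PHOTOPERIOD_H:
            raise ValidationError(f"unknown season {self.season!r}")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.indigeneity not in ("N", "NN"):
            raise ValidationError(f"unknown indigeneity {self.indigeneity!r}")
        for name in ("tc", "ldl", "hdl", "tg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"lipid {name} must be positive")

    @property
    def photoperiod_h(self) -> int:
        return SEASON_PHOTOPERIOD_H[self.season]

    @property
    def tg_hdl(self) -> float:
        """TG/HDL-C ratio, always recomputed, never stored."""
        return self.tg / self.hdl

    def to_row(self) -> dict:
        row = {
            "subject": self.subject, "season": self.season,
            "age": self.age, "male": 1.0 if self.sex == "male" else 0.0,
            "nn": 1.0 if self.indigeneity == "NN" else 0.0,
            "photoperiod_h": float(self.photoperiod_h),
            "meq": self.meq,
            "tc": self.tc, "ldl": self.ldl, "hdl": self.hdl, "tg": self.tg,
            "tg_hdl": self.tg_hdl,
            "melatonin_acrophase_h": self.melatonin_acrophase_h,
        }
        prefix = {"blue_irradiance": "ble", "white_lux": "le"}
        for channel, (cos, nonpar) in self.metrics.items():
            p = prefix.get(channel, channel)
            row[f"{p}_mesor"] = cos.mesor
            row[f"{p}_amplitude"] = cos.amplitude
            row[f"{p}_acrophase_h"] = cos.acrophase_h
            if nonpar is not None:
                row[f"{p}_m10"] = nonpar.m10
                row[f"{p}_m10_onset_h"] = nonpar.m10_onset_h
                row[f"{p}_l5"] = nonpar.l5
                row[f"{p}_l5_onset_h"] = nonpar.l5_onset_h
                row[f"{p}_ra"] = nonpar.ra
                row[f"{p}_na"] = nonpar.na
        return row


def cohort_frame(participants: Sequence[ParticipantSeason]) -> pd.DataFrame:
    """Flatten subject-season records into the analysis DataFrame."""
    return pd.DataFrame([p.to_row() for p in participants])


@dataclass
class AssociationRow:
    outcome: str
    predictor: str
    model: str                       # simple | photoperiod_adjusted | fully_adjusted
    estimate: float                  # r or standardized beta
    variance_explained: float        # R^2 or partial eta^2
    p: float
    n: int
    p_rank_significant: Optional[bool] = None
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def linearize_circular(values: np.ndarray, center: Optional[float] = None) -> np.ndarray:
    """Unwrap clock-hour values onto a continuous +/-12 h band.

    Values are mapped to ``center + ((v - center + 12) mod 24) - 12`` with
    ``center`` defaulting to the circular mean, so e.g. nocturnal onsets
    straddling midnight (23.5 h and 0.5 h) become numerically adjacent.
    NaNs pass through.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        return v.copy()
    if center is None:
        center = circular_mean_clock(v[finite]).mean_h
        if not np.isfinite(center):
            center = 0.0
    out = v.copy()
    out[finite] = center + ((v[finite] - center + 12.0) % 24.0) - 12.0
    return out


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("zero-variance column cannot be standardized")
    return (x - np.mean(x)) / sd


def bh_adjust(pvalues: Sequence[float], fdr: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags.

    Sort p ascending, find the largest rank i with p_(i) <= (i/m) q and flag
    all ranks up to i.  Returns a boolean array aligned with the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    # p = 0 is tolerated as floating-point underflow of a tiny p-value
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if not 0 < fdr < 1:
        raise ValidationError("FDR level must lie in (0, 1)")
    order = np.argsort(p, kind="stable")
    m = p.size
    thresh = fdr * (np.arange(1, m + 1) / m)
    below = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        flags[order[: k + 1]] = True
    return flags


def _prepare(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Complete-case subframe with circular columns unwrapped."""
    sub = df.loc[:, list(columns)].astype(float).dropna()
    for col in sub.columns:
        if col in CIRCULAR_COLUMNS:
            sub[col] = linearize_circular(sub[col].to_numpy())
    return sub


# ---------------------------------------------------------------------------
# model tiers
# ---------------------------------------------------------------------------

def simple_correlations(
    df: pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    outcomes: Sequence[str] = LIPID_COLUMNS,
    fdr: float = 0.1,
    bh_family: str = "global",
) -> list[AssociationRow]:
    """Pearson r (with BH flags) for every predictor x outcome pair.

    Rows missing either variable are dropped per pair (melatonin models run
    on the complete-case subset).  ``bh_family`` is ``"global"`` (one family
    across the whole table, the default) or ``"per_outcome"``.
    """
    rows: list[AssociationRow] = []
    for outcome in outcomes:
        for pred in predictors:
            if pred == outcome:
                continue
            sub = _prepare(df, [pred, outcome])
            if len(sub) < 4:
                raise InsufficientDataError(
                    f"{pred} vs {outcome}: {len(sub)} complete rows < 4")
            x, y = sub[pred].to_numpy(), sub[outcome].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValidationError(
                    f"zero variance in {pred!r} or {outcome!r}")
            r, p = stats.pearsonr(x, y)
            rows.append(AssociationRow(
                outcome=outcome, predictor=pred, model="simple",
                estimate=float(r), variance_explained=float(r * r),
                p=float(p), n=len(sub)))
    _apply_bh(rows, fdr, bh_family)
    return rows


def _apply_bh(rows: list[AssociationRow], fdr: float, bh_family: str) -> None:
    if not rows:
        return
    if bh_family == "global":
        groups = {None: rows}
    elif bh_family == "per_outcome":
        groups = {}
        for row in rows:
            groups.setdefault(row.outcome, []).append(row)
    else:
        raise ValidationError(f"unknown BH family {bh_family!r}")
    for grp in groups.values():
        flags = bh_adjust([r.p for r in grp], fdr=fdr)
        for row, flag in zip(grp, flags):
            row.p_rank_significant = bool(flag)


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with explicit rank check; returns (coef, resid, rss, XtX_inv)."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    return coef, resid, rss, xtx_inv


def _standardized_fit(sub: pd.DataFrame, outcome: str, predictor: str,
                      covariates: Sequence[str]):
    """OLS of z-outcome on z-predictor + z-covariates (+ intercept).

    Returns (beta, se, p, r2, rss_full, df_resid, Z) where Z is the
    standardized design frame (without intercept).
    """
    cols = [predictor, *covariates]
    Z = np.column_stack([zscore(sub[c].to_numpy()) for c in cols])
    y = zscore(sub[outcome].to_numpy())
    X = np.column_stack([np.ones(len(y)), Z])
    coef, _, rss, xtx_inv = _ols(X, y)
    n, k = X.shape
    df_resid = n - k
    if df_resid < 1:
        raise InsufficientDataError("insufficient df for residual variance")
    mse = rss / df_resid
    se = float(np.sqrt(mse * xtx_inv[1, 1]))
    beta = float(coef[1])
    tval = beta / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(tval), df_resid))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return beta, se, p, r2, rss, df_resid, Z


def photoperiod_adjusted_model(
    df: pd.DataFrame, outcome: str, predictor: str,
) -> AssociationRow:
    """Standardized beta of the predictor, adjusted for photoperiod only."""
    covs = [] if predictor == "photoperiod_h" else ["photoperiod_h"]
    sub = _prepare(df, [predictor, *covs, outcome])
    if len(sub) < 5:
        raise InsufficientDataError(
            f"{len(sub)} complete rows < 5 (insufficient df)")
    beta, _, p, r2, *_ = _standardized_fit(sub, outcome, predictor, covs)
    return AssociationRow(
        outcome=outcome, predictor=predictor, model="photoperiod_adjusted",
        estimate=beta, variance_explained=r2, p=p, n=len(sub))


def fully_adjusted_model(
    df: pd.DataFrame, outcome: str, predictor: str,
    vif_ceiling: float = 10.0,
) -> AssociationRow:
    """ANCOVA-style model: predictor + photoperiod + age + sex + indigeneity.

    Reports the predictor's standardized beta and its Type III partial
    eta^2 = SS_predictor / (SS_predictor + SS_residual) - identical here to
    the reduced-vs-full RSS difference because the predictor enters once.
    """
    covs = [c for c in DEMOGRAPHIC_COVARIATES if c != predictor]
    sub = _prepare(df, [predictor, *covs, outcome])
    if len(sub) < 8:
        raise InsufficientDataError(
            f"{len(sub)} complete rows < 8 (insufficient df)")
    beta, se, p, _, rss_full, df_resid, Z = _standardized_fit(
        sub, outcome, predictor, covs)
    tval = beta / se if se > 0 else np.inf
    partial_eta2 = tval * tval / (tval * tval + df_resid)
    row = AssociationRow(
        outcome=outcome, predictor=predictor, model="fully_adjusted",
        estimate=beta, variance_explained=float(partial_eta2), p=p, n=len(sub))
    vifs = vif(Z)
    if np.any(vifs > vif_ceiling):
        worst = [c for c, v in zip([predictor, *covs], vifs) if v > vif_ceiling]
        row.warnings.append(f"VIF above {vif_ceiling:g} for: {', '.join(worst)}")
    return row


def demographic_model(df: pd.DataFrame, outcome: str) -> list[AssociationRow]:
    """Standardized betas of the demographic covariates themselves
    (age, sex, indigeneity, photoperiod) in the fully adjusted model."""
    sub = _prepare(df, [*DEMOGRAPHIC_COVARIATES, outcome])
    if len(sub) < 8:
        raise InsufficientDataError(
            f"{len(sub)} complete rows < 8 (insufficient df)")
    rows = []
    for pred in ("age", "male", "nn", "photoperiod_h"):
        covs = [c for c in DEMOGRAPHIC_COVARIATES if c != pred]
        beta, se, p, _, _, df_resid, _ = _standardized_fit(sub, outcome, pred, covs)
        tval = beta / se if se > 0 else np.inf
        rows.append(AssociationRow(
            outcome=outcome, predictor=pred, model="fully_adjusted",
            estimate=beta,
            variance_explained=float(tval * tval / (tval * tval + df_resid)),
            p=p, n=len(sub)))
    return rows


def vif(design_columns) -> np.ndarray:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R^2_j).

    ``R^2_j`` comes from regressing column j on the remaining columns plus an
    intercept.  Perfect collinearity yields ``inf``.
    """
    X = np.asarray(design_columns, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("VIF needs >= 2 columns")
    n = X.shape[0]
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        y = X[:, j]
        if np.std(y) == 0:
            raise ValidationError(f"column {j} is constant")
        others = np.column_stack(
            [np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# seasonal comparison with normality routing
# ---------------------------------------------------------------------------

@dataclass
class SeasonComparison:
    variable: str
    test: str                    # t | mannwhitney | anova | kruskal
    statistic: float
    p: float
    routing: str                 # parametric | nonparametric
    normality: dict              # season -> {"shapiro_p": ., "ks_p": .}
    group_sizes: dict


def compare_seasons(
    df: pd.DataFrame, variable: str, by: str = "season",
    alpha: float = 0.05, routing: str = "auto",
) -> SeasonComparison:
    """Compare a variable across seasons with normality-gated test routing.

    Shapiro-Wilk (decisive) and Kolmogorov-Smirnov are run per group; if
    every group passes Shapiro at ``alpha`` the parametric branch is used
    (t-test for two groups, one-way ANOVA for three), otherwise the rank
    branch (Mann-Whitney U / Kruskal-Wallis).  ``routing`` may force either
    branch.
    """
    if routing not in ("auto", "parametric", "nonparametric"):
        raise ValidationError(f"unknown routing {routing!r}")
    groups = {}
    for season, sub in df.groupby(by):
        vals = sub[variable].dropna().to_numpy(dtype=float)
        if len(vals) >= 3:
            groups[season] = vals
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 seasons with >= 3 values each")

    normality = {}
    all_normal = True
    for season, vals in groups.items():
        sh = stats.shapiro(vals)
        mu, sd = np.mean(vals), np.std(vals, ddof=1)
        ks = stats.kstest(vals, "norm", args=(mu, sd if sd > 0 else 1.0))
        normality[season] = {"shapiro_p": float(sh.pvalue),
                             "ks_p": float(ks.pvalue)}
        if sh.pvalue <= alpha:
            all_normal = False

    if routing == "auto":
        branch = "parametric" if all_normal else "nonparametric"
    else:
        branch = routing

    samples = list(groups.values())
    if branch == "parametric":
        if len(samples) == 2:
            res = stats.ttest_ind(*samples)
            test = "t"
        else:
            res = stats.f_oneway(*samples)
            test = "anova"
    else:
        if len(samples) == 2:
            res = stats.mannwhitneyu(*samples, alternative="two-sided")
            test = "mannwhitney"
        else:
            res = stats.kruskal(*samples)
            test = "kruskal"
    return SeasonComparison(
        variable=variable, test=test, statistic=float(res.statistic),
        p=float(res.pvalue), routing=branch, normality=normality,
        group_sizes={s: len(v) for s, v in groups.items()})


# ---------------------------------------------------------------------------
# battery over all tiers
# ---------------------------------------------------------------------------

def association_battery(
    df: pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    outcomes: Sequence[str] = LIPID_COLUMNS,
    fdr: float = 0.1,
    bh_family: str = "global",
) -> pd.DataFrame:
    """All three model tiers for every available predictor x outcome pair.

    Predictors absent from the frame (e.g. no melatonin) are skipped; BH
    flags are assigned within each model tier's family.
    """
    avail = [p for p in predictors if p in df.columns
             and df[p].notna().sum() >= 4]
    simple = simple_correlations(df, avail, outcomes, fdr, bh_family)
    adj, full = [], []
    for outcome in outcomes:
        for pred in avail:
            if pred == outcome or pred == "photoperiod_h":
                continue
            # degenerate subsets (e.g. collinear binaries among the few
            # melatonin-complete subjects) are skipped, not fatal
            try:
                adj.append(photoperiod_adjusted_model(df, outcome, pred))
            except CircalipidError as exc:
                logger.warning("photoperiod model %s~%s skipped: %s",
                               outcome, pred, exc)
            try:
                full.append(fully_adjusted_model(df, outcome, pred))
            except CircalipidError as exc:
                logger.warning("adjusted model %s~%s skipped: %s",
                               outcome, pred, exc)
    _apply_bh(adj, fdr, bh_family)
    _apply_bh(full, fdr, bh_family)
    rows = simple + adj + full
    return pd.DataFrame([{
        "outcome": r.outcome, "predictor": r.predictor, "model": r.model,
        "estimate": r.estimate, "variance_explained": r.variance_explained,
        "p": r.p, "p_rank_significant": r.p_rank_significant, "n": r.n,
        "warnings": "; ".join(r.warnings),
    } for r in rows])
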