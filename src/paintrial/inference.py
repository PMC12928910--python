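"""Pairwise ANCOVA least-squares means, gatekeeping, survival and risk
differences for derived trial endpoints.

Every hypothesis test follows the trial's conventions: for each pairwise
treatment comparison a separate linear model is fitted on the two arms'
data only, with treatment and site as fixed effects; least-squares means
average the model predictions with equal weight over site levels; CIs and
p values use the t distribution on the residual degrees of freedom.  The
primary and key secondary comparisons are multiplicity-protected by a
fixed-sequence (serial) gatekeeping rule.  Time to first rescue is
summarized by Kaplan-Meier quartiles and a Cox proportional-hazards model
(Efron tie handling) per active arm versus placebo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import confint_proportions_2indep

from .config import PGA_CATEGORIES, TrialConfig

__all__ = [
    "ComparisonResult",
    "GatekeepingOutcome",
    "SurvivalResult",
    "RiskDifferenceResult",
    "ancova_pairwise",
    "percent_change",
    "fold_change",
    "gatekeep",
    "km_cox",
    "risk_difference",
    "pga_sis_summaries",
    "pool_rubin",
]


class InferenceError(ValueError):
    """Raised when a comparison cannot be computed from the supplied data."""


@dataclass
class ComparisonResult:
    """One pairwise endpoint contrast: LSMs, difference, CI and p value."""

    endpoint: str
    arm_a: str
    arm_b: str
    lsm_a: float
    se_a: float
    lsm_b: float
    se_b: float
    lsmd: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int
    population: str = "itt"

    def as_row(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "comparison": f"{self.arm_a} vs {self.arm_b}",
            "lsm_a": self.lsm_a,
            "se_a": self.se_a,
            "lsm_b": self.lsm_b,
            "se_b": self.se_b,
            "lsmd": self.lsmd,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
            "p": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "population": self.population,
        }


@dataclass
class GatekeepingOutcome:
    """Serial (fixed-sequence) gatekeeping decision for primary and key
    secondary hypotheses."""

    primary_significant: bool
    key_secondary_tested: bool
    key_secondary_significant: bool
    alpha: float


@dataclass
class ArmSurvival:
    arm: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    q1: float
    q3: float


@dataclass
class HazardRatio:
    arm: str
    reference: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    log_hr: float
    se_log_hr: float


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves with quartiles per arm and pairwise Cox hazard
    ratios of each active arm versus the reference arm."""

    curves: dict[str, ArmSurvival]
    hazard_ratios: dict[str, HazardRatio]
    reference: str


@dataclass
class RiskDifferenceResult:
    """Difference in rescue-user proportions (percentage points) with a
    Newcombe hybrid-score CI and a chi-square p value."""

    interval: tuple[float, float]
    arm_a: str
    arm_b: str
    users_a: int
    n_a: int
    users_b: int
    n_b: int
    difference_pct: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def proportion_a(self) -> float:
        return self.users_a / self.n_a

    @property
    def proportion_b(self) -> float:
        return self.users_b / self.n_b


# --------------------------------------------------------------------------- #
# ANCOVA with least-squares means
# --------------------------------------------------------------------------- #

def ancova_pairwise(
    data: pd.DataFrame,
    arms: tuple[str, str],
    endpoint: str = "value",
    site_col: str = "site_id",
    arm_col: str = "arm",
    alpha: float = 0.05,
    population: str = "itt",
    single_arm_sites: str = "drop",
) -> ComparisonResult:
    """ANCOVA contrast of two arms with treatment and site fixed effects.

    The model is fitted on the two arms' rows only.  Least-squares means
    average the cell predictions with equal weight across site levels, so
    with a single site they reduce exactly to the raw arm means and the
    p value to the pooled-variance two-sample t-test.  Sites represented in
    only one arm are dropped with a warning (``single_arm_sites='drop'``)
    or raise (``'error'``).
    """
    import warnings

    arm_a, arm_b = arms
    df = data[data[arm_col].isin(arms)][[endpoint, arm_col, site_col]].dropna()
    counts = df.groupby(arm_col)[endpoint].count()
    if counts.reindex(list(arms)).fillna(0).min() < 2:
        raise InferenceError(f"fewer than 2 subjects in one of arms {arms}")
    per_site = df.groupby(site_col)[arm_col].nunique()
    lonely = per_site[per_site < 2].index
    if len(lonely):
        msg = f"site(s) {list(lonely)} represented in only one arm"
        if single_arm_sites == "error":
            raise InferenceError(msg)
        warnings.warn(msg + "; dropping", stacklevel=2)
        df = df[~df[site_col].isin(lonely)]

    y = df[endpoint].to_numpy(dtype=float)
    sites = np.sort(df[site_col].unique())
    n_sites = len(sites)
    # design: intercept, treatment indicator (arm_a = 1), site deviations
    trt = (df[arm_col] == arm_a).to_numpy(dtype=float)
    X = [np.ones(len(df)), trt]
    for s in sites[1:]:
        X.append((df[site_col] == s).to_numpy(dtype=float))
    X = np.column_stack(X)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(df) - rank
    if dof <= 0:
        raise InferenceError("no residual degrees of freedom")
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)

    # LSM contrast vectors: intercept + trt + equal-weight site average
    site_w = np.full(n_sites - 1, 1.0 / n_sites) if n_sites > 1 else np.array([])
    c_a = np.concatenate(([1.0, 1.0], site_w))
    c_b = np.concatenate(([1.0, 0.0], site_w))
    c_d = c_a - c_b

    def _est(c: np.ndarray) -> tuple[float, float]:
        est = float(c @ beta)
        se = float(np.sqrt(s2 * c @ XtX_inv @ c))
        return est, se

    lsm_a, se_a = _est(c_a)
    lsm_b, se_b = _est(c_b)
    lsmd, se_d = _est(c_d)
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    tstat = lsmd / se_d
    # guard against underflow to exactly 0 at extreme sample sizes
    p = max(2 * stats.t.sf(abs(tstat), dof), np.finfo(float).tiny)
    return ComparisonResult(
        endpoint=endpoint,
        arm_a=arm_a,
        arm_b=arm_b,
        lsm_a=lsm_a,
        se_a=se_a,
        lsm_b=lsm_b,
        se_b=se_b,
        lsmd=lsmd,
        ci_low=lsmd - tcrit * se_d,
        ci_high=lsmd + tcrit * se_d,
        p_value=float(p),
        n_a=int(counts[arm_a]),
        n_b=int(counts[arm_b]),
        population=population,
    )


# --------------------------------------------------------------------------- #
# summary transforms
# --------------------------------------------------------------------------- #

def percent_change(lsm_active: float, lsm_reference: float) -> float:
    """Percent reduction of the active arm relative to the reference,
    ``100 * (reference - active) / reference``, to one decimal."""
    if lsm_reference == 0:
        raise InferenceError("reference LSM is zero; percent change undefined")
    return round(100.0 * (lsm_reference - lsm_active) / lsm_reference, 1)


def fold_change(
    value_reference: float, value_active: float, rounding: str = "decimal"
) -> float:
    """Fold elevation of the reference over the active value.

    ``rounding='decimal'`` rounds to one decimal; ``'integer'`` to the
    nearest whole fold.
    """
    if value_active == 0:
        raise InferenceError("active value is zero; fold change undefined")
    fold = value_reference / value_active
    if rounding == "integer":
        return float(round(fold))
    if rounding == "decimal":
        return round(fold, 1)
    raise InferenceError(f"unknown rounding spec: {rounding}")


def gatekeep(
    p_primary: float, p_key_secondary: float, alpha: float = 0.05
) -> GatekeepingOutcome:
    """Fixed-sequence gatekeeping: the key secondary hypothesis is tested
    (at full alpha) only if the primary succeeds."""
    for p in (p_primary, p_key_secondary):
        if not 0 < p <= 1:
            raise InferenceError(f"p value {p} outside (0, 1]")
    primary = p_primary < alpha
    tested = bool(primary)
    secondary = bool(tested and p_key_secondary < alpha)
    return GatekeepingOutcome(
        primary_significant=bool(primary),
        key_secondary_tested=tested,
        key_secondary_significant=secondary,
        alpha=alpha,
    )


# --------------------------------------------------------------------------- #
# time to first rescue: Kaplan-Meier and Cox
# --------------------------------------------------------------------------- #

def km_cox(
    ttr: pd.DataFrame,
    arm_of: pd.Series,
    reference: str = "placebo",
    alpha: float = 0.05,
) -> SurvivalResult:
    """Kaplan-Meier curves with quartiles per arm plus pairwise Cox hazard
    ratios (Efron ties) of each non-reference arm versus ``reference``.

    ``ttr`` columns: ``subject_id, time_h, event``.  Quartiles that the
    curve never reaches are reported as NaN (not estimable).  A pair with
    no events yields a flagged, non-estimable hazard ratio.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.utils import qth_survival_time

    df = ttr.merge(arm_of.rename("arm"), left_on="subject_id", right_index=True)
    curves: dict[str, ArmSurvival] = {}
    for arm, grp in df.groupby("arm"):
        km = KaplanMeierFitter()
        km.fit(grp["time_h"], grp["event"])
        sf = km.survival_function_.iloc[:, 0]
        ev = km.event_table
        curves[arm] = ArmSurvival(
            arm=arm,
            times=sf.index.to_numpy(dtype=float),
            survival=sf.to_numpy(dtype=float),
            at_risk=ev["at_risk"].to_numpy(dtype=float),
            median=float(qth_survival_time(0.5, sf)),
            q1=float(qth_survival_time(0.25, sf)),
            q3=float(qth_survival_time(0.75, sf)),
        )

    hrs: dict[str, HazardRatio] = {}
    zcrit = stats.norm.ppf(1 - alpha / 2)
    for arm in [a for a in df["arm"].unique() if a != reference]:
        sub = df[df["arm"].isin([arm, reference])].copy()
        not_estimable = HazardRatio(
            arm, reference, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan
        )
        if (
            sub["event"].sum() == 0
            or (sub["arm"] == reference).sum() == 0
            or (sub["arm"] == arm).sum() == 0
        ):
            hrs[arm] = not_estimable
            continue
        sub["treated"] = (sub["arm"] == arm).astype(float)
        cph = CoxPHFitter()
        try:
            cph.fit(
                sub[["time_h", "event", "treated"]],
                duration_col="time_h",
                event_col="event",
            )
        except Exception:
            hrs[arm] = not_estimable
            continue
        b = float(cph.params_["treated"])
        se = float(cph.standard_errors_["treated"])
        with np.errstate(over="ignore"):  # degenerate separation -> inf bound
            hrs[arm] = HazardRatio(
                arm=arm,
                reference=reference,
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - zcrit * se)),
                ci_high=float(np.exp(b + zcrit * se)),
                p_value=float(2 * stats.norm.sf(abs(b / se))),
                log_hr=b,
                se_log_hr=se,
            )
    return SurvivalResult(curves=curves, hazard_ratios=hrs, reference=reference)


# --------------------------------------------------------------------------- #
# risk differences
# --------------------------------------------------------------------------- #

def risk_difference(
    users_a: int,
    n_a: int,
    users_b: int,
    n_b: int,
    interval: tuple[float, float] = (0.0, 72.0),
    arm_a: str = "active",
    arm_b: str = "placebo",
    alpha: float = 0.05,
) -> RiskDifferenceResult:
    """Difference in rescue-user proportions (a - b, percentage points)
    with a Newcombe hybrid-score CI and a Pearson chi-square p value."""
    if n_a <= 0 or n_b <= 0:
        raise InferenceError("group sizes must be positive")
    pa, pb = users_a / n_a, users_b / n_b
    lo, hi = confint_proportions_2indep(
        users_a, n_a, users_b, n_b, method="newcomb", compare="diff",
        alpha=alpha,
    )
    table = np.array(
        [[users_a, n_a - users_a], [users_b, n_b - users_b]], dtype=float
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        p = 1.0
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return RiskDifferenceResult(
        interval=interval,
        arm_a=arm_a,
        arm_b=arm_b,
        users_a=int(users_a),
        n_a=int(n_a),
        users_b=int(users_b),
        n_b=int(n_b),
        difference_pct=100.0 * (pa - pb),
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        p_value=float(p),
    )


# --------------------------------------------------------------------------- #
# secondary scales
# --------------------------------------------------------------------------- #

def pga_sis_summaries(
    secondary: pd.DataFrame,
    roster: pd.DataFrame,
    config: TrialConfig | None = None,
    comparisons: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Per-arm, per-hour PGA and SIS summaries plus SIS ANCOVA contrasts.

    PGA categories are coded numerically from ``config.pga_coding_origin``
    (default poor=0 ... excellent=4).  Returns a tidy summary table of
    means/SDs and, for SIS at each hour, pairwise ANCOVA results for the
    requested arm pairs (default: each non-reference arm vs the last arm).
    """
    cfg = config or TrialConfig()
    coding = {
        cat: cfg.pga_coding_origin + i for i, cat in enumerate(PGA_CATEGORIES)
    }
    sec = secondary.merge(
        roster[["subject_id", "arm", "site_id"]], on="subject_id"
    )
    unknown = set(sec.loc[sec["scale"] == "pga", "value"]) - set(coding)
    if unknown:
        raise InferenceError(f"unknown PGA category label(s): {sorted(unknown)}")
    sec = sec.copy()
    is_pga = sec["scale"] == "pga"
    sec.loc[is_pga, "numeric"] = sec.loc[is_pga, "value"].map(coding).astype(float)
    sec.loc[~is_pga, "numeric"] = pd.to_numeric(sec.loc[~is_pga, "value"])
    summary = (
        sec.groupby(["scale", "hour", "arm"])["numeric"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    if comparisons is None:
        ref = cfg.arms[-1]
        comparisons = [(a, ref) for a in cfg.arms if a != ref]
    contrasts: list[ComparisonResult] = []
    sis = sec.loc[sec["scale"] == "sis"].drop(columns="value")
    for hour in sorted(sis["hour"].unique()):
        sub = sis[sis["hour"] == hour].rename(columns={"numeric": "value"})
        for pair in comparisons:
            if (sub["arm"].isin(pair).groupby(sub["arm"]).sum().reindex(
                    list(pair)).fillna(0) < 2).any():
                continue  # pair not represented in this dataset
            res = ancova_pairwise(sub, pair, alpha=cfg.alpha)
            res.endpoint = f"sis_{int(hour)}h"
            contrasts.append(res)
    return summary, contrasts


# --------------------------------------------------------------------------- #
# Rubin's rules (optional MI pooling)
# --------------------------------------------------------------------------- #

def pool_rubin(estimates: np.ndarray, variances: np.ndarray) -> tuple[float, float, float]:
    """Pool repeated-imputation estimates by Rubin's rules.

    Returns (pooled estimate, total SE, Barnard-Rubin-style dof based on the
    classic large-sample formula).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    total = ubar + (1 + 1 / m) * b
    if b > 0:
        dof = (m - 1) * (1 + ubar / ((1 + 1 / m) * b)) ** 2
    else:
        dof = np.inf
    return float(qbar), float(np.sqrt(total)), float(dof)
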