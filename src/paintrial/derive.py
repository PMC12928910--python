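"""Endpoint derivation: windowing, intercurrent-event imputation, SPI/AUC,
rescue consumption, time to first rescue, and analysis populations.

The derivation turns raw observation/event tables into analysis-ready
endpoints under a fixed, deterministic rule order:

1. *Windowing* — every efficacy NPRS record is assigned to at most one
   nominal hour.  The window for nominal ``t_k`` is half-open
   ``(t_k - (t_k - t_{k-1})/2,  t_k + (t_{k+1} - t_k)/2]`` with the first
   window starting at 0 and the last ending at 72.  Within a window the
   record closest in absolute time wins; an exact tie keeps the earlier one.
2. *Rescue windows* — each acetaminophen dose opens a 6-h window, each
   tramadol dose a 4-h window; chained windows (a second dose before the
   first window closes) merge, ending at the maximum member end.  Nominal
   values inside a window are replaced by the score recorded immediately
   before the earliest dose of the chain, overriding observed values.
3. *WOCF* — from an AE / lack-of-efficacy discontinuation (including
   off-protocol rescue, handled as LOE) onward, values are set to the
   subject's worst (maximum) genuinely recorded value up to the event time.
4. *Leading missing* — values before the first non-missing observation take
   the same-arm median of observed scores at that timepoint.
5. *LOCF* — remaining interior/trailing missing values carry the last
   observation forward, except subjects who withdrew for other reasons,
   whose post-withdrawal cells are flagged for multiple imputation.
6. *Multiple imputation* — flagged cells are drawn 20 times from arm-wise
   sequential regressions on preceding timepoints with posterior noise;
   the analysis value is the across-imputation mean.

Summed pain intensity (SPI) through hour *H* is the trapezoidal area under
the NPRS curve built from actual-time observed points (all efficacy records,
regardless of windowing, with rules 2-3 applied) together with imputed
nominal points placed at their nominal hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TrialConfig
from .data import TrialData

__all__ = [
    "DerivationError",
    "DerivedSeries",
    "assign_windows",
    "build_rescue_windows",
    "check_rescue_limits",
    "impute_series",
    "multiple_impute",
    "compute_auc",
    "consumption",
    "time_to_first_rescue",
    "build_populations",
    "derive_trial",
    "DerivedTrial",
]

PROV_OBSERVED = "observed"
PROV_RESCUE = "rescue_window"
PROV_WOCF = "wocf"
PROV_MEDIAN = "median_pre_first"
PROV_LOCF = "locf"
PROV_MI_PENDING = "mi_pending"
PROV_MI = "mi_mean"
PROV_MISSING = "missing"

#: provenances that represent genuinely recorded (or rescue-carried) values,
#: the basis for WOCF maxima and for arm medians
_RECORDED = (PROV_OBSERVED, PROV_RESCUE)

_LOE_KINDS = ("ae_discontinuation", "loe_discontinuation", "off_protocol_rescue")


class DerivationError(ValueError):
    """Raised when an endpoint cannot be derived from the supplied tables."""


@dataclass
class DerivedSeries:
    """Per-subject NPRS values at nominal hours with provenance flags.

    All three frames share the same subject index and nominal-hour columns;
    ``actual_time`` holds the source collection time for observed cells.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    actual_time: pd.DataFrame

    def copy(self) -> "DerivedSeries":
        return DerivedSeries(
            self.values.copy(), self.provenance.copy(), self.actual_time.copy()
        )

    @property
    def hours(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)


def _efficacy_obs(pain: pd.DataFrame) -> pd.DataFrame:
    obs = pain[
        pain["context"].isin(["scheduled", "pre_rescue"])
        & (pain["time_h"] >= 0)
        & pain["score"].notna()
    ]
    return obs


# --------------------------------------------------------------------------- #
# windowing
# --------------------------------------------------------------------------- #

def assign_windows(
    pain: pd.DataFrame,
    schedule: tuple[float, ...] | np.ndarray,
    subjects: pd.Index | list | None = None,
) -> DerivedSeries:
    """Map efficacy observations to nominal hours (pre-imputation series).

    Pre-operative ``pre_dose`` records and negative times are excluded.
    ``subjects`` fixes the output row index (subjects with no usable
    observation get an all-missing row); by default the subjects appearing
    in ``pain`` are used.
    """
    sched = np.asarray(schedule, dtype=float)
    if len(sched) < 2 or np.any(np.diff(sched) <= 0):
        raise DerivationError("schedule must be strictly increasing")
    mids = (sched[:-1] + sched[1:]) / 2.0

    obs = _efficacy_obs(pain)
    obs = obs[obs["time_h"] <= sched[-1]].copy()
    k = np.searchsorted(mids, obs["time_h"].to_numpy(), side="left")
    obs["nominal"] = sched[k]
    obs["absdist"] = (obs["time_h"] - obs["nominal"]).abs()
    best = (
        obs.sort_values(["subject_id", "nominal", "absdist", "time_h"], kind="stable")
        .groupby(["subject_id", "nominal"], as_index=False)
        .first()
    )
    if subjects is None:
        subjects = pd.Index(sorted(set(pain["subject_id"])), name="subject_id")
    else:
        subjects = pd.Index(subjects, name="subject_id")
    values = best.pivot(index="subject_id", columns="nominal", values="score")
    actual = best.pivot(index="subject_id", columns="nominal", values="time_h")
    values = values.reindex(index=subjects, columns=sched).astype(float)
    actual = actual.reindex(index=subjects, columns=sched).astype(float)
    prov = values.where(values.isna(), PROV_OBSERVED).where(
        values.notna(), PROV_MISSING
    )
    return DerivedSeries(values, prov.astype(object), actual)


# --------------------------------------------------------------------------- #
# rescue windows
# --------------------------------------------------------------------------- #

def _window_length(drug: str, config: TrialConfig | None) -> float:
    if config is not None:
        return {
            "acetaminophen": config.apap_window_h,
            "tramadol": config.tramadol_window_h,
        }[drug]
    return {"acetaminophen": 6.0, "tramadol": 4.0}[drug]


def build_rescue_windows(
    rescue: pd.DataFrame,
    pain: pd.DataFrame,
    config: TrialConfig | None = None,
) -> pd.DataFrame:
    """Merged per-subject rescue-imputation windows with carry scores.

    Each dose opens a half-open window ``(time, time + 6 or 4]``; windows
    whose next dose falls strictly before the current end are chained and
    merged, ending at the maximum member end.  The carry score is the last
    efficacy NPRS at or before the earliest dose of the merged chain.

    Returns columns ``subject_id, start_h, end_h, carry_score, n_events``.
    """
    if rescue.empty:
        return pd.DataFrame(
            columns=["subject_id", "start_h", "end_h", "carry_score", "n_events"]
        )
    obs = _efficacy_obs(pain).sort_values("time_h", kind="stable")
    obs_map = {
        sid: (g["time_h"].to_numpy(), g["score"].to_numpy())
        for sid, g in obs.groupby("subject_id")
    }
    rows = []
    for sid, grp in rescue.sort_values("time_h", kind="stable").groupby("subject_id"):
        times = grp["time_h"].to_numpy()
        wlen = np.array([_window_length(d, config) for d in grp["drug"]])
        start = end = None
        n_ev = 0
        for t, w in zip(times, wlen):
            if start is None:
                start, end, n_ev = t, t + w, 1
            elif t < end:
                end = max(end, t + w)
                n_ev += 1
            else:
                rows.append((sid, start, end, n_ev))
                start, end, n_ev = t, t + w, 1
        rows.append((sid, start, end, n_ev))
    out = pd.DataFrame(rows, columns=["subject_id", "start_h", "end_h", "n_events"])
    carries = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        ot, ov = obs_map.get(row.subject_id, (np.array([]), np.array([])))
        k = np.searchsorted(ot, row.start_h, side="right") - 1
        if k < 0:
            raise DerivationError(
                f"subject {row.subject_id}: rescue at {row.start_h} h has "
                "no prior pain observation"
            )
        carries[i] = ov[k]
    out["carry_score"] = carries
    return out[["subject_id", "start_h", "end_h", "carry_score", "n_events"]]


def check_rescue_limits(rescue: pd.DataFrame, config: TrialConfig | None = None) -> pd.DataFrame:
    """Flag protocol dosing-limit violations (tolerated, not fatal).

    Checks the per-drug minimum re-dosing gap and the rolling 24-h dose cap;
    returns one row per violation with ``subject_id, drug, time_h, rule``.
    """
    cfg = config or TrialConfig()
    limits = {
        "acetaminophen": (cfg.apap_window_h, cfg.apap_max_mg_24h),
        "tramadol": (cfg.tramadol_window_h, cfg.tramadol_max_mg_24h),
    }
    bad = []
    for (sid, drug), grp in rescue.sort_values("time_h").groupby(["subject_id", "drug"]):
        gap, cap = limits[drug]
        t = grp["time_h"].to_numpy()
        d = grp["dose_mg"].to_numpy()
        for i in range(len(t)):
            if i > 0 and t[i] - t[i - 1] < gap:
                bad.append((sid, drug, t[i], "redose_gap"))
            window = (t > t[i] - 24) & (t <= t[i])
            if d[window].sum() > cap:
                bad.append((sid, drug, t[i], "daily_cap"))
    return pd.DataFrame(bad, columns=["subject_id", "drug", "time_h", "rule"])


# --------------------------------------------------------------------------- #
# imputation
# --------------------------------------------------------------------------- #

def _worst_recorded(series: DerivedSeries, event_time: float, sid) -> float:
    """Maximum recorded (observed or rescue-carried) value up to event time."""
    hours = series.hours
    prov = series.provenance.loc[sid].to_numpy()
    vals = series.values.loc[sid].to_numpy(dtype=float)
    mask = (hours <= event_time) & np.isin(prov, _RECORDED) & ~np.isnan(vals)
    if not mask.any():
        return np.nan
    return float(np.nanmax(vals[mask]))


def impute_series(
    series: DerivedSeries,
    rescue_windows: pd.DataFrame,
    events: pd.DataFrame,
    arm_of: pd.Series,
) -> DerivedSeries:
    """Apply the deterministic imputation rules in their fixed order.

    Rule order: rescue-window replacement (overriding observed values),
    worst-observation-carried-forward from AE/LOE discontinuation, same-arm
    timepoint medians for leading missing values, then LOCF — except cells
    after an other-cause withdrawal, which are flagged ``mi_pending`` for
    :func:`multiple_impute`.  Idempotent: re-running on its own output is a
    no-op (WOCF maxima and arm medians are always taken over genuinely
    recorded cells only).

    ``arm_of`` maps subject_id -> arm label for the group medians.
    """
    out = series.copy()
    hours = out.hours
    vals = out.values
    prov = out.provenance
    v = vals.to_numpy(dtype=float)
    p = prov.to_numpy(dtype=object)
    row_of = {sid: i for i, sid in enumerate(vals.index)}

    # (1) rescue-window replacement, overriding observed values
    for w in rescue_windows.itertuples(index=False):
        r = row_of.get(w.subject_id)
        if r is None:
            continue
        inside = (hours > w.start_h) & (hours <= w.end_h)
        v[r, inside] = w.carry_score
        p[r, inside] = PROV_RESCUE

    # (2) WOCF from AE/LOE discontinuation onward
    wocf_events = events[events["kind"].isin(_LOE_KINDS)] if len(events) else events
    recorded = np.isin(p, _RECORDED) & ~np.isnan(v)
    for ev in wocf_events.itertuples(index=False):
        r = row_of.get(ev.subject_id)
        if r is None:
            continue
        upto = recorded[r] & (hours <= ev.time_h)
        if not upto.any():
            continue  # nothing recorded yet; later rules fill these cells
        worst = np.nanmax(v[r, upto])
        onward = hours >= ev.time_h
        v[r, onward] = worst
        p[r, onward] = PROV_WOCF

    # (3) leading missing -> same-arm timepoint median of observed scores
    observed_only = pd.DataFrame(
        np.where(p == PROV_OBSERVED, v, np.nan), index=vals.index, columns=vals.columns
    )
    arm_index = arm_of.reindex(vals.index)
    medians = observed_only.groupby(arm_index).median()
    nonmiss = ~np.isnan(v)
    first_idx = np.where(nonmiss.any(axis=1), nonmiss.argmax(axis=1), v.shape[1])
    col_pos = np.arange(v.shape[1])
    lead_rows = np.flatnonzero(first_idx > 0)
    for i in lead_rows:
        lead = (col_pos < first_idx[i]) & np.isnan(v[i])
        if not lead.any():
            continue
        arm = arm_index.iloc[i]
        med = medians.loc[arm].to_numpy(dtype=float)
        if np.isnan(med[lead]).any():
            bad = hours[lead][np.isnan(med[lead])][0]
            raise DerivationError(
                f"no observed score in arm '{arm}' at hour {bad}: "
                "leading-missing median unavailable"
            )
        v[i, lead] = med[lead]
        p[i, lead] = PROV_MEDIAN

    # (4) LOCF, except post-withdrawal cells which await multiple imputation
    withdraw_time = pd.Series(np.inf, index=vals.index)
    if len(events):
        wd = events[events["kind"] == "withdrawal_other"]
        withdraw_time.update(wd.set_index("subject_id")["time_h"])
    missing = np.isnan(v)
    mi_cells = missing & (hours[None, :] >= withdraw_time.to_numpy()[:, None])
    ffilled = pd.DataFrame(v).ffill(axis=1).to_numpy()
    locf_cells = missing & ~mi_cells & ~np.isnan(ffilled)
    v[locf_cells] = ffilled[locf_cells]
    p[locf_cells] = PROV_LOCF
    p[mi_cells] = PROV_MI_PENDING

    out.values = pd.DataFrame(v, index=vals.index, columns=vals.columns)
    out.provenance = pd.DataFrame(p, index=prov.index, columns=prov.columns)
    still = out.values.isna() & (out.provenance != PROV_MI_PENDING)
    if still.to_numpy().any():
        sid = out.values.index[still.any(axis=1)][0]
        raise DerivationError(f"subject {sid}: values remain missing after imputation")
    return out


def multiple_impute(
    series: DerivedSeries,
    arm_of: pd.Series,
    n_imputations: int = 20,
    seed: int = 0,
    max_predictors: int = 3,
) -> tuple[DerivedSeries, list[pd.DataFrame]]:
    """Fill ``mi_pending`` cells by arm-wise sequential (monotone) regression.

    For each timepoint with flagged cells, an ordinary regression of that
    timepoint on the ``max_predictors`` preceding timepoints is fitted to the
    arm's donors; each of the ``n_imputations`` datasets draws residual
    variance from its scaled inverse-chi-square posterior, coefficients from
    their normal posterior and adds predictive noise, clamping to [0, 10].
    The analysis value of a flagged cell is the across-imputation mean
    (provenance ``mi_mean``).  Returns the completed series and the
    individual imputed datasets.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    vals = series.values
    prov = series.provenance
    mi_mask = (prov == PROV_MI_PENDING).to_numpy()
    if not mi_mask.any():
        out = series.copy()
        return out, [vals.copy() for _ in range(n_imputations)]

    hours = series.hours
    arm_index = arm_of.reindex(vals.index)
    base = vals.to_numpy(dtype=float)
    datasets = [base.copy() for _ in range(n_imputations)]
    for arm in arm_index.dropna().unique():
        rows = np.flatnonzero((arm_index == arm).to_numpy())
        if not mi_mask[rows].any():
            continue
        complete = rows[~mi_mask[rows].any(axis=1)]
        if len(complete) < 2:
            raise DerivationError(
                f"arm '{arm}': fewer than 2 complete subjects for multiple imputation"
            )
        for j in range(len(hours)):
            need = rows[mi_mask[rows, j]]
            if need.size == 0:
                continue
            lo = max(0, j - max_predictors)
            pred_cols = np.arange(lo, j)
            donors = rows[~mi_mask[rows, j]]
            if pred_cols.size:
                donors = donors[~mi_mask[donors][:, pred_cols].any(axis=1)]
            y = base[donors, j]
            if pred_cols.size == 0 or len(donors) < pred_cols.size + 2:
                # degenerate: draw around the donor mean
                mu, sd = float(y.mean()), float(y.std(ddof=1)) if len(y) > 1 else 0.0
                for m in range(n_imputations):
                    draw = mu + sd * rng.standard_normal(need.size)
                    datasets[m][need, j] = np.clip(draw, 0, 10)
                continue
            X = np.column_stack([np.ones(len(donors)), base[donors][:, pred_cols]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            df = max(len(donors) - X.shape[1], 1)
            s2 = float(resid @ resid) / df
            XtX_inv = np.linalg.pinv(X.T @ X)
            for m in range(n_imputations):
                sigma2 = s2 * df / rng.chisquare(df) if s2 > 0 else 0.0
                if sigma2 > 0:
                    beta_m = rng.multivariate_normal(beta, sigma2 * XtX_inv)
                else:
                    beta_m = beta
                Xn = np.column_stack(
                    [np.ones(need.size), datasets[m][need][:, pred_cols]]
                )
                draw = Xn @ beta_m + np.sqrt(sigma2) * rng.standard_normal(need.size)
                datasets[m][need, j] = np.clip(draw, 0, 10)

    out = series.copy()
    mean = np.mean(np.stack(datasets), axis=0)
    v = out.values.to_numpy(dtype=float)
    v[mi_mask] = mean[mi_mask]
    out.values = pd.DataFrame(v, index=vals.index, columns=vals.columns)
    p = out.provenance.to_numpy(dtype=object)
    p[mi_mask] = PROV_MI
    out.provenance = pd.DataFrame(p, index=prov.index, columns=prov.columns)
    frames = [pd.DataFrame(d, index=vals.index, columns=vals.columns) for d in datasets]
    return out, frames


# --------------------------------------------------------------------------- #
# AUC / SPI
# --------------------------------------------------------------------------- #

def compute_auc(times, values, through_hour: float, grace_h: float = 0.5) -> float:
    """Trapezoidal area under the score curve from 0 through ``through_hour``.

    ``times``/``values`` are the subject's curve points (actual-time observed
    plus nominal-hour imputed values); duplicate times keep their first
    value.  The endpoint value is linearly interpolated if ``through_hour``
    falls between points.  Collections jitter within minutes of the nominal
    boundary hours, so the curve is extended flat over gaps of at most
    ``grace_h`` at either end; a larger gap raises :class:`DerivationError`.
    """
    if not 0 < through_hour <= 72:
        raise DerivationError(f"through_hour must lie in (0, 72], got {through_hour}")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    uniq = np.concatenate(([True], np.diff(t) > 0))
    t, v = t[uniq], v[uniq]
    if t.size == 0:
        raise DerivationError("curve has no points")
    if t[0] > grace_h:
        raise DerivationError(f"curve starts at {t[0]} h, no value near hour 0")
    if t[0] > 0:
        t = np.concatenate(([0.0], t))
        v = np.concatenate(([v[0]], v))
    if t[-1] < through_hour - grace_h:
        raise DerivationError(
            f"curve ends at {t[-1]} h, before through_hour {through_hour}"
        )
    if t[-1] < through_hour:
        t = np.concatenate((t, [through_hour]))
        v = np.concatenate((v, [v[-1]]))
    keep = t <= through_hour
    tt = t[keep]
    vv = v[keep]
    if tt[-1] < through_hour:
        tt = np.append(tt, through_hour)
        vv = np.append(vv, np.interp(through_hour, t, v))
    return float(np.trapezoid(vv, tt))


# --------------------------------------------------------------------------- #
# consumption and time to rescue
# --------------------------------------------------------------------------- #

def consumption(
    rescue: pd.DataFrame,
    interval: tuple[float, float],
    meq_factor: float = 0.1,
    subjects: pd.Index | list | None = None,
) -> pd.DataFrame:
    """Per-subject rescue-drug totals over the half-open interval [start, end).

    Returns ``subject_id, start_h, end_h, acetaminophen_mg, tramadol_mg,
    tramadol_meq_mg`` with ``tramadol_meq_mg = tramadol_mg * meq_factor``
    (morphine equivalents).  ``subjects`` adds zero rows for subjects with
    no event.
    """
    if meq_factor <= 0:
        raise DerivationError("meq_factor must be > 0")
    start, end = interval
    inside = rescue[(rescue["time_h"] >= start) & (rescue["time_h"] < end)]
    totals = (
        inside.pivot_table(
            index="subject_id", columns="drug", values="dose_mg", aggfunc="sum"
        )
        .reindex(columns=["acetaminophen", "tramadol"])
        .fillna(0.0)
    )
    if subjects is not None:
        totals = totals.reindex(pd.Index(subjects, name="subject_id")).fillna(0.0)
    out = totals.rename(
        columns={"acetaminophen": "acetaminophen_mg", "tramadol": "tramadol_mg"}
    ).reset_index()
    out.insert(1, "start_h", start)
    out.insert(2, "end_h", end)
    out["tramadol_meq_mg"] = out["tramadol_mg"] * meq_factor
    return out


def time_to_first_rescue(
    rescue: pd.DataFrame, roster: pd.DataFrame, horizon: float = 72.0
) -> pd.DataFrame:
    """Time to first rescue use, censored at the horizon.

    Subjects who never used rescue medication, or whose first use falls after
    the horizon, are censored at ``horizon``; subjects without surgery are
    excluded.  Returns ``subject_id, time_h, event``.
    """
    eligible = roster[roster["had_surgery"]]
    first = rescue.groupby("subject_id")["time_h"].min()
    t = first.reindex(eligible["subject_id"])
    event = (t <= horizon).fillna(False).astype(int)
    t = t.where(event == 1, horizon).fillna(horizon).clip(upper=horizon)
    return pd.DataFrame(
        {"subject_id": eligible["subject_id"].to_numpy(), "time_h": t.to_numpy(),
         "event": event.to_numpy()}
    )


def build_populations(
    roster: pd.DataFrame,
    pain: pd.DataFrame,
    deviations: list | pd.Series | None = None,
) -> pd.DataFrame:
    """ITT / mITT / PPS / observed-ITT membership flags.

    ITT = all randomized; mITT = ITT who were dosed and have at least one
    post-surgery NPRS; PPS = mITT without a major protocol deviation;
    observed-ITT = ITT (analyzed with minimal imputation).  The nesting
    pps <= mitt <= itt holds by construction.
    """
    has_obs = set(_efficacy_obs(pain)["subject_id"])
    if deviations is None:
        deviators = set(roster.loc[roster.get("major_deviation", False), "subject_id"])
    else:
        deviators = set(deviations)
    itt = pd.Series(True, index=roster["subject_id"])
    mitt = (
        roster.set_index("subject_id")["dosed"]
        & itt.index.isin(has_obs)
    )
    pps = mitt & ~mitt.index.isin(deviators)
    return pd.DataFrame(
        {
            "subject_id": roster["subject_id"].to_numpy(),
            "itt": itt.to_numpy(),
            "mitt": mitt.to_numpy(),
            "pps": pps.to_numpy(),
            "observed_itt": itt.to_numpy(),
        }
    )


# --------------------------------------------------------------------------- #
# full derivation
# --------------------------------------------------------------------------- #

@dataclass
class DerivedTrial:
    """Analysis-ready endpoints for one trial."""

    config: TrialConfig
    series: DerivedSeries
    imputed_datasets: list[pd.DataFrame] = field(repr=False, default_factory=list)
    rescue_windows: pd.DataFrame | None = None
    populations: pd.DataFrame | None = None
    time_to_rescue: pd.DataFrame | None = None
    arm_of: pd.Series | None = None
    _adjusted_obs: pd.DataFrame | None = field(repr=False, default=None)

    def spi(self, through_hour: float, subjects=None) -> pd.Series:
        """Per-subject summed pain intensity through ``through_hour``."""
        vals = self.series.values
        prov = self.series.provenance
        hours = self.series.hours
        if subjects is None:
            subjects = vals.index
        obs_by_subject = (
            dict(tuple(self._adjusted_obs.groupby("subject_id")))
            if self._adjusted_obs is not None
            else {}
        )
        out = {}
        for sid in subjects:
            p = prov.loc[sid].to_numpy()
            v = vals.loc[sid].to_numpy(dtype=float)
            imput = p != PROV_OBSERVED
            t_pts = list(hours[imput])
            v_pts = list(v[imput])
            sub_obs = obs_by_subject.get(sid)
            if sub_obs is not None:
                t_pts += list(sub_obs["time_h"])
                v_pts += list(sub_obs["score"])
            else:
                t_pts += list(hours[~imput])
                v_pts += list(v[~imput])
            out[sid] = compute_auc(t_pts, v_pts, through_hour)
        return pd.Series(out, name=f"spi{int(through_hour)}")


def _adjust_observations(
    pain: pd.DataFrame,
    windows: pd.DataFrame,
    events: pd.DataFrame,
    worst_of: dict,
) -> pd.DataFrame:
    """All efficacy records at actual times with rescue/WOCF rules applied."""
    obs = (
        _efficacy_obs(pain)[["subject_id", "time_h", "score"]]
        .sort_values(["subject_id", "time_h"], kind="stable")
        .reset_index(drop=True)
    )
    t = obs["time_h"].to_numpy()
    s = obs["score"].to_numpy(dtype=float)
    sids = obs["subject_id"].to_numpy()
    bounds = np.concatenate(
        ([0], np.flatnonzero(sids[1:] != sids[:-1]) + 1, [len(sids)])
    )
    slice_of = {
        sids[lo]: (lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:]) if hi > lo
    }
    for w in windows.itertuples(index=False):
        span = slice_of.get(w.subject_id)
        if span is None:
            continue
        lo, hi = span
        inside = (t[lo:hi] > w.start_h) & (t[lo:hi] <= w.end_h)
        s[lo:hi][inside] = w.carry_score
    wocf_events = events[events["kind"].isin(_LOE_KINDS)] if len(events) else events
    for ev in wocf_events.itertuples(index=False):
        worst = worst_of.get(ev.subject_id, np.nan)
        span = slice_of.get(ev.subject_id)
        if span is None or np.isnan(worst):
            continue
        lo, hi = span
        s[lo:hi][t[lo:hi] >= ev.time_h] = worst
    obs["score"] = s
    return obs


def derive_trial(
    trial: TrialData,
    config: TrialConfig | None = None,
    seed: int = 0,
    minimal: bool = False,
) -> DerivedTrial:
    """Run the complete derivation pipeline on one trial.

    ``minimal=True`` applies only the rescue-window replacement and LOCF to
    span the assessment grid (the observed-data ITT convention); the full
    mode applies every rule including multiple imputation.
    """
    config = config or TrialConfig()
    roster = trial.roster
    arm_of = roster.set_index("subject_id")["arm"]
    series = assign_windows(
        trial.pain, config.schedule_hours, subjects=roster["subject_id"]
    )
    windows = build_rescue_windows(trial.rescue, trial.pain, config)
    events = trial.events if not minimal else trial.events.iloc[0:0]
    imputed = impute_series(series, windows, events, arm_of)
    if minimal:
        datasets: list[pd.DataFrame] = []
    else:
        imputed, datasets = multiple_impute(
            imputed, arm_of, n_imputations=config.n_imputations, seed=seed
        )
    worst_of = {}
    if len(events):
        for _, ev in events[events["kind"].isin(_LOE_KINDS)].iterrows():
            worst_of[ev["subject_id"]] = _worst_recorded(
                imputed, ev["time_h"], ev["subject_id"]
            )
    adjusted = _adjust_observations(trial.pain, windows, events, worst_of)
    return DerivedTrial(
        config=config,
        series=imputed,
        imputed_datasets=datasets,
        rescue_windows=windows,
        populations=build_populations(roster, trial.pain),
        time_to_rescue=time_to_first_rescue(trial.rescue, roster),
        arm_of=arm_of,
        _adjusted_obs=adjusted,
    )
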