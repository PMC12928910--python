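"""Synthetic acute-pain trial generator.

Generates complete three-arm bunionectomy-style trials with the structure the
downstream derivation and inference stages assume: stratified permuted-block
randomization (blocks of 6, site-stratified), scheduled NPRS assessments over
72 h with +/-10 min collection jitter, pain-threshold-driven rescue dosing
(acetaminophen q6h up to 4 g/24 h; tramadol q4h up to 300 mg/24 h), rescue
relief that masks the underlying pain for the drug window, intercurrent
events (AE and lack-of-efficacy discontinuations, off-protocol rescue,
withdrawals, missed surgery), and secondary scales (PGA, SIS, NNRS).

Randomness policy: one master seed; every subject draws from an independent
substream keyed by subject index, so enlarging the trial never perturbs
existing subjects.  Separate substreams drive site effects, site allocation
and the randomization list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    NNRS_HOURS,
    PGA_CATEGORIES,
    PGA_SIS_HOURS,
    ConfigurationError,
    TrialConfig,
)
from .data import TrialData

__all__ = [
    "randomize_blocked",
    "make_roster",
    "simulate_pain_trajectories",
    "simulate_rescue_and_events",
    "simulate_secondary_scores",
    "simulate_trial",
    "emit_trial_tables",
]


# --------------------------------------------------------------------------- #
# random substreams
# --------------------------------------------------------------------------- #

def _stream(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def eval_times(schedule: tuple[float, ...]) -> np.ndarray:
    """Rescue-decision times: scheduled hours plus interval midpoints."""
    out: list[float] = []
    for a, b in zip(schedule[:-1], schedule[1:]):
        out.append(a)
        out.append((a + b) / 2.0)
    out.append(schedule[-1])
    return np.asarray(out)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def subject_draws(config: TrialConfig, seed: int, n: int) -> dict[str, np.ndarray]:
    """All subject-level randomness, one independent substream per subject.

    The draw layout is fixed so that every generator stage sees the same
    values for a given (seed, subject index).
    """
    n_sched = len(config.schedule_hours)
    n_eval = len(eval_times(config.schedule_hours))
    cols: dict[str, list] = {k: [] for k in (
        "intercept", "sched_noise", "jitter", "u_miss0", "u_sporadic",
        "u_tram_only", "u_ae", "t_ae", "u_wd", "t_wd", "u_opr", "t_opr",
        "u_nosurg", "u_nodose", "u_dev", "predose_noise",
        "rescue_u", "rescue_noise", "loe_u", "sis_noise", "pga_noise",
        "nnrs_noise",
    )}
    for i in range(n):
        g = _stream(seed, (0, i))
        cols["intercept"].append(g.normal())
        cols["sched_noise"].append(g.normal(size=n_sched))
        cols["jitter"].append(g.uniform(-1 / 6, 1 / 6, size=n_sched))
        cols["u_miss0"].append(g.random())
        cols["u_sporadic"].append(g.random(n_sched))
        cols["u_tram_only"].append(g.random())
        cols["u_ae"].append(g.random())
        cols["t_ae"].append(g.uniform(2, 70))
        cols["u_wd"].append(g.random())
        cols["t_wd"].append(g.uniform(2, 70))
        cols["u_opr"].append(g.random())
        cols["t_opr"].append(g.uniform(2, 70))
        cols["u_nosurg"].append(g.random())
        cols["u_nodose"].append(g.random())
        cols["u_dev"].append(g.random())
        cols["predose_noise"].append(g.normal())
        cols["rescue_u"].append(g.random(n_eval))
        cols["rescue_noise"].append(g.normal(size=n_eval))
        cols["loe_u"].append(g.random(n_eval))
        cols["sis_noise"].append(g.normal(size=len(PGA_SIS_HOURS)))
        cols["pga_noise"].append(g.normal(size=len(PGA_SIS_HOURS)))
        cols["nnrs_noise"].append(g.normal(size=len(NNRS_HOURS)))
    return {k: np.asarray(v) for k, v in cols.items()}


def site_effects(config: TrialConfig, seed: int) -> np.ndarray:
    return _stream(seed, (3,)).normal(0.0, config.site_sd, size=config.n_sites)


# --------------------------------------------------------------------------- #
# randomization and roster
# --------------------------------------------------------------------------- #

def randomize_blocked(
    site_ids: np.ndarray,
    config: TrialConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Permuted-block randomization stratified by site.

    Subjects are assigned in enrollment order; each site draws fresh permuted
    blocks containing every arm ``block_size / n_arms`` times.  Returns the
    arm labels and the per-site block index of each subject.
    """
    arms = config.arms
    if config.block_size % len(arms) != 0:
        raise ConfigurationError(
            f"block_size {config.block_size} not divisible by {len(arms)} arms"
        )
    reps = config.block_size // len(arms)
    template = np.repeat(np.asarray(arms, dtype=object), reps)
    assignment = np.empty(len(site_ids), dtype=object)
    block_idx = np.empty(len(site_ids), dtype=int)
    buffers: dict[object, list] = {}
    counters: dict[object, int] = {}
    for i, s in enumerate(site_ids):
        if not buffers.get(s):
            counters[s] = counters.get(s, -1) + 1
            buffers[s] = list(rng.permutation(template))
        assignment[i] = buffers[s].pop(0)
        block_idx[i] = counters[s]
    return assignment, block_idx


def make_roster(
    config: TrialConfig,
    seed: int,
    draws: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Roster for ``n_per_arm * n_arms`` subjects with flags for surgery,
    dosing and major protocol deviations."""
    n = config.n_per_arm * len(config.arms)
    if draws is None:
        draws = subject_draws(config, seed, n)
    sites = _stream(seed, (1,)).integers(0, config.n_sites, size=n)
    site_ids = np.array([f"site{k + 1}" for k in sites], dtype=object)
    arms, blocks = randomize_blocked(site_ids, config, _stream(seed, (2,)))
    nosurg_rate = np.array([config.dropout_rate("no_surgery", a) for a in arms])
    nodose_rate = np.array([config.dropout_rate("never_dosed", a) for a in arms])
    had_surgery = draws["u_nosurg"] >= nosurg_rate
    dosed = had_surgery & (draws["u_nodose"] >= nodose_rate)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "site_id": site_ids,
            "arm": arms,
            "randomization_block": blocks,
            "had_surgery": had_surgery,
            "dosed": dosed,
            "major_deviation": draws["u_dev"] < config.major_deviation_prob,
        }
    )


# --------------------------------------------------------------------------- #
# latent pain
# --------------------------------------------------------------------------- #

def _latent_matrix(
    roster: pd.DataFrame,
    times: np.ndarray,
    config: TrialConfig,
    intercepts: np.ndarray,
    site_eff: np.ndarray,
) -> np.ndarray:
    """Latent (noise-free, rescue-free) pain for each subject at ``times``.

    ``times`` may be one row per subject (2-D) or a shared 1-D grid.
    """
    site_idx = roster["site_id"].str.removeprefix("site").astype(int).to_numpy() - 1
    base = np.zeros((len(roster), times.shape[-1]))
    for arm, traj in config.effect_model.items():
        mask = (roster["arm"] == arm).to_numpy()
        if not mask.any():
            continue
        t_arm = times[mask] if times.ndim == 2 else times[None, :]
        base[mask] = traj.mean(t_arm)
    return base + intercepts[:, None] + site_eff[site_idx][:, None]


def _terminal_times(
    roster: pd.DataFrame, config: TrialConfig, draws: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-drawn terminal intercurrent events (AE, withdrawal, off-protocol).

    Lack-of-efficacy discontinuations are produced dynamically by the rescue
    model.  Returns (time, kind) with ``inf``/'' for subjects without one.
    """
    arms = roster["arm"].to_numpy()
    n = len(roster)
    time = np.full(n, np.inf)
    kind = np.full(n, "", dtype=object)
    specs = (
        ("ae_discontinuation", "u_ae", "t_ae"),
        ("withdrawal_other", "u_wd", "t_wd"),
        ("off_protocol_rescue", "u_opr", "t_opr"),
    )
    for name, u_key, t_key in specs:
        rate = np.array([config.dropout_rate(name, a) for a in arms])
        hit = (draws[u_key] < rate) & (draws[t_key] < time)
        time[hit] = draws[t_key][hit]
        kind[hit] = name
    nosurg = ~roster["had_surgery"].to_numpy()
    time[nosurg] = np.inf
    kind[nosurg] = ""
    return time, kind


# --------------------------------------------------------------------------- #
# pain observations
# --------------------------------------------------------------------------- #

def simulate_pain_trajectories(
    roster: pd.DataFrame,
    config: TrialConfig,
    seed: int,
    draws: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Scheduled NPRS observations before any rescue relief is applied.

    One row per subject per scheduled hour (jittered within +/-10 min,
    clipped at 0), integer scores in [0, 10], plus one pre-operative
    ``pre_dose`` record per subject at -1 h.  No missingness or event
    truncation is applied here; :func:`simulate_rescue_and_events` produces
    the final observed table.
    """
    n = len(roster)
    if draws is None:
        draws = subject_draws(config, seed, n)
    sched = np.asarray(config.schedule_hours)
    times = np.clip(sched[None, :] + draws["jitter"], 0.0, None)
    intercepts = draws["intercept"] * config.between_subject_sd
    latent = _latent_matrix(roster, times, config, intercepts, site_effects(config, seed))
    scores = np.clip(
        _round_half_up(latent + draws["sched_noise"] * config.within_subject_sd), 0, 10
    )
    subject_ids = roster["subject_id"].to_numpy()
    scheduled = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, len(sched)),
            "time_h": times.ravel(),
            "score": scores.ravel(),
            "context": "scheduled",
        }
    )
    pre_dose = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "time_h": -1.0,
            "score": np.clip(_round_half_up(2.0 + draws["predose_noise"] * 1.5), 0, 10),
            "context": "pre_dose",
        }
    )
    return pd.concat([scheduled, pre_dose], ignore_index=True)


# --------------------------------------------------------------------------- #
# rescue dosing and intercurrent events
# --------------------------------------------------------------------------- #

def simulate_rescue_and_events(
    pain: pd.DataFrame,
    roster: pd.DataFrame,
    config: TrialConfig,
    seed: int,
    draws: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rescue doses, intercurrent events, and the final observed pain table.

    The decision model is a per-hour hazard
    ``base * exp(slope * (pain - threshold))`` (while current pain > 0)
    evaluated at scheduled hours and interval midpoints; ``seed`` must be the
    one used to generate ``pain`` so the subject substreams line up.  The
    drug is acetaminophen unless its 6-h re-dose gap or 4 g/24 h cap blocks
    it (or the subject is acetaminophen-intolerant), then tramadol under its
    own 4-h/300 mg constraints; if neither drug is available while pain is at
    or above the threshold the subject discontinues for lack of efficacy.
    Each dose is paired with a ``pre_rescue`` NPRS record and masks
    ``rescue_relief`` points of pain for the drug window.

    Returns ``(rescue_events, intercurrent_events, pain_observed)`` where
    ``pain_observed`` has rescue relief, event truncation and missingness
    applied and includes the ``pre_rescue`` records.
    """
    n = len(roster)
    if draws is None:
        draws = subject_draws(config, seed, n)
    sched = np.asarray(config.schedule_hours)
    evals = eval_times(config.schedule_hours)
    intercepts = draws["intercept"] * config.between_subject_sd
    site_eff = site_effects(config, seed)
    latent_eval = _latent_matrix(roster, evals, config, intercepts, site_eff)

    term_time, term_kind = _terminal_times(roster, config, draws)
    active_base = roster["had_surgery"].to_numpy() & roster["dosed"].to_numpy()

    max_apap = int(np.ceil(72 / config.apap_window_h)) + 2
    max_tram = int(np.ceil(72 / config.tramadol_window_h)) + 2
    apap_times = np.full((n, max_apap), -np.inf)
    tram_times = np.full((n, max_tram), -np.inf)
    apap_n = np.zeros(n, dtype=int)
    tram_n = np.zeros(n, dtype=int)
    relief_until = np.full(n, -np.inf)
    tram_only = draws["u_tram_only"] < config.tramadol_only_prob

    rescue_rows: list[pd.DataFrame] = []
    pre_rescue_rows: list[pd.DataFrame] = []
    subject_ids = roster["subject_id"].to_numpy()

    for i in range(1, len(evals)):
        t = evals[i]
        dt = t - evals[i - 1]
        pain_eff = np.clip(
            latent_eval[:, i] - config.rescue_relief * (t <= relief_until), 0.0, None
        )
        lam = np.where(
            pain_eff > 0,
            config.rescue_hazard_base
            * np.exp(
                config.rescue_hazard_slope * (pain_eff - config.rescue_threshold)
                - config.rescue_hazard_time_decay * t
            ),
            0.0,
        )
        p = 1.0 - np.exp(-lam * dt)
        want = active_base & (t < term_time) & (draws["rescue_u"][:, i] < p)
        if not want.any():
            continue
        apap_recent = (apap_times > t - 24).sum(axis=1)
        tram_recent = (tram_times > t - 24).sum(axis=1)
        last_apap = apap_times.max(axis=1)
        last_tram = tram_times.max(axis=1)
        apap_ok = (
            ~tram_only
            & (t - last_apap >= config.apap_window_h)
            & ((apap_recent + 1) * config.apap_dose_mg <= config.apap_max_mg_24h)
        )
        tram_ok = (t - last_tram >= config.tramadol_window_h) & (
            (tram_recent + 1) * config.tramadol_dose_mg <= config.tramadol_max_mg_24h
        )
        give_apap = want & apap_ok
        give_tram = want & ~apap_ok & tram_ok
        # blocked by caps/gaps with pain still at/above threshold: a fraction
        # of these subjects stop for lack of efficacy, the rest wait
        loe = (
            want
            & ~apap_ok
            & ~tram_ok
            & (pain_eff >= config.rescue_threshold)
            & (draws["loe_u"][:, i] < config.loe_prob)
        )

        for mask, drug, dose, window, times_arr, counts in (
            (give_apap, "acetaminophen", config.apap_dose_mg,
             config.apap_window_h, apap_times, apap_n),
            (give_tram, "tramadol", config.tramadol_dose_mg,
             config.tramadol_window_h, tram_times, tram_n),
        ):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            times_arr[idx, counts[idx]] = t
            counts[idx] += 1
            relief_until[idx] = np.maximum(relief_until[idx], t + window)
            rescue_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_ids[idx],
                        "drug": drug,
                        "dose_mg": dose,
                        "time_h": t,
                    }
                )
            )
            score = np.clip(
                _round_half_up(
                    pain_eff[idx]
                    + draws["rescue_noise"][idx, i] * config.within_subject_sd
                ),
                0,
                10,
            )
            pre_rescue_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_ids[idx],
                        "time_h": t,
                        "score": score,
                        "context": "pre_rescue",
                    }
                )
            )
        if loe.any():
            term_time[loe] = t
            term_kind[loe] = "loe_discontinuation"

    rescue = (
        pd.concat(rescue_rows, ignore_index=True)
        .sort_values(["subject_id", "time_h"], kind="stable")
        .reset_index(drop=True)
        if rescue_rows
        else pd.DataFrame(columns=["subject_id", "drug", "dose_mg", "time_h"])
    )

    has_event = np.isfinite(term_time) & (term_time <= 72)
    events = pd.DataFrame(
        {
            "subject_id": subject_ids[has_event],
            "kind": term_kind[has_event],
            "time_h": term_time[has_event],
        }
    )

    # rebuild the scheduled observations with rescue relief applied
    times = np.clip(sched[None, :] + draws["jitter"], 0.0, None)
    latent_sched = _latent_matrix(roster, times, config, intercepts, site_eff)
    covered = np.zeros_like(times, dtype=bool)
    for times_arr, window in (
        (apap_times, config.apap_window_h),
        (tram_times, config.tramadol_window_h),
    ):
        delta = times[:, None, :] - times_arr[:, :, None]
        covered |= ((delta > 0) & (delta <= window)).any(axis=1)
    scores = np.clip(
        _round_half_up(
            latent_sched
            - config.rescue_relief * covered
            + draws["sched_noise"] * config.within_subject_sd
        ),
        0,
        10,
    )
    keep = (
        roster["had_surgery"].to_numpy()[:, None]
        & (times <= np.minimum(term_time, 72.0)[:, None])
    )
    keep[:, 0] &= draws["u_miss0"] >= config.missing_hour0_prob
    keep[:, 1:] &= draws["u_sporadic"][:, 1:] >= config.sporadic_missing_prob
    scheduled = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, len(sched)),
            "time_h": times.ravel(),
            "score": scores.ravel(),
            "context": "scheduled",
        }
    )[keep.ravel()]

    pre_dose = pain[pain["context"] == "pre_dose"]
    parts = [scheduled, pre_dose]
    if pre_rescue_rows:
        parts.insert(1, pd.concat(pre_rescue_rows, ignore_index=True))
    pain_observed = (
        pd.concat(parts, ignore_index=True)
        .sort_values(["subject_id", "time_h"], kind="stable")
        .reset_index(drop=True)
    )
    return rescue, events, pain_observed


# --------------------------------------------------------------------------- #
# secondary scales
# --------------------------------------------------------------------------- #

def simulate_secondary_scores(
    roster: pd.DataFrame,
    config: TrialConfig,
    seed: int,
    events: pd.DataFrame | None = None,
    draws: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """PGA and SIS at 24/48/72 h and NNRS at the nausea schedule.

    PGA and SIS are driven by the subject's mean latent pain over the
    preceding 24 h (better pain control -> higher PGA, lower SIS); NNRS is a
    low-level nuisance scale with no arm effect.  Rows after a terminal
    intercurrent event are omitted.
    """
    n = len(roster)
    if draws is None:
        draws = subject_draws(config, seed, n)
    intercepts = draws["intercept"] * config.between_subject_sd
    site_eff = site_effects(config, seed)
    term = pd.Series(np.inf, index=roster["subject_id"])
    if events is not None and len(events):
        term.update(events.set_index("subject_id")["time_h"])
    term_arr = term.to_numpy()
    subject_ids = roster["subject_id"].to_numpy()
    surg = roster["had_surgery"].to_numpy()
    rows: list[pd.DataFrame] = []

    grid = np.linspace(0.5, 24, 24)
    for j, hour in enumerate(PGA_SIS_HOURS):
        window = hour - 24 + grid
        mean_pain = _latent_matrix(
            roster, window, config, intercepts, site_eff
        ).mean(axis=1)
        keep = surg & (hour <= term_arr)
        sis = np.clip(
            _round_half_up(0.65 * mean_pain + draws["sis_noise"][:, j]), 0, 10
        )
        pga_num = np.clip(
            _round_half_up(4.3 - 0.5 * mean_pain + 0.9 * draws["pga_noise"][:, j]),
            0,
            4,
        ).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[keep],
                    "scale": "sis",
                    "hour": float(hour),
                    "value": sis[keep].astype(str),
                }
            )
        )
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[keep],
                    "scale": "pga",
                    "hour": float(hour),
                    "value": np.asarray(PGA_CATEGORIES, dtype=object)[pga_num[keep]],
                }
            )
        )
    for j, hour in enumerate(NNRS_HOURS):
        keep = surg & (hour <= term_arr)
        nnrs = np.clip(_round_half_up(0.35 + 0.8 * draws["nnrs_noise"][:, j]), 0, 10)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[keep],
                    "scale": "nnrs",
                    "hour": float(hour),
                    "value": nnrs[keep].astype(str),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------- #
# orchestration
# --------------------------------------------------------------------------- #

def simulate_trial(config: TrialConfig, seed: int | None = None) -> TrialData:
    """Generate one complete synthetic trial."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigurationError("a seed is required (argument or config.seed)")
    n = config.n_per_arm * len(config.arms)
    draws = subject_draws(config, seed, n)
    roster = make_roster(config, seed, draws=draws)
    pain0 = simulate_pain_trajectories(roster, config, seed, draws=draws)
    rescue, events, pain = simulate_rescue_and_events(
        pain0, roster, config, seed, draws=draws
    )
    secondary = simulate_secondary_scores(
        roster, config, seed, events=events, draws=draws
    )
    trial = TrialData(
        roster=roster, pain=pain, rescue=rescue, events=events, secondary=secondary
    )
    trial.validate()
    return trial


def emit_trial_tables(trial: TrialData, outdir) -> dict:
    """Validate and write the five trial CSVs to ``outdir``."""
    trial.validate()
    return trial.to_dir(outdir)
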