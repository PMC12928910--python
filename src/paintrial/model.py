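"""Model/Results interface tying generation, derivation and inference together.

:class:`PainReliefTrial` is built from patient-level :class:`~paintrial.data.TrialData`
(loaded from CSVs or simulated) and a :class:`~paintrial.config.TrialConfig`;
its :meth:`~PainReliefTrial.fit` runs the full endpoint derivation and the
trial's comparison battery and returns a :class:`TrialFitResults` carrying
least-squares-mean comparisons with CIs and p values, the gatekeeping
outcome, Kaplan-Meier/Cox time-to-rescue results, daily rescue-use risk
differences and secondary-scale summaries, with a ``summary()`` table in the
shape of a trial efficacy table.

Example
-------
>>> from paintrial import TrialConfig, PainReliefTrial
>>> model = PainReliefTrial.simulate(TrialConfig(n_per_arm=50), seed=11)
>>> res = model.fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TrialConfig
from .data import TrialData
from .derive import DerivedTrial, consumption, derive_trial
from .inference import (
    ComparisonResult,
    GatekeepingOutcome,
    RiskDifferenceResult,
    SurvivalResult,
    ancova_pairwise,
    fold_change,
    gatekeep,
    km_cox,
    pga_sis_summaries,
    risk_difference,
)

__all__ = ["PainReliefTrial", "TrialFitResults"]

#: daily windows over which rescue-use risk differences are reported
DAY_WINDOWS = ((0.0, 24.0), (24.0, 48.0), (48.0, 72.0))


class PainReliefTrial:
    """Three-arm acute-pain trial model: data + configuration.

    Parameters
    ----------
    data : TrialData
        The five patient-level tables (roster, pain, rescue, events,
        secondary scores).
    config : TrialConfig, optional
        Design and analysis options; defaults describe the reference
        bunionectomy design.
    """

    def __init__(self, data: TrialData, config: TrialConfig | None = None):
        self.data = data
        self.config = config or TrialConfig()
        data.validate()

    # ------------------------- constructors ---------------------------- #

    @classmethod
    def from_csv_dir(
        cls, path: str | Path, config: TrialConfig | None = None
    ) -> "PainReliefTrial":
        """Build the model from a directory of the five trial CSVs."""
        return cls(TrialData.from_dir(path), config)

    @classmethod
    def simulate(
        cls, config: TrialConfig | None = None, seed: int | None = None
    ) -> "PainReliefTrial":
        """Generate a synthetic trial under ``config`` and wrap it."""
        from .simulate import simulate_trial

        config = config or TrialConfig()
        return cls(simulate_trial(config, seed), config)

    # ----------------------------- fit --------------------------------- #

    def fit(self, population: str = "itt", seed: int = 0) -> "TrialFitResults":
        """Derive all endpoints and run the comparison battery.

        ``population`` selects the analysis set: ``itt`` (all randomized,
        full imputation), ``mitt``, ``pps`` (subsets, full imputation) or
        ``observed_itt`` (all randomized, minimal imputation).
        """
        cfg = self.config
        minimal = population == "observed_itt"
        derived = derive_trial(self.data, cfg, seed=seed, minimal=minimal)
        roster = self.data.roster
        pops = derived.populations.set_index("subject_id")
        flag = "itt" if minimal else population
        if flag not in pops.columns:
            raise ValueError(f"unknown population: {population}")
        subjects = pops.index[pops[flag]]

        arm_site = roster.set_index("subject_id")[["arm", "site_id"]]
        high, low, placebo = cfg.arms

        def _frame(series: pd.Series) -> pd.DataFrame:
            df = series.rename("value").to_frame().join(arm_site, how="inner")
            return df.loc[df.index.isin(subjects)]

        spi48 = derived.spi(48)
        spi_frame = _frame(spi48)
        comparisons: dict[str, ComparisonResult] = {}
        for name, pair in (
            ("spi48_high_vs_placebo", (high, placebo)),
            ("spi48_low_vs_placebo", (low, placebo)),
            ("spi48_high_vs_low", (high, low)),
        ):
            res = ancova_pairwise(
                spi_frame, pair, alpha=cfg.alpha, population=population
            )
            res.endpoint = "spi48"
            comparisons[name] = res

        gate = gatekeep(
            comparisons["spi48_high_vs_placebo"].p_value,
            comparisons["spi48_low_vs_placebo"].p_value,
            alpha=cfg.alpha,
        )

        cons: dict[str, ComparisonResult] = {}
        cons_tables: dict[tuple[float, float], pd.DataFrame] = {}
        for end_h in (48.0, 72.0):
            table = consumption(
                self.data.rescue,
                (0.0, end_h),
                cfg.meq_factor,
                subjects=roster["subject_id"],
            ).set_index("subject_id")
            cons_tables[(0.0, end_h)] = table
            for col, label in (
                ("tramadol_meq_mg", f"tramadol_meq_{int(end_h)}h"),
                ("tramadol_mg", f"tramadol_mg_{int(end_h)}h"),
                ("acetaminophen_mg", f"acetaminophen_mg_{int(end_h)}h"),
            ):
                for arm in (high, low):
                    res = ancova_pairwise(
                        _frame(table[col]),
                        (arm, placebo),
                        alpha=cfg.alpha,
                        population=population,
                    )
                    res.endpoint = label
                    cons[f"{label}_{arm}_vs_placebo"] = res

        survival = km_cox(
            derived.time_to_rescue, arm_site["arm"], reference=placebo,
            alpha=cfg.alpha,
        )

        risk: list[RiskDifferenceResult] = []
        ttr_elig = roster[roster["had_surgery"]]
        first_by_subject = self.data.rescue.groupby("subject_id")["time_h"]
        rescue_times = self.data.rescue
        for window in DAY_WINDOWS:
            users = rescue_times[
                (rescue_times["time_h"] >= window[0])
                & (rescue_times["time_h"] < window[1])
            ]["subject_id"].unique()
            for arm in (high, low):
                ids_a = ttr_elig.loc[ttr_elig["arm"] == arm, "subject_id"]
                ids_b = ttr_elig.loc[ttr_elig["arm"] == placebo, "subject_id"]
                risk.append(
                    risk_difference(
                        users_a=int(ids_a.isin(users).sum()),
                        n_a=len(ids_a),
                        users_b=int(ids_b.isin(users).sum()),
                        n_b=len(ids_b),
                        interval=window,
                        arm_a=arm,
                        arm_b=placebo,
                        alpha=cfg.alpha,
                    )
                )

        sec_summary, sis_contrasts = pga_sis_summaries(
            self.data.secondary, roster, cfg
        )

        return TrialFitResults(
            model=self,
            population=population,
            derived=derived,
            spi48=spi48,
            comparisons=comparisons,
            consumption_comparisons=cons,
            consumption_tables=cons_tables,
            gatekeeping=gate,
            survival=survival,
            risk_differences=risk,
            secondary_summary=sec_summary,
            sis_contrasts=sis_contrasts,
        )


@dataclass
class TrialFitResults:
    """Estimates, uncertainties and diagnostics from one trial analysis."""

    model: PainReliefTrial
    population: str
    derived: DerivedTrial
    spi48: pd.Series
    comparisons: dict[str, ComparisonResult]
    consumption_comparisons: dict[str, ComparisonResult]
    consumption_tables: dict[tuple[float, float], pd.DataFrame]
    gatekeeping: GatekeepingOutcome
    survival: SurvivalResult
    risk_differences: list[RiskDifferenceResult]
    secondary_summary: pd.DataFrame
    sis_contrasts: list[ComparisonResult] = field(default_factory=list)

    # ------------------------- derived views --------------------------- #

    @property
    def primary(self) -> ComparisonResult:
        return self.comparisons["spi48_high_vs_placebo"]

    @property
    def key_secondary(self) -> ComparisonResult:
        return self.comparisons["spi48_low_vs_placebo"]

    def comparisons_frame(self) -> pd.DataFrame:
        """All LSM comparisons as one tidy table."""
        rows = [c.as_row() for c in self.comparisons.values()]
        rows += [c.as_row() for c in self.consumption_comparisons.values()]
        rows += [c.as_row() for c in self.sis_contrasts]
        return pd.DataFrame(rows)

    def percent_reduction(self, which: str = "primary") -> float:
        from .inference import percent_change

        cmp = self.primary if which == "primary" else self.key_secondary
        return percent_change(cmp.lsm_a, cmp.lsm_b)

    def consumption_fold_changes(self) -> dict[str, float]:
        """Placebo-over-active fold changes of 72-h LSM consumption."""
        out = {}
        for drug, rounding in (("tramadol_mg", "decimal"), ("acetaminophen_mg", "decimal")):
            for arm in (self.model.config.arms[0], self.model.config.arms[1]):
                cmp = self.consumption_comparisons[f"{drug}_72h_{arm}_vs_placebo"]
                if cmp.lsm_a > 0:
                    out[f"{drug}_72h_placebo_over_{arm}"] = fold_change(
                        cmp.lsm_b, cmp.lsm_a, rounding
                    )
        return out

    # ---------------------------- summary ------------------------------ #

    def summary(self) -> str:
        """Efficacy-table-shaped text summary of the fitted comparisons."""
        cfg = self.model.config
        high, low, placebo = cfg.arms
        lines = [
            "Acute-pain trial analysis"
            f" (population: {self.population}, alpha={cfg.alpha})",
            "=" * 74,
            f"{'Endpoint / comparison':38s}{'LSMD':>9s}{'95% CI':>18s}{'p':>9s}",
            "-" * 74,
        ]

        def _fmt(c: ComparisonResult, label: str) -> str:
            ci = f"({c.ci_low:.1f}, {c.ci_high:.1f})"
            p = f"{c.p_value:.4f}" if c.p_value >= 1e-4 else "<0.0001"
            return f"{label:38s}{c.lsmd:9.1f}{ci:>18s}{p:>9s}"

        lines.append(_fmt(self.primary, f"SPI48 {high} vs {placebo} (primary)"))
        lines.append(_fmt(self.key_secondary, f"SPI48 {low} vs {placebo} (key 2nd)"))
        lines.append(_fmt(self.comparisons["spi48_high_vs_low"], f"SPI48 {high} vs {low}"))
        for key, label in (
            (f"tramadol_meq_48h_{high}_vs_placebo", f"Tramadol MEQ 0-48h {high} vs pbo"),
            (f"tramadol_meq_48h_{low}_vs_placebo", f"Tramadol MEQ 0-48h {low} vs pbo"),
            (f"acetaminophen_mg_48h_{high}_vs_placebo", f"Acetaminophen 0-48h {high} vs pbo"),
            (f"acetaminophen_mg_48h_{low}_vs_placebo", f"Acetaminophen 0-48h {low} vs pbo"),
        ):
            lines.append(_fmt(self.consumption_comparisons[key], label))
        lines.append("-" * 74)
        gate = self.gatekeeping
        lines.append(
            f"Gatekeeping: primary {'PASS' if gate.primary_significant else 'fail'}; "
            f"key secondary "
            + (
                ("PASS" if gate.key_secondary_significant else "fail")
                if gate.key_secondary_tested
                else "not tested"
            )
        )
        for arm, hr in self.survival.hazard_ratios.items():
            med = self.survival.curves[arm].median
            lines.append(
                f"Time to rescue {arm:8s}: median "
                + (f"{med:5.1f} h" if np.isfinite(med) else "  NE  ")
                + f", HR vs {self.survival.reference} "
                + (
                    f"{hr.hr:.2f} ({hr.ci_low:.2f}-{hr.ci_high:.2f})"
                    if np.isfinite(hr.hr)
                    else "NE"
                )
            )
        pbo_med = self.survival.curves[placebo].median
        lines.append(
            f"Time to rescue {placebo:8s}: median "
            + (f"{pbo_med:5.1f} h" if np.isfinite(pbo_med) else "  NE  ")
        )
        for rd in self.risk_differences:
            lines.append(
                f"Rescue users {int(rd.interval[0]):2d}-{int(rd.interval[1]):2d} h "
                f"{rd.arm_a:6s} vs {rd.arm_b}: {rd.difference_pct:6.1f}% "
                f"({rd.ci_low:.1f}, {rd.ci_high:.1f}), p={rd.p_value:.2g}"
            )
        lines.append("=" * 74)
        return "\n".join(lines)

    # ----------------------------- plots ------------------------------- #

    def plot_km(self, ax=None):
        """Kaplan-Meier curves of time to first rescue (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for arm, curve in self.survival.curves.items():
            ax.step(curve.times, curve.survival, where="post", label=arm)
        ax.set_xlabel("hours from end of surgery")
        ax.set_ylabel("fraction without rescue")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax
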