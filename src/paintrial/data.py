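"""Patient-level trial tables and their on-disk CSV representation.

A trial is five long-format tables keyed by ``subject_id``:

``roster``
    one row per randomized subject: ``subject_id, site_id, arm,
    randomization_block, had_surgery, dosed, major_deviation``
``pain``
    NPRS observations: ``subject_id, time_h, score, context`` with
    ``context`` one of ``scheduled``, ``pre_rescue``, ``pre_dose``.
    Times are decimal hours from end of surgery (pre-operative
    ``pre_dose`` records may be negative).
``rescue``
    rescue-analgesic administrations: ``subject_id, drug, dose_mg, time_h``
``events``
    intercurrent events: ``subject_id, kind, time_h``
``secondary``
    secondary scores, one row per (subject, scale, hour):
    ``subject_id, scale, hour, value`` with ``scale`` in
    ``{pga, sis, nnrs}``; PGA values are the ordinal category labels.

CSV dialect: UTF-8, comma separated, header row, ``.`` decimal point,
empty string for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

PAIN_CONTEXTS = ("scheduled", "pre_rescue", "pre_dose")
RESCUE_DRUGS = ("acetaminophen", "tramadol")

_SCHEMAS: dict[str, dict[str, object]] = {
    "roster": {
        "subject_id": str,
        "site_id": str,
        "arm": str,
        "randomization_block": int,
        "had_surgery": bool,
        "dosed": bool,
        "major_deviation": bool,
    },
    "pain": {"subject_id": str, "time_h": float, "score": float, "context": str},
    "rescue": {"subject_id": str, "drug": str, "dose_mg": float, "time_h": float},
    "events": {"subject_id": str, "kind": str, "time_h": float},
    "secondary": {"subject_id": str, "scale": str, "hour": float, "value": str},
}


class IntegrityError(ValueError):
    """Raised when trial tables violate referential integrity."""


def _empty(table: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _SCHEMAS[table].items()})


@dataclass
class TrialData:
    """Container for the five patient-level tables of one trial."""

    roster: pd.DataFrame = field(default_factory=lambda: _empty("roster"))
    pain: pd.DataFrame = field(default_factory=lambda: _empty("pain"))
    rescue: pd.DataFrame = field(default_factory=lambda: _empty("rescue"))
    events: pd.DataFrame = field(default_factory=lambda: _empty("events"))
    secondary: pd.DataFrame = field(default_factory=lambda: _empty("secondary"))

    def validate(self) -> None:
        """Check referential integrity and value ranges; raise IntegrityError."""
        roster = self.roster
        if roster["subject_id"].duplicated().any():
            dup = roster.loc[roster["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise IntegrityError(f"duplicate subject_id in roster: {dup}")
        known = set(roster["subject_id"])
        for name in ("pain", "rescue", "events", "secondary"):
            table = getattr(self, name)
            extra = set(table["subject_id"]) - known
            if extra:
                raise IntegrityError(
                    f"{name} table references subject(s) absent from roster: "
                    f"{sorted(extra)[:5]}"
                )
        pain = self.pain.dropna(subset=["score"])
        if len(pain) and not pain["score"].between(0, 10).all():
            raise IntegrityError("pain scores outside [0, 10]")
        bad_ctx = set(self.pain["context"]) - set(PAIN_CONTEXTS)
        if bad_ctx:
            raise IntegrityError(f"unknown pain context(s): {sorted(bad_ctx)}")
        bad_drug = set(self.rescue["drug"]) - set(RESCUE_DRUGS)
        if bad_drug:
            raise IntegrityError(f"unknown rescue drug(s): {sorted(bad_drug)}")
        terminal = self.events[self.events["kind"] != "off_protocol_rescue"]
        # off-protocol rescue is terminal too (handled as lack of efficacy),
        # so every subject may carry at most one event row overall
        if self.events["subject_id"].duplicated().any():
            dup = self.events.loc[
                self.events["subject_id"].duplicated(), "subject_id"
            ].iloc[0]
            raise IntegrityError(f"more than one intercurrent event for {dup}")
        del terminal

    # ------------------------------ I/O -------------------------------- #

    def to_dir(self, path: str | Path) -> dict[str, Path]:
        """Write the five CSV files into ``path`` (created if needed)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        written = {}
        for f in fields(self):
            out = path / f"{f.name}.csv"
            getattr(self, f.name).to_csv(out, index=False)
            written[f.name] = out
        return written

    @classmethod
    def from_dir(cls, path: str | Path, validate: bool = True) -> "TrialData":
        """Read the five CSV files from ``path``."""
        path = Path(path)
        tables = {}
        for name, schema in _SCHEMAS.items():
            file = path / f"{name}.csv"
            if not file.exists():
                raise FileNotFoundError(f"missing trial table: {file}")
            df = pd.read_csv(file, dtype={"subject_id": str, "value": str})
            if df.empty:
                df = _empty(name)
            else:
                for col, typ in schema.items():
                    if typ is bool:
                        df[col] = df[col].astype(bool)
                    elif typ is int:
                        df[col] = df[col].astype(int)
                    elif typ is float:
                        df[col] = df[col].astype(float)
                    else:
                        df[col] = df[col].astype(str)
            tables[name] = df[list(schema)]
        data = cls(**tables)
        if validate:
            data.validate()
        return data

    def n_subjects(self) -> int:
        return len(self.roster)
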