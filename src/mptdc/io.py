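"""Delimited-text readers/writers and run configuration.

Trials travel as CSV/TSV with header columns ``subject, condition,
stimulus, response[, confidence][, rt]``; count tables as long-format
CSV ``subject, condition, stimulus, category, count``.  Condition
labels are the target proportions themselves (".35", ".50", ".65").
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .binning import CountTable, TrialRecord
from .errors import ConfigurationError, ValidationError

_REQUIRED_COLUMNS = ("subject", "condition", "stimulus", "response")


def format_condition(p: float) -> str:
    """Target proportion as the paradigm's block label, e.g. 0.35 -> \".35\"."""
    s = f"{p:.2f}"
    return s[1:] if s.startswith("0.") else s


def read_trials(path, rt_unit: str = "s") -> list[TrialRecord]:
    """Read trial records from a delimited text file.

    The delimiter is sniffed from the extension (.tsv -> tab, else
    comma).  ``rt_unit="ms"`` converts RTs to seconds on ingest.
    Row-level problems are collected and reported together with their
    (1-based, header-exclusive) row numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    if rt_unit not in ("s", "ms"):
        raise ConfigurationError("rt_unit must be 's' or 'ms'")
    scale = 0.001 if rt_unit == "ms" else 1.0
    has_cl = "confidence" in df.columns
    has_rt = "rt" in df.columns
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            confidence = row["confidence"].strip() if has_cl else ""
            rt_raw = row["rt"].strip() if has_rt else ""
            records.append(
                TrialRecord(
                    subject=str(row["subject"]).strip(),
                    condition=float(row["condition"]),
                    stimulus=str(row["stimulus"]).strip().lower(),
                    response=str(row["response"]).strip().lower(),
                    confidence=confidence.lower() or None,
                    rt=float(rt_raw) * scale if rt_raw else None,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        head = "; ".join(problems[:10])
        raise ValidationError(f"{len(problems)} invalid row(s): {head}")
    return records


def write_trials(trials: Sequence[TrialRecord], path) -> None:
    df = pd.DataFrame(
        {
            "subject": [t.subject for t in trials],
            "condition": [format_condition(t.condition) for t in trials],
            "stimulus": [t.stimulus for t in trials],
            "response": [t.response for t in trials],
            "confidence": [t.confidence or "" for t in trials],
            "rt": [("" if t.rt is None else repr(t.rt)) for t in trials],
        }
    )
    df.to_csv(path, index=False)


def write_counts(tables: Sequence[CountTable], path) -> None:
    """Long-format count CSV: subject, condition, stimulus, category, count."""
    rows = []
    for table in tables:
        for (j, stim), cell in sorted(table.counts.items()):
            for category, count in sorted(cell.items()):
                rows.append(
                    {
                        "subject": table.subject,
                        "condition": format_condition(table.conditions[j]),
                        "stimulus": stim,
                        "category": category,
                        "count": count,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts(path) -> list[CountTable]:
    df = pd.read_csv(path, dtype={"subject": str, "category": str})
    required = {"subject", "condition", "stimulus", "category", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing count column(s): {sorted(missing)}")
    conditions = tuple(sorted(float(c) for c in df["condition"].unique()))
    index = {c: j for j, c in enumerate(conditions)}
    tables: dict[str, CountTable] = {}
    for row in df.itertuples(index=False):
        table = tables.setdefault(
            str(row.subject), CountTable(str(row.subject), conditions, {})
        )
        key = (index[float(row.condition)], row.stimulus)
        cell = table.counts.setdefault(key, {})
        cell[row.category] = cell.get(row.category, 0) + int(row.count)
    return [tables[s] for s in sorted(tables)]


@dataclass
class RunConfig:
    """Validated options for a pipeline run; echoed into every output."""

    family: str = "2HT"
    variant: str = "classic"
    n_conditions: int = 3
    target_proportions: tuple[float, ...] = (0.35, 0.50, 0.65)
    n_rt_bins: int = 2
    rt_unit: str = "s"
    n_restarts: int = 10
    tolerance: float = 1e-10
    seed: int | None = None
    bootstrap_reps: int = 1000
    alpha: float = 0.05
    criterion: str = "AICc"
    out_dir: str = "."

    def __post_init__(self):
        from .models import FAMILIES, VARIANTS

        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.rt_unit not in ("s", "ms"):
            raise ConfigurationError("rt_unit must be 's' or 'ms'")
        if self.criterion not in ("AIC", "AICc"):
            raise ConfigurationError("criterion must be AIC or AICc")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_rt_bins < 2:
            raise ConfigurationError("n_rt_bins must be >= 2")
        self.target_proportions = tuple(float(p) for p in self.target_proportions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config": self.to_dict(), "config_hash": self.hash, "seed": self.seed}
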