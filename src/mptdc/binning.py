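"""Per-subject RT discretization and trial -> count-table aggregation.

RT cutoffs follow the log-normal approximation: log-transform the RTs,
take equal-probability quantiles of the fitted normal on the log scale,
and back-transform.  With two bins the single cutoff is the geometric
mean of the subject's RTs; responses at or below the cutoff are *fast*,
responses above it are *slow*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import DomainError, InsufficientDataError, ValidationError
from .models import ModelSpec

CONFIDENCE_LEVELS = ("high", "medium", "low")


@dataclass(frozen=True)
class TrialRecord:
    """One recognition trial.

    ``condition`` is the block's target proportion (e.g. 0.35);
    ``confidence`` and ``rt`` are optional and only required when a CL
    or RT model variant is to be fitted.
    """

    subject: str
    condition: float
    stimulus: str  # "old" | "new"
    response: str  # "old" | "new"
    confidence: str | None = None
    rt: float | None = None

    def __post_init__(self):
        if self.stimulus not in ("old", "new"):
            raise ValidationError(f"stimulus must be old/new, got {self.stimulus!r}")
        if self.response not in ("old", "new"):
            raise ValidationError(f"response must be old/new, got {self.response!r}")
        if self.confidence is not None and self.confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(f"confidence must be high/medium/low, got {self.confidence!r}")
        if self.rt is not None and not self.rt > 0:
            raise ValidationError(f"rt must be > 0 seconds, got {self.rt}")


@dataclass(frozen=True)
class BinningRule:
    """Ordered RT cutoffs (seconds) for one subject; k cutoffs = k+1 bins."""

    subject: str
    cutoffs: tuple[float, ...]

    def __post_init__(self):
        if any(c <= 0 for c in self.cutoffs):
            raise DomainError("cutoffs must be positive")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise DomainError("cutoffs must be strictly increasing")


def lognormal_bin_boundaries(
    rts: Iterable[float], n_bins: int = 2, subject: str = ""
) -> BinningRule:
    """Equal-probability log-normal quantile cutoffs for a subject's RTs.

    For ``n_bins == 2`` the single cutoff reduces to ``exp(mean(log rt))``,
    the geometric mean.  Higher bin counts use the ``k/n_bins`` quantiles
    of N(mean(log rt), sd(log rt)) back-transformed to seconds.
    """
    rts = np.asarray(list(rts), dtype=float)
    if rts.size < 2:
        raise InsufficientDataError("need at least 2 RTs to set bin boundaries")
    if np.any(rts <= 0):
        raise DomainError("all RTs must be > 0")
    if n_bins < 2:
        raise DomainError("n_bins must be >= 2")
    logs = np.log(rts)
    m = logs.mean()
    s = logs.std(ddof=1)
    qs = np.arange(1, n_bins) / n_bins
    cutoffs = np.exp(m + s * norm.ppf(qs))
    return BinningRule(subject, tuple(float(c) for c in cutoffs))


def assign_bin(rt: float, rule: BinningRule) -> int:
    """Bin index for one RT (0 = fast); ties at a cutoff go to the faster bin."""
    if not rt > 0:
        raise DomainError(f"rt must be > 0, got {rt}")
    return int(np.searchsorted(rule.cutoffs, rt, side="left"))


RT_BIN_LABELS = ("fast", "slow")


@dataclass
class CountTable:
    """Per-subject multinomial counts, one cell per (condition, stimulus,
    category).

    ``conditions`` holds the target proportions in ascending order;
    condition indices into it key the ``counts`` map together with the
    stimulus type.
    """

    subject: str
    conditions: tuple[float, ...]
    counts: dict[tuple[int, str], dict[str, int]]

    def tree_total(self, condition: int, stimulus: str) -> int:
        return sum(self.counts.get((condition, stimulus), {}).values())

    @property
    def n_trials(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def to_arrays(self, model: ModelSpec) -> list[np.ndarray]:
        """Count vectors aligned with ``model.trees`` (and their category
        order).  Raises :class:`ValidationError` on layout mismatch."""
        if len(self.conditions) != model.n_conditions:
            raise ValidationError(
                f"table has {len(self.conditions)} conditions, model expects "
                f"{model.n_conditions}"
            )
        out = []
        for tree in model.trees:
            cell = self.counts.get((tree.condition, tree.stimulus), {})
            unknown = set(cell) - set(tree.categories)
            if unknown:
                raise ValidationError(
                    f"categories {sorted(unknown)} not defined for {model.name} "
                    f"tree (condition {tree.condition}, {tree.stimulus})"
                )
            out.append(
                np.array([cell.get(c, 0) for c in tree.categories], dtype=float)
            )
        return out

    @classmethod
    def from_arrays(
        cls,
        subject: str,
        model: ModelSpec,
        arrays: Sequence[np.ndarray],
    ) -> "CountTable":
        counts: dict[tuple[int, str], dict[str, int]] = {}
        for tree, arr in zip(model.trees, arrays):
            counts[(tree.condition, tree.stimulus)] = {
                c: int(v) for c, v in zip(tree.categories, arr)
            }
        return cls(subject, model.target_proportions, counts)


def _category_label(
    trial: TrialRecord, variant: str, rule: BinningRule | None
) -> str:
    parts = [trial.response]
    if variant in ("CL", "CL_RT"):
        parts.append(trial.confidence)  # presence validated by caller
    if variant in ("RT", "CL_RT"):
        parts.append(RT_BIN_LABELS[min(assign_bin(trial.rt, rule), 1)])
    return ":".join(parts)


def aggregate_counts(
    trials: Sequence[TrialRecord],
    variant: str = "classic",
    rules: Mapping[str, BinningRule] | None = None,
    conditions: Sequence[float] | None = None,
) -> dict[str, CountTable]:
    """Aggregate trial records into per-subject count tables.

    RT cutoffs are taken from ``rules`` when given, otherwise computed
    per subject from all of that subject's RTs pooled across conditions
    and stimulus types.  Rows missing a field the ``variant`` requires
    are collected and reported together.
    """
    needs_cl = variant in ("CL", "CL_RT")
    needs_rt = variant in ("RT", "CL_RT")
    bad_rows = []
    for i, t in enumerate(trials):
        if needs_cl and t.confidence is None:
            bad_rows.append((i, "missing confidence"))
        if needs_rt and t.rt is None:
            bad_rows.append((i, "missing rt"))
    if bad_rows:
        head = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise ValidationError(
            f"{len(bad_rows)} trial(s) unusable for variant {variant}: {head}"
        )

    if conditions is None:
        conditions = tuple(sorted({t.condition for t in trials}))
    else:
        conditions = tuple(conditions)
    cond_index = {c: j for j, c in enumerate(conditions)}
    unknown_conds = {t.condition for t in trials} - set(cond_index)
    if unknown_conds:
        raise ValidationError(f"conditions {sorted(unknown_conds)} not in {conditions}")

    subjects = sorted({t.subject for t in trials})
    if needs_rt and rules is None:
        rules = {
            s: lognormal_bin_boundaries(
                [t.rt for t in trials if t.subject == s], 2, subject=s
            )
            for s in subjects
        }

    tables = {
        s: CountTable(s, conditions, {}) for s in subjects
    }
    for t in trials:
        rule = rules[t.subject] if needs_rt else None
        label = _category_label(t, variant, rule)
        key = (cond_index[t.condition], t.stimulus)
        cell = tables[t.subject].counts.setdefault(key, {})
        cell[label] = cell.get(label, 0) + 1
    return tables
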