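"""Per-subject model comparison and selection crosstab analysis.

SDT-vs-2HT winners are decided by the smaller AICc (or AIC); paired
selections under two model variants form a 2x2 crosstab analyzed with
the Pearson chi-square test of independence (no continuity correction)
and the phi coefficient as effect size.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .errors import ValidationError
from .fitting import FitResult


@dataclass(frozen=True)
class SelectionRecord:
    """Winner of one SDT-vs-2HT comparison for one subject."""

    subject: str
    variant: str
    criterion: str  # "AICc" | "AIC"
    value_sdt: float
    value_2ht: float
    winner: str | None  # "SDT" | "2HT" | None on an exact tie
    delta: float  # |value_sdt - value_2ht|

    @property
    def tie(self) -> bool:
        return self.winner is None


def select_best(
    fit_sdt: FitResult,
    fit_2ht: FitResult,
    subject: str = "",
    variant: str = "",
    criterion: str = "AICc",
) -> SelectionRecord:
    """Pick the winning family for one subject by information criterion."""
    if criterion not in ("AICc", "AIC"):
        raise ValidationError(f"criterion must be AICc or AIC, got {criterion!r}")
    a = fit_sdt.aicc if criterion == "AICc" else fit_sdt.aic
    b = fit_2ht.aicc if criterion == "AICc" else fit_2ht.aic
    if a == b:
        winner = None
    else:
        winner = "SDT" if a < b else "2HT"
    return SelectionRecord(subject, variant, criterion, a, b, winner, abs(a - b))


@dataclass(frozen=True)
class CrossTab:
    """2x2 selection crosstab: rows = winner under variant A, columns =
    winner under variant B, in (SDT, 2HT) order."""

    cells: tuple[tuple[int, int], tuple[int, int]]
    variant_a: str = ""
    variant_b: str = ""

    def __post_init__(self):
        if any(v < 0 for row in self.cells for v in row):
            raise ValidationError("crosstab cells must be non-negative")

    @property
    def n(self) -> int:
        return sum(v for row in self.cells for v in row)

    def transpose(self) -> "CrossTab":
        (a, b), (c, d) = self.cells
        return CrossTab(((a, c), (b, d)), self.variant_b, self.variant_a)


def crosstab_from_selections(
    sel_a: dict[str, SelectionRecord], sel_b: dict[str, SelectionRecord]
) -> CrossTab:
    """Cross-classify subjects by their winners under two variants.

    Subjects missing from either side, or tied on either side, are
    dropped (with a warning)."""
    order = ("SDT", "2HT")
    cells = [[0, 0], [0, 0]]
    dropped = 0
    for subj in sorted(set(sel_a) & set(sel_b)):
        wa, wb = sel_a[subj].winner, sel_b[subj].winner
        if wa is None or wb is None:
            dropped += 1
            continue
        cells[order.index(wa)][order.index(wb)] += 1
    if dropped:
        warnings.warn(f"{dropped} tied subject(s) excluded from crosstab")
    va = next(iter(sel_a.values())).variant if sel_a else ""
    vb = next(iter(sel_b.values())).variant if sel_b else ""
    return CrossTab(((cells[0][0], cells[0][1]), (cells[1][0], cells[1][1])), va, vb)


@dataclass(frozen=True)
class IndependenceTestResult:
    """Pearson chi-square test of independence for a 2x2 crosstab."""

    chi2: float
    df: int
    p: float
    phi: float
    n: int

    def to_json(self) -> str:
        return json.dumps(
            {"chi2": self.chi2, "df": self.df, "p": self.p, "phi": self.phi, "n": self.n},
            indent=2,
        )


def chi2_independence(table: CrossTab) -> IndependenceTestResult:
    """Uncorrected Pearson chi-square and phi for a 2x2 table.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); phi = sqrt(chi2 / N).
    A degenerate margin (an empty row or column) yields chi2 = phi = 0
    with a warning.
    """
    (a, b), (c, d) = table.cells
    n = table.n
    if n < 1:
        raise ValidationError("crosstab must contain at least one subject")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        warnings.warn("degenerate margin in crosstab; chi2 and phi set to 0")
        return IndependenceTestResult(0.0, 1, 1.0, 0.0, n)
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    p = float(chi2_dist.sf(chi2, 1))
    phi = math.sqrt(chi2 / n)
    return IndependenceTestResult(float(chi2), 1, p, phi, n)


def selection_summary(records: dict[str, SelectionRecord]) -> dict:
    """Counts and proportions of SDT/2HT winners over a subject set."""
    winners = [r.winner for r in records.values()]
    n = len(winners)
    n_sdt = sum(w == "SDT" for w in winners)
    n_2ht = sum(w == "2HT" for w in winners)
    return {
        "n": n,
        "SDT": n_sdt,
        "2HT": n_2ht,
        "ties": n - n_sdt - n_2ht,
        "prop_SDT": n_sdt / n if n else float("nan"),
    }
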