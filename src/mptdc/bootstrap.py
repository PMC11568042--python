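"""Parametric-bootstrap goodness-of-fit test.

Asymptotic chi-square calibration is unreliable for these models (many
cells have small expected counts), so the null distribution of the
Pearson statistic is obtained by simulating from the fitted model with
the observed per-tree trial totals, refitting, and collecting the
refit statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MPTDCError, ValidationError
from .fitting import FitResult, fit, _counts_to_arrays
from .models import CompiledModel, ModelSpec


@dataclass
class BootstrapGofResult:
    """Bootstrap chi-square distribution and the resulting GOF decision."""

    model_name: str
    B: int
    alpha: float
    observed_chi2: float
    bootstrap_chi2: np.ndarray
    critical_value: float
    reject: bool
    n_failed_refits: int
    seed: int | None = None
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "B": self.B,
            "alpha": self.alpha,
            "observed_chi2": self.observed_chi2,
            "critical_value": self.critical_value,
            "reject": self.reject,
            "n_failed_refits": self.n_failed_refits,
            "seed": self.seed,
            "bootstrap_chi2": [float(x) for x in self.bootstrap_chi2],
            "messages": self.messages,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def empirical_critical_value(sample: np.ndarray, alpha: float) -> float:
    """Order-statistic (1 - alpha) quantile: the ceil((1-alpha) m)-th of m
    sorted values."""
    m = sample.size
    if m < 1:
        raise ValidationError("empty bootstrap sample")
    k = min(max(math.ceil((1.0 - alpha) * m), 1), m)
    return float(np.sort(sample)[k - 1])


def parametric_bootstrap_gof(
    model: ModelSpec,
    fit_result: FitResult,
    counts,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    n_restarts: int = 2,
) -> BootstrapGofResult:
    """Parametric bootstrap GOF test for one subject and model.

    Simulates ``B`` datasets from the fitted parameters, holding each
    tree's trial total at its observed value, refits the same model
    (warm-started at the original estimate plus ``n_restarts - 1``
    random starts), and compares the observed Pearson chi-square with
    the empirical (1 - alpha) quantile of the refit statistics.  H0
    (adequate fit) is retained iff observed <= critical value.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if not fit_result.converged:
        raise ValidationError("bootstrap requires a converged fit")
    arrays = _counts_to_arrays(model, counts)
    totals = [int(round(a.sum())) for a in arrays]
    compiled = CompiledModel(model)
    theta = compiled.params_to_vector(fit_result.estimates)
    probs = compiled.probs(theta)
    # clip tiny negative round-off and renormalize for the multinomial draw
    probs = [np.clip(p, 0.0, None) for p in probs]
    probs = [p / p.sum() for p in probs]

    rng = np.random.default_rng(seed)
    stats = []
    n_failed = 0
    messages: list[str] = []
    for b in range(B):
        sim = [rng.multinomial(n, p).astype(float) for n, p in zip(totals, probs)]
        refit_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = fit(
                model,
                sim,
                n_restarts=n_restarts,
                seed=refit_seed,
                start=fit_result.estimates,
                compute_se=False,
            )
        except MPTDCError:
            n_failed += 1
            continue
        if not np.isfinite(res.chi2):
            n_failed += 1
            continue
        stats.append(res.chi2)
    if not stats:
        raise MPTDCError("all bootstrap refits failed")
    if n_failed:
        messages.append(f"{n_failed} bootstrap refit(s) failed and were excluded")
    sample = np.array(stats)
    crit = empirical_critical_value(sample, alpha)
    return BootstrapGofResult(
        model_name=model.name,
        B=B,
        alpha=alpha,
        observed_chi2=fit_result.chi2,
        bootstrap_chi2=sample,
        critical_value=crit,
        reject=bool(fit_result.chi2 > crit),
        n_failed_refits=n_failed,
        seed=seed,
        messages=messages,
    )
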