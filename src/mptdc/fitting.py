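"""Maximum-likelihood fitting of MPT-DC models to count tables.

The multinomial kernel log-likelihood is maximized in a transformed,
unconstrained space (log-odds for probability parameters, log for the
old-item SD and criterion increments, identity for d' and criteria)
with multiple restarts.  Standard errors come from the inverse observed
information at the optimum, mapped back to the natural scale by the
delta method; they are reported as NaN when the information matrix is
singular or an estimate sits on its boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtri
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess1

from .binning import CountTable
from .errors import ValidationError
from .models import CompiledModel, ModelSpec, build_model

_P_FLOOR = 1e-12
_BOUNDARY_TOL = 1e-5


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

def pearson_chi2(observed, expected) -> float:
    """Pearson chi-square over one or several trees.

    Cells with expected = 0 contribute 0 when also observed = 0 and
    +inf otherwise.
    """
    if isinstance(observed, np.ndarray):
        observed, expected = [observed], [expected]
    total = 0.0
    for obs, exp in zip(observed, expected):
        obs = np.asarray(obs, dtype=float)
        exp = np.asarray(exp, dtype=float)
        if obs.shape != exp.shape:
            raise ValidationError("observed/expected layouts differ")
        zero = exp <= 0
        if np.any(zero & (obs > 0)):
            import warnings

            warnings.warn("observed counts in a zero-expectation cell; chi2 = inf")
            return math.inf
        ok = ~zero
        total += float(np.sum((obs[ok] - exp[ok]) ** 2 / exp[ok]))
    return total


def g_squared(observed, expected) -> float:
    """Likelihood-ratio statistic G^2 = 2 sum O log(O/E) over O > 0 cells."""
    if isinstance(observed, np.ndarray):
        observed, expected = [observed], [expected]
    total = 0.0
    for obs, exp in zip(observed, expected):
        obs = np.asarray(obs, dtype=float)
        exp = np.asarray(exp, dtype=float)
        pos = obs > 0
        if np.any(pos & (exp <= 0)):
            return math.inf
        total += 2.0 * float(np.sum(obs[pos] * np.log(obs[pos] / exp[pos])))
    return total


def aicc_correction(p: int, n: int) -> float:
    """Small-sample AIC correction 2 p (p + 1) / (n - p - 1)."""
    if n <= p + 1:
        return math.inf
    return 2.0 * p * (p + 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

class _Transform:
    """Elementwise map between the natural box and an unconstrained space."""

    def __init__(self, compiled: CompiledModel):
        kinds = []
        for lo, hi in zip(compiled.lower, compiled.upper):
            if lo == 0.0 and hi == 1.0:
                kinds.append("logit")
            elif lo == 0.0 and math.isinf(hi):
                kinds.append("log")
            else:
                kinds.append("identity")
        self.kinds = kinds

    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        eta = np.empty_like(theta)
        for i, k in enumerate(self.kinds):
            if k == "logit":
                eta[i] = logit(np.clip(theta[i], 1e-9, 1 - 1e-9))
            elif k == "log":
                eta[i] = math.log(max(theta[i], 1e-9))
            else:
                eta[i] = theta[i]
        return eta

    def to_natural(self, eta: np.ndarray) -> np.ndarray:
        theta = np.empty_like(eta)
        for i, k in enumerate(self.kinds):
            if k == "logit":
                theta[i] = expit(eta[i])
            elif k == "log":
                theta[i] = math.exp(min(eta[i], 50.0))
            else:
                theta[i] = eta[i]
        return theta

    def jacobian_diag(self, theta: np.ndarray) -> np.ndarray:
        """d theta / d eta at the natural-scale point theta."""
        j = np.empty_like(theta)
        for i, k in enumerate(self.kinds):
            if k == "logit":
                j[i] = theta[i] * (1.0 - theta[i])
            elif k == "log":
                j[i] = theta[i]
            else:
                j[i] = 1.0
        return j


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _counts_to_arrays(model: ModelSpec, counts) -> list[np.ndarray]:
    if isinstance(counts, CountTable):
        return counts.to_arrays(model)
    arrays = [np.asarray(a, dtype=float) for a in counts]
    if len(arrays) != len(model.trees):
        raise ValidationError(
            f"expected {len(model.trees)} count vectors, got {len(arrays)}"
        )
    for arr, tree in zip(arrays, model.trees):
        if arr.shape != (len(tree.categories),):
            raise ValidationError("count vector length does not match tree categories")
    return arrays


def negative_log_likelihood(
    model: ModelSpec, params: Mapping[str, float], counts
) -> float:
    """Multinomial-kernel negative log-likelihood -sum n_k log p_k.

    The multinomial normalizing constant is omitted (it cancels in every
    comparison the package makes).  Returns +inf when a category with
    observed counts has zero model probability.
    """
    model.validate_params(params)
    compiled = CompiledModel(model)
    arrays = _counts_to_arrays(model, counts)
    theta = compiled.params_to_vector(params)
    total = 0.0
    for p, n in zip(compiled.probs(theta), arrays):
        pos = n > 0
        if np.any(p[pos] <= 0):
            return math.inf
        total -= float(np.sum(n[pos] * np.log(p[pos])))
    return total


def _nll_vec(compiled: CompiledModel, arrays: list[np.ndarray], theta: np.ndarray) -> float:
    total = 0.0
    for p, n in zip(compiled.probs(theta), arrays):
        pos = n > 0
        pp = np.clip(p[pos], _P_FLOOR, None)
        total -= float(np.sum(n[pos] * np.log(pp)))
    return total


def _nll_and_grad(
    compiled: CompiledModel, arrays: list[np.ndarray], theta: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient w.r.t. natural parameters."""
    probs, jacs = compiled.probs_and_jac(theta)
    total = 0.0
    grad = np.zeros(compiled.n_params)
    for p, jac, n in zip(probs, jacs, arrays):
        pos = n > 0
        pp = np.clip(p[pos], _P_FLOOR, None)
        total -= float(np.sum(n[pos] * np.log(pp)))
        grad -= (n[pos] / pp) @ jac[pos]
    return total, grad


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _marginal_rates(model: ModelSpec, arrays: list[np.ndarray]):
    """Observed per-condition old-response rates and pooled CL/RT margins."""
    J = model.n_conditions
    hits = np.zeros(J)
    fas = np.zeros(J)
    cl_margin = np.zeros(3)
    fast = [0.0, 0.0]
    for tree, arr in zip(model.trees, arrays):
        tot = arr.sum()
        if tot <= 0:
            continue
        old_mass = sum(
            v for c, v in zip(tree.categories, arr) if c.split(":")[0] == "old"
        )
        rate = old_mass / tot
        if tree.stimulus == "old":
            hits[tree.condition] = rate
        else:
            fas[tree.condition] = rate
        for c, v in zip(tree.categories, arr):
            parts = c.split(":")
            if model.n_cl_bins > 1:
                cl_margin[("high", "medium", "low").index(parts[1])] += v
            if model.n_rt_bins > 1:
                fast[0 if parts[-1] == "fast" else 1] += v
    return hits, fas, cl_margin, fast


def smart_start(model: ModelSpec, arrays: list[np.ndarray]) -> dict[str, float]:
    """Moment-style data-informed starting values.

    Inverts the classic hit/false-alarm structure for the core
    parameters and uses pooled confidence/RT margins for the L and H
    parameters.  Crude on purpose: it only needs to land in the basin.
    """
    hits, fas, cl_margin, fast = _marginal_rates(model, arrays)
    clip = lambda x, lo=0.05, hi=0.95: float(np.clip(x, lo, hi))
    start: dict[str, float] = {}
    J = model.n_conditions
    if model.family == "2HT":
        d0 = clip(hits.mean() - fas.mean(), 0.05, 0.9)
        start["do"] = start["dn"] = d0
        for j in range(J):
            start[f"g_{j + 1}"] = clip(fas[j] / max(1.0 - d0, 0.1))
    else:
        zf = ndtri(np.clip(fas, 0.01, 0.99))
        zh = ndtri(np.clip(hits, 0.01, 0.99))
        c = -zf
        start["d_prime"] = float(np.mean(c + zh))
        start["sigma"] = 1.0
        if model.n_cl_bins > 1:
            for k in range(2, 6):
                start[f"dc_{k}"] = 0.3
            for j in range(J):
                start[f"c1_{j + 1}"] = float(c[j]) - 0.6
        else:
            for j in range(J):
                start[f"c_{j + 1}"] = float(c[j])
    if model.n_cl_bins > 1 and model.family == "2HT":
        tot = cl_margin.sum()
        p_high = cl_margin[0] / tot if tot > 0 else 1 / 3
        p_med = cl_margin[1] / tot if tot > 0 else 1 / 3
        l1 = clip(p_high)
        l2 = clip(p_med / max(1.0 - p_high, 0.05))
        for code in ("do", "dn", "go", "gn"):
            start[f"L_{code}1"] = l1
            start[f"L_{code}2"] = l2
    if model.n_rt_bins > 1:
        tot = fast[0] + fast[1]
        h = clip(fast[0] / tot if tot > 0 else 0.5)
        for p in model.parameters:
            if p.role == "rt":
                start[p.name] = h
    return start


def _random_start(model: ModelSpec, rng: np.random.Generator) -> dict[str, float]:
    start = {}
    for p in model.parameters:
        if p.role in ("detect", "guess", "confidence", "rt"):
            start[p.name] = rng.uniform(0.1, 0.9)
        elif p.role == "sensitivity":
            start[p.name] = rng.uniform(0.0, 2.5)
        elif p.role == "sd":
            start[p.name] = rng.uniform(0.6, 1.8)
        elif p.role == "criterion":
            start[p.name] = rng.uniform(-1.0, 1.0)
        elif p.role == "criterion_increment":
            start[p.name] = rng.uniform(0.1, 0.7)
        else:  # pragma: no cover
            start[p.name] = rng.uniform(0.1, 0.9)
    return start


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one subject's counts."""

    model_name: str
    estimates: dict[str, float]
    se: dict[str, float]
    loglik: float
    chi2: float
    g2: float
    df: int
    aic: float
    aicc: float
    n: int
    p: int
    converged: bool
    n_restarts_used: int
    se_defined: bool = True
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "model": self.model_name,
            "estimates": self.estimates,
            "se": {k: (None if not np.isfinite(v) else v) for k, v in self.se.items()},
            "loglik": self.loglik,
            "chi2": self.chi2,
            "g2": self.g2,
            "df": self.df,
            "aic": self.aic,
            "aicc": self.aicc,
            "n": self.n,
            "p": self.p,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "se_defined": self.se_defined,
            "messages": self.messages,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def expected_counts(
    model: ModelSpec, params: Mapping[str, float], totals: Sequence[float]
) -> list[np.ndarray]:
    """Model-implied expected counts per tree given per-tree trial totals."""
    compiled = CompiledModel(model)
    theta = compiled.params_to_vector(params)
    return [n * p for n, p in zip(totals, compiled.probs(theta))]


# ---------------------------------------------------------------------------
# the fitter
# ---------------------------------------------------------------------------

def _standard_errors(
    compiled: CompiledModel,
    transform: _Transform,
    arrays: list[np.ndarray],
    eta_hat: np.ndarray,
    theta_hat: np.ndarray,
    messages: list[str],
) -> tuple[np.ndarray, bool]:
    """Delta-method SEs on the natural scale; NaN when undefined."""
    p = eta_hat.size
    se = np.full(p, np.nan)
    on_boundary = np.zeros(p, dtype=bool)
    for i, k in enumerate(transform.kinds):
        if k == "logit" and (
            theta_hat[i] < _BOUNDARY_TOL or theta_hat[i] > 1 - _BOUNDARY_TOL
        ):
            on_boundary[i] = True
        elif k == "log" and theta_hat[i] < _BOUNDARY_TOL:
            on_boundary[i] = True
    try:
        hess = approx_hess1(
            eta_hat, lambda e: _nll_vec(compiled, arrays, transform.to_natural(e))
        )
        # symmetrize against finite-difference noise
        hess = 0.5 * (hess + hess.T)
        eigvals = np.linalg.eigvalsh(hess)
        if np.min(eigvals) <= 1e-10 * max(np.max(np.abs(eigvals)), 1.0):
            messages.append("information matrix singular or not positive definite")
            return se, False
        cov = np.linalg.inv(hess)
        jac = transform.jacobian_diag(theta_hat)
        var = np.diag(cov) * jac**2
        se = np.sqrt(np.clip(var, 0.0, None))
    except np.linalg.LinAlgError:
        messages.append("Hessian inversion failed")
        return se, False
    if np.any(on_boundary):
        se[on_boundary] = np.nan
        messages.append("estimates on boundary; their SEs undefined")
    return se, True


def fit(
    model: ModelSpec,
    counts,
    n_restarts: int = 10,
    seed: int | None = None,
    tol: float = 1e-10,
    start: Mapping[str, float] | None = None,
    compute_se: bool = True,
    max_iter: int = 500,
) -> FitResult:
    """Fit a model to one subject's counts by maximum likelihood.

    Parameters
    ----------
    model
        The :class:`~mptdc.models.ModelSpec` to fit.
    counts
        A :class:`~mptdc.binning.CountTable` or a list of per-tree count
        vectors aligned with ``model.trees``.
    n_restarts
        Total optimizer starts: one data-informed start (or the supplied
        ``start``) plus random restarts.
    seed
        Seeds the random restarts; fits are reproducible given the seed.
    start
        Optional warm start used in place of the data-informed one.

    Returns
    -------
    FitResult
        Never raises on non-convergence; the ``converged`` flag and
        ``messages`` record what happened.
    """
    arrays = _counts_to_arrays(model, counts)
    totals = [a.sum() for a in arrays]
    if any(t < 1 for t in totals):
        raise ValidationError("each tree needs at least one trial")
    compiled = CompiledModel(model)
    transform = _Transform(compiled)
    rng = np.random.default_rng(seed)

    starts = [start if start is not None else smart_start(model, arrays)]
    while len(starts) < max(n_restarts, 1):
        starts.append(_random_start(model, rng))

    def obj(eta):
        theta = transform.to_natural(eta)
        value, grad_theta = _nll_and_grad(compiled, arrays, theta)
        return value, grad_theta * transform.jacobian_diag(theta)

    best = None
    any_success = False
    for s in starts:
        eta0 = transform.to_unconstrained(compiled.params_to_vector(s))
        res = minimize(
            obj,
            eta0,
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    eta_hat = best.x
    theta_hat = transform.to_natural(eta_hat)
    estimates = compiled.vector_to_params(theta_hat)
    nll = float(best.fun)
    messages: list[str] = []
    if not any_success:
        messages.append("no optimizer start reported convergence")

    exp = [n * p for n, p in zip(totals, compiled.probs(theta_hat))]
    chi2 = pearson_chi2(arrays, exp)
    g2 = g_squared(arrays, exp)
    p_free = model.n_free_parameters
    n_total = int(round(sum(totals)))
    df = sum(len(t.categories) - 1 for t in model.trees) - p_free
    aic = 2.0 * nll + 2.0 * p_free
    aicc = aic + aicc_correction(p_free, n_total)

    if compute_se:
        se_vec, se_defined = _standard_errors(
            compiled, transform, arrays, eta_hat, theta_hat, messages
        )
    else:
        se_vec = np.full(p_free, np.nan)
        se_defined = False
    se = compiled.vector_to_params(se_vec)

    return FitResult(
        model_name=model.name,
        estimates=estimates,
        se=se,
        loglik=-nll,
        chi2=chi2,
        g2=g2,
        df=df,
        aic=aic,
        aicc=aicc,
        n=n_total,
        p=p_free,
        converged=any_success,
        n_restarts_used=len(starts),
        se_defined=se_defined,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------

class MPTEstimator(BaseEstimator):
    """Scikit-learn-style estimator wrapping :func:`fit`.

    Parameters mirror :func:`fit`; ``fit(X)`` accepts a
    :class:`~mptdc.binning.CountTable` (or per-tree count vectors) and
    exposes the results as fitted attributes (``estimates_``, ``se_``,
    ``aicc_``, ...).

    Examples
    --------
    >>> est = MPTEstimator(family="2HT", variant="classic").fit(table)
    >>> est.estimates_["do"], est.aicc_
    """

    def __init__(
        self,
        family: str = "2HT",
        variant: str = "classic",
        n_conditions: int = 3,
        target_proportions: tuple[float, ...] | None = None,
        n_restarts: int = 10,
        random_state: int | None = None,
        tol: float = 1e-10,
        compute_se: bool = True,
    ):
        self.family = family
        self.variant = variant
        self.n_conditions = n_conditions
        self.target_proportions = target_proportions
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.tol = tol
        self.compute_se = compute_se

    def fit(self, X, y=None) -> "MPTEstimator":
        self.model_ = build_model(
            self.family, self.variant, self.n_conditions, self.target_proportions
        )
        self.result_ = fit(
            self.model_,
            X,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            tol=self.tol,
            compute_se=self.compute_se,
        )
        r = self.result_
        self.estimates_ = r.estimates
        self.se_ = r.se
        self.loglik_ = r.loglik
        self.chi2_ = r.chi2
        self.g2_ = r.g2
        self.df_ = r.df
        self.aic_ = r.aic
        self.aicc_ = r.aicc
        self.converged_ = r.converged
        return self

    def predict_proba(self) -> list[np.ndarray]:
        """Fitted category-probability vectors, one per tree."""
        compiled = CompiledModel(self.model_)
        return compiled.probs(compiled.params_to_vector(self.estimates_))

    def score(self, X, y=None) -> float:
        """Multinomial-kernel log-likelihood of counts X at the fitted
        estimates (higher is better)."""
        return -negative_log_likelihood(self.model_, self.estimates_, X)
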