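"""Declarative construction of 2HT and SDT recognition-memory models.

Two model families are supported, each in four variants:

* ``2HT`` -- the two-high-threshold model: discrete *detect old*,
  *detect new*, *guess old* and *guess new* states.  Detection
  probabilities ``do``/``dn`` are condition-invariant; the guessing
  probability ``g_j`` varies over the ``J`` target-proportion conditions.
* ``SDT`` -- equal-or-unequal-variance signal detection theory
  reparameterized as a multinomial model: new-item familiarity is
  N(0, 1), old-item familiarity is N(d', sigma), and decision criteria
  partition the familiarity axis into response categories.

Variants: ``classic`` (old/new response only), ``CL`` (3 confidence
bins), ``RT`` (2 reaction-time bins), ``CL_RT`` (both).  Confidence in
the 2HT family uses nested ``L`` parameters per latent state
(high = L1, medium = (1-L1)*L2, low = (1-L1)*(1-L2)); in the SDT family
it uses K = 5 ordered criteria, parameterized as a first criterion per
condition plus non-negative neighbourhood increments ``dc_k`` shared
across conditions.  RT bins attach an ``H`` parameter (probability of a
fast response) to each latent branch class.

Branch probabilities are stored as explicit term lists (parameters,
complements, or criterion-interval Gaussian masses), so a model can be
serialized, inspected and evaluated without closures.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError

FAMILIES = ("2HT", "SDT")
VARIANTS = ("classic", "CL", "RT", "CL_RT")
CL_BINS = ("high", "medium", "low")
RT_BINS = ("fast", "slow")
RESPONSES = ("old", "new")
DEFAULT_TARGET_PROPORTIONS = (0.35, 0.50, 0.65)

#: latent-state short codes used in parameter names
_STATE_CODE = {
    "detect_old": "do",
    "detect_new": "dn",
    "guess_old": "go",
    "guess_new": "gn",
}

_SQRT2 = math.sqrt(2.0)


def normal_cdf(x: float) -> float:
    """Standard normal CDF Phi(x), exact to double precision via erf."""
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _normal_pdf(x: float) -> float:
    return _INV_SQRT_2PI * math.exp(-0.5 * x * x)


@dataclass(frozen=True)
class ParamTerm:
    """A multiplicative term that is a parameter value or its complement."""

    name: str
    complement: bool = False

    def to_dict(self) -> dict:
        return {"kind": "param", "name": self.name, "complement": self.complement}


@dataclass(frozen=True)
class IntervalTerm:
    """Gaussian mass between two decision criteria.

    ``lower``/``upper`` are 1-based criterion ordinals; ``None`` means the
    corresponding infinite tail.  Which Gaussian (new: N(0,1), old:
    N(d', sigma)) and which condition's criteria apply is determined by
    the tree the branch belongs to.
    """

    lower: int | None
    upper: int | None

    def to_dict(self) -> dict:
        return {"kind": "interval", "lower": self.lower, "upper": self.upper}


Term = ParamTerm | IntervalTerm


def _term_from_dict(d: Mapping) -> Term:
    if d["kind"] == "param":
        return ParamTerm(d["name"], bool(d["complement"]))
    if d["kind"] == "interval":
        return IntervalTerm(d["lower"], d["upper"])
    raise ConfigurationError(f"unknown term kind {d['kind']!r}")


@dataclass(frozen=True)
class Branch:
    """One root-to-leaf path: a product of terms ending in a category."""

    terms: tuple[Term, ...]
    state: str | None  # latent 2HT state; None for SDT branches
    category: str

    def to_dict(self) -> dict:
        return {
            "terms": [t.to_dict() for t in self.terms],
            "state": self.state,
            "category": self.category,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Branch":
        return cls(
            tuple(_term_from_dict(t) for t in d["terms"]),
            d["state"],
            d["category"],
        )


@dataclass(frozen=True)
class TreeSpec:
    """One multinomial tree: a condition x stimulus cell of the design."""

    condition: int  # 0-based condition index
    target_proportion: float
    stimulus: str  # "old" | "new"
    branches: tuple[Branch, ...]
    categories: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "target_proportion": self.target_proportion,
            "stimulus": self.stimulus,
            "branches": [b.to_dict() for b in self.branches],
            "categories": list(self.categories),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreeSpec":
        return cls(
            int(d["condition"]),
            float(d["target_proportion"]),
            d["stimulus"],
            tuple(Branch.from_dict(b) for b in d["branches"]),
            tuple(d["categories"]),
        )


@dataclass(frozen=True)
class ParameterDef:
    """A free parameter: name, role, box bounds, condition-indexed flag."""

    name: str
    role: str
    lower: float | None
    upper: float | None
    per_condition: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterDef":
        return cls(d["name"], d["role"], d["lower"], d["upper"], bool(d["per_condition"]))


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified model variant: trees, categories and parameters."""

    family: str
    variant: str
    n_conditions: int
    target_proportions: tuple[float, ...]
    n_cl_bins: int
    n_rt_bins: int
    trees: tuple[TreeSpec, ...]
    parameters: tuple[ParameterDef, ...]

    # -- basic accessors -------------------------------------------------
    @property
    def n_free_parameters(self) -> int:
        return len(self.parameters)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def name(self) -> str:
        suffix = {"classic": "", "CL": "-CL", "RT": "-RT", "CL_RT": "-CL-RT"}[self.variant]
        return self.family + suffix

    def tree(self, condition: int, stimulus: str) -> TreeSpec:
        for t in self.trees:
            if t.condition == condition and t.stimulus == stimulus:
                return t
        raise KeyError((condition, stimulus))

    # -- parameter handling ----------------------------------------------
    def validate_params(self, params: Mapping[str, float]) -> None:
        """Raise :class:`DomainError` unless ``params`` is a complete,
        in-bounds parameter set for this model."""
        missing = [p.name for p in self.parameters if p.name not in params]
        if missing:
            raise DomainError(f"missing parameters: {missing}")
        extra = set(params) - set(self.parameter_names)
        if extra:
            raise DomainError(f"unknown parameters: {sorted(extra)}")
        for p in self.parameters:
            v = params[p.name]
            if not np.isfinite(v):
                raise DomainError(f"{p.name}={v} is not finite")
            if p.lower is not None and v < p.lower:
                raise DomainError(f"{p.name}={v} below lower bound {p.lower}")
            if p.upper is not None and v > p.upper:
                raise DomainError(f"{p.name}={v} above upper bound {p.upper}")

    def criteria(self, params: Mapping[str, float], condition: int) -> np.ndarray:
        """Ordered decision-criterion locations for one condition (SDT only)."""
        if self.family != "SDT":
            raise ConfigurationError("criteria are defined for SDT models only")
        j = condition + 1
        if self.n_cl_bins == 1:
            return np.array([params[f"c_{j}"]])
        base = params[f"c1_{j}"]
        incr = np.array([params[f"dc_{k}"] for k in range(2, 6)])
        return base + np.concatenate([[0.0], np.cumsum(incr)])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "variant": self.variant,
            "n_conditions": self.n_conditions,
            "target_proportions": list(self.target_proportions),
            "n_cl_bins": self.n_cl_bins,
            "n_rt_bins": self.n_rt_bins,
            "trees": [t.to_dict() for t in self.trees],
            "parameters": [p.to_dict() for p in self.parameters],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            d["family"],
            d["variant"],
            int(d["n_conditions"]),
            tuple(float(x) for x in d["target_proportions"]),
            int(d["n_cl_bins"]),
            int(d["n_rt_bins"]),
            tuple(TreeSpec.from_dict(t) for t in d["trees"]),
            tuple(ParameterDef.from_dict(p) for p in d["parameters"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, s: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(s))


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _category_labels(variant: str) -> tuple[str, ...]:
    """Fixed category order: response (old, new), then CL high->low, then
    RT fast->slow."""
    cls = CL_BINS if variant in ("CL", "CL_RT") else (None,)
    rts = RT_BINS if variant in ("RT", "CL_RT") else (None,)
    labels = []
    for r in RESPONSES:
        for c in cls:
            for b in rts:
                labels.append(":".join(p for p in (r, c, b) if p is not None))
    return tuple(labels)


def _cl_terms(code: str, cl: str) -> tuple[ParamTerm, ...]:
    l1, l2 = f"L_{code}1", f"L_{code}2"
    if cl == "high":
        return (ParamTerm(l1),)
    if cl == "medium":
        return (ParamTerm(l1, True), ParamTerm(l2))
    return (ParamTerm(l1, True), ParamTerm(l2, True))


def _expand_rt_cl(
    base_terms: tuple[Term, ...],
    state: str | None,
    response: str,
    variant: str,
    cl_code: str,
    rt_code: str,
) -> list[Branch]:
    """Attach CL and/or RT sub-branches to one base branch.

    ``cl_code`` names the branch class for nested-L parameters (2HT state
    code); ``rt_code`` names the branch class for H parameters (2HT state
    code, or SDT stimulus-response code).
    """
    out: list[Branch] = []
    if variant == "classic":
        return [Branch(base_terms, state, response)]
    if variant == "RT":
        h = f"H_{rt_code}"
        for b, comp in (("fast", False), ("slow", True)):
            out.append(Branch(base_terms + (ParamTerm(h, comp),), state, f"{response}:{b}"))
        return out
    for cl in CL_BINS:
        terms_cl = base_terms + _cl_terms(cl_code, cl) if cl_code else base_terms
        if variant == "CL":
            out.append(Branch(terms_cl, state, f"{response}:{cl}"))
        else:  # CL_RT
            h = f"H_{rt_code}_{cl}"
            for b, comp in (("fast", False), ("slow", True)):
                out.append(
                    Branch(terms_cl + (ParamTerm(h, comp),), state, f"{response}:{cl}:{b}")
                )
    return out


def _build_2ht(variant: str, n_conditions: int, proportions: Sequence[float]) -> ModelSpec:
    categories = _category_labels(variant)
    trees = []
    for j in range(n_conditions):
        g = f"g_{j + 1}"
        # (state, response, classic terms) per stimulus; high thresholds
        # forbid detect_old on new items and detect_new on old items.
        layouts = {
            "old": [
                ("detect_old", "old", (ParamTerm("do"),)),
                ("guess_old", "old", (ParamTerm("do", True), ParamTerm(g))),
                ("guess_new", "new", (ParamTerm("do", True), ParamTerm(g, True))),
            ],
            "new": [
                ("detect_new", "new", (ParamTerm("dn"),)),
                ("guess_old", "old", (ParamTerm("dn", True), ParamTerm(g))),
                ("guess_new", "new", (ParamTerm("dn", True), ParamTerm(g, True))),
            ],
        }
        for stim, layout in layouts.items():
            branches: list[Branch] = []
            for state, response, terms in layout:
                code = _STATE_CODE[state]
                branches.extend(
                    _expand_rt_cl(terms, state, response, variant, code, code)
                )
            trees.append(
                TreeSpec(j, float(proportions[j]), stim, tuple(branches), categories)
            )

    params = [
        ParameterDef("do", "detect", 0.0, 1.0),
        ParameterDef("dn", "detect", 0.0, 1.0),
    ]
    params += [
        ParameterDef(f"g_{j + 1}", "guess", 0.0, 1.0, per_condition=True)
        for j in range(n_conditions)
    ]
    if variant in ("CL", "CL_RT"):
        for code in ("do", "dn", "go", "gn"):
            params.append(ParameterDef(f"L_{code}1", "confidence", 0.0, 1.0))
            params.append(ParameterDef(f"L_{code}2", "confidence", 0.0, 1.0))
    if variant == "RT":
        params += [ParameterDef(f"H_{c}", "rt", 0.0, 1.0) for c in ("do", "dn", "go", "gn")]
    elif variant == "CL_RT":
        params += [
            ParameterDef(f"H_{c}_{cl}", "rt", 0.0, 1.0)
            for c in ("do", "dn", "go", "gn")
            for cl in CL_BINS
        ]
    return ModelSpec(
        "2HT",
        variant,
        n_conditions,
        tuple(float(p) for p in proportions),
        3 if variant in ("CL", "CL_RT") else 1,
        2 if variant in ("RT", "CL_RT") else 1,
        tuple(trees),
        tuple(params),
    )


#: SDT criterion regions for the confidence layout: 5 ordered criteria
#: define 6 regions, from "new-high" (lowest familiarity) to "old-high".
_SDT_CL_REGIONS = (
    ("new", "high", None, 1),
    ("new", "medium", 1, 2),
    ("new", "low", 2, 3),
    ("old", "low", 3, 4),
    ("old", "medium", 4, 5),
    ("old", "high", 5, None),
)


def _build_sdt(variant: str, n_conditions: int, proportions: Sequence[float]) -> ModelSpec:
    categories = _category_labels(variant)
    with_cl = variant in ("CL", "CL_RT")
    trees = []
    for j in range(n_conditions):
        for stim in ("old", "new"):
            scode = "s" if stim == "old" else "n"
            branches: list[Branch] = []
            if with_cl:
                regions = [(r, cl, lo, hi) for r, cl, lo, hi in _SDT_CL_REGIONS]
            else:
                regions = [("old", None, 1, None), ("new", None, None, 1)]
            for response, cl, lo, hi in regions:
                rcode = scode + ("o" if response == "old" else "n")
                base: tuple[Term, ...] = (IntervalTerm(lo, hi),)
                if variant == "classic":
                    branches.append(Branch(base, None, response))
                elif variant == "RT":
                    h = f"H_{rcode}"
                    for b, comp in (("fast", False), ("slow", True)):
                        branches.append(
                            Branch(base + (ParamTerm(h, comp),), None, f"{response}:{b}")
                        )
                elif variant == "CL":
                    branches.append(Branch(base, None, f"{response}:{cl}"))
                else:  # CL_RT
                    h = f"H_{rcode}_{cl}"
                    for b, comp in (("fast", False), ("slow", True)):
                        branches.append(
                            Branch(
                                base + (ParamTerm(h, comp),), None, f"{response}:{cl}:{b}"
                            )
                        )
            trees.append(
                TreeSpec(j, float(proportions[j]), stim, tuple(branches), categories)
            )

    params = [
        ParameterDef("d_prime", "sensitivity", None, None),
        ParameterDef("sigma", "sd", 0.0, None),
    ]
    if with_cl:
        params += [
            ParameterDef(f"c1_{j + 1}", "criterion", None, None, per_condition=True)
            for j in range(n_conditions)
        ]
        params += [
            ParameterDef(f"dc_{k}", "criterion_increment", 0.0, None) for k in range(2, 6)
        ]
    else:
        params += [
            ParameterDef(f"c_{j + 1}", "criterion", None, None, per_condition=True)
            for j in range(n_conditions)
        ]
    if variant == "RT":
        params += [
            ParameterDef(f"H_{s}{r}", "rt", 0.0, 1.0) for s in "sn" for r in "on"
        ]
    elif variant == "CL_RT":
        params += [
            ParameterDef(f"H_{s}{'o' if resp == 'old' else 'n'}_{cl}", "rt", 0.0, 1.0)
            for s in "sn"
            for resp, cl, _, _ in _SDT_CL_REGIONS
        ]
    return ModelSpec(
        "SDT",
        variant,
        n_conditions,
        tuple(float(p) for p in proportions),
        3 if with_cl else 1,
        2 if variant in ("RT", "CL_RT") else 1,
        tuple(trees),
        tuple(params),
    )


def build_model(
    family: str,
    variant: str,
    n_conditions: int = 3,
    target_proportions: Sequence[float] | None = None,
) -> ModelSpec:
    """Construct one of the eight model variants.

    Parameters
    ----------
    family
        ``"2HT"`` or ``"SDT"``.
    variant
        ``"classic"``, ``"CL"``, ``"RT"`` or ``"CL_RT"``.
    n_conditions
        Number of target-proportion conditions J (default 3).
    target_proportions
        Target proportion per condition; defaults to (.35, .50, .65)
        when J = 3, else equally spaced in (0, 1).

    Returns
    -------
    ModelSpec
        With free-parameter totals 5 (classic), 13/9 (2HT/SDT CL),
        9 (RT), 25/21 (2HT/SDT CL+RT) at J = 3.
    """
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if n_conditions < 1:
        raise ConfigurationError("n_conditions must be >= 1")
    if target_proportions is None:
        if n_conditions == 3:
            target_proportions = DEFAULT_TARGET_PROPORTIONS
        else:
            target_proportions = tuple(
                (j + 1) / (n_conditions + 1) for j in range(n_conditions)
            )
    elif len(target_proportions) != n_conditions:
        raise ConfigurationError("target_proportions length must equal n_conditions")
    builder = _build_2ht if family == "2HT" else _build_sdt
    return builder(variant, n_conditions, target_proportions)


# ---------------------------------------------------------------------------
# probability evaluation
# ---------------------------------------------------------------------------

def _interval_mass(
    term: IntervalTerm, criteria: np.ndarray, mu: float, sigma: float
) -> float:
    lo = -math.inf if term.lower is None else (criteria[term.lower - 1] - mu) / sigma
    hi = math.inf if term.upper is None else (criteria[term.upper - 1] - mu) / sigma
    upper = 1.0 if hi == math.inf else normal_cdf(hi)
    lower = 0.0 if lo == -math.inf else normal_cdf(lo)
    return upper - lower


def category_probabilities(
    model: ModelSpec, params: Mapping[str, float], tree: TreeSpec
) -> np.ndarray:
    """Category probability vector for one tree at a given parameter set.

    The result is ordered as ``tree.categories`` and sums to 1 for any
    in-bounds parameter set.
    """
    model.validate_params(params)
    if model.family == "SDT":
        crit = model.criteria(params, tree.condition)
        mu = params["d_prime"] if tree.stimulus == "old" else 0.0
        sigma = params["sigma"] if tree.stimulus == "old" else 1.0
    probs = np.zeros(len(tree.categories))
    index = {c: i for i, c in enumerate(tree.categories)}
    for branch in tree.branches:
        v = 1.0
        for term in branch.terms:
            if isinstance(term, ParamTerm):
                x = params[term.name]
                v *= (1.0 - x) if term.complement else x
            else:
                v *= _interval_mass(term, crit, mu, sigma)
        probs[index[branch.category]] += v
    return probs


def branch_probabilities(
    model: ModelSpec, params: Mapping[str, float], tree: TreeSpec
) -> np.ndarray:
    """Per-branch probabilities (in ``tree.branches`` order).

    Unlike :func:`category_probabilities` this does not pool branches
    that share a category; the trial-level simulator samples latent
    branches from it.
    """
    model.validate_params(params)
    if model.family == "SDT":
        crit = model.criteria(params, tree.condition)
        mu = params["d_prime"] if tree.stimulus == "old" else 0.0
        sigma = params["sigma"] if tree.stimulus == "old" else 1.0
    out = np.zeros(len(tree.branches))
    for k, branch in enumerate(tree.branches):
        v = 1.0
        for term in branch.terms:
            if isinstance(term, ParamTerm):
                x = params[term.name]
                v *= (1.0 - x) if term.complement else x
            else:
                v *= _interval_mass(term, crit, mu, sigma)
        out[k] = v
    return out


class CompiledModel:
    """Index-based fast evaluator for a :class:`ModelSpec`.

    Precomputes, per tree, each branch's parameter indices so that the
    full set of category-probability vectors can be evaluated from a raw
    parameter vector in microseconds.  Used heavily by the fitter.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        names = model.parameter_names
        self.index = {n: i for i, n in enumerate(names)}
        self.n_params = len(names)
        self.lower = np.array(
            [-np.inf if p.lower is None else p.lower for p in model.parameters]
        )
        self.upper = np.array(
            [np.inf if p.upper is None else p.upper for p in model.parameters]
        )
        self.roles = tuple(p.role for p in model.parameters)
        self.is_sdt = model.family == "SDT"
        if self.is_sdt:
            self._i_dprime = self.index["d_prime"]
            self._i_sigma = self.index["sigma"]
            if model.n_cl_bins > 1:
                self._i_cbase = [
                    self.index[f"c1_{j + 1}"] for j in range(model.n_conditions)
                ]
                self._i_dc = [self.index[f"dc_{k}"] for k in range(2, 6)]
            else:
                self._i_cbase = [
                    self.index[f"c_{j + 1}"] for j in range(model.n_conditions)
                ]
                self._i_dc = []
        self.trees = []
        for tree in model.trees:
            cat_index = {c: i for i, c in enumerate(tree.categories)}
            branches = []
            for b in tree.branches:
                direct, comp, interval = [], [], None
                for t in b.terms:
                    if isinstance(t, ParamTerm):
                        (comp if t.complement else direct).append(self.index[t.name])
                    else:
                        interval = (t.lower, t.upper)
                branches.append(
                    (cat_index[b.category], tuple(direct), tuple(comp), interval)
                )
            self.trees.append(
                {
                    "key": (tree.condition, tree.stimulus),
                    "condition": tree.condition,
                    "old": tree.stimulus == "old",
                    "n_categories": len(tree.categories),
                    "branches": branches,
                }
            )

    def criteria(self, theta: np.ndarray, condition: int) -> list[float]:
        base = theta[self._i_cbase[condition]]
        out = [base]
        for i in self._i_dc:
            base = base + theta[i]
            out.append(base)
        return out

    def probs(self, theta: np.ndarray) -> list[np.ndarray]:
        """Category-probability vectors for all trees, in tree order."""
        out = []
        cdf = normal_cdf
        for tree in self.trees:
            if self.is_sdt:
                crit = self.criteria(theta, tree["condition"])
                if tree["old"]:
                    mu, sigma = theta[self._i_dprime], theta[self._i_sigma]
                else:
                    mu, sigma = 0.0, 1.0
                edges = [cdf((c - mu) / sigma) for c in crit]
            p = np.zeros(tree["n_categories"])
            for cat, direct, comp, interval in tree["branches"]:
                v = 1.0
                for i in direct:
                    v *= theta[i]
                for i in comp:
                    v *= 1.0 - theta[i]
                if interval is not None:
                    lo, hi = interval
                    upper = 1.0 if hi is None else edges[hi - 1]
                    lower = 0.0 if lo is None else edges[lo - 1]
                    v *= upper - lower
                p[cat] += v
            out.append(p)
        return out

    def probs_and_jac(
        self, theta: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Category probabilities and their Jacobians d p / d theta.

        Returns one (n_categories,) vector and one (n_categories,
        n_params) matrix per tree.  Branch values are products of simple
        terms, so derivatives come from the product rule; criterion
        interval masses differentiate through the normal pdf.
        """
        P = self.n_params
        probs_out, jac_out = [], []
        cdf, pdf = normal_cdf, _normal_pdf
        for tree in self.trees:
            if self.is_sdt:
                j = tree["condition"]
                crit = self.criteria(theta, j)
                if tree["old"]:
                    mu, sigma = theta[self._i_dprime], theta[self._i_sigma]
                else:
                    mu, sigma = 0.0, 1.0
                K = len(crit)
                zs = [(c - mu) / sigma for c in crit]
                edges = [cdf(z) for z in zs]
                pdfs = [pdf(z) for z in zs]
                # d z_k / d theta_i is nonzero only for the condition's
                # base criterion, the increments up to k, d' and sigma.
                dz = np.zeros((K, P))
                for k in range(K):
                    dz[k, self._i_cbase[j]] = 1.0 / sigma
                    for m, idx in enumerate(self._i_dc):
                        if m < k:
                            dz[k, idx] = 1.0 / sigma
                    if tree["old"]:
                        dz[k, self._i_dprime] = -1.0 / sigma
                        dz[k, self._i_sigma] = -zs[k] / sigma
            p = np.zeros(tree["n_categories"])
            jac = np.zeros((tree["n_categories"], P))
            for cat, direct, comp, interval in tree["branches"]:
                v = 1.0
                for i in direct:
                    v *= theta[i]
                for i in comp:
                    v *= 1.0 - theta[i]
                if interval is not None:
                    lo, hi = interval
                    upper = 1.0 if hi is None else edges[hi - 1]
                    lower = 0.0 if lo is None else edges[lo - 1]
                    mass = upper - lower
                    w = v  # product of the plain parameter terms
                    v = v * mass
                p[cat] += v
                row = jac[cat]
                for i in direct:
                    if theta[i] != 0.0:
                        row[i] += v / theta[i]
                    else:
                        alt = 1.0
                        for k2 in direct:
                            if k2 != i:
                                alt *= theta[k2]
                        for k2 in comp:
                            alt *= 1.0 - theta[k2]
                        if interval is not None:
                            alt *= mass
                        row[i] += alt
                for i in comp:
                    if theta[i] != 1.0:
                        row[i] -= v / (1.0 - theta[i])
                    else:
                        alt = 1.0
                        for k2 in direct:
                            alt *= theta[k2]
                        for k2 in comp:
                            if k2 != i:
                                alt *= 1.0 - theta[k2]
                        if interval is not None:
                            alt *= mass
                        row[i] -= alt
                if interval is not None:
                    lo, hi = interval
                    dmass = np.zeros(P)
                    if hi is not None:
                        dmass += pdfs[hi - 1] * dz[hi - 1]
                    if lo is not None:
                        dmass -= pdfs[lo - 1] * dz[lo - 1]
                    row += w * dmass
            probs_out.append(p)
            jac_out.append(jac)
        return probs_out, jac_out

    def params_to_vector(self, params: Mapping[str, float]) -> np.ndarray:
        return np.array([params[n] for n in self.model.parameter_names])

    def vector_to_params(self, theta: Iterable[float]) -> dict[str, float]:
        return dict(zip(self.model.parameter_names, map(float, theta)))
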