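"""Synthetic data generation and model-recovery studies.

The default design emulates the recognition paradigm the models target:
three analyzed target-proportion blocks (.35 / .50 / .65) of 100 test
trials each, a 3-point confidence scale, and continuous positive RTs
with branch-dependent log-normal distributions (detection responses
faster than guesses).  Counts can be drawn directly from a model's
multinomial category probabilities, or full trial records can be
emitted (latent branch -> response, confidence, continuous RT) so the
binning-and-aggregation pipeline is exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binning import CountTable, TrialRecord
from .errors import ConfigurationError
from .models import ModelSpec, branch_probabilities, build_model, _STATE_CODE
from .fitting import FitResult, fit
from .selection import select_best

CL_BINS = ("high", "medium", "low")


# ---------------------------------------------------------------------------
# generating parameter defaults
# ---------------------------------------------------------------------------

def default_parameters(model: ModelSpec) -> dict[str, float]:
    """Plausible mid-range generating values for any model variant.

    Detection/sensitivity is moderate (do = dn = .6; d' = 1.5 with
    sigma = 1.3), guessing tracks the target proportion (g = .3/.5/.7),
    confidence favours high bins in detect states and low/medium bins
    in guess states, and detection responses are more likely fast
    (H ~ .7) than guesses (H ~ .4).
    """
    J = model.n_conditions
    params: dict[str, float] = {}
    gs = np.linspace(0.3, 0.7, J) if J > 1 else np.array([0.5])
    cs = np.linspace(0.9, 0.4, J) if J > 1 else np.array([0.65])
    if model.family == "2HT":
        params["do"] = params["dn"] = 0.6
        for j in range(J):
            params[f"g_{j + 1}"] = float(gs[j])
        if model.n_cl_bins > 1:
            for code, (l1, l2) in {
                "do": (0.7, 0.6),
                "dn": (0.7, 0.6),
                "go": (0.3, 0.5),
                "gn": (0.3, 0.5),
            }.items():
                params[f"L_{code}1"] = l1
                params[f"L_{code}2"] = l2
        if model.n_rt_bins > 1:
            detect_h = {"high": 0.75, "medium": 0.65, "low": 0.55}
            guess_h = {"high": 0.50, "medium": 0.40, "low": 0.45}
            for code in ("do", "dn", "go", "gn"):
                h_by_cl = detect_h if code in ("do", "dn") else guess_h
                if model.n_cl_bins > 1:
                    for cl in CL_BINS:
                        params[f"H_{code}_{cl}"] = h_by_cl[cl]
                else:
                    params[f"H_{code}"] = 0.7 if code in ("do", "dn") else 0.4
    else:
        params["d_prime"] = 1.5
        params["sigma"] = 1.3
        if model.n_cl_bins > 1:
            for k in range(2, 6):
                params[f"dc_{k}"] = 0.45
            for j in range(J):
                # place the old/new boundary (3rd criterion) at the classic c
                params[f"c1_{j + 1}"] = float(cs[j]) - 0.9
        else:
            for j in range(J):
                params[f"c_{j + 1}"] = float(cs[j])
        if model.n_rt_bins > 1:
            correct_h = {"high": 0.70, "medium": 0.60, "low": 0.50}
            error_h = {"high": 0.50, "medium": 0.45, "low": 0.40}
            for cls in ("so", "sn", "no", "nn"):
                correct = cls in ("so", "nn")
                if model.n_cl_bins > 1:
                    for cl in CL_BINS:
                        params[f"H_{cls}_{cl}"] = (correct_h if correct else error_h)[cl]
                else:
                    params[f"H_{cls}"] = 0.65 if correct else 0.45
    return params


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def block_trial_totals(model: ModelSpec, block_size: int = 100) -> dict:
    """Per-tree trial totals from the block design: an old-item tree gets
    ``block_size * target_proportion`` trials, the new-item tree the rest."""
    totals = {}
    for tree in model.trees:
        n_old = int(round(block_size * tree.target_proportion))
        totals[(tree.condition, tree.stimulus)] = (
            n_old if tree.stimulus == "old" else block_size - n_old
        )
    return totals


@dataclass
class SimulationDesign:
    """Generating model, parameters, trial totals and emission specs.

    ``trials_per_tree`` may be ``None`` (block design: 100-trial blocks
    split by target proportion), an integer (flat per tree), or a map
    ``(condition, stimulus) -> n``.  ``rt_emission`` maps a branch class
    (2HT state code ``do/dn/go/gn`` or SDT stimulus-response code
    ``so/sn/no/nn``, optionally suffixed ``_high/_medium/_low``) to
    log-normal ``(meanlog, sdlog)`` of the RT in seconds; ``cl_emission``
    maps a branch class to ``(p_high, p_medium, p_low)``.
    """

    model: ModelSpec
    params: Mapping[str, float]
    n_subjects: int = 1
    trials_per_tree: int | Mapping | None = None
    block_size: int = 100
    seed: int | None = None
    rt_emission: Mapping[str, tuple[float, float]] | None = None
    cl_emission: Mapping[str, tuple[float, float, float]] | None = None

    def tree_totals(self) -> dict:
        if self.trials_per_tree is None:
            return block_trial_totals(self.model, self.block_size)
        if isinstance(self.trials_per_tree, int):
            if self.trials_per_tree < 1:
                raise ConfigurationError("trials_per_tree must be >= 1")
            return {
                (t.condition, t.stimulus): self.trials_per_tree
                for t in self.model.trees
            }
        return dict(self.trials_per_tree)


def _subject_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_counts(design: SimulationDesign) -> list[CountTable]:
    """Draw per-subject count tables from the design's model.

    Each tree's counts are multinomial with the model's category
    probabilities and the design's trial total; one seed sequence spawns
    independent per-subject streams, so runs are reproducible and any
    subject can be regenerated alone.
    """
    design.model.validate_params(design.params)
    totals = design.tree_totals()
    from .models import CompiledModel

    compiled = CompiledModel(design.model)
    theta = compiled.params_to_vector(design.params)
    probs = compiled.probs(theta)
    probs = [np.clip(p, 0.0, None) for p in probs]
    probs = [p / p.sum() for p in probs]
    tables = []
    for i, rng in enumerate(_subject_rngs(design.seed, design.n_subjects)):
        arrays = [
            rng.multinomial(totals[(t.condition, t.stimulus)], p).astype(float)
            for t, p in zip(design.model.trees, probs)
        ]
        tables.append(CountTable.from_arrays(f"sim{i + 1:03d}", design.model, arrays))
    return tables


# ---------------------------------------------------------------------------
# trial-level simulation
# ---------------------------------------------------------------------------

def _branch_class(model: ModelSpec, tree, branch) -> tuple[str, str | None]:
    """(base class code, confidence bin or None) for one branch."""
    parts = branch.category.split(":")
    response = parts[0]
    cl = parts[1] if model.n_cl_bins > 1 else None
    if model.family == "2HT":
        return _STATE_CODE[branch.state], cl
    code = ("s" if tree.stimulus == "old" else "n") + ("o" if response == "old" else "n")
    return code, cl


def _emission_key(table: Mapping, cls: str, cl: str | None):
    if cl is not None and f"{cls}_{cl}" in table:
        return table[f"{cls}_{cl}"]
    if cls in table:
        return table[cls]
    raise ConfigurationError(f"no emission spec for branch class {cls!r} (cl={cl!r})")


def simulate_trials(design: SimulationDesign) -> list[TrialRecord]:
    """Emit trial-level records (response, confidence, continuous RT).

    The generating model supplies the latent branch structure; it must
    not itself contain RT bins (use ``rt_emission`` for the continuous
    RTs instead).  Confidence comes from the model's CL branches when
    present, else from ``cl_emission``.
    """
    model = design.model
    if model.n_rt_bins > 1:
        raise ConfigurationError(
            "trial-level simulation needs a classic or CL skeleton; RTs are "
            "continuous and specified via rt_emission"
        )
    if design.rt_emission is None:
        raise ConfigurationError("simulate_trials requires an rt_emission spec")
    model.validate_params(design.params)
    totals = design.tree_totals()
    records: list[TrialRecord] = []
    for i, rng in enumerate(_subject_rngs(design.seed, design.n_subjects)):
        subject = f"sim{i + 1:03d}"
        for tree in model.trees:
            n = totals[(tree.condition, tree.stimulus)]
            if n == 0:
                continue
            bp = branch_probabilities(model, design.params, tree)
            bp = np.clip(bp, 0.0, None)
            bp = bp / bp.sum()
            draws = rng.choice(len(tree.branches), size=n, p=bp)
            for k in draws:
                branch = tree.branches[k]
                cls, cl = _branch_class(model, tree, branch)
                response = branch.category.split(":")[0]
                if cl is None and design.cl_emission is not None:
                    pcl = np.asarray(_emission_key(design.cl_emission, cls, None))
                    cl = CL_BINS[rng.choice(3, p=pcl / pcl.sum())]
                meanlog, sdlog = _emission_key(design.rt_emission, cls, cl)
                rt = float(rng.lognormal(meanlog, sdlog))
                records.append(
                    TrialRecord(
                        subject=subject,
                        condition=tree.target_proportion,
                        stimulus=tree.stimulus,
                        response=response,
                        confidence=cl,
                        rt=rt,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# model recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    """Proportion of simulated subjects whose true family won the
    information-criterion comparison, per generating design."""

    rows: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.rows, indent=2)

    def proportion(self, generating: str) -> float:
        for row in self.rows:
            if row["generating"] == generating:
                return row["proportion_true"]
        raise KeyError(generating)


def recovery_study(
    designs: Sequence[SimulationDesign],
    n_subjects: int | None = None,
    seed: int | None = None,
    criterion: str = "AICc",
    n_restarts: int = 3,
) -> RecoveryResult:
    """Generate -> fit -> select grid over a set of generating designs.

    For each design, ``n_subjects`` datasets are simulated and both
    families of the design's variant (SDT and 2HT) are fitted; the
    reported proportion is how often the generating family wins the
    ``criterion`` comparison.  Ties and failed fits are counted against
    recovery (logged per cell), keeping the proportion conservative.
    """
    if not designs:
        raise ConfigurationError("need at least one design")
    result = RecoveryResult()
    master = np.random.SeedSequence(seed)
    for design, ss in zip(designs, master.spawn(len(designs))):
        gen_model = design.model
        child_seeds = ss.spawn(2)
        local = SimulationDesign(
            model=gen_model,
            params=design.params,
            n_subjects=n_subjects or design.n_subjects,
            trials_per_tree=design.trials_per_tree,
            block_size=design.block_size,
            seed=int(child_seeds[0].generate_state(1)[0] % (2**31 - 1)),
        )
        tables = simulate_counts(local)
        candidates = {
            fam: build_model(
                fam, gen_model.variant, gen_model.n_conditions, gen_model.target_proportions
            )
            for fam in ("SDT", "2HT")
        }
        fit_seed = int(child_seeds[1].generate_state(1)[0] % (2**31 - 1))
        n_true = 0
        n_failed = 0
        for idx, table in enumerate(tables):
            fits: dict[str, FitResult] = {}
            ok = True
            for fam, cand in candidates.items():
                res = fit(cand, table, n_restarts=n_restarts, seed=fit_seed + idx,
                          compute_se=False)
                if not res.converged:
                    ok = False
                fits[fam] = res
            if not ok:
                n_failed += 1
                continue
            rec = select_best(
                fits["SDT"], fits["2HT"], subject=table.subject,
                variant=gen_model.variant, criterion=criterion,
            )
            if rec.winner == gen_model.family:
                n_true += 1
        n_total = len(tables)
        result.rows.append(
            {
                "generating": gen_model.name,
                "variant": gen_model.variant,
                "n_subjects": n_total,
                "n_true": n_true,
                "n_failed_fits": n_failed,
                "proportion_true": n_true / n_total if n_total else float("nan"),
                "criterion": criterion,
            }
        )
    return result
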