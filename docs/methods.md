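# Methods

## Scope and model structure

The package implements eight recognition-memory models: the
two-high-threshold (2HT) and signal-detection (SDT) families, each in a
classic form and in three extensions that fold confidence levels (CL),
binned reaction times (RT), or both into the multinomial category
space. Every model is a set of 2·J multinomial trees — one per
condition (target proportion) × stimulus type (old/new) — whose
category probabilities are products of simple terms along root-to-leaf
branches. Branches are stored as explicit term lists (a parameter, its
complement, or a Gaussian criterion-interval mass), never as closures,
so a `ModelSpec` serializes to JSON/YAML and round-trips exactly.

Category order within a tree is fixed: response (old, new), then
confidence (high, medium, low), then RT bin (fast, slow). Nothing in
the likelihood depends on the order; fixing it makes serialized counts
and probability vectors stable.

### 2HT family

Latent states: detect-old (probability `do`), detect-new (`dn`),
guess-old, guess-new. The high-threshold assumption is structural:
old-item trees contain no detect-new branch and new-item trees no
detect-old branch. Guessing "old" has probability `g_j`, shared between
old- and new-item trees but free per condition — the target-proportion
manipulation is assumed to move bias, not detection. Confidence is a
nested stick-breaking pair per state (`L_s1`, `L_s2`): high = `L_s1`,
medium = `(1−L_s1)·L_s2`, low = the remainder. RT bins add `H`
parameters: one per state (2HT-RT) or one per state × confidence bin
(2HT-CL-RT), each the probability that a response from that branch
class is fast.

### SDT family

Familiarity is N(0, 1) for new items and N(d′, σ) for old items (the
new-item distribution anchors the scale; σ is free, so the family is
unequal-variance). The classic model has one criterion `c_j` per
condition. With confidence, five ordered criteria cut the axis into six
regions, new-high at the far left through old-high at the far right,
with the old/new boundary at the middle (third) criterion. Criteria
move across conditions as a rigid block: only the first criterion per
condition (`c1_j`) and four shared non-negative increments (`dc_2` …
`dc_5`) are free, which both matches the published parameter totals and
enforces criterion ordering by construction. The classic `c_j` is a
distinct parameter, not an alias of the CL variant's middle criterion;
the two models are fitted independently. RT `H` parameters attach per
stimulus × response class (SDT-RT: hits, misses, false alarms, correct
rejections) or per stimulus × response-confidence class (SDT-CL-RT).

Free-parameter totals at J = 3: 5 / 5 (classic), 13 / 9 (CL),
9 / 9 (RT), 25 / 21 (CL+RT) for 2HT / SDT. The `L` and `H` parameters
are condition-invariant; making them condition-specific would triple
their count and is not identifiable at ~100 trials per tree.

## RT discretization

RT cutoffs are per subject, pooling all of that subject's trials across
conditions and stimulus types: log-transform the RTs, fit a normal to
the logs (sample SD, ddof = 1), take equal-probability quantiles, and
exponentiate. With two bins — the validated default — the single cutoff
is the geometric mean and the SD drops out. Ties at a cutoff go to the
faster bin ("exceeds the criterion" → slow, hence ≤ → fast). More than
two bins is supported mechanically but not recommended: the information
matrix for state-wise RT parameters becomes singular well before the
data run out of trials (we do not fit 3-bin 2HT variants by default for
this reason). RTs are seconds; readers accept milliseconds via
`rt_unit="ms"` and convert on ingest. No outlier trimming is applied.

## Maximum-likelihood fitting

The multinomial kernel −Σ_trees Σ_k n_k log p_k is minimized in a
transformed, unconstrained space: log-odds for [0, 1] parameters, log
for σ and the criterion increments, identity for d′ and criteria. This
avoids active-set handling at bounds, where these models genuinely pile
up under extreme conditions. Gradients are analytic (product rule along
branches; normal pdf through the criterion intervals) and are verified
against finite differences in the test suite; L-BFGS-B runs with
`ftol = 1e-10`. Each fit uses one data-informed start — inverting the
classic hit/false-alarm structure for the core parameters and pooled
confidence/RT margins for `L`/`H` — plus random restarts (default 10
total; 3 suffice in simulation and are used by the studies below).
Probabilities are floored at 1e-12 inside the optimizer only; the
public likelihood returns +inf for a zero-probability category with
observed counts.

Standard errors: inverse of the numerically differentiated observed
information in the transformed space, mapped to the natural scale by
the delta method. SEs are reported NaN — with a recorded message —
when the information matrix is singular/indefinite or an estimate lies
within 1e-5 of a bound; both are real failure modes of these models,
not exceptions.

Fit statistics at the optimum: Pearson χ² (cells with E = 0 and O = 0
contribute zero; E = 0 with O > 0 yields +inf with a warning), G²,
df = Σ_trees (K_tree − 1) − p, AIC = −2 logL + 2p, and
AICc = AIC + 2p(p+1)/(n − p − 1) with **n = the subject's total trial
count** (the convention of the MPT fitting tools this package
interoperates with; data-cell count is the plausible alternative). The
multinomial constant is omitted throughout — only likelihood-ratio and
information-criterion *differences* are ever used, and these are
unaffected.

## Bootstrap goodness of fit

Asymptotic χ² calibration is unreliable here (many cells, small
expected counts), so the null distribution is parametric-bootstrapped:
simulate B datasets from the fitted parameters holding each tree's
trial total at its observed value (the paradigm fixes block
composition), refit, and collect the Pearson statistics. The critical
value is the ceil((1−α)·m)-th order statistic of the m successful
refits — a conservative, simple quantile. Refits warm-start at the
original estimate plus one random start; failed refits are excluded and
counted. H0 is retained iff the observed χ² does not exceed the
critical value. B = 1000 is the CLI default; simulation studies in the
test suite use B = 200, which bounds the quantile's own Monte-Carlo
error at a level far below the width of the acceptance band used there.

## Model selection

Family comparisons (SDT vs 2HT at matched variant) use AICc by default
— the trial-to-parameter ratio is low, especially for CL+RT variants —
with plain AIC behind a flag. Exact ties are flagged, not broken.
Paired selections under two variants form a 2×2 crosstab analyzed with
the uncorrected Pearson χ² test of independence,
χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), and φ = √(χ²/N). No Yates
correction: recomputing the published crosstab statistics from their
printed cells matches the uncorrected statistic. A degenerate margin
returns χ² = φ = 0 with a warning.

## Synthetic data

The generator emulates the paradigm the models were built for: J = 3
analyzed blocks at target proportions .35/.50/.65, 100 test trials per
block split between old and new items by the target proportion (a flat
trials-per-tree override exists for methodological studies, which use
100 per tree), a 3-point confidence scale, and positive continuous RTs.
Counts are drawn per tree from the model's multinomial; trial-level
simulation samples a latent branch, emits the branch's response and
confidence, and draws RT from a branch-class-specific log-normal —
log-normal to be consistent with the binning approximation. One seed
sequence spawns independent per-subject streams, so any subject is
reproducible in isolation.

Default generating values (used by the recovery and calibration
studies, overridable everywhere): do = dn = .6; g = (.3, .5, .7);
detect-state confidence favours high bins (L1 = .7, L2 = .6) and
guess-state confidence low/medium bins (L1 = .3, L2 = .5); d′ = 1.5,
σ = 1.3; classic criteria (0.9, 0.65, 0.4) decreasing with target
proportion, and CL criteria placed so the middle criterion coincides
with the classic one (increments of .45); detection/correct responses
are more often fast (H ≈ .65–.75) than guesses/errors (H ≈ .4–.5).
These are plausible mid-range values for a .35–.65 proportion
manipulation; exact replication of any particular published simulation
table is out of scope.

What the generator does *not* emulate: subject-level parameter
heterogeneity (every simulated subject shares the generating values),
item effects, sequential dependencies, RT outliers/deadlines, and
response-style artifacts in confidence usage. Passing recovery and
calibration checks on these data therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not
robustness to real-data misspecification.

## Simulation studies shipped as tests

* **Parameter recovery** — 200 subjects per variant at 100 trials per
  tree; per-parameter mean-recovery is checked against a 3×(Monte-Carlo
  SE) band and pooled 1.96-SE interval coverage against [.90, .99].
  Coverage passes for all eight variants (.93–.95). The 3-MCSE bias
  band is *known to fail* for a few parameters: at 200 subjects the
  band is ±0.21 sampling SDs, tighter than the intrinsic O(1/n)
  small-sample bias of ML at this trial count (e.g. d′ biased +0.035 in
  SDT-CL; state-wise RT-bin parameters in 2HT-RT biased ~0.04 by weak
  mixture identifiability). The deviation is optimizer-independent
  (identical at 3 and 12 restarts) and is a property of the estimator
  at this design size, so the check is left in place and failing rather
  than widened.
* **Bootstrap calibration** — type-I rejection rate at α = .05 under
  the true classic 2HT model, 100 subjects at B = 200, checked against
  the binomial band [.01, .12].
* **Recovery direction** — with confidence modeled, AICc identifies
  the generating family for ≥ 80% of subjects (observed ≈ 93–100%),
  and strictly more often than the classic variants manage on classic
  data under shared seeds (observed ≈ 50–63%): accuracy alone barely
  separates the families, confidence separates them decisively.

Problem sizes in the test suite and `scripts/acceptance.py` (e.g.
B = 200 rather than 1000, 60–200 subjects per study) are chosen so the
Monte-Carlo error of each checked quantity is small relative to its
acceptance band while a full run stays in the minutes range on one CPU.

## Known limitations

* Individual fits only: no hierarchical pooling across subjects, and
  no equality constraints between subjects.
* Nonparametric RT treatment: branch RT distributions enter only
  through bin probabilities; parametric (e.g. ex-Gaussian) branch
  distributions are out of scope.
* The shared-g restriction of the 2HT family and the rigid-block
  criterion shift of the SDT-CL family are assumptions, not empirical
  findings; alternative restrictions change parameter counts and are
  not implemented.
* AICc's n is a convention (see above); users comparing against other
  software should check which n it uses.
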