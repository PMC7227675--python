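"""Scoring variable selection against a random-draw null, and accuracy metrics.

For each simulated species we count r, the number of true driver
variables among the three lowest-UI covariates. Under the null of picking
3 of the n covariates at random, r follows the hypergeometric law

    P(R = r) = C(k, r) * C(n - k, k - r) / C(n, k)

(n = 10, k = 3 gives 35/120, 63/120, 21/120, 1/120). Observed tallies of
r over species are compared to the null expectation with a one-tailed
(upper tail) Pearson chi-square goodness-of-fit test, and the weak vs
strong scenarios with a chi-square homogeneity test. Map accuracy of an
agreement raster is summarised by total/average omission, total/average
commission, and the trapezoidal ROC AUC with Hanley–McNeil standard
error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import garp, species as species_mod, ui as ui_mod
from .grids import Landscape

log = logging.getLogger(__name__)


# ------------------------------------------------------------------ null model
@dataclass(frozen=True)
class NullModel:
    """Hypergeometric null for the overlap of a random k-subset with the truth."""

    n_covariates: int = 10
    k: int = 3

    def __post_init__(self):
        if not 1 <= self.k <= self.n_covariates:
            raise ValueError("need 1 <= k <= n_covariates")

    @property
    def probabilities(self) -> np.ndarray:
        return null_probabilities(self.n_covariates, self.k)


def count_correct(true_vars, chosen_vars) -> int:
    """r = |true ∩ chosen|; both sets must have the same size."""
    t, c = set(true_vars), set(chosen_vars)
    if len(t) != len(c):
        raise ValueError(f"set sizes differ: {len(t)} vs {len(c)}")
    return len(t & c)


def null_probabilities(n: int, k: int) -> np.ndarray:
    """P(R = r) for r = 0..k when drawing k of n at random without replacement."""
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    r = np.arange(k + 1)
    # hypergeom(M population, n successes, N draws): overlap with a fixed k-set
    return sps.hypergeom.pmf(r, n, k, k)


def expected_counts(null: NullModel, n_species: int) -> tuple[np.ndarray, np.ndarray]:
    """Expected tallies (exact and rounded-half-away-from-zero) under the null."""
    if n_species < 0:
        raise ValueError("n_species must be >= 0")
    exact = n_species * null.probabilities
    rounded = np.floor(exact + 0.5).astype(int)  # half away from zero (values >= 0)
    return exact, rounded


def chisq_gof(observed, null: NullModel) -> tuple[float, int, float]:
    """One-tailed Pearson chi-square GOF of observed tallies vs the null.

    Expected counts are the *unrounded* null expectations; the p-value is
    the upper tail of chi-square with (categories - 1) df.
    """
    observed = np.asarray(observed, dtype=float)
    expected = observed.sum() * null.probabilities
    if len(observed) != len(expected):
        raise ValueError("observed vector length must be k + 1")
    if np.any(expected <= 0):
        raise ValueError("expected count of zero; invalid null")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = len(observed) - 1
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def chisq_homogeneity(counts_a, counts_b) -> tuple[float, int, float]:
    """Chi-square homogeneity test of two tally vectors (no continuity correction).

    Categories whose column total is zero are dropped with a warning and
    the degrees of freedom reduced accordingly.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have the same length")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both vectors need a positive total")
    keep = (a + b) > 0
    if not keep.all():
        log.warning("dropping %d empty categories from homogeneity test", (~keep).sum())
        a, b = a[keep], b[keep]
    if np.array_equal(a, b):
        return 0.0, len(a) - 1, 1.0
    stat, p, df, _ = sps.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(stat), int(df), float(p)


# ------------------------------------------------------------- accuracy report
@dataclass
class AccuracyReport:
    total_omission: float  # % of test presences with agreement 0
    average_omission: float  # mean per-model omission % on the test presences
    total_commission: float  # % of cells with agreement = n_best
    average_commission: float  # mean per-model % predicted present
    auc: float
    auc_se: float
    auc_z: float


def _roc_auc(pos_scores: np.ndarray, neg_scores: np.ndarray, n_levels: int) -> float:
    """Trapezoidal AUC from thresholding integer agreement scores at 0..n_levels.

    Thresholds are swept in decreasing order so (FPR, TPR) traces the ROC
    staircase from (0, 0) to (1, 1) monotonically.
    """
    thresholds = np.arange(n_levels + 1, -1, -1)
    tpr = np.array([(pos_scores >= t).mean() for t in thresholds])
    fpr = np.array([(neg_scores >= t).mean() for t in thresholds])
    return float(np.trapezoid(tpr, fpr))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of the AUC by the Hanley–McNeil (1982) formulation."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def accuracy_metrics(
    best: garp.BestSubset,
    landscape: Landscape,
    test_presences: np.ndarray,
    background: np.ndarray | None = None,
    n_background: int = 10_000,
    seed: int | np.random.SeedSequence | None = 0,
) -> AccuracyReport:
    """Accuracy of a best-subset agreement raster against external test points.

    Total omission: percentage of test presences falling on agreement-0
    cells. Average omission: mean over member models of the percentage of
    test presences that model predicts absent. Total commission:
    percentage of landscape cells with unanimous agreement. Average
    commission: mean member commission. AUC: trapezoidal area under the
    ROC obtained by thresholding the agreement level against test
    presences vs a uniform background sample, with Hanley–McNeil standard
    error and z-score versus the chance value 0.5.
    """
    test_presences = np.atleast_2d(np.asarray(test_presences, dtype=float))
    if len(test_presences) == 0:
        raise ValueError("empty test presence set")
    n_best = len(best.members)
    grid = landscape.grid
    row, col = grid.cell_of(test_presences[:, 0], test_presences[:, 1])
    agree_at_test = best.agreement[row, col]
    total_omission = 100.0 * float(np.mean(agree_at_test == 0))

    per_model_om = []
    Xtest = landscape.values_at(test_presences)
    for member in best.members:
        pred = member.ruleset.predict(Xtest)
        per_model_om.append(100.0 * float(np.mean(pred == 0)))
    average_omission = float(np.mean(per_model_om))

    total_commission = 100.0 * float(np.mean(best.agreement == n_best))
    average_commission = float(np.mean([m.evaluation.commission for m in best.members]))

    if background is None:
        background = garp.sample_background(landscape, n_background, seed)
    brow, bcol = grid.cell_of(background[:, 0], background[:, 1])
    agree_bg = best.agreement[brow, bcol]
    auc = _roc_auc(agree_at_test, agree_bg, n_best)
    se = hanley_mcneil_se(auc, len(agree_at_test), len(agree_bg))
    z = (auc - 0.5) / se if se > 0 else float("inf") if auc != 0.5 else 0.0
    return AccuracyReport(
        total_omission=total_omission,
        average_omission=average_omission,
        total_commission=total_commission,
        average_commission=average_commission,
        auc=auc,
        auc_se=se,
        auc_z=float(z),
    )


# ------------------------------------------------------------ simulation study
@dataclass
class SelectionScore:
    species_id: str
    scenario: str
    true_vars: list[str]
    chosen_vars: list[str]
    r: int


@dataclass
class ValidationResult:
    scores: list[SelectionScore]
    observed: dict[str, np.ndarray]  # scenario (+ 'all') -> tallies over r
    expected: dict[str, np.ndarray]
    gof: dict[str, tuple[float, int, float]]
    homogeneity: tuple[float, int, float] | None
    null: NullModel
    n_failures: int = 0
    seeds: dict = field(default_factory=dict)

    def fraction_r_at_least(self, r_min: int, scenario: str = "all") -> float:
        obs = self.observed[scenario]
        return float(obs[r_min:].sum() / obs.sum())


def score_species(
    sp: species_mod.VirtualSpecies,
    landscape: Landscape,
    seed: int | np.random.SeedSequence,
    n_models: int = 200,
    ga_params: dict | None = None,
    subset_params: dict | None = None,
    species_id: str = "sp",
) -> SelectionScore:
    """Full per-species loop: experiment -> best subset -> UI -> r."""
    results = garp.run_experiment(
        sp.presences, landscape, n_models=n_models, seed=seed, **(ga_params or {})
    )
    best = garp.best_subset(results, **(subset_params or {}))
    contrib = ui_mod.variable_contributions(best, landscape)
    chosen = ui_mod.lowest_k(contrib, len(sp.true_vars))
    return SelectionScore(
        species_id=species_id,
        scenario=sp.scenario.name,
        true_vars=list(sp.true_vars),
        chosen_vars=chosen,
        r=count_correct(sp.true_vars, chosen),
    )


def run_simulation_study(
    n_species_per_scenario: int = 100,
    scenarios: tuple[str, ...] = ("weak", "strong"),
    landscape: Landscape | None = None,
    seed: int | np.random.SeedSequence = 0,
    n_models: int = 200,
    ga_params: dict | None = None,
    subset_params: dict | None = None,
    desk_scale: bool = True,
) -> ValidationResult:
    """Benchmark UI variable recovery on simulated species.

    Simulates ``n_species_per_scenario`` virtual species per scenario on a
    shared landscape (one landscape per experiment; simulated here if not
    supplied), runs the full modelling + UI pipeline per species, tallies
    r, and computes the goodness-of-fit tests per scenario and pooled plus
    the weak-vs-strong homogeneity test. Per-species failures are logged
    and excluded from the tallies.
    """
    from .landscape import default_grid, simulate_landscape

    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    land_ss, *scen_ss = master.spawn(1 + len(scenarios))
    if landscape is None:
        landscape = simulate_landscape(default_grid(desk_scale), seed=land_ss)
    null = NullModel(n_covariates=landscape.n_covariates, k=3)
    scores: list[SelectionScore] = []
    n_failures = 0
    for scen_name, scen_seed in zip(scenarios, scen_ss):
        scenario = species_mod.SCENARIOS[scen_name]
        for i, child in enumerate(scen_seed.spawn(n_species_per_scenario)):
            sp_ss, model_ss = child.spawn(2)
            sid = f"{scen_name}-{i:03d}"
            try:
                sp = species_mod.simulate_species(landscape, scenario, sp_ss)
                scores.append(
                    score_species(
                        sp,
                        landscape,
                        model_ss,
                        n_models=n_models,
                        ga_params=ga_params,
                        subset_params=subset_params,
                        species_id=sid,
                    )
                )
                log.info("species %s: r = %d", sid, scores[-1].r)
            except (RuntimeError, ValueError) as e:
                n_failures += 1
                log.warning("species %s failed and is excluded: %s", sid, e)
    observed: dict[str, np.ndarray] = {}
    expected: dict[str, np.ndarray] = {}
    gof: dict[str, tuple[float, int, float]] = {}
    groups = {s: [sc.r for sc in scores if sc.scenario == s] for s in scenarios}
    groups["all"] = [sc.r for sc in scores]
    for name, rs in groups.items():
        obs = np.bincount(rs, minlength=null.k + 1)
        observed[name] = obs
        expected[name] = expected_counts(null, len(rs))[0]
        if len(rs):
            gof[name] = chisq_gof(obs, null)
    homogeneity = None
    if len(scenarios) == 2 and all(observed[s].sum() > 0 for s in scenarios):
        homogeneity = chisq_homogeneity(observed[scenarios[0]], observed[scenarios[1]])
    return ValidationResult(
        scores=scores,
        observed=observed,
        expected=expected,
        gof=gof,
        homogeneity=homogeneity,
        null=null,
        n_failures=n_failures,
        seeds={"master": str(master.entropy)},
    )
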