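"""Genetic evolution of rule-sets, projection and best-subset selection.

The model is presence-only: pseudo-absences are uniform random draws of
the landscape background. Each candidate model is an ordered list of 50
rules (first match wins, unmatched cells predicted absent). A genetic
algorithm maintains a population of rules; every generation it draws a
fresh bootstrap of presence and background points, scores each rule with
a 2x2 chi-square (no continuity correction) and its predictive accuracy,
keeps the significant rules ranked by fitness, and refills the population
with crossover, mutation, insertion and deletion offspring. Evolution
stops at ``max_iter`` generations or when the population mean accuracy
changes by less than ``tol`` between generations.

A multi-model experiment repeats this with independent seeds and internal
75/25 train/test splits; the best subset keeps, among the 20 lowest-
omission models under a 10% extrinsic-omission ceiling, the 10 whose
commission (percent of landscape predicted present) is closest to the
median, and sums their binary maps into a 0-10 agreement raster.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .grids import Landscape
from .rules import CHI2_CRITICAL, Rule, RuleStats, score_rule

log = logging.getLogger(__name__)


# --------------------------------------------------------------------- splits
def _train_size(n: int, fraction: float, rounding: str) -> int:
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"split fraction must be in (0, 1), got {fraction}")
    if rounding == "half_up":
        n_train = math.floor(fraction * n + 0.5)
    elif rounding == "down":
        n_train = math.floor(fraction * n)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    # always keep at least one point on each side
    return min(max(n_train, 1), n - 1)


def internal_split(
    presences: np.ndarray,
    fraction: float = 0.75,
    seed: int | np.random.SeedSequence | None = 0,
    rounding: str = "half_up",
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test partition of presence points.

    ``|train| = round(fraction * n)`` under the chosen rounding rule
    ('half_up', the default, rounds .5 up; 'down' truncates), with at
    least one point on each side.
    """
    presences = np.asarray(presences)
    n = len(presences)
    if n < 2:
        raise ValueError("need at least 2 points to split")
    n_train = _train_size(n, fraction, rounding)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return presences[perm[:n_train]], presences[perm[n_train:]]


def sample_background(
    landscape: Landscape, n: int, seed: int | np.random.SeedSequence | None = 0
) -> np.ndarray:
    """Draw n cell centroids uniformly (with replacement) from the grid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = landscape.grid
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, grid.n_rows, n)
    cols = rng.integers(0, grid.n_cols, n)
    x, y = grid.centroid(rows, cols)
    return np.column_stack([x, y])


# ------------------------------------------------------------------ estimator
class GarpRuleset(ClassifierMixin, BaseEstimator):
    """Rule-set presence/absence classifier evolved by a genetic algorithm.

    Parameters
    ----------
    n_rules : int, default 50
        Number of rules retained in the final ordered ruleset (also the
        population size of the genetic algorithm).
    max_iter : int, default 1000
        Generation cap.
    tol : float, default 0.01
        Convergence threshold on the change of the population mean
        accuracy between generations.
    resample_size : int, default 1250
        Bootstrap draws per class per generation: each generation scores
        rules on ``resample_size`` presence rows and ``resample_size``
        absence (background) rows resampled with replacement from the
        training data.
    chi2_threshold : float
        Significance cutoff for the per-rule 2x2 chi-square (default
        3.84, alpha = 0.05 at 1 df).
    p_crossover, p_mutation, p_insertion, p_deletion : float
        Genetic operator rates; the remainder of the offspring mass
        clones a parent.
    max_rule_vars : int, default 3
        Maximum number of covariates a range/atomic rule may reference.
    atomic_bins : int, default 254
        Number of discretisation levels for atomic rules (emulating
        8-bit environmental grids); the half bin width is the atomic
        matching tolerance.
    random_state : int, Generator or None
        Seeds every stochastic step; identical inputs and seeds give an
        identical ruleset.

    Attributes
    ----------
    rules_ : list of Rule
        Final ruleset, ordered by descending internal accuracy (ties:
        higher chi-square, then insertion order); this is the projection
        order.
    n_iter_ : int
        Generations run.
    converged_ : bool
    feature_names_ : list of str
    """

    def __init__(
        self,
        n_rules: int = 50,
        max_iter: int = 1000,
        tol: float = 0.01,
        resample_size: int = 1250,
        chi2_threshold: float = CHI2_CRITICAL,
        p_crossover: float = 0.25,
        p_mutation: float = 0.25,
        p_insertion: float = 0.1,
        p_deletion: float = 0.1,
        max_rule_vars: int = 3,
        atomic_bins: int = 254,
        allow_negated_presence: bool = False,
        random_state=None,
    ):
        self.n_rules = n_rules
        self.max_iter = max_iter
        self.tol = tol
        self.resample_size = resample_size
        self.chi2_threshold = chi2_threshold
        self.p_crossover = p_crossover
        self.p_mutation = p_mutation
        self.p_insertion = p_insertion
        self.p_deletion = p_deletion
        self.max_rule_vars = max_rule_vars
        self.atomic_bins = atomic_bins
        self.allow_negated_presence = allow_negated_presence
        self.random_state = random_state

    # -- rule generation helpers ------------------------------------------
    def _random_vars(self, rng) -> list[int]:
        nv = int(rng.integers(1, self.max_rule_vars + 1))
        return list(rng.choice(self._n_features, size=min(nv, self._n_features), replace=False))

    def _envelope_rule(self, rng, consequent: int = 1, negated: bool = False) -> Rule:
        """Range rule with bounds at a random percentile envelope of presences."""
        idx = self._random_vars(rng)
        q_lo = rng.uniform(0.0, 0.3, len(idx))
        q_hi = rng.uniform(0.7, 1.0, len(idx))
        P = self._pres[:, idx]
        lo = np.array([np.quantile(P[:, j], q_lo[j]) for j in range(len(idx))])
        hi = np.array([np.quantile(P[:, j], q_hi[j]) for j in range(len(idx))])
        return Rule(
            "negated_range" if negated else "range",
            consequent,
            tuple(self.feature_names_[i] for i in idx),
            lower=lo,
            upper=hi,
        )

    def _atomic_rule(self, rng) -> Rule:
        idx = self._random_vars(rng)
        row = self._pres[int(rng.integers(len(self._pres)))]
        widths = self._bin_width[idx]
        mins = self._feat_min[idx]
        bins = np.clip(np.floor((row[idx] - mins) / widths), 0, self.atomic_bins - 1)
        atoms = mins + (bins + 0.5) * widths
        return Rule(
            "atomic",
            1,
            tuple(self.feature_names_[i] for i in idx),
            atoms=atoms,
            tolerance=widths / 2.0,
        )

    def _logit_rule(self, rng, X: np.ndarray, y: np.ndarray) -> Rule:
        idx = self._random_vars(rng)
        sub = rng.choice(len(X), size=min(400, len(X)), replace=False)
        lr = LogisticRegression(max_iter=200)
        try:
            lr.fit(X[sub][:, idx], y[sub])
            coef, intercept = lr.coef_[0], float(lr.intercept_[0])
        except Exception:  # single-class subsample
            coef, intercept = rng.normal(0, 1, len(idx)), 0.0
        return Rule(
            "logit",
            1,
            tuple(self.feature_names_[i] for i in idx),
            coefficients=coef,
            intercept=intercept,
        )

    def _new_rule(self, rng, X, y, allow_logit: bool = True) -> Rule:
        u = rng.random()
        if u < 0.60:
            return self._envelope_rule(rng)
        if u < 0.75 and allow_logit:
            return self._logit_rule(rng, X, y)
        if u < 0.90:
            return self._atomic_rule(rng)
        return self._envelope_rule(
            rng,
            consequent=1 if self.allow_negated_presence and rng.random() < 0.5 else 0,
            negated=True,
        )

    # -- genetic operators -------------------------------------------------
    def _mutate(self, rule: Rule, rng) -> Rule:
        r = rule.copy()
        if r.rule_type in ("range", "negated_range"):
            idx = [self._name_to_col[v] for v in r.variables]
            scale = 0.15 * self._feat_std[idx]
            r.lower = r.lower + rng.normal(0, 1, len(idx)) * scale
            r.upper = r.upper + rng.normal(0, 1, len(idx)) * scale
            swap = r.lower > r.upper
            r.lower[swap], r.upper[swap] = r.upper[swap], r.lower[swap]
        elif r.rule_type == "logit":
            r.coefficients = r.coefficients + rng.normal(0, 0.2, len(r.coefficients)) * (
                1.0 / np.maximum(self._feat_std[[self._name_to_col[v] for v in r.variables]], 1e-9)
            )
            r.intercept = r.intercept + rng.normal(0, 0.2)
        else:
            row = self._pres[int(rng.integers(len(self._pres)))]
            idx = [self._name_to_col[v] for v in r.variables]
            widths = self._bin_width[idx]
            mins = self._feat_min[idx]
            bins = np.clip(np.floor((row[idx] - mins) / widths), 0, self.atomic_bins - 1)
            r.atoms = mins + (bins + 0.5) * widths
        return r

    def _delete_var(self, rule: Rule, rng) -> Rule:
        if rule.rule_type not in ("range", "negated_range") or len(rule.variables) <= 1:
            return self._mutate(rule, rng)
        drop = int(rng.integers(len(rule.variables)))
        keep = [j for j in range(len(rule.variables)) if j != drop]
        r = rule.copy()
        r.variables = tuple(rule.variables[j] for j in keep)
        r.lower, r.upper = r.lower[keep], r.upper[keep]
        return r

    def _crossover(self, a: Rule, b: Rule, rng) -> Rule:
        if a.rule_type not in ("range", "negated_range") or b.rule_type != a.rule_type:
            return self._mutate(a, rng)
        merged: dict[str, tuple[float, float]] = {}
        for r in (a, b):
            for v, lo, hi in zip(r.variables, r.lower, r.upper):
                if v in merged and rng.random() < 0.5:
                    continue
                merged[v] = (lo, hi)
        names = list(merged)
        if len(names) > self.max_rule_vars:
            names = [names[i] for i in rng.choice(len(names), self.max_rule_vars, replace=False)]
        out = Rule(
            a.rule_type,
            a.consequent,
            tuple(names),
            lower=np.array([merged[v][0] for v in names]),
            upper=np.array([merged[v][1] for v in names]),
        )
        return out

    def _offspring(self, survivors: list[Rule], rng, X, y) -> Rule:
        weights = np.array(
            [0.0 if np.isnan(r.stats.accuracy) else max(r.stats.accuracy, 1e-6) for r in survivors]
        )
        if weights.sum() == 0:
            weights = np.ones(len(survivors))
        weights = weights / weights.sum()
        pick = lambda: survivors[int(rng.choice(len(survivors), p=weights))]
        u = rng.random()
        p_c, p_m, p_i, p_d = (
            self.p_crossover,
            self.p_mutation,
            self.p_insertion,
            self.p_deletion,
        )
        if u < p_c:
            return self._crossover(pick(), pick(), rng)
        if u < p_c + p_m:
            return self._mutate(pick(), rng)
        if u < p_c + p_m + p_i:
            return self._new_rule(rng, X, y, allow_logit=False)
        if u < p_c + p_m + p_i + p_d:
            return self._delete_var(pick(), rng)
        return pick().copy()

    # -- fitting -----------------------------------------------------------
    @staticmethod
    def _rank_key(rule: Rule, order: int):
        acc = -1.0 if np.isnan(rule.stats.accuracy) else rule.stats.accuracy
        return (-int(rule.stats.significant), -acc, -rule.stats.chi2, order)

    def fit(self, X, y, feature_names: list[str] | None = None) -> "GarpRuleset":
        """Evolve a ruleset on a labelled presence (1) / background (0) sample.

        X may be a (n, p) array or a pandas DataFrame (column names become
        the rule vocabulary).
        """
        if hasattr(X, "columns"):
            feature_names = list(X.columns) if feature_names is None else feature_names
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("y must be binary (1 = presence, 0 = background)")
        if (y == 1).sum() < 2:
            raise ValueError("need at least 2 presence rows")
        if (y == 0).sum() < 1:
            raise ValueError("need background (pseudo-absence) rows")
        self._n_features = X.shape[1]
        self.feature_names_ = (
            feature_names if feature_names is not None else [f"x{j}" for j in range(X.shape[1])]
        )
        if len(self.feature_names_) != X.shape[1]:
            raise ValueError("feature_names length mismatch")
        self._name_to_col = {n: j for j, n in enumerate(self.feature_names_)}
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        self._pres = X[y == 1]
        bg = X[y == 0]
        self._feat_min = X.min(axis=0)
        self._feat_max = X.max(axis=0)
        span = np.maximum(self._feat_max - self._feat_min, 1e-12)
        self._bin_width = span / self.atomic_bins
        self._feat_std = np.maximum(X.std(axis=0), 1e-12)

        m = self.resample_size

        def resample(size: int = m):
            pi = rng.integers(0, len(self._pres), size)
            bi = rng.integers(0, len(bg), size)
            Xg = np.vstack([self._pres[pi], bg[bi]])
            yg = np.concatenate([np.ones(size, int), np.zeros(size, int)])
            return Xg, yg

        Xg, yg = resample()
        population = [self._new_rule(rng, Xg, yg) for _ in range(self.n_rules)]
        order = {id(r): i for i, r in enumerate(population)}
        next_order = len(population)
        prev_mean = 0.0
        self.converged_ = False
        n_iter = 0
        for gen in range(1, self.max_iter + 1):
            n_iter = gen
            for rule in population:
                score_rule(rule, Xg, yg, self._name_to_col)
            population.sort(key=lambda r: self._rank_key(r, order.get(id(r), 0)))
            accs = np.array([r.stats.accuracy for r in population])
            mean_acc = float(np.nanmean(accs)) if not np.all(np.isnan(accs)) else 0.0
            if abs(mean_acc - prev_mean) < self.tol:
                self.converged_ = True
                break
            prev_mean = mean_acc
            survivors = [
                r for r in population if r.stats.significant and r.stats.chi2 >= self.chi2_threshold
            ]
            if not survivors:
                survivors = population[: max(2, self.n_rules // 5)]
            Xg, yg = resample()
            children = []
            for _ in range(self.n_rules - len(survivors[: self.n_rules])):
                child = self._offspring(survivors, rng, Xg, yg)
                order[id(child)] = next_order
                next_order += 1
                children.append(child)
            population = survivors[: self.n_rules] + children

        # final scoring on a larger fresh resample: the projection order is
        # the accuracy ranking, so low-variance final statistics matter
        Xg, yg = resample(5 * m)
        for rule in population:
            score_rule(rule, Xg, yg, self._name_to_col)
        final = [r for r in population if r.stats.chi2 >= self.chi2_threshold]
        if not final:
            raise RuntimeError(
                "no rule reached chi-square significance; the training sample is "
                "likely too small or uninformative — provide more presence points"
            )
        final.sort(key=lambda r: self._rank_key(r, order.get(id(r), 0)))
        self.rules_ = final[: self.n_rules]
        self.n_iter_ = n_iter
        return self

    # -- prediction --------------------------------------------------------
    def decision_index(self, X) -> np.ndarray:
        """Index (into ``rules_``) of the first firing rule per row; -1 if none."""
        check_is_fitted(self, "rules_")
        if hasattr(X, "to_numpy"):
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(len(X), -1, dtype=np.int32)
        undecided = np.ones(len(X), dtype=bool)
        for i, rule in enumerate(self.rules_):
            if not undecided.any():
                break
            rows = np.flatnonzero(undecided)
            fired = rule.fires(X[rows], self._name_to_col)
            hit = rows[fired]
            out[hit] = i
            undecided[hit] = False
        return out

    def predict(self, X) -> np.ndarray:
        """Presence (1) / absence (0) by first-match-wins; no match = absent."""
        idx = self.decision_index(X)
        cons = np.array([r.consequent for r in self.rules_], dtype=np.int8)
        pred = np.where(idx >= 0, cons[np.clip(idx, 0, None)], 0).astype(np.int8)
        return pred


# ------------------------------------------------------------------ pipeline
@dataclass
class ModelEvaluation:
    extrinsic_omission: float  # % of internal test presences predicted absent
    commission: float  # % of landscape cells predicted present

    def __post_init__(self):
        for v in (self.extrinsic_omission, self.commission):
            if not 0.0 <= v <= 100.0:
                raise ValueError("rates are percentages in [0, 100]")


@dataclass
class GarpModelResult:
    ruleset: GarpRuleset
    evaluation: ModelEvaluation
    binary: np.ndarray  # (rows, cols) uint8 presence map
    rule_index: np.ndarray  # (rows, cols) int32 deciding-rule index, -1 = none
    seed: object = None


@dataclass
class BestSubset:
    members: list[GarpModelResult]
    agreement: np.ndarray  # integer raster in {0..len(members)}
    median_commission: float
    underfilled: bool = False
    landscape_names: list[str] = field(default_factory=list)


def project(ruleset: GarpRuleset, landscape: Landscape) -> tuple[np.ndarray, np.ndarray]:
    """Project a ruleset onto the landscape grid.

    Returns (binary presence/absence raster, deciding-rule-index raster);
    cells matched by no rule are absent with index -1.
    """
    X = landscape.feature_matrix()
    # rules are evaluated by name, so a landscape with extra covariates works
    missing = [v for r in ruleset.rules_ for v in r.variables if v not in landscape]
    if missing:
        raise KeyError(f"landscape lacks covariates referenced by rules: {sorted(set(missing))}")
    name_to_col = {n: j for j, n in enumerate(landscape.names)}
    saved = ruleset._name_to_col
    ruleset._name_to_col = name_to_col
    try:
        idx = ruleset.decision_index(X)
    finally:
        ruleset._name_to_col = saved
    cons = np.array([r.consequent for r in ruleset.rules_], dtype=np.int8)
    binary = np.where(idx >= 0, cons[np.clip(idx, 0, None)], 0).astype(np.uint8)
    shape = landscape.grid.shape
    return binary.reshape(shape), idx.reshape(shape).astype(np.int32)


def evolve_ruleset(
    train_presences: np.ndarray,
    landscape: Landscape,
    seed: int | np.random.SeedSequence | None = 0,
    background_pool: int = 5000,
    **params,
) -> GarpRuleset:
    """Fit one GarpRuleset from presence points on a landscape.

    Builds the labelled sample (presence features + a uniform background
    pool of ``background_pool`` cells) and fits :class:`GarpRuleset` with
    the given parameters.
    """
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    bg_ss, fit_ss = master.spawn(2)
    bg = sample_background(landscape, background_pool, bg_ss)
    Xp = landscape.values_at(np.asarray(train_presences))
    Xb = landscape.values_at(bg)
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xb), int)])
    est = GarpRuleset(random_state=np.random.default_rng(fit_ss), **params)
    return est.fit(X, y, feature_names=landscape.names)


def run_experiment(
    presences: np.ndarray,
    landscape: Landscape,
    n_models: int = 200,
    seed: int | np.random.SeedSequence | None = 0,
    train_fraction: float = 0.75,
    rounding: str = "half_up",
    background_pool: int = 5000,
    **params,
) -> list[GarpModelResult]:
    """Run a multi-model experiment: n_models independently seeded rulesets.

    Each model gets its own internal train/test split of the presences;
    its extrinsic omission is the percentage of its internal test
    presences it predicts absent, and its commission the percentage of
    landscape cells it predicts present. Models that fail to evolve any
    significant rule are logged and skipped.
    """
    presences = np.asarray(presences, dtype=float)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    results: list[GarpModelResult] = []
    failures = 0
    for m, child in enumerate(master.spawn(n_models)):
        split_ss, fit_ss = child.spawn(2)
        train, test = internal_split(presences, train_fraction, split_ss, rounding)
        try:
            ruleset = evolve_ruleset(
                train, landscape, seed=fit_ss, background_pool=background_pool, **params
            )
        except RuntimeError as e:
            failures += 1
            log.warning("model %d failed: %s", m, e)
            continue
        binary, rule_index = project(ruleset, landscape)
        test_pred = ruleset.predict(landscape.values_at(test))
        omission = 100.0 * float(np.mean(test_pred == 0))
        commission = 100.0 * float(binary.mean())
        results.append(
            GarpModelResult(
                ruleset=ruleset,
                evaluation=ModelEvaluation(omission, commission),
                binary=binary,
                rule_index=rule_index,
                seed=str(child.entropy),
            )
        )
    if failures:
        log.warning("%d of %d models failed to evolve a significant ruleset", failures, n_models)
    return results


def best_subset(
    models: list[GarpModelResult],
    omission_threshold: float = 10.0,
    n_low_omission: int = 20,
    commission_window: float = 0.5,
    n_best: int | None = None,
    pool_order: str = "run",
) -> BestSubset:
    """Select the best subset of models by omission then commission.

    Models with extrinsic omission <= ``omission_threshold`` (%) qualify;
    ``n_low_omission`` of them are pooled — in run order by default
    (``pool_order="run"``), or lowest omission first
    (``pool_order="omission"``, which systematically favours the broadest
    models, since omission 0 is easiest at near-total commission). The
    pool's median commission is computed and the ``n_best`` (default:
    ``commission_window * n_low_omission``) models with commission
    closest to that median are selected (ties: lower omission, then input
    order). Their binary maps are summed into the agreement raster. If
    fewer than ``n_best`` models qualify, all qualifying models are
    returned with ``underfilled=True`` and a warning.
    """
    if n_best is None:
        n_best = int(round(commission_window * n_low_omission))
    qualifying = [
        (i, r) for i, r in enumerate(models) if r.evaluation.extrinsic_omission <= omission_threshold
    ]
    underfilled = len(qualifying) < n_best
    if underfilled:
        warnings.warn(
            f"only {len(qualifying)} models meet the {omission_threshold}% omission "
            f"threshold (< {n_best}); returning all of them",
            stacklevel=2,
        )
    if pool_order == "omission":
        qualifying.sort(key=lambda t: (t[1].evaluation.extrinsic_omission, t[0]))
    elif pool_order != "run":
        raise ValueError(f"unknown pool_order {pool_order!r}")
    pool = qualifying[:n_low_omission]
    if not pool:
        raise ValueError("no model meets the omission threshold")
    commissions = np.array([r.evaluation.commission for _, r in pool])
    med = float(np.median(commissions))
    ranked = sorted(
        pool,
        key=lambda t: (
            abs(t[1].evaluation.commission - med),
            t[1].evaluation.extrinsic_omission,
            t[0],
        ),
    )
    selected = [r for _, r in ranked[:n_best]]
    agreement = np.sum([r.binary.astype(np.int32) for r in selected], axis=0)
    return BestSubset(
        members=selected,
        agreement=agreement,
        median_commission=med,
        underfilled=underfilled,
    )
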