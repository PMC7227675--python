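"""Variable-contribution estimation from a best subset of rule-set models.

The Unimportance Index (UI) scores each covariate from the *dominant
presence rules* of the best subset — the smallest set of presence rules
that together account for more than 90% of the subset's presence
predictions on the landscape. For each covariate k:

    prevalence_k   = (# dominant rules referencing k) / (# dominant rules)
    median_range_k = median(per-rule upper bound) - median(per-rule lower bound)
    UI_k           = (1 - prevalence_k) * scaled_median_range_k
    rescaled UI_k  = (UI_k - UI_min) / (UI_max - UI_min)

where the median range is scaled to [0, 1] by the covariate's full range
over the landscape. Low UI means high contribution: the model uses the
variable often and constrains it tightly. Bounds come from the stored
envelope for (negated) range rules, from zonal min/max over the cells a
logit rule decides for logit rules, and from the (point) atom values for
atomic rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .garp import BestSubset
from .grids import Landscape
from .rules import Rule

log = logging.getLogger(__name__)


@dataclass
class DominantRule:
    model_index: int
    rule_index: int
    rule: Rule
    coverage: float  # fraction of pooled presence cell-decisions


@dataclass
class DominantRuleSet:
    rules: list[DominantRule]
    cumulative_coverage: float

    def __len__(self) -> int:
        return len(self.rules)


def dominant_presence_rules(best: BestSubset, coverage_target: float = 0.90) -> DominantRuleSet:
    """Extract the dominant presence rules of a best subset.

    Pools presence-predicting cell decisions across all member models (a
    cell predicted present by 4 models contributes 4 decisions); a rule's
    coverage is its share of that pool. Rules are sorted by descending
    coverage and the smallest prefix with cumulative coverage strictly
    greater than ``coverage_target`` is kept.
    """
    entries: list[DominantRule] = []
    total = 0
    for m_i, member in enumerate(best.members):
        pres = member.binary == 1
        n_pres = int(pres.sum())
        total += n_pres
        if n_pres == 0:
            continue
        counts = np.bincount(member.rule_index[pres], minlength=len(member.ruleset.rules_))
        for r_i in np.flatnonzero(counts):
            entries.append(
                DominantRule(m_i, int(r_i), member.ruleset.rules_[r_i], int(counts[r_i]))
            )
    if total == 0:
        raise ValueError("the best subset predicts presence nowhere; no dominant rules")
    for e in entries:
        e.coverage = e.coverage / total
    entries.sort(key=lambda e: (-e.coverage, e.model_index, e.rule_index))
    kept: list[DominantRule] = []
    cum = 0.0
    for e in entries:
        kept.append(e)
        cum += e.coverage
        if cum > coverage_target:
            break
    by_type: dict[str, int] = {}
    for e in kept:
        by_type[e.rule.rule_type] = by_type.get(e.rule.rule_type, 0) + 1
    log.info("dominant presence rules: %d (coverage %.3f) by type %s", len(kept), cum, by_type)
    return DominantRuleSet(rules=kept, cumulative_coverage=cum)


def prevalence(covariate: str, dominant: DominantRuleSet) -> float:
    """Fraction of dominant presence rules whose condition references the covariate."""
    if not dominant.rules:
        raise ValueError("empty dominant rule set")
    hits = sum(1 for e in dominant.rules if covariate in e.rule.variables)
    return hits / len(dominant.rules)


def rule_bounds(
    entry: DominantRule, covariate: str, best: BestSubset, landscape: Landscape
) -> tuple[float, float, bool] | None:
    """Bounds (min, max, is_point) a dominant rule implies for a covariate.

    Range and negated-range rules yield their stored envelope; logit rules
    the zonal min/max of the covariate over the cells this rule decides as
    presence; atomic rules their (point) atom value. Returns None when a
    logit rule decides no presence cells (bounds undefined; logged).
    """
    rule = entry.rule
    if covariate not in rule.variables:
        raise ValueError(f"rule does not reference {covariate!r}")
    j = rule.variables.index(covariate)
    if rule.rule_type in ("range", "negated_range"):
        return float(rule.lower[j]), float(rule.upper[j]), False
    if rule.rule_type == "atomic":
        return float(rule.atoms[j]), float(rule.atoms[j]), True
    member = best.members[entry.model_index]
    mask = (member.rule_index == entry.rule_index) & (member.binary == 1)
    if not mask.any():
        log.info("logit rule %d/%d decides no presence cells; bounds undefined",
                 entry.model_index, entry.rule_index)
        return None
    vals = landscape[covariate][mask]
    return float(vals.min()), float(vals.max()), False


def median_range(
    covariate: str,
    dominant: DominantRuleSet,
    best: BestSubset,
    landscape: Landscape,
) -> float:
    """Median of per-rule maxima minus median of per-rule minima.

    Computed over the dominant rules referencing the covariate (atomic
    points contribute equal min and max). Raises if the covariate appears
    in no dominant rule with defined bounds.
    """
    mins, maxs = [], []
    for e in dominant.rules:
        if covariate not in e.rule.variables:
            continue
        b = rule_bounds(e, covariate, best, landscape)
        if b is None:
            continue
        mins.append(b[0])
        maxs.append(b[1])
    if not mins:
        raise ValueError(f"{covariate!r} appears in no dominant rule with defined bounds")
    return float(np.median(maxs) - np.median(mins))


def scaled_median_range(covariate: str, median_range_value: float, landscape: Landscape) -> float:
    """Median range divided by the covariate's full landscape range, clipped to [0, 1]."""
    lo, hi = landscape.value_range(covariate)
    if not hi > lo:
        raise ValueError(f"covariate {covariate!r} is constant on the landscape")
    return float(np.clip(median_range_value / (hi - lo), 0.0, 1.0))


def unimportance_index(prevalence_value: float, scaled_range: float) -> float:
    """UI = (1 - prevalence) * scaled median range."""
    return (1.0 - prevalence_value) * scaled_range


def rescale_ui(ui_values: np.ndarray) -> np.ndarray:
    """Min-max rescale UIs to [0, 1]; all-equal input degenerates to zeros."""
    ui = np.asarray(ui_values, dtype=float)
    lo, hi = ui.min(), ui.max()
    if hi == lo:
        warnings.warn("all UI values are equal; rescaled UI set to 0 for every covariate",
                      stacklevel=2)
        return np.zeros_like(ui)
    return (ui - lo) / (hi - lo)


def variable_contributions(
    best: BestSubset,
    landscape: Landscape,
    threshold: float = 0.5,
    coverage_target: float = 0.90,
) -> pd.DataFrame:
    """Per-covariate contribution table.

    Columns: covariate, prevalence, median_range, scaled_median_range, ui,
    rescaled_ui, rank (1 = lowest UI = highest contribution), selected
    (rescaled UI strictly below ``threshold``). A covariate never used by
    any dominant rule gets prevalence 0 and scaled median range 1 — the
    model never constrained it, so it is maximally unimportant.
    """
    dominant = dominant_presence_rules(best, coverage_target)
    rows = []
    for name in landscape.names:
        p = prevalence(name, dominant)
        try:
            mr = median_range(name, dominant, best, landscape)
            smr = scaled_median_range(name, mr, landscape)
        except ValueError:
            mr, smr = float("nan"), 1.0
        rows.append({"covariate": name, "prevalence": p, "median_range": mr,
                     "scaled_median_range": smr, "ui": unimportance_index(p, smr)})
    df = pd.DataFrame(rows)
    df["rescaled_ui"] = rescale_ui(df["ui"].to_numpy())
    # stable, deterministic ranking: UI ascending, landscape order breaks ties
    df["rank"] = np.argsort(np.argsort(df["ui"].to_numpy(), kind="stable"), kind="stable") + 1
    df["selected"] = df["rescaled_ui"] < threshold
    return df


def select_variables(contributions: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Covariates with rescaled UI strictly below the threshold.

    Falls back (with a warning) to the single lowest-UI covariate when the
    strict cut selects nothing.
    """
    sel = contributions.loc[contributions["rescaled_ui"] < threshold, "covariate"].tolist()
    if not sel:
        warnings.warn("threshold selected no covariate; returning the lowest-UI one",
                      stacklevel=2)
        best_row = contributions.sort_values(["ui", "rank"]).iloc[0]
        sel = [best_row["covariate"]]
    return sel


def lowest_k(contributions: pd.DataFrame, k: int = 3) -> list[str]:
    """The k covariates with the lowest UI (highest contribution)."""
    return contributions.sort_values("rank").head(k)["covariate"].tolist()


def plot_median_ranges(contributions: pd.DataFrame, landscape: Landscape, ax=None):
    """Bar plot of scaled median ranges annotated with the raw landscape ranges."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    df = contributions.sort_values("rank")
    ax.bar(df["covariate"], df["scaled_median_range"], color="steelblue")
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = landscape.value_range(row["covariate"])
        ax.text(i, row["scaled_median_range"] + 0.02, f"[{lo:.2g}, {hi:.2g}]",
                ha="center", fontsize=7, rotation=90)
    ax.set_ylabel("scaled median range")
    ax.set_ylim(0, 1.25)
    ax.tick_params(axis="x", rotation=90)
    return ax
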