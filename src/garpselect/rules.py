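"""If/then rules relating environmental conditions to presence or absence.

Four rule types are supported, mirroring classic rule-set niche models:

* ``range`` — presence inside an envelope of per-variable bounds
  (``IF cov01=(10.2,13.5) AND cov02=(0.15,0.23) THEN species=PRESENCE``);
* ``negated_range`` — fires *outside* the envelope;
* ``logit`` — a logistic-regression condition, firing where the predicted
  probability exceeds 0.5 (i.e. where the linear predictor is positive);
* ``atomic`` — exact (binned) covariate values.

Rules carry their internal performance statistics (predictive accuracy,
2x2 chi-square without continuity correction, coverage) from the last
scoring pass. Rulesets serialize to JSON (canonical) and to a
human-readable ``IF ... THEN species=...`` text dump; both round-trip.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np

RULE_TYPES = ("range", "negated_range", "logit", "atomic")

#: chi-square critical value at alpha = 0.05 with 1 df
CHI2_CRITICAL = 3.841458820694124


@dataclass
class RuleStats:
    accuracy: float = float("nan")
    chi2: float = 0.0
    significant: bool = False
    coverage: float = 0.0

    def to_dict(self) -> dict:
        return {
            "accuracy": None if np.isnan(self.accuracy) else self.accuracy,
            "chi2": self.chi2,
            "significant": self.significant,
            "coverage": self.coverage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleStats":
        return cls(
            accuracy=float("nan") if d.get("accuracy") is None else d["accuracy"],
            chi2=d.get("chi2", 0.0),
            significant=d.get("significant", False),
            coverage=d.get("coverage", 0.0),
        )


@dataclass
class Rule:
    """One if/then rule.

    Exactly one payload is populated, matching ``rule_type``:
    (``lower``, ``upper``) for range/negated_range, (``coefficients``,
    ``intercept``) for logit, (``atoms``, ``tolerance``) for atomic.
    Arrays are aligned with ``variables``.
    """

    rule_type: str
    consequent: int  # 1 = presence, 0 = absence
    variables: tuple[str, ...]
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    coefficients: np.ndarray | None = None
    intercept: float | None = None
    atoms: np.ndarray | None = None
    tolerance: np.ndarray | None = None
    stats: RuleStats = field(default_factory=RuleStats)

    def __post_init__(self) -> None:
        if self.rule_type not in RULE_TYPES:
            raise ValueError(f"unknown rule type {self.rule_type!r}")
        if self.consequent not in (0, 1):
            raise ValueError("consequent must be 0 (absence) or 1 (presence)")
        if not self.variables:
            raise ValueError("a rule must reference at least one covariate")
        k = len(self.variables)
        if self.rule_type in ("range", "negated_range"):
            if self.lower is None or self.upper is None:
                raise ValueError(f"{self.rule_type} rule needs lower and upper bounds")
            self.lower = np.asarray(self.lower, dtype=float)
            self.upper = np.asarray(self.upper, dtype=float)
            if self.lower.shape != (k,) or self.upper.shape != (k,):
                raise ValueError("bounds must align with variables")
            if np.any(self.lower > self.upper):
                raise ValueError("every lower bound must be <= its upper bound")
        elif self.rule_type == "logit":
            if self.coefficients is None or self.intercept is None:
                raise ValueError("logit rule needs coefficients and intercept")
            self.coefficients = np.asarray(self.coefficients, dtype=float)
            if self.coefficients.shape != (k,):
                raise ValueError("coefficients must align with variables")
        else:  # atomic
            if self.atoms is None:
                raise ValueError("atomic rule needs atom values")
            self.atoms = np.asarray(self.atoms, dtype=float)
            if self.atoms.shape != (k,):
                raise ValueError("atoms must align with variables")
            if self.tolerance is None:
                self.tolerance = np.zeros(k)
            else:
                self.tolerance = np.asarray(self.tolerance, dtype=float)

    def fires(self, X: np.ndarray, name_to_col: dict[str, int]) -> np.ndarray:
        """Boolean firing mask over the rows of feature matrix X."""
        try:
            idx = [name_to_col[v] for v in self.variables]
        except KeyError as e:
            raise KeyError(f"rule references covariate {e.args[0]!r} absent from data")
        V = X[:, idx]
        if self.rule_type in ("range", "negated_range"):
            inside = np.all((V >= self.lower) & (V <= self.upper), axis=1)
            return inside if self.rule_type == "range" else ~inside
        if self.rule_type == "logit":
            # logistic(eta) > 0.5  <=>  eta > 0
            return V @ self.coefficients + self.intercept > 0.0
        return np.all(np.abs(V - self.atoms) <= self.tolerance, axis=1)

    def copy(self) -> "Rule":
        return replace(
            self,
            lower=None if self.lower is None else self.lower.copy(),
            upper=None if self.upper is None else self.upper.copy(),
            coefficients=None if self.coefficients is None else self.coefficients.copy(),
            atoms=None if self.atoms is None else self.atoms.copy(),
            tolerance=None if self.tolerance is None else self.tolerance.copy(),
            stats=RuleStats(),
        )

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d: dict = {
            "rule_type": self.rule_type,
            "consequent": self.consequent,
            "variables": list(self.variables),
            "stats": self.stats.to_dict(),
        }
        if self.rule_type in ("range", "negated_range"):
            d["lower"] = self.lower.tolist()
            d["upper"] = self.upper.tolist()
        elif self.rule_type == "logit":
            d["coefficients"] = self.coefficients.tolist()
            d["intercept"] = self.intercept
        else:
            d["atoms"] = self.atoms.tolist()
            d["tolerance"] = self.tolerance.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        kwargs = dict(
            rule_type=d["rule_type"],
            consequent=d["consequent"],
            variables=tuple(d["variables"]),
            stats=RuleStats.from_dict(d.get("stats", {})),
        )
        for key in ("lower", "upper", "coefficients", "atoms", "tolerance"):
            if key in d:
                kwargs[key] = np.asarray(d[key], dtype=float)
        if "intercept" in d:
            kwargs["intercept"] = d["intercept"]
        return cls(**kwargs)

    def to_text(self) -> str:
        """Human-readable IF ... THEN line."""
        species = "PRESENCE" if self.consequent == 1 else "ABSENCE"
        if self.rule_type in ("range", "negated_range"):
            parts = [
                f"{v}=({lo:.6g},{hi:.6g})"
                for v, lo, hi in zip(self.variables, self.lower, self.upper)
            ]
            cond = " AND ".join(parts)
            if self.rule_type == "negated_range":
                cond = "NOT " + cond
        elif self.rule_type == "logit":
            parts = [f"{v}*{c:.6g}" for v, c in zip(self.variables, self.coefficients)]
            cond = " + ".join(parts) + f" + {self.intercept:.6g}"
        else:
            parts = [f"{v}={a:.6g}" for v, a in zip(self.variables, self.atoms)]
            cond = " AND ".join(parts)
        return f"IF {cond} THEN species={species}"


_RANGE_RE = re.compile(r"^(\w+)=\(([-\d.eE+]+),([-\d.eE+]+)\)$")
_ATOM_RE = re.compile(r"^(\w+)=([-\d.eE+]+)$")
_TERM_RE = re.compile(r"^(\w+)\*([-\d.eE+]+)$")


def rule_from_text(line: str, atomic_tolerance: dict[str, float] | None = None) -> Rule:
    """Parse one ``IF ... THEN species=...`` line back into a Rule."""
    m = re.match(r"^IF\s+(.*)\s+THEN\s+species=(PRESENCE|ABSENCE)\s*$", line.strip())
    if not m:
        raise ValueError(f"unparseable rule line: {line!r}")
    cond, species = m.group(1), m.group(2)
    consequent = 1 if species == "PRESENCE" else 0
    negated = cond.startswith("NOT ")
    if negated:
        cond = cond[4:]
    if " AND " in cond or _RANGE_RE.match(cond) or (_ATOM_RE.match(cond) and "+" not in cond):
        parts = cond.split(" AND ")
        if all(_RANGE_RE.match(p) for p in parts):
            names, los, his = [], [], []
            for p in parts:
                g = _RANGE_RE.match(p)
                names.append(g.group(1))
                los.append(float(g.group(2)))
                his.append(float(g.group(3)))
            return Rule(
                "negated_range" if negated else "range",
                consequent,
                tuple(names),
                lower=np.array(los),
                upper=np.array(his),
            )
        if all(_ATOM_RE.match(p) for p in parts):
            names = [_ATOM_RE.match(p).group(1) for p in parts]
            vals = [float(_ATOM_RE.match(p).group(2)) for p in parts]
            tol = np.array([(atomic_tolerance or {}).get(n, 0.0) for n in names])
            return Rule("atomic", consequent, tuple(names), atoms=np.array(vals), tolerance=tol)
        raise ValueError(f"unparseable condition: {cond!r}")
    # logit: "v*c + v*c + intercept"
    terms = [t.strip() for t in cond.split("+")]
    names, coefs = [], []
    intercept = 0.0
    for t in terms:
        g = _TERM_RE.match(t)
        if g:
            names.append(g.group(1))
            coefs.append(float(g.group(2)))
        else:
            intercept = float(t)
    if not names:
        raise ValueError(f"unparseable condition: {cond!r}")
    return Rule(
        "logit", consequent, tuple(names), coefficients=np.array(coefs), intercept=intercept
    )


def score_rule(rule: Rule, X: np.ndarray, y: np.ndarray, name_to_col: dict[str, int]) -> RuleStats:
    """Score a rule on a labelled sample and store the stats on the rule.

    Builds the 2x2 contingency of (rule fires) x (label) and computes the
    Pearson chi-square statistic without continuity correction, the rule's
    predictive accuracy among the points where it fires (fraction whose
    label matches the consequent) and its coverage (firing fraction).
    Degenerate margins (rule firing nowhere/everywhere, or single-class
    labels) yield chi2 = 0 and a non-significant rule.
    """
    fired = rule.fires(X, name_to_col)
    n = len(y)
    a = int(np.sum(fired & (y == 1)))  # fired, presence
    b = int(np.sum(fired & (y == 0)))  # fired, absence
    c = int(np.sum(~fired & (y == 1)))
    d = n - a - b - c
    n_fired = a + b
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = 0.0 if denom == 0 else n * (a * d - b * c) ** 2 / denom
    if n_fired == 0:
        accuracy = float("nan")
    else:
        accuracy = (a if rule.consequent == 1 else b) / n_fired
    stats = RuleStats(
        accuracy=accuracy,
        chi2=float(chi2),
        significant=bool(chi2 >= CHI2_CRITICAL),
        coverage=n_fired / n,
    )
    rule.stats = stats
    return stats


def rules_to_json(rules: list[Rule], **meta) -> str:
    return json.dumps({"rules": [r.to_dict() for r in rules], **meta}, indent=1)


def rules_from_json(text: str) -> tuple[list[Rule], dict]:
    d = json.loads(text)
    meta = {k: v for k, v in d.items() if k != "rules"}
    return [Rule.from_dict(r) for r in d["rules"]], meta
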