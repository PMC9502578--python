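"""Rule-based applicability domain learned from training LOOCV errors.

The applicability domain (AD) marks the region of descriptor space where
the model is expected to predict reliably.  Leverage-style ADs that look at
test residuals leak information; here the AD is derived from the training
set alone:

1. the absolute LOOCV error of each training chemical becomes the target of
   a CART regression tree grown on the model's selected (normalized)
   features;
2. every leaf yields one candidate exclusion rule — the conjunction of the
   root-to-leaf threshold conditions, tagged with the leaf's mean error;
3. candidates are ranked by leaf mean error, descending, and appended
   iteratively: a rule is accepted iff removing its matching chemicals
   improves the Pearson correlation between observed CI and the (frozen)
   LOOCV predictions over the retained chemicals by at least a threshold
   (default 0.01); the first rejection stops the accumulation.

The tree is grown once and the model is never refit during accumulation.
A chemical is out of the AD iff it satisfies all conditions of at least one
accepted rule.  Thresholds are expressed in normalized-feature units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .metrics import pearson_r
from .tables import DescriptorTable

__all__ = [
    "TreeConfig",
    "RuleCondition",
    "ExclusionRule",
    "ADModel",
    "derive_ad",
    "apply_ad",
]


@dataclass(frozen=True)
class TreeConfig:
    max_depth: int = 3
    min_samples_leaf: int = 5
    seed: int = 0


@dataclass(frozen=True)
class RuleCondition:
    feature: str
    comparator: str  # "<=" or ">"
    threshold: float

    def matches(self, x: float) -> bool:
        # CART split convention: the left branch is closed (x <= t)
        return x <= self.threshold if self.comparator == "<=" else x > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.comparator} {self.threshold:.6g}"


@dataclass
class ExclusionRule:
    id: str
    conditions: list[RuleCondition]
    leaf_mean_abs_error: float
    n_train_matched: int = 0

    def matches_row(self, table: DescriptorTable, row: int) -> bool:
        pos = {f: i for i, f in enumerate(table.feature_names)}
        return all(
            c.matches(table.values[row, pos[c.feature]]) for c in self.conditions
        )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "conditions": [
                {"feature": c.feature, "comparator": c.comparator, "threshold": c.threshold}
                for c in self.conditions
            ],
            "leaf_mean_abs_error": self.leaf_mean_abs_error,
            "n_train_matched": self.n_train_matched,
        }


@dataclass
class ADModel:
    rules: list[ExclusionRule] = field(default_factory=list)
    training_coverage: float = 1.0
    improvement_log: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    normalization: dict | None = None  # embedded for raw-unit display of thresholds

    def to_dict(self) -> dict:
        return {
            "rules": [r.to_dict() for r in self.rules],
            "training_coverage": self.training_coverage,
            "improvement_log": self.improvement_log,
            "notes": self.notes,
            "normalization": self.normalization,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ADModel":
        d = json.loads(Path(path).read_text())
        rules = [
            ExclusionRule(
                id=r["id"],
                conditions=[RuleCondition(**c) for c in r["conditions"]],
                leaf_mean_abs_error=r["leaf_mean_abs_error"],
                n_train_matched=r["n_train_matched"],
            )
            for r in d["rules"]
        ]
        return cls(
            rules=rules,
            training_coverage=d["training_coverage"],
            improvement_log=d["improvement_log"],
            notes=d.get("notes", []),
            normalization=d.get("normalization"),
        )


def _leaf_rules(
    tree: DecisionTreeRegressor, feature_names: list[str]
) -> list[tuple[list[RuleCondition], float, int]]:
    """Extract (conditions, leaf mean target, leaf n) for every leaf."""
    t = tree.tree_
    out: list[tuple[list[RuleCondition], float, int]] = []

    def walk(node: int, conds: list[RuleCondition]) -> None:
        if t.children_left[node] == -1:  # leaf
            out.append((conds, float(t.value[node][0][0]), int(t.n_node_samples[node])))
            return
        f = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [RuleCondition(f, "<=", thr)])
        walk(t.children_right[node], conds + [RuleCondition(f, ">", thr)])

    walk(0, [])
    return out


def derive_ad(
    table: DescriptorTable,
    features: list[str],
    loocv_predictions: np.ndarray,
    threshold: float = 0.01,
    tree_config: TreeConfig | None = None,
) -> ADModel:
    """Learn exclusion rules from training LOOCV errors; see module docstring.

    ``loocv_predictions`` must be aligned with ``table`` rows and the table
    must carry observed CI.  Only training data enters here.
    """
    tree_config = tree_config or TreeConfig()
    if table.ci is None:
        raise ValueError("AD derivation requires observed CI on the training table")
    preds = np.asarray(loocv_predictions, dtype=float)
    if preds.shape != (table.n_chemicals,):
        raise ValueError("loocv_predictions must align with the table rows")
    abs_err = np.abs(table.ci - preds)

    sub = table.select_features(features)
    ad = ADModel()
    if np.ptp(abs_err) == 0:
        ad.notes.append("homogeneous LOOCV errors: degenerate single-leaf tree, no rules")
        return ad

    cart = DecisionTreeRegressor(
        criterion="squared_error",
        max_depth=tree_config.max_depth,
        min_samples_leaf=tree_config.min_samples_leaf,
        random_state=tree_config.seed,
    ).fit(sub.values, abs_err)
    leaves = _leaf_rules(cart, list(features))
    if len(leaves) <= 1:
        ad.notes.append("degenerate single-leaf tree: no exclusion rules derived")
        return ad

    # rank candidate rules by leaf mean error, worst first
    leaves.sort(key=lambda item: -item[1])

    n = table.n_chemicals
    retained = np.ones(n, dtype=bool)
    current_r = pearson_r(table.ci, preds)
    for k, (conds, leaf_err, _leaf_n) in enumerate(leaves, start=1):
        rule = ExclusionRule(id=f"rule_{k}", conditions=conds, leaf_mean_abs_error=leaf_err)
        matched = np.array(
            [rule.matches_row(sub, i) for i in range(n)], dtype=bool
        )
        rule.n_train_matched = int(matched.sum())
        tentative = retained & ~matched
        if tentative.sum() < 3:
            raise ValueError(
                "candidate exclusion rules would remove nearly all training chemicals"
            )
        try:
            new_r = pearson_r(table.ci[tentative], preds[tentative])
        except ValueError:
            break  # retained set degenerate -> treat as no improvement
        delta = new_r - current_r
        entry = {
            "rule": rule.id,
            "leaf_mean_abs_error": leaf_err,
            "n_matched": rule.n_train_matched,
            "r_before": float(current_r),
            "r_after": float(new_r),
            "delta_r": float(delta),
        }
        if delta >= threshold:
            entry["accepted"] = True
            ad.improvement_log.append(entry)
            ad.rules.append(rule)
            retained = tentative
            current_r = new_r
        else:
            entry["accepted"] = False
            ad.improvement_log.append(entry)
            break  # stop at the first rejection
    ad.training_coverage = float(retained.sum() / n)
    return ad


def apply_ad(
    ad: ADModel, table: DescriptorTable
) -> tuple[np.ndarray, list[list[str]], float]:
    """Flag chemicals of ``table`` against the AD.

    Returns ``(in_ad, matched_rule_ids, coverage)``: a chemical is out of
    the domain iff it satisfies every condition of at least one accepted
    rule.  The table's observed CI (if any) is never consulted.
    """
    needed = {c.feature for r in ad.rules for c in r.conditions}
    missing = sorted(needed - set(table.feature_names))
    if missing:
        raise ValueError(f"table lacks features referenced by AD rules: {missing}")
    n = table.n_chemicals
    matched: list[list[str]] = [[] for _ in range(n)]
    for rule in ad.rules:
        for i in range(n):
            if rule.matches_row(table, i):
                matched[i].append(rule.id)
    in_ad = np.array([len(m) == 0 for m in matched], dtype=bool)
    coverage = float(in_ad.mean())
    return in_ad, matched, coverage
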