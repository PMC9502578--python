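"""Sequential forward feature selection driven by LOOCV correlation.

Starting from the empty set, each step evaluates every remaining candidate
appended to the current set by leave-one-out cross-validation and keeps the
one maximizing the Pearson correlation between out-of-fold predictions and
observed CI.  Selection stops when the best candidate improves the LOOCV
correlation by less than a threshold (default 0.01, read as an absolute
increment in r; a relative mode — 1% of the current r — is available and
differs negligibly for r near 0.85).  The first feature is accepted
unconditionally.

Ties are broken by input column order (lower index wins) and the same model
seed is reused for every candidate so scores are comparable; the procedure
is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .metrics import pearson_r
from .models import ModelSpec, loocv
from .tables import DescriptorTable

__all__ = ["SelectionStep", "SelectionTrace", "sequential_forward_select"]


@dataclass
class SelectionStep:
    feature: str
    loocv_r: float
    improvement: float
    accepted: bool


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    threshold: float = 0.01
    mode: str = "absolute"
    failed_candidates: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [s.feature for s in self.steps if s.accepted]

    @property
    def accepted_count(self) -> int:
        return len(self.selected)

    @property
    def final_r(self) -> float:
        acc = [s for s in self.steps if s.accepted]
        return acc[-1].loocv_r if acc else float("nan")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "mode": self.mode,
            "accepted_count": self.accepted_count,
            "steps": [
                {
                    "feature": s.feature,
                    "loocv_r": s.loocv_r,
                    "improvement": s.improvement,
                    "accepted": s.accepted,
                }
                for s in self.steps
            ],
            "failed_candidates": self.failed_candidates,
        }


def sequential_forward_select(
    table: DescriptorTable,
    spec: ModelSpec,
    threshold: float = 0.01,
    max_features: int | None = None,
    mode: Literal["absolute", "relative"] = "absolute",
) -> SelectionTrace:
    """Greedy forward selection on a normalized training table with CI.

    Returns the full trace including the final step that triggered stopping
    (recorded as rejected).  Candidates whose LOOCV fails (e.g. singular
    design) are scored −inf and logged, never fatal.
    """
    if table.ci is None:
        raise ValueError("selection requires the CI target column")
    if table.n_features < 2:
        raise ValueError("selection requires at least 2 candidate features")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = table.n_chemicals
    if max_features is None:
        max_features = min(n - 2, 30)

    trace = SelectionTrace(threshold=threshold, mode=mode)
    selected: list[str] = []
    remaining = list(table.feature_names)  # file order = tie-break order
    current_r = -np.inf

    while remaining and len(selected) < max_features:
        best_feature = None
        best_r = -np.inf
        for f in remaining:  # iteration order implements the tie-break
            try:
                preds = loocv(table, selected + [f], spec)
                r = pearson_r(table.ci, preds)
            except Exception:  # noqa: BLE001 - candidate failure is not fatal
                trace.failed_candidates.append(f)
                r = -np.inf
            if r > best_r:
                best_r = r
                best_feature = f
        if best_feature is None:
            break
        if not selected:
            improvement = np.inf  # first feature accepted unconditionally
        elif mode == "absolute":
            improvement = best_r - current_r
        else:
            improvement = (best_r - current_r) / abs(current_r)
        accepted = not selected or improvement >= threshold
        trace.steps.append(
            SelectionStep(
                feature=best_feature,
                loocv_r=float(best_r),
                improvement=float(improvement if np.isfinite(improvement) else best_r),
                accepted=accepted,
            )
        )
        if not accepted:
            break
        selected.append(best_feature)
        remaining.remove(best_feature)
        current_r = best_r
    return trace
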