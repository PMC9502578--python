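"""Feature pruning and z-score normalization.

Descriptor tables computed on small chemical sets carry many uninformative
columns.  Three filters, applied sequentially, remove features with

1. *extreme values* — the largest absolute value exceeds ``extreme_fold``
   (default 100) times the average absolute value of the remaining entries;
2. *scarcity* — at least ``zero_fraction`` (default 30%) of entries are
   exactly zero;
3. *low variation* — fewer than ``min_unique`` (default 12) distinct values.

Each removed feature is reported under the first criterion that fired.

The extreme-value average excludes the candidate maximum by default: with
n ≲ 100 rows a maximum can essentially never exceed 100× a mean that
includes it (the maximum alone contributes max/n to the mean), so the
naive reading removes nothing; ``extreme_mean="all"`` restores it.

Normalization is the usual z-score z = (x − μ)/σ with μ and σ estimated on
the training table only and reused verbatim for test/external tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .tables import DescriptorTable

__all__ = [
    "FilterConfig",
    "FilterReport",
    "NormalizationParams",
    "remove_useless_features",
    "fit_normalizer",
    "apply_normalizer",
]


@dataclass(frozen=True)
class FilterConfig:
    extreme_fold: float = 100.0
    zero_fraction: float = 0.30
    min_unique: int = 12
    extreme_mean: Literal["loo", "all"] = "loo"

    def __post_init__(self) -> None:
        if self.extreme_fold <= 1:
            raise ValueError("extreme_fold must exceed 1")
        if not 0 <= self.zero_fraction <= 1:
            raise ValueError("zero_fraction must lie in [0, 1]")
        if self.min_unique < 2:
            raise ValueError("min_unique must be at least 2")


@dataclass
class FilterReport:
    removed_extreme: list[str] = field(default_factory=list)
    removed_scarce: list[str] = field(default_factory=list)
    removed_low_variation: list[str] = field(default_factory=list)
    n_surviving: int = 0

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_extreme)
            + len(self.removed_scarce)
            + len(self.removed_low_variation)
        )

    def to_dict(self) -> dict:
        return {
            "removed_extreme": self.removed_extreme,
            "removed_scarce": self.removed_scarce,
            "removed_low_variation": self.removed_low_variation,
            "n_surviving": self.n_surviving,
        }


def _is_extreme(x: np.ndarray, fold: float, mode: str) -> bool:
    a = np.abs(x)
    imax = int(np.argmax(a))
    peak = a[imax]
    if mode == "all":
        mean = a.mean()
    else:  # leave-one-out: exclude the candidate maximum itself
        rest = np.delete(a, imax)
        mean = rest.mean()
    if mean == 0.0:
        return peak > 0.0  # a lone spike among zeros is infinitely extreme
    return peak > fold * mean


def remove_useless_features(
    table: DescriptorTable, config: FilterConfig | None = None
) -> tuple[DescriptorTable, FilterReport]:
    """Apply the three pruning filters sequentially; see module docstring.

    Raises if every feature is removed.
    """
    config = config or FilterConfig()
    if table.n_chemicals < 2:
        raise ValueError("filtering requires at least 2 chemicals")
    report = FilterReport()
    keep: list[int] = []
    for j, name in enumerate(table.feature_names):
        x = table.values[:, j]
        if _is_extreme(x, config.extreme_fold, config.extreme_mean):
            report.removed_extreme.append(name)
        elif np.mean(x == 0.0) >= config.zero_fraction:
            report.removed_scarce.append(name)
        elif np.unique(x).size < config.min_unique:
            report.removed_low_variation.append(name)
        else:
            keep.append(j)
    if not keep:
        raise ValueError("no features survive filtering")
    report.n_surviving = len(keep)
    filtered = replace(
        table,
        feature_names=[table.feature_names[j] for j in keep],
        values=table.values[:, keep],
    )
    return filtered, report


@dataclass
class NormalizationParams:
    """Per-feature center/scale learned on the training table (z = (x − μ)/σ)."""

    feature_names: list[str]
    center: np.ndarray  # μ
    scale: np.ndarray  # σ (population SD by default)
    mode: Literal["sd", "variance"] = "sd"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if not (len(self.feature_names) == self.center.size == self.scale.size):
            raise ValueError("feature_names, center and scale must align")
        if np.any(self.scale <= 0):
            bad = [self.feature_names[i] for i in np.flatnonzero(self.scale <= 0)]
            raise ValueError(f"non-positive scale for features {bad}")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "features": {
                f: {"center": float(m), "scale": float(s)}
                for f, m, s in zip(self.feature_names, self.center, self.scale)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        feats = list(d["features"])
        return cls(
            feature_names=feats,
            center=np.array([d["features"][f]["center"] for f in feats]),
            scale=np.array([d["features"][f]["scale"] for f in feats]),
            mode=d.get("mode", "sd"),
        )


def fit_normalizer(
    table: DescriptorTable, mode: Literal["sd", "variance"] = "sd"
) -> NormalizationParams:
    """Estimate μ and σ per feature on the given (training) table.

    σ is the population standard deviation (ddof = 0); ``mode="variance"``
    scales by the population variance instead, for parity experiments with
    tables normalized that way.
    """
    mu = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [table.feature_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance features cannot be normalized: {bad}")
    scale = sd if mode == "sd" else sd**2
    return NormalizationParams(
        feature_names=list(table.feature_names), center=mu, scale=scale, mode=mode
    )


def apply_normalizer(
    table: DescriptorTable, params: NormalizationParams
) -> DescriptorTable:
    """Return a copy of ``table`` with features z-scored by ``params``.

    Every feature of the table must be covered by the params (learned on
    training data); CI columns are left untouched.
    """
    pos = {f: i for i, f in enumerate(params.feature_names)}
    missing = [f for f in table.feature_names if f not in pos]
    if missing:
        raise ValueError(f"no normalization parameters for features: {missing}")
    idx = np.array([pos[f] for f in table.feature_names], dtype=int)
    z = (table.values - params.center[idx]) / params.scale[idx]
    return replace(table, values=z, normalized=True)
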