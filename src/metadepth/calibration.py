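"""Detection-threshold calibration against a known mock community.

Benchmarking a classifier on a staggered mock community reduces to a
confusion table per candidate abundance threshold: a declared species
observed at or above the threshold is a true positive, a declared
species below it (or absent) a false negative, and any other species at
or above it a false positive.  True negatives are unknowable in an open
species universe, so performance is summarised by the F1 score

    F1 = 2*TP / (2*TP + FP + FN),

the harmonic mean of precision and recall.  Sweeping thresholds and
picking the F1 maximum yields the operating detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .taxprofile import AbundanceVector

__all__ = [
    "CommunitySpec",
    "ConfusionCounts",
    "ThresholdSweep",
    "confusion_counts",
    "f1_score",
    "threshold_sweep",
    "best_threshold",
]


@dataclass(frozen=True)
class CommunitySpec:
    """A declared community: species names and their nominal percent abundances."""

    declared: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.declared:
            raise ValueError("community spec must declare at least one species")
        for name, value in self.declared.items():
            if value <= 0:
                raise ValueError(f"declared abundance for {name!r} must be > 0")
        total = sum(self.declared.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"declared abundances sum to {total}, expected 100")
        object.__setattr__(self, "declared", dict(self.declared))

    @property
    def species(self) -> list[str]:
        return list(self.declared)

    def fractions(self) -> dict[str, float]:
        """Declared abundances as probabilities summing to 1."""
        return {name: value / 100.0 for name, value in self.declared.items()}

    def __len__(self) -> int:
        return len(self.declared)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_counts(
    observed: AbundanceVector, reference: CommunitySpec, threshold: float
) -> ConfusionCounts:
    """Confusion table of an observed profile against a declared community.

    A declared species counts as detected when its observed abundance is
    ``>= threshold`` percent (inclusive); declared species below threshold
    or absent are false negatives even if their *declared* abundance is
    itself below the threshold.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be a percentage in [0, 100]")
    declared = set(reference.species)
    tp = sum(1 for s in declared if observed.get(s) >= threshold)
    fn = len(declared) - tp
    fp = sum(
        1
        for s, frac in observed.fractions.items()
        if s not in declared and frac >= threshold
    )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2·TP / (2·TP + FP + FN); undefined when all counts are zero."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("F1 undefined: tp, fp and fn are all zero")
    return 2 * c.tp / denom


@dataclass(frozen=True)
class ThresholdSweep:
    """Confusion counts and F1 per candidate threshold, ascending."""

    rows: tuple[tuple[float, ConfusionCounts, float], ...]

    def thresholds(self) -> list[float]:
        return [t for t, _, _ in self.rows]

    def f1_scores(self) -> list[float]:
        return [f for _, _, f in self.rows]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns threshold, tp, fp, fn, f1."""
        return pd.DataFrame(
            [
                {"threshold": t, "tp": c.tp, "fp": c.fp, "fn": c.fn, "f1": f}
                for t, c, f in self.rows
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def threshold_sweep(
    observed: AbundanceVector,
    reference: CommunitySpec,
    thresholds: Sequence[float],
) -> ThresholdSweep:
    """Evaluate confusion counts and F1 over a set of detection thresholds."""
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    if len(set(thresholds)) != len(thresholds):
        raise ValueError("duplicate thresholds")
    rows = []
    for t in sorted(thresholds):
        c = confusion_counts(observed, reference, t)
        rows.append((float(t), c, f1_score(c)))
    return ThresholdSweep(rows=tuple(rows))


def sweep_from_counts(
    rows: Sequence[tuple[float, int, int, int]]
) -> ThresholdSweep:
    """Build a sweep from pre-tabulated (threshold, tp, fp, fn) rows.

    F1 is recomputed from the counts.  Useful when the underlying
    abundance table censors values below a reporting floor, so the
    confusion counts are known but not recomputable from abundances.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    thresholds = [r[0] for r in rows]
    if len(set(thresholds)) != len(thresholds):
        raise ValueError("duplicate thresholds")
    out = []
    for t, tp, fp, fn in sorted(rows):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn)
        out.append((float(t), c, f1_score(c)))
    return ThresholdSweep(rows=tuple(out))


def best_threshold(sweep: ThresholdSweep) -> float:
    """Threshold with maximal F1; ties resolve to the smallest threshold."""
    if not sweep.rows:
        raise ValueError("empty sweep")
    # rows are sorted ascending, so max() keeps the first (smallest) maximiser
    best_t, _, _ = max(sweep.rows, key=lambda row: (row[2], -row[0]))
    return best_t
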