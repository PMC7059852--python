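"""Depth reduction by read subsampling, replicated with confidence bands.

A lower sequencing depth is emulated by drawing a fixed number of reads
*without replacement* from a sample's classified-plus-unclassified read
pool — a multivariate hypergeometric draw over the species count vector,
matching what read-level subsampling of the raw FASTQ does to the
downstream count table.  Each depth is replicated (default 5×) and a
two-sided Student-t confidence interval (default 99%) summarises the
replicate spread of any per-profile metric.

The default depth grid is 10k, 25k, 50k, 100k, 250k, 500k and 1M reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxprofile import TaxonProfile

__all__ = ["DEFAULT_DEPTHS", "DepthSeries", "subsample_profile", "depth_series"]

logger = logging.getLogger(__name__)

DEFAULT_DEPTHS: tuple[int, ...] = (
    10_000,
    25_000,
    50_000,
    100_000,
    250_000,
    500_000,
    1_000_000,
)


def subsample_profile(
    profile: TaxonProfile,
    depth: int,
    seed: int | np.random.SeedSequence,
    replace: bool = False,
) -> TaxonProfile:
    """Draw ``depth`` reads from a profile, without replacement by default.

    The draw is multivariate hypergeometric over the category vector
    (species counts plus the unclassified pool); the result's total read
    count equals ``depth`` exactly.  ``replace=True`` switches to a
    multinomial draw on the observed proportions (an infinite-pool
    approximation useful for sampling from declared compositions).
    """
    total = profile.total_reads
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if not replace and depth > total:
        raise ValueError(
            f"cannot subsample {depth} reads from {total} without replacement "
            f"(sample {profile.sample_id!r})"
        )
    rng = np.random.default_rng(seed)
    names = profile.species
    colors = np.array([profile.counts[n] for n in names] + [profile.unclassified])
    if replace:
        drawn = rng.multinomial(depth, colors / colors.sum())
    else:
        drawn = rng.multivariate_hypergeometric(colors, depth)
    counts = {n: int(k) for n, k in zip(names, drawn[:-1]) if k > 0}
    return TaxonProfile(
        sample_id=profile.sample_id, counts=counts, unclassified=int(drawn[-1])
    )


@dataclass(frozen=True)
class DepthSeries:
    """A metric evaluated on replicated subsamples across a depth grid."""

    metric: str
    depths: tuple[int, ...]
    values: tuple[tuple[float, ...], ...]  # one replicate tuple per depth
    ci_level: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.depths):
            raise ValueError("one replicate tuple required per depth")
        reps = {len(v) for v in self.values}
        if len(reps) > 1:
            raise ValueError("replicate count must be constant across depths")

    @property
    def n_replicates(self) -> int:
        return len(self.values[0]) if self.values else 0

    def means(self) -> np.ndarray:
        return np.array([np.mean(v) for v in self.values])

    def confidence_limits(self) -> tuple[np.ndarray, np.ndarray]:
        """Two-sided Student-t interval on the replicate mean, per depth."""
        lows, highs = [], []
        for reps in self.values:
            arr = np.asarray(reps, dtype=float)
            m = arr.mean()
            if len(arr) < 2:
                lows.append(m)
                highs.append(m)
                continue
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            half = stats.t.ppf(0.5 + self.ci_level / 2, df=len(arr) - 1) * se
            lows.append(m - half)
            highs.append(m + half)
        return np.array(lows), np.array(highs)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample_id,
                "metric": self.metric,
                "depth": d,
                "replicate": r,
                "value": v,
            }
            for d, reps in zip(self.depths, self.values)
            for r, v in enumerate(reps)
        ]
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        low, high = self.confidence_limits()
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "metric": self.metric,
                "depth": list(self.depths),
                "mean": self.means(),
                "ci_low": low,
                "ci_high": high,
            }
        )

    def to_tsv(self, path: str | Path, kind: Literal["long", "summary"] = "summary") -> None:
        frame = self.to_long_frame() if kind == "long" else self.summary_frame()
        frame.to_csv(path, sep="\t", index=False)


def replicate_seed(
    master_seed: int, depth_index: int, replicate_index: int
) -> np.random.SeedSequence:
    """Deterministic per-(depth, replicate) seed derived from one master seed."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(depth_index, replicate_index)
    )


def depth_series(
    profile: TaxonProfile,
    metric: Callable[[TaxonProfile], float],
    depths: Sequence[int] = DEFAULT_DEPTHS,
    n_reps: int = 5,
    ci_level: float = 0.99,
    seed: int = 0,
    metric_name: str | None = None,
    replace: bool = False,
) -> DepthSeries:
    """Evaluate a per-profile metric on replicated subsamples per depth.

    Depths exceeding the profile's total read count are skipped with a
    warning (depth is never inflated).  Replicate seeds derive
    deterministically from ``seed`` and the (depth, replicate) indices,
    so the full grid reproduces from the single master seed.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for confidence limits")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    kept_depths = []
    all_values = []
    for di, depth in enumerate(depths):
        if not replace and depth > profile.total_reads:
            logger.warning(
                "skipping depth %d > total reads %d for sample %s",
                depth,
                profile.total_reads,
                profile.sample_id,
            )
            continue
        reps = []
        for ri in range(n_reps):
            sub = subsample_profile(
                profile, depth, seed=replicate_seed(seed, di, ri), replace=replace
            )
            try:
                reps.append(float(metric(sub)))
            except Exception as exc:  # noqa: BLE001 - annotate replicate context
                raise RuntimeError(
                    f"metric failed at depth {depth}, replicate {ri} "
                    f"(sample {profile.sample_id!r}): {exc}"
                ) from exc
        kept_depths.append(int(depth))
        all_values.append(tuple(reps))
    name = metric_name if metric_name is not None else getattr(metric, "__name__", "metric")
    return DepthSeries(
        metric=name,
        depths=tuple(kept_depths),
        values=tuple(all_values),
        ci_level=ci_level,
        sample_id=profile.sample_id,
    )
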