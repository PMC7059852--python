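"""Beta-diversity stability under depth reduction.

Pairwise Bray-Curtis dissimilarities over detected-species relative
abundances are ordinated (PCoA, or nonmetric MDS with seeded
multi-start), and the ordination of each reduced dataset is compared to
the full-depth ordination by Procrustes superimposition.  The symmetric
Procrustes correlation t = √(1 − m²) — where m² is the residual sum of
squares after optimal translation, rotation/reflection and scaling of
both unit-normalised configurations — measures how well the reduced
ordination preserves the full one, and PROTEST assesses it against a
row-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.manifold import MDS

from .diversity import detected_abundances
from .taxprofile import TaxonProfile

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "ProcrustesResult",
    "bray_curtis",
    "ordinate",
    "procrustes_fit",
    "protest",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with sample ids."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if not np.allclose(values, values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _abundance_matrix(
    profiles: Sequence[TaxonProfile],
    min_reads: int,
    min_frac: float,
) -> tuple[list[str], np.ndarray]:
    vectors = []
    for p in profiles:
        if p.classified_reads == 0:
            raise ValueError(f"sample {p.sample_id!r} has no classified reads")
        vectors.append(detected_abundances(p, min_reads=min_reads, min_frac=min_frac))
    union = sorted(set().union(*(v.fractions for v in vectors)))
    matrix = np.array([[v.get(s) for s in union] for v in vectors])
    return union, matrix


def bray_curtis(
    profiles: Sequence[TaxonProfile],
    min_reads: int = 10,
    min_frac: float = 0.1,
    transform: Literal["none", "hellinger"] = "none",
) -> DissimilarityMatrix:
    """Pairwise dissimilarity over detected-species relative abundances.

    Default is Bray-Curtis, BC(a, b) = 1 − 2·Σ min(aᵢ, bᵢ) / Σ (aᵢ + bᵢ),
    over the species union (absent species at zero).  With
    ``transform="hellinger"`` the abundances are square-root transformed
    proportions compared by Euclidean distance instead.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a dissimilarity matrix")
    ids = [p.sample_id for p in profiles]
    _, matrix = _abundance_matrix(profiles, min_reads, min_frac)
    if transform == "hellinger":
        hell = np.sqrt(matrix / matrix.sum(axis=1, keepdims=True))
        condensed = pdist(hell, metric="euclidean")
    elif transform == "none":
        condensed = pdist(matrix, metric="braycurtis")
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return DissimilarityMatrix(sample_ids=tuple(ids), values=squareform(condensed))


@dataclass(frozen=True)
class OrdinationResult:
    """Low-dimensional sample coordinates from a dissimilarity matrix."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples × dimensions
    method: Literal["pcoa", "nmds"]
    stress: float | None = None  # Kruskal stress-1, nmds only

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape[0] != len(self.sample_ids):
            raise ValueError("one coordinate row required per sample")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"axis{i + 1}" for i in range(self.coordinates.shape[1])],
        )


def ordinate(
    d: DissimilarityMatrix,
    method: Literal["pcoa", "nmds"] = "pcoa",
    dims: int = 2,
    seed: int = 0,
    n_starts: int = 20,
) -> OrdinationResult:
    """Embed a dissimilarity matrix in ``dims`` dimensions.

    PCoA (deterministic) eigendecomposes the double-centred squared
    dissimilarities.  NMDS minimises Kruskal stress-1 by monotone
    regression from ``n_starts`` seeded random starts, keeping the best.
    """
    n = len(d.sample_ids)
    if dims >= n:
        raise ValueError(f"dims ({dims}) must be below the sample count ({n})")
    if method == "pcoa":
        res = _skbio_pcoa(DistanceMatrix(d.values, ids=d.sample_ids), number_of_dimensions=dims)
        coords = res.samples.to_numpy()[:, :dims]
        return OrdinationResult(sample_ids=d.sample_ids, coordinates=coords, method="pcoa")
    if method == "nmds":
        seeds = np.random.SeedSequence(seed).generate_state(n_starts)
        best_coords, best_stress = None, np.inf
        for s in seeds:
            mds = MDS(
                n_components=dims,
                metric_mds=False,
                metric="precomputed",
                init="random",
                n_init=1,
                random_state=int(s % (2**31)),
                normalized_stress=True,
                max_iter=300,
            )
            coords = mds.fit_transform(d.values)
            if mds.stress_ < best_stress:
                best_stress, best_coords = float(mds.stress_), coords
        return OrdinationResult(
            sample_ids=d.sample_ids,
            coordinates=best_coords,
            method="nmds",
            stress=best_stress,
        )
    raise ValueError(f"unknown ordination method {method!r}")


@dataclass(frozen=True)
class ProcrustesResult:
    """Procrustes superimposition summary.

    ``correlation`` is the symmetric Procrustes statistic √(1 − m²);
    ``rss`` the residual sum of squares after superimposition;
    ``rotation`` the orthogonal matrix (reflections permitted) applied
    to the second configuration; ``scale`` its optimal scaling;
    ``p_value`` the PROTEST permutation p when computed.
    """

    correlation: float
    rss: float
    rotation: np.ndarray
    scale: float
    p_value: float | None = None


def _aligned_configs(x: OrdinationResult, y: OrdinationResult) -> tuple[np.ndarray, np.ndarray]:
    if set(x.sample_ids) != set(y.sample_ids):
        raise ValueError("sample-id mismatch between configurations")
    if x.coordinates.shape[1] != y.coordinates.shape[1]:
        raise ValueError("dimension mismatch between configurations")
    order = {sid: i for i, sid in enumerate(y.sample_ids)}
    idx = [order[sid] for sid in x.sample_ids]
    return x.coordinates, y.coordinates[idx]


def _center_norm(m: np.ndarray) -> tuple[np.ndarray, float]:
    c = m - m.mean(axis=0)
    norm = np.sqrt((c**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return c, norm


def procrustes_fit(
    x: OrdinationResult, y: OrdinationResult, symmetric: bool = True
) -> ProcrustesResult:
    """Superimpose configuration ``y`` onto ``x``.

    Both are centred; in symmetric mode both are scaled to unit sum of
    squares, the optimal rotation comes from the SVD of the
    cross-product, and the correlation statistic is the trace of the
    singular values (equivalently √(1 − m²)).
    """
    xm, ym = _aligned_configs(x, y)
    xc, xnorm = _center_norm(xm)
    yc, ynorm = _center_norm(ym)
    if symmetric:
        xc, yc = xc / xnorm, yc / ynorm
    u, s, vt = np.linalg.svd(yc.T @ xc)
    rotation = u @ vt
    trace = s.sum()
    if symmetric:
        scale = trace  # optimal scaling of unit-normalised y
        rss = 1.0 - trace**2
        correlation = float(min(trace, 1.0))
    else:
        yss = (yc**2).sum()
        xss = (xc**2).sum()
        scale = trace / yss
        rss = xss - trace**2 / yss
        correlation = float(np.sqrt(max(0.0, 1.0 - rss / xss)))
    return ProcrustesResult(
        correlation=correlation,
        rss=float(max(rss, 0.0)),
        rotation=rotation,
        scale=float(scale),
    )


def protest(
    x: OrdinationResult,
    y: OrdinationResult,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Permutation test of Procrustes concordance (symmetric statistic).

    Rows of ``y`` are permuted ``n_perm`` times;
    p = (1 + #{permuted correlation ≥ observed}) / (n_perm + 1), so the
    smallest attainable p at the default 999 permutations is 0.001.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = procrustes_fit(x, y, symmetric=True)
    xm, ym = _aligned_configs(x, y)
    xc, xnorm = _center_norm(xm)
    yc, ynorm = _center_norm(ym)
    xc, yc = xc / xnorm, yc / ynorm
    rng = np.random.default_rng(seed)
    n = xc.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = np.linalg.svd(yc[perm].T @ xc, compute_uv=False)
        if s.sum() >= observed.correlation - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ProcrustesResult(
        correlation=observed.correlation,
        rss=observed.rss,
        rotation=observed.rotation,
        scale=observed.scale,
        p_value=p,
    )
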