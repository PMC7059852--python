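"""Alpha diversity and abundance agreement between depth levels.

Observed richness S is the number of species passing the detection rule;
Shannon's index H = −Σ pᵢ ln pᵢ (natural log, over the detected species'
renormalised frequencies) combines richness and evenness, and Pielou's
J = H / ln S rescales it by its maximum so that equifrequent communities
score 1.  Agreement between a full and a depth-reduced profile is a
rank (Spearman) or linear (Pearson) correlation over the species union,
with species lost by subsampling entered at zero.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy import stats

from .taxprofile import AbundanceVector, TaxonProfile, detect_species, relative_abundances

__all__ = [
    "observed_taxa",
    "shannon",
    "pielou",
    "detected_abundances",
    "abundance_correlation",
    "profile_alpha_diversity",
]


def observed_taxa(
    profile: TaxonProfile, min_reads: int = 10, min_frac: float = 0.1
) -> int:
    """Number of species passing the detection rule."""
    return len(detect_species(profile, min_reads=min_reads, min_frac=min_frac))


def _positive_fractions(p: AbundanceVector) -> np.ndarray:
    values = np.array([v for v in p.fractions.values() if v > 0], dtype=float)
    if values.size == 0:
        raise ValueError("diversity undefined: no species with positive abundance")
    return values / values.sum()


def shannon(p: AbundanceVector) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ in nats.

    Fractions are renormalised to sum to one over the included species;
    zero-abundance entries are excluded (lim p→0 of p ln p is 0).
    """
    q = _positive_fractions(p)
    return float(-(q * np.log(q)).sum())


def pielou(p: AbundanceVector) -> float:
    """Pielou evenness J = H / ln S over species with positive abundance.

    Undefined for a single-species community (ln S = 0).
    """
    q = _positive_fractions(p)
    if q.size < 2:
        raise ValueError("evenness undefined for a single-species community")
    h = float(-(q * np.log(q)).sum())
    return h / np.log(q.size)


def detected_abundances(
    profile: TaxonProfile, min_reads: int = 10, min_frac: float = 0.1
) -> AbundanceVector:
    """Relative abundances restricted to detected species, renormalised.

    This is the vector the alpha-diversity indices operate on: S counts
    only species passing the detection rule, and their frequencies are
    renormalised to sum to 100%.
    """
    detected = detect_species(profile, min_reads=min_reads, min_frac=min_frac)
    if not detected:
        raise ValueError(
            f"no species detected in sample {profile.sample_id!r} "
            f"at min_reads={min_reads}, min_frac={min_frac}"
        )
    total = sum(profile.counts[s] for s in detected)
    return AbundanceVector(
        fractions={s: 100.0 * profile.counts[s] / total for s in detected},
        basis="classified",
    )


def profile_alpha_diversity(
    profile: TaxonProfile, min_reads: int = 10, min_frac: float = 0.1
) -> dict[str, float]:
    """Observed taxa, Shannon and Pielou of one profile under the detection rule.

    Pielou is reported as NaN when fewer than two species are detected.
    """
    s = observed_taxa(profile, min_reads, min_frac)
    if s == 0:
        return {"observed_taxa": 0, "shannon": float("nan"), "pielou": float("nan")}
    p = detected_abundances(profile, min_reads, min_frac)
    h = shannon(p)
    j = pielou(p) if s >= 2 else float("nan")
    return {"observed_taxa": s, "shannon": h, "pielou": j}


def abundance_correlation(
    a: AbundanceVector,
    b: AbundanceVector,
    method: Literal["spearman", "pearson"] = "spearman",
    union_rule: Literal["union_zeros", "intersection"] = "union_zeros",
) -> float:
    """Correlation between two abundance vectors over a common species set.

    ``union_zeros`` (default) scores every species seen in either vector,
    filling absences with zero — appropriate for full-vs-reduced
    comparisons where subsampling legitimately drops rare species.
    ``intersection`` keeps only shared species.
    """
    if union_rule == "union_zeros":
        keys = sorted(set(a.fractions) | set(b.fractions))
    elif union_rule == "intersection":
        keys = sorted(set(a.fractions) & set(b.fractions))
    else:
        raise ValueError(f"unknown union rule {union_rule!r}")
    if len(keys) < 3:
        raise ValueError(
            f"insufficient species overlap ({len(keys)}) for a correlation"
        )
    x = np.array([a.get(k) for k in keys])
    y = np.array([b.get(k) for k in keys])
    if method == "spearman":
        r = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r)


def full_vs_reduced_correlation(
    full: TaxonProfile,
    reduced: TaxonProfile,
    method: Literal["spearman", "pearson"] = "spearman",
) -> float:
    """Correlation of species abundances between a full and a reduced profile."""
    return abundance_correlation(
        relative_abundances(full),
        relative_abundances(reduced),
        method=method,
        union_rule="union_zeros",
    )
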