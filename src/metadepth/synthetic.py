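"""Synthetic classifier output: labelled reads from a known community.

Real input to the pipeline is the species-labelled read table a k-mer
classifier (plus Bayesian abundance re-estimation) produces from shotgun
reads.  This module emulates that output directly: reads are abstract
labelled draws, with no nucleotide sequence, read length or sequencing
error — taxonomic misclassification and unclassifiable reads are the
only error channels modelled.

Two generators are provided:

* :func:`simulate_profile` draws ``depth`` reads multinomially from a
  declared community and pushes each species' reads through a
  misclassification kernel (label emission probabilities plus an
  unclassified sink).  The packaged default kernel is the identity plus
  a single sister-species leakage channel, reproducing the one
  systematic false positive the mock-community benchmark exhibits
  (an *Escherichia coli* → *Shigella flexneri* confusion).
* :func:`simulate_study` builds a heterogeneous multi-sample panel whose
  per-sample richness spans the observed range in real surveys (a
  handful of species up to ~140), with long-tailed abundances drawn
  from a log-normal or log-series distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .calibration import CommunitySpec
from .taxprofile import TaxonProfile, detect_species

__all__ = [
    "MisclassificationModel",
    "SampleDesign",
    "StudyDesign",
    "mock_spec",
    "simulate_profile",
    "simulate_study",
]

#: Declared composition of the 20-strain staggered mock community
#: (ATCC MSA-1003): five species at each of 18%, 1.8%, 0.18% and 0.02%.
MOCK_DECLARED: dict[str, float] = {
    "Acinetobacter baumannii": 0.18,
    "Actinomyces odontolyticus": 0.02,
    "Bacillus cereus": 1.80,
    "Bacteroides vulgatus": 0.02,
    "Bifidobacterium adolescentis": 0.02,
    "Clostridium beijerinckii": 1.80,
    "Cutibacterium acnes": 0.18,
    "Deinococcus radiodurans": 0.02,
    "Enterococcus faecalis": 0.02,
    "Escherichia coli": 18.0,
    "Helicobacter pylori": 0.18,
    "Lactobacillus gasseri": 0.18,
    "Neisseria meningitidis": 0.18,
    "Porphyromonas gingivalis": 18.0,
    "Pseudomonas aeruginosa": 1.80,
    "Rhodobacter sphaeroides": 18.0,
    "Staphylococcus aureus": 1.80,
    "Staphylococcus epidermidis": 18.0,
    "Streptococcus agalactiae": 1.80,
    "Streptococcus mutans": 18.0,
}


def mock_spec() -> CommunitySpec:
    """The staggered 20-species mock community used for calibration."""
    return CommunitySpec(declared=MOCK_DECLARED)


@dataclass(frozen=True)
class MisclassificationModel:
    """Per-species label emission distribution plus an unclassified sink.

    ``kernel[true_species]`` lists ``(emitted_label, probability)``
    pairs; for every true species the emission probabilities plus
    ``unclassified_rate`` must sum to one.
    """

    kernel: Mapping[str, tuple[tuple[str, float], ...]]
    unclassified_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.unclassified_rate <= 1:
            raise ValueError("unclassified_rate must be a probability")
        normalized = {}
        for true_species, emissions in self.kernel.items():
            emissions = tuple((label, float(p)) for label, p in emissions)
            for label, p in emissions:
                if not 0 <= p <= 1:
                    raise ValueError(
                        f"emission probability for {true_species!r}→{label!r} "
                        f"out of [0,1]: {p}"
                    )
            total = self.unclassified_rate + sum(p for _, p in emissions)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"emissions for {true_species!r} sum to {total}, expected 1"
                )
            normalized[true_species] = emissions
        object.__setattr__(self, "kernel", normalized)

    @classmethod
    def identity(
        cls, species: Sequence[str], unclassified_rate: float = 0.0
    ) -> "MisclassificationModel":
        """Each read keeps its true label (minus the unclassified sink)."""
        keep = 1.0 - unclassified_rate
        return cls(
            kernel={s: ((s, keep),) for s in species},
            unclassified_rate=unclassified_rate,
        )

    @classmethod
    def with_leakage(
        cls,
        species: Sequence[str],
        leaks: Mapping[str, tuple[str, float]],
        unclassified_rate: float = 0.0,
    ) -> "MisclassificationModel":
        """Identity kernel with per-species leakage to one sister label.

        ``leaks[true] = (sister, p)`` diverts a fraction ``p`` of the
        true species' reads to ``sister``.
        """
        kernel = {}
        for s in species:
            keep = 1.0 - unclassified_rate
            if s in leaks:
                sister, p = leaks[s]
                if not 0 <= p <= keep:
                    raise ValueError(f"leakage probability for {s!r} out of range: {p}")
                kernel[s] = ((s, keep - p), (sister, p))
            else:
                kernel[s] = ((s, keep),)
        return cls(kernel=kernel, unclassified_rate=unclassified_rate)


def default_mock_model(
    leak_probability: float = 0.007, unclassified_rate: float = 0.0
) -> MisclassificationModel:
    """Identity kernel with E. coli → S. flexneri leakage (default 0.7%)."""
    return MisclassificationModel.with_leakage(
        species=list(MOCK_DECLARED),
        leaks={"Escherichia coli": ("Shigella flexneri", leak_probability)},
        unclassified_rate=unclassified_rate,
    )


def simulate_profile(
    spec: CommunitySpec,
    model: MisclassificationModel,
    depth: int,
    seed: int | np.random.SeedSequence,
    sample_id: str = "simulated",
) -> TaxonProfile:
    """Draw ``depth`` classified-read labels from a declared community.

    Reads are allocated to true species by a single multinomial draw on
    the declared fractions, then each species' reads are redistributed
    over the model's emission labels (or dropped to unclassified) by a
    second multinomial.  The output counts plus the unclassified count
    always sum to ``depth``.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    missing = [s for s in spec.species if s not in model.kernel]
    if missing:
        raise ValueError(f"misclassification kernel missing species: {missing}")
    rng = np.random.default_rng(seed)

    species = spec.species
    probs = np.array([spec.declared[s] for s in species]) / 100.0
    true_counts = rng.multinomial(depth, probs)

    counts: dict[str, int] = {}
    unclassified = 0
    for s, n in zip(species, true_counts):
        if n == 0:
            continue
        emissions = model.kernel[s]
        labels = [label for label, _ in emissions] + [None]
        ps = [p for _, p in emissions] + [model.unclassified_rate]
        emitted = rng.multinomial(n, ps)
        for label, k in zip(labels, emitted):
            if label is None:
                unclassified += int(k)
            elif k:
                counts[label] = counts.get(label, 0) + int(k)
    return TaxonProfile(sample_id=sample_id, counts=counts, unclassified=unclassified)


@dataclass(frozen=True)
class SampleDesign:
    """One synthetic sample: target richness, depth and abundance shape."""

    sample_id: str
    richness: int
    depth: int
    distribution: Literal["lognormal", "logseries"] = "lognormal"
    sigma: float = 1.0  # log-normal shape; ignored for logseries
    logseries_p: float = 0.95

    def __post_init__(self) -> None:
        if self.richness < 1:
            raise ValueError("richness must be >= 1")
        if self.depth < self.richness:
            raise ValueError("depth must be at least the richness")


@dataclass(frozen=True)
class StudyDesign:
    samples: tuple[SampleDesign, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))


# Detection rule the richness calibration targets (reads >= 10, >= 0.1%).
_DETECT_MIN_READS = 10
_DETECT_MIN_FRAC = 0.1


def _draw_weights(rng: np.random.Generator, n: int, design: SampleDesign) -> np.ndarray:
    if design.distribution == "lognormal":
        w = rng.lognormal(mean=0.0, sigma=design.sigma, size=n)
    elif design.distribution == "logseries":
        w = rng.logseries(design.logseries_p, size=n).astype(float)
    else:
        raise ValueError(f"unknown abundance distribution {design.distribution!r}")
    return w / w.sum()


def _calibrated_fractions(
    rng: np.random.Generator, design: SampleDesign
) -> np.ndarray:
    """Abundance fractions whose detectable count (>= 0.1%) tracks the target.

    Long-tailed draws push part of the community below the detection
    floor, so the community size is grown until the number of species at
    or above 0.1% lands within the target's tolerance band (or a search
    cap is hit, keeping the closest draw).
    """
    target = design.richness
    if target * (_DETECT_MIN_FRAC / 100.0) > 1.0:
        raise ValueError(
            f"richness {target} cannot all sit above {_DETECT_MIN_FRAC}% — infeasible design"
        )
    n = target
    best: tuple[int, np.ndarray] | None = None
    for _ in range(60):
        w = _draw_weights(rng, n, design)
        detected = int((w >= _DETECT_MIN_FRAC / 100.0).sum())
        gap = abs(detected - target)
        if best is None or gap < best[0]:
            best = (gap, w)
        if abs(detected - target) <= max(1, round(0.1 * target)):
            return w
        # grow (or shrink) the pool proportionally to the shortfall
        n = max(target, n + (target - detected))
    assert best is not None
    return best[1]


def simulate_study(
    design: StudyDesign,
    seed: int | np.random.SeedSequence,
    pool_size: int = 300,
) -> list[TaxonProfile]:
    """Simulate one profile per sample in a study design.

    Each sample's abundances are drawn from its configured long-tailed
    distribution, calibrated so that the count of species at or above
    the 0.1% detection floor approximates the richness target, then
    read counts are drawn multinomially at the design depth.  Species
    identities are drawn (per sample, without replacement) from a
    shared pool of ``pool_size`` names, so samples overlap partially —
    richer samples share more species, which is what makes
    between-sample dissimilarities informative.
    """
    master = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    profiles = []
    for i, sample in enumerate(design.samples):
        child = np.random.SeedSequence(entropy=master.entropy, spawn_key=(i,))
        rng = np.random.default_rng(child)
        fractions = _calibrated_fractions(rng, sample)
        pool = max(pool_size, len(fractions))
        chosen = rng.choice(pool, size=len(fractions), replace=False)
        names = [f"sp{k:05d}" for k in chosen]
        counts = rng.multinomial(sample.depth, fractions)
        profiles.append(
            TaxonProfile(
                sample_id=sample.sample_id,
                counts={n: int(c) for n, c in zip(names, counts) if c > 0},
                unclassified=0,
            )
        )
    return profiles


def detected_richness(profile: TaxonProfile) -> int:
    """Convenience: species count under the default detection rule."""
    return len(detect_species(profile, _DETECT_MIN_READS, _DETECT_MIN_FRAC))
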