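"""Gene-recovery summaries of metagenome reconstruction.

Assembly completeness per species is summarised BUSCO-style as the
fractions of a conserved single-copy gene set found complete, fragmented
or missing.  A species' *reconstructed* fraction is complete plus
fragmented, and a sample's recovery is the unweighted mean of that
fraction over the species detected in it.

:func:`simulate_recovery` generates synthetic completeness tables from a
declared community using the Lander-Waterman coverage model: at mean
per-base coverage c = depth × abundance × read_length / genome_size,
each base is covered with probability 1 − e^{−c}.  A gene is discretised
into read-length segments; it is complete when every segment is covered,
missing when none is, fragmented otherwise.  Coupling the per-segment
uniform draws across depths makes recovery monotone in depth seed-for-
seed, mirroring how the same read pool subsampled deeper can only add
covered bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calibration import CommunitySpec

__all__ = [
    "GeneRecoveryTable",
    "reconstructed_fraction",
    "mean_recovery",
    "simulate_recovery",
    "read_recovery_tsv",
    "write_recovery_tsv",
]


@dataclass(frozen=True)
class GeneRecoveryTable:
    """Per-species complete/fragmented/missing gene fractions."""

    fractions: Mapping[str, tuple[float, float, float]]  # complete, fragmented, missing
    n_genes: Mapping[str, int]

    def __post_init__(self) -> None:
        for species, (c, f, m) in self.fractions.items():
            for v in (c, f, m):
                if not 0 <= v <= 1:
                    raise ValueError(f"fraction out of [0,1] for {species!r}")
            if abs(c + f + m - 1.0) > 1e-9:
                raise ValueError(
                    f"fractions for {species!r} sum to {c + f + m}, expected 1"
                )
        object.__setattr__(self, "fractions", dict(self.fractions))
        object.__setattr__(self, "n_genes", dict(self.n_genes))

    @property
    def species(self) -> list[str]:
        return list(self.fractions)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": s,
                "n_genes": self.n_genes.get(s, 0),
                "complete": c,
                "fragmented": f,
                "missing": m,
            }
            for s, (c, f, m) in self.fractions.items()
        ]
        return pd.DataFrame(rows)


def reconstructed_fraction(table: GeneRecoveryTable, species: str) -> float:
    """Fraction of genes fully or partially reconstructed for one species."""
    if species not in table.fractions:
        raise KeyError(f"species {species!r} not in recovery table")
    complete, fragmented, _ = table.fractions[species]
    return complete + fragmented


def mean_recovery(table: GeneRecoveryTable, detected: Iterable[str]) -> float:
    """Unweighted mean reconstructed fraction over the detected species.

    Every detected species must be present in the table; a missing
    species raises rather than silently contributing zero.
    """
    detected = list(detected)
    if not detected:
        raise ValueError("mean recovery undefined over an empty species set")
    return float(np.mean([reconstructed_fraction(table, s) for s in detected]))


def simulate_recovery(
    spec: CommunitySpec,
    depth: int,
    seed: int,
    read_length: int = 125,
    genome_sizes: Mapping[str, int] | None = None,
    default_genome_size: int = 5_000_000,
    n_genes: int = 100,
    gene_length: int = 1_000,
) -> GeneRecoveryTable:
    """Synthetic completeness table for a declared community at a depth.

    Per species, mean coverage is c = depth × fraction × read_length /
    genome_size; each gene consists of ceil(gene_length / read_length)
    segments, each covered when its uniform draw falls below 1 − e^{−c}.
    The uniform draws depend on the seed and species but not on the
    depth, so recovery is monotone non-decreasing in depth for a fixed
    seed.
    """
    if min(read_length, gene_length, n_genes, default_genome_size) <= 0:
        raise ValueError("read_length, gene_length, n_genes and genome sizes must be positive")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    genome_sizes = dict(genome_sizes or {})
    for s, size in genome_sizes.items():
        if size <= 0:
            raise ValueError(f"genome size for {s!r} must be positive")

    n_segments = int(np.ceil(gene_length / read_length))
    fractions: dict[str, tuple[float, float, float]] = {}
    genes: dict[str, int] = {}
    for i, species in enumerate(spec.species):
        size = genome_sizes.get(species, default_genome_size)
        coverage = depth * (spec.declared[species] / 100.0) * read_length / size
        p_covered = 1.0 - np.exp(-coverage)
        # species-specific stream, invariant to depth → coupled across depths
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        u = rng.random((n_genes, n_segments))
        covered = u < p_covered
        per_gene = covered.sum(axis=1)
        complete = float((per_gene == n_segments).mean())
        missing = float((per_gene == 0).mean())
        fragmented = 1.0 - complete - missing
        fractions[species] = (complete, fragmented, missing)
        genes[species] = n_genes
    return GeneRecoveryTable(fractions=fractions, n_genes=genes)


def write_recovery_tsv(table: GeneRecoveryTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_recovery_tsv(path: str | Path) -> GeneRecoveryTable:
    """Read a completeness TSV (species, n_genes, complete, fragmented, missing)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"species", "n_genes", "complete", "fragmented", "missing"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"recovery table missing column(s): {sorted(missing_cols)}")
    fractions = {
        row["species"]: (row["complete"], row["fragmented"], row["missing"])
        for _, row in frame.iterrows()
    }
    genes = {row["species"]: int(row["n_genes"]) for _, row in frame.iterrows()}
    return GeneRecoveryTable(fractions=fractions, n_genes=genes)
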