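"""Species-level taxonomic profiles and the detection rule.

The unit of data flowing through every analysis stage is a
:class:`TaxonProfile`: a per-sample mapping of species binomial name to
read count, plus the number of reads the classifier could not assign.
Profiles are read from and written to Bracken-style species reports
(tab-delimited, one row per species).

A species is declared *present* in a sample when it is supported by at
least ``min_reads`` reads **and** its relative abundance is at least
``min_frac`` percent; both comparisons are inclusive, so a species at
exactly 0.1% passes the default 0.1% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

__all__ = [
    "TaxonProfile",
    "AbundanceVector",
    "read_bracken_tsv",
    "write_bracken_tsv",
    "relative_abundances",
    "detect_species",
    "BrackenFormatError",
]

#: Columns a Bracken species report must carry (others are tolerated).
REQUIRED_COLUMNS = ("name", "taxonomy_lvl", "new_est_reads", "fraction_total_reads")

#: Full column set written by :func:`write_bracken_tsv`.
BRACKEN_COLUMNS = (
    "name",
    "taxonomy_id",
    "taxonomy_lvl",
    "kraken_assigned_reads",
    "added_reads",
    "new_est_reads",
    "fraction_total_reads",
)

#: Reserved row name holding reads the classifier left unassigned.
UNCLASSIFIED_NAME = "unclassified"

Basis = Literal["classified", "total"]


class BrackenFormatError(ValueError):
    """Raised when a species report is malformed."""


@dataclass(frozen=True)
class TaxonProfile:
    """Per-sample species read counts plus the unclassified remainder.

    Parameters
    ----------
    sample_id:
        Free-text sample label.
    counts:
        Mapping of species binomial name to non-negative read count.
    unclassified:
        Reads not assigned to any species.
    """

    sample_id: str
    counts: Mapping[str, int]
    unclassified: int = 0

    def __post_init__(self) -> None:
        if self.unclassified < 0:
            raise ValueError(f"unclassified count is negative: {self.unclassified}")
        for name, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative read count for {name!r}: {count}")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def classified_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def total_reads(self) -> int:
        return self.classified_reads + self.unclassified

    @property
    def species(self) -> list[str]:
        return list(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class AbundanceVector:
    """Relative abundances in percent, on a declared basis.

    ``basis="classified"`` normalises over classified species-level reads
    (fractions sum to 100); ``basis="total"`` divides by the full read
    count including unclassified, so the sum may fall short of 100.
    """

    fractions: Mapping[str, float]
    basis: Basis = "classified"

    def __post_init__(self) -> None:
        for name, frac in self.fractions.items():
            if frac < 0:
                raise ValueError(f"negative abundance for {name!r}: {frac}")
        object.__setattr__(self, "fractions", dict(self.fractions))

    def get(self, species: str, default: float = 0.0) -> float:
        return self.fractions.get(species, default)

    @property
    def species(self) -> list[str]:
        return list(self.fractions)

    def __len__(self) -> int:
        return len(self.fractions)


def read_bracken_tsv(path: str | Path, sample_id: str | None = None) -> TaxonProfile:
    """Read a Bracken-style species report into a :class:`TaxonProfile`.

    Species-level rows (``taxonomy_lvl == "S"``) become count entries; a
    reserved ``unclassified`` row (taxonomy level ``U``), when present,
    supplies the unclassified count.
    """
    path = Path(path)
    # keep_default_na=False: species names like "NA" must survive parsing
    table = pd.read_csv(path, sep="\t", dtype={"name": str}, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise BrackenFormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    if (table["new_est_reads"] < 0).any():
        bad = table.loc[table["new_est_reads"] < 0, "name"].iloc[0]
        raise ValueError(f"{path.name}: negative read count for {bad!r}")

    lvl = table["taxonomy_lvl"].astype(str)
    species_rows = table[lvl == "S"]
    counts = dict(
        zip(species_rows["name"], species_rows["new_est_reads"].astype(int))
    )
    if len(counts) != len(species_rows):
        raise BrackenFormatError(f"{path.name}: duplicate species names")

    unclassified_rows = table[(lvl == "U") | (table["name"] == UNCLASSIFIED_NAME)]
    unclassified = int(unclassified_rows["new_est_reads"].sum())
    return TaxonProfile(
        sample_id=sample_id if sample_id is not None else path.stem,
        counts=counts,
        unclassified=unclassified,
    )


def write_bracken_tsv(profile: TaxonProfile, path: str | Path) -> None:
    """Write a profile as a Bracken-style TSV readable by :func:`read_bracken_tsv`.

    ``fraction_total_reads`` is recomputed from counts over the total
    (classified + unclassified) reads, matching Bracken's convention.
    """
    total = profile.total_reads
    rows = []
    if profile.unclassified > 0:
        rows.append(
            {
                "name": UNCLASSIFIED_NAME,
                "taxonomy_id": 0,
                "taxonomy_lvl": "U",
                "kraken_assigned_reads": profile.unclassified,
                "added_reads": 0,
                "new_est_reads": profile.unclassified,
                "fraction_total_reads": profile.unclassified / total,
            }
        )
    for name, count in profile.counts.items():
        rows.append(
            {
                "name": name,
                "taxonomy_id": "",
                "taxonomy_lvl": "S",
                "kraken_assigned_reads": count,
                "added_reads": 0,
                "new_est_reads": count,
                "fraction_total_reads": count / total if total else 0.0,
            }
        )
    pd.DataFrame(rows, columns=list(BRACKEN_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def relative_abundances(profile: TaxonProfile, basis: Basis = "classified") -> AbundanceVector:
    """Convert read counts to percent relative abundances.

    With ``basis="classified"`` the denominator is the classified read
    count (percentages sum to 100); with ``basis="total"`` it is the full
    read count including unclassified.
    """
    if basis not in ("classified", "total"):
        raise ValueError(f"unknown basis {basis!r}")
    denom = profile.classified_reads if basis == "classified" else profile.total_reads
    if denom == 0:
        raise ValueError(
            f"sample {profile.sample_id!r} has no "
            + ("classified" if basis == "classified" else "")
            + " reads; abundances undefined"
        )
    fractions = {name: 100.0 * count / denom for name, count in profile.counts.items()}
    return AbundanceVector(fractions=fractions, basis=basis)


def detect_species(
    profile: TaxonProfile,
    min_reads: int = 10,
    min_frac: float = 0.1,
    basis: Basis = "classified",
) -> set[str]:
    """Species passing the detection rule: ``count >= min_reads`` and
    relative abundance ``>= min_frac`` percent.

    Both comparisons are inclusive. The abundance basis defaults to the
    classified read fraction.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    if not 0 <= min_frac <= 100:
        raise ValueError("min_frac must be a percentage in [0, 100]")
    if profile.classified_reads == 0:
        return set()
    abundances = relative_abundances(profile, basis=basis)
    return {
        name
        for name, count in profile.counts.items()
        if count >= min_reads and abundances.get(name) >= min_frac
    }
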