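"""Packaged transcriptions of the study's printed summary tables.

Three small TSVs ship inside the package and are loadable by id with no
network access:

* ``table1`` — the detection-threshold performance sweep on the mock
  community (threshold, TP, FP, FN, F1).
* ``table2`` — per-sample totals for the ten study samples (read count
  and number of species detected at full depth).
* ``table3`` — mock-community abundance estimates under six classifier
  databases.  ``NP`` marks a species not passing the 0.1% detection
  threshold under that database; ``ND`` in the declared-abundance column
  marks a species not declared in the mock (i.e. any call is a false
  positive).

Transcriptions are character-faithful; each file's SHA-256 is frozen
here and verified at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .taxprofile import TaxonProfile

__all__ = ["PaperFixture", "load_fixture", "fixture_to_profile", "NOT_PRESENT", "NOT_DECLARED"]

#: Sentinel in abundance cells: species below the detection threshold.
NOT_PRESENT = "NP"
#: Sentinel in the declared column: species not part of the mock community.
NOT_DECLARED = "ND"

_CHECKSUMS = {
    "table1": "fcbc15a8bf911769cca2b0168c3b1359515060c9331ae254122e50ecf3a57c54",
    "table2": "989d6f282ecaaa0a72aae8bcfd5a595a1639ec2ce0706f80660e3dd3bc213a93",
    "table3": "ddc582effb5bfeed2ca304596e463791ce3d988cec94e594b71532348c7c45fa",
}

_TABLE3_ESTIMATE_COLUMNS = ("v1_100", "v1_150", "v2_100", "v2_150", "standard", "nt")


@dataclass(frozen=True)
class PaperFixture:
    table_id: str
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def _read_packaged_tsv(table_id: str) -> pd.DataFrame:
    ref = resources.files("metadepth.data").joinpath(f"{table_id}.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[table_id]:
        raise RuntimeError(f"fixture {table_id} is corrupted (checksum mismatch)")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype=str)


def load_fixture(table_id: str) -> PaperFixture:
    """Load a packaged fixture by id (``table1``, ``table2`` or ``table3``).

    Numeric columns are converted where unambiguous; the ``NP``/``ND``
    sentinels of table3 are preserved as strings.
    """
    if table_id not in _CHECKSUMS:
        raise KeyError(f"unknown fixture id {table_id!r}; expected one of {sorted(_CHECKSUMS)}")
    rows = _read_packaged_tsv(table_id)
    if table_id == "table1":
        rows = rows.astype(
            {"threshold": float, "tp": int, "fp": int, "fn": int, "f1": float}
        )
    elif table_id == "table2":
        rows = rows.astype({"n_reads": int, "n_species": int})
    return PaperFixture(table_id=table_id, rows=rows)


def table3_abundances(column: str) -> dict[str, float]:
    """Printed percent abundances of one table3 database column.

    Species marked ``NP`` (below the detection threshold) are omitted;
    false-positive (``ND``) species with a printed value are included.
    """
    fixture = load_fixture("table3")
    if column not in _TABLE3_ESTIMATE_COLUMNS:
        raise KeyError(
            f"unknown table3 column {column!r}; expected one of {_TABLE3_ESTIMATE_COLUMNS}"
        )
    out: dict[str, float] = {}
    for _, row in fixture.rows.iterrows():
        value = row[column]
        if value != NOT_PRESENT:
            out[row["species"]] = float(value)
    return out


def declared_mock_abundances() -> dict[str, float]:
    """Declared percent abundances of the 20 mock species (table3 column)."""
    fixture = load_fixture("table3")
    return {
        row["species"]: float(row["abundance"])
        for _, row in fixture.rows.iterrows()
        if row["abundance"] != NOT_DECLARED
    }


def false_positive_total(column: str) -> float:
    """Summed printed abundance of non-declared (ND) species in a column."""
    fixture = load_fixture("table3")
    total = 0.0
    for _, row in fixture.rows.iterrows():
        if row["abundance"] == NOT_DECLARED and row[column] != NOT_PRESENT:
            total += float(row[column])
    return total


def fixture_to_profile(
    column: str, total_reads: int, sample_id: str | None = None
) -> TaxonProfile:
    """Reconstitute a read-count profile from a table3 percentage column.

    Counts are the printed percentages times ``total_reads`` with half-up
    rounding; the unclassified count absorbs the remainder (printed
    columns sum below 100%).  Exact-fraction comparisons should use
    :func:`table3_abundances` directly, since rounding at small totals
    can nudge a species across the 0.1% boundary.
    """
    import decimal

    abundances = table3_abundances(column)
    counts: dict[str, int] = {}
    for name, percent in abundances.items():
        exact = decimal.Decimal(str(percent)) / 100 * total_reads
        counts[name] = int(exact.quantize(0, rounding=decimal.ROUND_HALF_UP))
    classified = sum(counts.values())
    if classified > total_reads:
        raise ValueError(
            f"column {column!r} percentages exceed 100% at total {total_reads}"
        )
    return TaxonProfile(
        sample_id=sample_id if sample_id is not None else f"table3_{column}",
        counts=counts,
        unclassified=total_reads - classified,
    )
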