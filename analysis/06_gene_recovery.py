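"""Gene recovery under coverage reduction (full vs 1M reads).

Simulates BUSCO-style completeness tables for the staggered mock at the
full simulated depth (~5M reads, the mock's real-world scale) and at the
1M-read reduction, then summarises the reconstructed-gene fraction per
abundance tier and the per-sample mean over detected species.

Writes results/recovery.tsv.
"""

from pathlib import Path

import pandas as pd

from metadepth.gene_recovery import mean_recovery, reconstructed_fraction, simulate_recovery
from metadepth.synthetic import mock_spec

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 404
FULL_DEPTH = 4_969_245
REDUCED_DEPTH = 1_000_000

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    mock = mock_spec()
    detected = [s for s, v in mock.declared.items() if v >= 0.18]  # 0.1% rule on declared

    rows = []
    for depth in (REDUCED_DEPTH, FULL_DEPTH):
        table = simulate_recovery(mock, depth=depth, seed=SEED)
        for species in table.species:
            c, f, m = table.fractions[species]
            rows.append(
                {
                    "depth": depth,
                    "species": species,
                    "declared_percent": mock.declared[species],
                    "complete": c,
                    "fragmented": f,
                    "missing": m,
                    "reconstructed": c + f,
                }
            )
        print(f"depth {depth:>9}: mean recovery over detected species = "
              f"{mean_recovery(table, detected):.3f}")
        frame = pd.DataFrame([r for r in rows if r["depth"] == depth])
        tier_means = frame.groupby("declared_percent")["reconstructed"].mean()
        print("  reconstructed fraction by declared tier:")
        print(tier_means.round(3).to_string(), "\n")

    pd.DataFrame(rows).to_csv(RESULTS / "recovery.tsv", sep="\t", index=False)

if __name__ == "__main__":
    main()
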