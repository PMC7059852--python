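"""Abundance agreement: expected-vs-observed and full-vs-reduced.

Two questions, answered on the simulated profiles:
(1) how well do abundances re-estimated from shallow subsamples of the
mock agree with the declared composition (Pearson r per depth)?
(2) how well does each reduced sample's composition rank-correlate with
its own full-depth profile (Spearman rho per sample and depth)?

Writes results/expected_observed.tsv and results/full_vs_reduced.tsv.
"""

from pathlib import Path

import pandas as pd

from metadepth.diversity import abundance_correlation, full_vs_reduced_correlation
from metadepth.fixtures import declared_mock_abundances
from metadepth.rarefaction import DEFAULT_DEPTHS, replicate_seed, subsample_profile
from metadepth.taxprofile import AbundanceVector, read_bracken_tsv, relative_abundances

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 202
N_REPS = 5

def main() -> None:
    profile_dir = RESULTS / "profiles"
    if not profile_dir.exists():
        raise SystemExit("run 02_simulate_communities.py first")
    declared = AbundanceVector(fractions=declared_mock_abundances(), basis="classified")
    mock = read_bracken_tsv(profile_dir / "A1sim.tsv")

    expected_rows = []
    for di, depth in enumerate(DEFAULT_DEPTHS):
        for ri in range(N_REPS):
            sub = subsample_profile(mock, depth, seed=replicate_seed(SEED, di, ri))
            observed = relative_abundances(sub)
            r = abundance_correlation(declared, observed, method="pearson")
            expected_rows.append({"depth": depth, "replicate": ri, "pearson_r": r})
    expected = pd.DataFrame(expected_rows)
    expected.to_csv(RESULTS / "expected_observed.tsv", sep="\t", index=False)
    print("mean Pearson r, declared vs re-estimated mock abundances:")
    print(expected.groupby("depth")["pearson_r"].mean().round(3).to_string())

    fvr_rows = []
    for path in sorted(profile_dir.glob("*.tsv")):
        profile = read_bracken_tsv(path)
        for di, depth in enumerate(DEFAULT_DEPTHS):
            for ri in range(N_REPS):
                sub = subsample_profile(profile, depth, seed=replicate_seed(SEED, di, ri))
                rho = full_vs_reduced_correlation(profile, sub)
                fvr_rows.append(
                    {"sample": profile.sample_id, "depth": depth, "replicate": ri, "spearman_rho": rho}
                )
    fvr = pd.DataFrame(fvr_rows)
    fvr.to_csv(RESULTS / "full_vs_reduced.tsv", sep="\t", index=False)
    by_depth = fvr.groupby("depth")["spearman_rho"].mean()
    print("\nmean full-vs-reduced Spearman rho by depth (improves with depth):")
    print(by_depth.round(3).to_string())

if __name__ == "__main__":
    main()
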