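import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_hypergeom

from metadepth.rarefaction import (
    DEFAULT_DEPTHS,
    DepthSeries,
    depth_series,
    replicate_seed,
    subsample_profile,
)
from metadepth.taxprofile import TaxonProfile


class TestSubsampleProfile:
    def test_full_depth_is_identity(self, toy_profile):
        sub = subsample_profile(toy_profile, toy_profile.total_reads, seed=0)
        assert sub.counts == toy_profile.counts
        assert sub.unclassified == toy_profile.unclassified

    def test_zero_depth_is_empty(self, toy_profile):
        sub = subsample_profile(toy_profile, 0, seed=0)
        assert sub.total_reads == 0

    def test_depth_exceeding_total_rejected(self, toy_profile):
        with pytest.raises(ValueError, match="without replacement"):
            subsample_profile(toy_profile, toy_profile.total_reads + 1, seed=0)

    def test_output_total_is_exact(self, mock_profile_1m):
        sub = subsample_profile(mock_profile_1m, 123_457, seed=1)
        assert sub.total_reads == 123_457

    def test_toy_enumeration_probability(self):
        """{A:2, B:1} at depth 2: exactly 1 of the C(3,2)=3 read pairs is
        {A,A}, so P(A=2) = 1/3."""
        profile = TaxonProfile("t", {"A": 2, "B": 1})
        n = 3000
        hits = sum(
            subsample_profile(profile, 2, seed=s).counts.get("A", 0) == 2
            for s in range(n)
        )
        # 4 sigma band around 1/3 at n=3000
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(hits / n - 1 / 3) < 4 * se

    @pytest.mark.parametrize(
        "counts,unclassified,depth",
        [
            ({"A": 2, "B": 1}, 0, 2),
            ({"A": 3, "B": 2, "C": 1}, 0, 3),
            ({"A": 2, "B": 2}, 2, 4),
            ({"A": 5}, 3, 4),
        ],
    )
    def test_matches_hypergeometric_enumeration(self, counts, unclassified, depth):
        """Empirical draw frequencies match the exact multivariate
        hypergeometric pmf on all instances with <= 8 total reads."""
        profile = TaxonProfile("t", counts, unclassified=unclassified)
        names = profile.species
        colors = [counts[n] for n in names] + [unclassified]
        n_draws = 4000
        observed: dict[tuple, int] = {}
        for s in range(n_draws):
            sub = subsample_profile(profile, depth, seed=s)
            key = tuple(sub.counts.get(n, 0) for n in names) + (sub.unclassified,)
            observed[key] = observed.get(key, 0) + 1
        # enumerate the support and compare each outcome's frequency
        support = [
            k
            for k in itertools.product(*(range(c + 1) for c in colors))
            if sum(k) == depth
        ]
        for outcome in support:
            p = multivariate_hypergeom.pmf(list(outcome), colors, depth)
            freq = observed.get(outcome, 0) / n_draws
            se = np.sqrt(p * (1 - p) / n_draws)
            assert abs(freq - p) < 5 * se + 1e-9

    def test_unbiasedness_three_species(self):
        """E[count_i] = depth * count_i / total on a 3-species toy."""
        profile = TaxonProfile("t", {"A": 50, "B": 30, "C": 20})
        depth = 40
        draws = np.array(
            [
                [subsample_profile(profile, depth, seed=s).counts.get(n, 0) for n in "ABC"]
                for s in range(1000)
            ]
        )
        expected = depth * np.array([50, 30, 20]) / 100
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert (np.abs(draws.mean(axis=0) - expected) <= 3 * se).all()

    def test_multinomial_option_can_upsample(self, toy_profile):
        sub = subsample_profile(toy_profile, 500, seed=0, replace=True)
        assert sub.total_reads == 500


class TestDepthSeries:
    def test_constant_metric_zero_width_ci(self, mock_profile_1m):
        series = depth_series(
            mock_profile_1m, lambda p: 7.0, depths=[1000, 2000], n_reps=5, seed=0
        )
        low, high = series.confidence_limits()
        assert (series.means() == 7.0).all()
        assert np.allclose(low, 7.0) and np.allclose(high, 7.0)

    def test_default_grid_and_ci_level(self):
        assert DEFAULT_DEPTHS == (10_000, 25_000, 50_000, 100_000, 250_000, 500_000, 1_000_000)
        profile = TaxonProfile("t", {"A": 30_000, "B": 10_000})
        series = depth_series(profile, lambda p: float(len(p)), depths=[10_000, 25_000])
        assert series.ci_level == 0.99 and series.n_replicates == 5

    def test_wider_interval_at_higher_confidence(self, mock_profile_1m):
        from metadepth.diversity import shannon
        from metadepth.taxprofile import relative_abundances

        metric = lambda p: shannon(relative_abundances(p))
        s99 = depth_series(mock_profile_1m, metric, depths=[10_000], ci_level=0.99, seed=3)
        s95 = depth_series(mock_profile_1m, metric, depths=[10_000], ci_level=0.95, seed=3)
        w99 = np.subtract(*reversed(s99.confidence_limits()))[0]
        w95 = np.subtract(*reversed(s95.confidence_limits()))[0]
        assert w99 > w95 > 0

    def test_depths_above_total_skipped_with_warning(self, caplog):
        profile = TaxonProfile("t", {"A": 800, "B": 200})
        with caplog.at_level("WARNING"):
            series = depth_series(profile, lambda p: 1.0, depths=[500, 5000], n_reps=3)
        assert series.depths == (500,)
        assert "skipping depth" in caplog.text

    def test_nested_determinism_from_master_seed(self, mock_profile_1m):
        metric = lambda p: float(len(p))
        a = depth_series(mock_profile_1m, metric, depths=[10_000, 50_000], seed=42)
        b = depth_series(mock_profile_1m, metric, depths=[10_000, 50_000], seed=42)
        assert a.values == b.values
        c = depth_series(mock_profile_1m, metric, depths=[10_000, 50_000], seed=43)
        assert a.values != c.values

    def test_replicate_seeds_distinct(self):
        keys = {
            tuple(replicate_seed(1, d, r).generate_state(2))
            for d in range(7)
            for r in range(5)
        }
        assert len(keys) == 35

    def test_metric_failure_names_replicate(self, mock_profile_1m):
        def bad_metric(p):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="depth 10000, replicate 0"):
            depth_series(mock_profile_1m, bad_metric, depths=[10_000])

    def test_detected_count_grows_with_depth(self, mock_profile_1m):
        """On the staggered mock, the 0.18% tier is reliably detectable at
        10^6 reads but not at 10^4 (expected read support 18 vs ~1800)."""
        from metadepth.diversity import observed_taxa

        series = depth_series(
            mock_profile_1m, lambda p: float(observed_taxa(p)), depths=[10_000, 1_000_000], seed=5
        )
        mean_low, mean_high = series.means()
        assert mean_low <= mean_high

    def test_long_and_summary_export(self, tmp_path, mock_profile_1m):
        series = depth_series(mock_profile_1m, lambda p: 1.0, depths=[10_000], n_reps=3)
        series.to_tsv(tmp_path / "long.tsv", kind="long")
        series.to_tsv(tmp_path / "summary.tsv")
        long_header = (tmp_path / "long.tsv").read_text().splitlines()[0]
        assert long_header == "sample\tmetric\tdepth\treplicate\tvalue"
        summary_header = (tmp_path / "summary.tsv").read_text().splitlines()[0]
        assert summary_header == "sample\tmetric\tdepth\tmean\tci_low\tci_high"
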