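import math
from fractions import Fraction

import numpy as np
import pytest

from ramscreen.motifs import KmerSet, MatchHit, canonical_form, find_matches
from ramscreen.screen import (
    BinProfile,
    ScreenConfig,
    bin_hits,
    binomial_p,
    bonferroni,
    center_flank_counts,
    enrichment_factor,
    pattern_profiles,
    results_to_frame,
    run_screen,
    screen_from_profiles,
    write_screen_table,
)
from ramscreen.simulate import SimulationConfig, simulate_dataset

CFG = ScreenConfig()


def exact_binomial_p(C, F):
    """1 - CDF(4C, 4C+F, 1/2) as an exact rational, independent of scipy."""
    if C == 0 and F == 0:
        return Fraction(1, 2)
    n, N = 4 * C, 4 * C + F
    tail = sum(math.comb(N, i) for i in range(n + 1, N + 1))
    return Fraction(tail, 2**N)


class TestBinGeometry:
    def test_config_regions(self):
        assert CFG.n_bins == 50
        assert list(CFG.center_bins) == [23, 24, 25, 26]
        left, right = CFG.flank_bins
        assert list(left) == list(range(8)) and list(right) == list(range(42, 50))

    @pytest.mark.parametrize(
        "rel, bin_idx", [(-1000, 0), (-80, 23), (-1, 24), (0, 25), (79, 26), (990, 49)]
    )
    def test_hit_binning(self, rel, bin_idx):
        profile = bin_hits([MatchHit("w", rel, "+")], CFG)
        assert profile.counts[bin_idx] == 1 and profile.total == 1

    def test_no_hits_gives_zero_profile(self):
        assert bin_hits([], CFG).total == 0

    def test_hit_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside window"):
            bin_hits([MatchHit("w", 1000, "+")], CFG)

    def test_center_flank_counts(self):
        assert center_flank_counts(BinProfile(np.ones(50)), CFG) == (4, 16)
        buffer_only = np.zeros(50)
        buffer_only[8:23] = 5
        buffer_only[27:42] = 5
        assert center_flank_counts(BinProfile(buffer_only), CFG) == (0, 0)
        one_end = np.zeros(50)
        one_end[49] = 1
        assert center_flank_counts(BinProfile(one_end), CFG) == (0, 1)


class TestStatistics:
    @pytest.mark.parametrize(
        "C, F, E", [(10, 40, 1.0), (0, 16, 0.0), (8, 8, 4.0), (663, 604, 4 * 663 / 604)]
    )
    def test_enrichment_factor(self, C, F, E):
        assert enrichment_factor(C, F) == pytest.approx(E)

    def test_enrichment_factor_sentinels(self):
        assert enrichment_factor(0, 0) == 0.0
        assert math.isinf(enrichment_factor(5, 0))

    def test_zero_hit_p_is_half(self):
        assert binomial_p(0, 0) == 0.5

    def test_full_support_p_is_zero(self):
        assert binomial_p(1, 0) == 0.0

    def test_p_matches_exact_rational(self):
        assert binomial_p(5, 20) == pytest.approx(
            float(exact_binomial_p(5, 20)), abs=1e-14
        )

    def test_p_monotone_in_C_at_fixed_F(self):
        for F in (5, 20, 100):
            ps = [binomial_p(C, F) for C in range(30)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize(
        "p, m, expected", [(0.001, 128, 0.128), (0.5, 128, 1.0), (0.0, 7, 0.0)]
    )
    def test_bonferroni(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_bonferroni_rejects_m_below_one(self):
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


@pytest.fixture(scope="module")
def small_planted():
    """400 enhancers, planted center/flank ratio 4, plus screen inputs."""
    cfg = SimulationConfig(n_enhancers=400, seed=7)
    genome, centers, truth = simulate_dataset(cfg)
    return cfg, genome, centers, truth


class TestRunScreen:
    def test_planted_pattern_detected_in_single_pattern_screen(self, small_planted):
        cfg, genome, centers, _ = small_planted
        pat = canonical_form(cfg.planted_pattern)
        results = run_screen(genome, centers, KmerSet(k=10, patterns=(pat,)))
        (r,) = results
        assert not r.excluded and r.rank == 1
        assert r.p_adj < 0.05
        assert r.E > 2  # strongly centrally enriched

    def test_absent_pattern_gets_half_p_and_excluded(self):
        cfg = SimulationConfig(
            n_enhancers=5, seed=1, rate_center=0, rate_flank=0,
            base_composition={"A": 0.5, "C": 0.0, "G": 0.0, "T": 0.5},
        )
        genome, centers, _ = simulate_dataset(cfg)
        pat = canonical_form("TCGTGACTCA")  # needs C/G, absent from an AT genome
        (r,) = run_screen(genome, centers, KmerSet(k=10, patterns=(pat,)))
        assert r.excluded and r.p == 0.5 and r.reason.startswith("no hits")

    def test_order_of_enhancers_is_immaterial(self, small_planted, rng):
        cfg, genome, centers, _ = small_planted
        pat = canonical_form(cfg.planted_pattern)
        kmers = KmerSet(k=10, patterns=(pat, canonical_form("TGACTCACCC")))
        a = results_to_frame(run_screen(genome, centers, kmers))
        shuffled = list(centers)
        rng.shuffle(shuffled)
        b = results_to_frame(run_screen(genome, shuffled, kmers))
        assert a.equals(b)

    def test_hit_conservation_center_plus_flank_plus_middle(self, small_planted):
        cfg, genome, centers, _ = small_planted
        from ramscreen.sequence_io import extract_windows

        windows, _ = extract_windows(genome, centers)
        pat = canonical_form(cfg.planted_pattern)
        profiles = pattern_profiles(windows, KmerSet(k=10, patterns=(pat,)))
        profile = profiles[pat]
        C, F = center_flank_counts(profile)
        total_by_window = sum(len(find_matches(pat, w)) for w in windows)
        assert profile.total == total_by_window
        middle = profile.total - C - F
        assert middle >= 0 and C + F + middle == total_by_window

    def test_m_rule_all_versus_tested(self):
        profiles = {
            "AAAA": BinProfile(np.ones(50)),         # C=4, F=16
            "CCCC": BinProfile(np.zeros(50)),        # zero hits -> untested
        }
        tested = screen_from_profiles(profiles, ScreenConfig(m_rule="tested"))
        all_m = screen_from_profiles(
            profiles, ScreenConfig(m_rule="all"), n_patterns=128
        )
        r_t = next(r for r in tested if r.pattern == "AAAA")
        r_a = next(r for r in all_m if r.pattern == "AAAA")
        assert r_t.p_adj == pytest.approx(r_t.p)  # m = 1 tested pattern
        assert r_a.p_adj == pytest.approx(min(1.0, 128 * r_a.p))

    def test_center_only_pattern_flagged_not_excluded(self):
        counts = np.zeros(50)
        counts[24] = 6  # all hits central, none in flanks
        (r,) = screen_from_profiles({"AAAA": BinProfile(counts)})
        assert math.isinf(r.E) and r.p == 0.0 and not r.excluded
        assert "review" in r.reason

    def test_ranking_orders_by_E_then_p(self):
        strong = np.zeros(50)
        strong[23:27] = 25  # C=100
        strong[:8] = 5      # F=40 -> E=10
        weak = np.zeros(50)
        weak[23:27] = 25
        weak[:8] = 10       # F=80 -> E=5
        results = screen_from_profiles(
            {"CCCC": BinProfile(weak), "AAAA": BinProfile(strong)}
        )
        assert [r.pattern for r in results] == ["AAAA", "CCCC"]
        assert [r.rank for r in results] == [1, 2]

    def test_written_table_round_trips_through_pandas(self, small_planted, tmp_path):
        import pandas as pd

        cfg, genome, centers, _ = small_planted
        pat = canonical_form(cfg.planted_pattern)
        results = run_screen(genome, centers, KmerSet(k=10, patterns=(pat,)))
        out = tmp_path / "screen.tsv"
        write_screen_table(results, out)
        table = pd.read_csv(out, sep="\t")
        assert list(table.columns) == [
            "pattern", "C", "F", "E", "p", "p_adj", "rank", "excluded", "reason"
        ]
        assert table.loc[0, "pattern"] == pat
        assert table.loc[0, "C"] == results[0].C
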