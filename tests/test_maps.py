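"""Map summaries, window rates, hotspots, enrichment statistics and
map comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spermrec import (
    SimConfig,
    bh_adjust,
    compare_maps,
    cumulative_map,
    detect_hotspots,
    double_crossover_spacing,
    fisher_exact_2x2,
    map_summary,
    qtl_enrichment,
    simulate_donor,
    simulate_gametes,
    window_rates,
)
from spermrec.datatypes import CrossoverEvent, events_to_frame
from spermrec.io import GenomicInterval
from spermrec.maps import Hotspot, shared_hotspots

CHROMS = {"chr1": 5_000_000, "chr2": 3_000_000}


def make_events(specs):
    """specs: (cell, chrom, midpoint) — events 2 kb wide around midpoint."""
    return events_to_frame([
        CrossoverEvent(cell, chrom, int(mid) - 1000, int(mid) + 1000)
        for cell, chrom, mid in specs
    ])


class TestMapSummary:
    def test_per_cell_statistics_exact(self):
        events = make_events(
            [("a", "chr1", 500_000)] * 3
            + [("b", "chr1", 1_500_000)] * 2
            + [("b", "chr2", 100_000)]
        )
        m = map_summary(events, n_cells=3, chrom_lengths=CHROMS,
                        cells=["a", "b", "c"])
        per_cell = np.array([3, 3, 0])
        assert m.total_events == 6
        assert m.mean_per_cell == 2.0
        assert m.sd == pytest.approx(per_cell.std(ddof=1))
        assert m.se == m.sd / math.sqrt(3)
        assert m.genome_morgans == pytest.approx(6 / 3)
        # Morgans additive across chromosomes
        assert m.per_chrom["morgans"].sum() == pytest.approx(m.genome_morgans)

    def test_zero_events(self):
        m = map_summary(make_events([]), n_cells=5, chrom_lengths=CHROMS,
                        cells=["a"])
        assert m.genome_morgans == 0.0 and m.sd == 0.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            map_summary(make_events([]), n_cells=0, chrom_lengths=CHROMS)

    def test_masked_events_excluded_everywhere(self):
        events = make_events(
            [("a", "chr1", 500_000), ("a", "chr1", 1_500_000)]
        )
        masks = [GenomicInterval("chr1", 1_000_000, 2_000_000)]
        m = map_summary(events, n_cells=1, chrom_lengths=CHROMS, masks=masks,
                        cells=["a"])
        assert m.total_events == 1
        assert m.unmasked_mb == 7.0


class TestWindowRates:
    def test_rate_formula(self):
        events = make_events([("c%d" % i, "chr1", 500_000) for i in range(5)])
        rates = window_rates(events, n_cells=50, chrom_lengths=CHROMS)
        first = rates.iloc[0]
        assert first["count"] == 5
        assert first["rate_cm_per_mb"] == pytest.approx(10.0)  # 100*(5/50)/1

    def test_boundary_midpoint_goes_right(self):
        events = events_to_frame(
            [CrossoverEvent("c", "chr1", 999_000, 1_001_000)]  # midpoint 1 Mb
        )
        rates = window_rates(events, n_cells=1, chrom_lengths=CHROMS)
        w = rates[(rates["chrom"] == "chr1") & (rates["start"] == 1_000_000)]
        assert int(w["count"].iloc[0]) == 1

    def test_masked_windows_absent_not_zero(self):
        masks = [GenomicInterval("chr1", 0, 1_000_000)]
        rates = window_rates(make_events([]), 10, CHROMS, masks)
        assert not ((rates["chrom"] == "chr1") & (rates["start"] == 0)).any()

    def test_window_counts_conserve_map_total(self, noisy_panel):
        cfg, donor, matrix, truth = noisy_panel
        events = make_events(
            [("a", "chr1", p) for p in
             np.random.default_rng(0).integers(10_000, 4_990_000, 40)]
        )
        masks = [GenomicInterval("chr1", 2_000_000, 3_000_000)]
        rates = window_rates(events, 10, CHROMS, masks)
        m = map_summary(events, 10, CHROMS, masks, cells=["a"])
        assert rates["count"].sum() == m.total_events

    def test_uniform_simulation_window_rates_match_genome_rate(self):
        cfg = SimConfig(
            chrom_lengths={"chr1": 20_000_000}, htsnp_density=100,
            map_length=2.0, distal_enrichment=0.0, error_rate=0.0,
            missing_rate=0.0, n_cells=100, seed=29,
        )
        donor, _ = simulate_donor(cfg)
        _, truth = simulate_gametes(donor, cfg)
        events = make_events(
            [(c, ch, p) for c, ch, p in truth.crossovers.itertuples(index=False)]
        )
        rates = window_rates(events, 100, {"chr1": 20_000_000})
        m = map_summary(events, 100, {"chr1": 20_000_000},
                        cells=[f"cell{i:03d}" for i in range(100)])
        se = rates["rate_cm_per_mb"].std(ddof=1) / math.sqrt(len(rates))
        assert abs(rates["rate_cm_per_mb"].mean() - m.rate_cm_per_mb) < 4 * se


class TestDetectHotspots:
    def fixture_rates(self):
        df = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(100) * 10**6,
            "end": (np.arange(100) + 1) * 10**6,
            "count": 0, "rate_cm_per_mb": [1.0] * 99 + [10.0],
        })
        return df

    def test_single_outlier_window_flagged(self):
        hot, threshold = detect_hotspots(self.fixture_rates(), k=2.5)
        assert len(hot) == 1
        assert hot[0].rate == 10.0
        assert threshold == pytest.approx(
            1.09 + 2.5 * self.fixture_rates()["rate_cm_per_mb"].std(ddof=1)
        )

    def test_constant_rates_flag_nothing(self):
        df = self.fixture_rates()
        df["rate_cm_per_mb"] = 2.0
        assert detect_hotspots(df)[0] == []

    def test_scale_equivariance(self):
        df = self.fixture_rates()
        base = {(h.chrom, h.start) for h in detect_hotspots(df)[0]}
        df2 = df.assign(rate_cm_per_mb=df["rate_cm_per_mb"] * 37.5)
        scaled = {(h.chrom, h.start) for h in detect_hotspots(df2)[0]}
        assert base == scaled

    def test_shared_hotspots_by_overlap(self):
        a = [Hotspot("chr1", 0, 10**6, 5.0, 1.0)]
        b = [Hotspot("chr1", 0, 10**6, 6.0, 1.0),
             Hotspot("chr2", 0, 10**6, 6.0, 1.0)]
        assert len(shared_hotspots(a, b)) == 1

    def test_needs_two_windows(self):
        with pytest.raises(ValueError):
            detect_hotspots(self.fixture_rates().head(1))


def fisher_greater_oracle(a, b, c, d):
    """Hypergeometric tail by direct enumeration over tables with the
    observed margins (the independent check for the library route)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p = 0.0
    for x in range(a, min(r1, c1) + 1):
        if c1 - x > r2:
            continue
        p += math.comb(r1, x) * math.comb(r2, c1 - x) / denom
    return p


class TestFisherExact:
    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    def test_small_table_matches_enumeration(self):
        p = fisher_exact_2x2([[3, 1], [1, 3]], alternative="greater")
        assert p == pytest.approx(fisher_greater_oracle(3, 1, 1, 3), rel=1e-12)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, 4)
            p = fisher_exact_2x2([[a, b], [c, d]], alternative="greater")
            if min(a + b, c + d, a + c, b + d) == 0:
                assert p == 1.0
            else:
                assert p == pytest.approx(
                    fisher_greater_oracle(a, b, c, d), rel=1e-9
                )

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2], [3, -1]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 1], [1, 1]], alternative="less")


def bh_definition(p):
    """q(i) = min_{j >= i} p(j) * m / j over the sorted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_definitional_formula(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_definition(p))

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestQtlEnrichment:
    def windows(self):
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(50) * 10**6,
            "end": (np.arange(50) + 1) * 10**6,
            "count": 0, "rate_cm_per_mb": 1.0,
        })

    def test_perfect_overlap_minimizes_p(self):
        win = self.windows()
        hot = [Hotspot("chr1", 0, 10**6, 9.0, 1.0),
               Hotspot("chr1", 10**6, 2 * 10**6, 9.0, 1.0)]
        qtl = pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [2 * 10**6],
            "trait": ["fertility"],
        })
        out = qtl_enrichment(hot, win, qtl)
        assert out.loc[0, "p"] == pytest.approx(
            fisher_greater_oracle(2, 0, 0, 48)
        )

    def test_trait_without_overlap_reports_p_one(self):
        win = self.windows()
        qtl = pd.DataFrame({
            "chrom": ["chrX"], "start": [0], "end": [10**6], "trait": ["t"],
        })
        out = qtl_enrichment([], win, qtl)
        assert out.loc[0, "p"] == 1.0

    def test_bh_applied_across_traits(self):
        win = self.windows()
        hot = [Hotspot("chr1", 0, 10**6, 9.0, 1.0)]
        qtl = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 10**6],
            "end": [10**6, 2 * 10**6], "trait": ["a", "b"],
        })
        out = qtl_enrichment(hot, win, qtl)
        assert np.allclose(out["q"], bh_definition(out["p"].to_numpy()))


class TestCompareMaps:
    def grid_rates(self, values, length=30_000_000):
        n = length // 10**6
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 10**6,
            "end": (np.arange(n) + 1) * 10**6,
            "count": 0, "rate_cm_per_mb": values,
        })

    def test_self_comparison_is_perfectly_correlated(self):
        rng = np.random.default_rng(9)
        rates = self.grid_rates(rng.gamma(2.0, 1.0, 30))
        _, r, _ = compare_maps(rates, rates, {"chr1": 30_000_000})
        assert r == pytest.approx(1.0)

    def test_local_linear_smoother_reproduces_linear_profile(self):
        vals = np.linspace(1.0, 4.0, 30)
        rates = self.grid_rates(vals)
        table, r, _ = compare_maps(
            rates, rates, {"chr1": 30_000_000}, exclude_terminal_bp=0
        )
        assert np.allclose(table["smooth_a"], table["rate_a"], atol=1e-8)

    def test_terminal_windows_excluded(self):
        rates = self.grid_rates(np.ones(30))
        table, _, _ = compare_maps(
            rates, rates.assign(rate_cm_per_mb=np.linspace(0, 2, 30)),
            {"chr1": 30_000_000}, exclude_terminal_bp=5_000_000,
        )
        assert table["start"].min() >= 5_000_000
        assert table["end"].max() <= 25_000_000

    def test_too_few_windows_rejected(self):
        rates = self.grid_rates(np.ones(30)).head(2)
        with pytest.raises(ValueError):
            compare_maps(rates, rates, {"chr1": 30_000_000},
                         exclude_terminal_bp=0)

    def test_same_generator_correlates_higher_than_independent(self):
        rng = np.random.default_rng(10)
        base = rng.gamma(2.0, 1.0, 30)
        noisy1 = base + rng.normal(0, 0.3, 30)
        noisy2 = base + rng.normal(0, 0.3, 30)
        other = rng.permutation(base)
        chrom = {"chr1": 30_000_000}
        _, r_same, _ = compare_maps(
            self.grid_rates(noisy1), self.grid_rates(noisy2), chrom,
            exclude_terminal_bp=0,
        )
        _, r_other, _ = compare_maps(
            self.grid_rates(noisy1), self.grid_rates(other), chrom,
            exclude_terminal_bp=0,
        )
        assert r_same > r_other


class TestCumulativeMap:
    def test_curve_properties(self):
        events = make_events(
            [("a", "chr1", 500_000), ("a", "chr1", 2_500_000),
             ("b", "chr1", 2_600_000)]
        )
        rates = window_rates(events, 2, CHROMS)
        curves = cumulative_map(rates, 2)
        c = curves["chr1"]
        assert np.all(np.diff(c["cum_morgans"]) >= 0)
        assert c["cum_morgans"].iloc[-1] == pytest.approx(3 / 2)

    def test_zero_events_flat_zero(self):
        rates = window_rates(make_events([]), 2, CHROMS)
        curves = cumulative_map(rates, 2)
        assert (curves["chr1"]["cum_morgans"] == 0).all()


class TestDoubleCrossoverSpacing:
    def test_single_pair_arithmetic(self):
        events = make_events(
            [("a", "chr1", 10_000_000), ("a", "chr1", 42_000_000)]
        )
        mean, n = double_crossover_spacing(events)
        assert (mean, n) == (32_000_000.0, 1)

    def test_no_qualifying_chromosome(self):
        events = make_events([("a", "chr1", 1_000_000)])
        mean, n = double_crossover_spacing(events)
        assert math.isnan(mean) and n == 0

    def test_uniform_two_point_spacing_matches_order_statistics(self):
        # two independent uniforms on (0, L): E|X1 - X2| = L/3
        cfg = SimConfig(
            chrom_lengths={"chr1": 30_000_000}, htsnp_density=10,
            map_length=2.0, distal_enrichment=0.0, error_rate=0.0,
            missing_rate=0.0, n_cells=400, seed=33,
        )
        donor, _ = simulate_donor(cfg)
        _, truth = simulate_gametes(donor, cfg)
        events = make_events(
            [(c, ch, p) for c, ch, p in truth.crossovers.itertuples(index=False)]
        )
        mean, n = double_crossover_spacing(events)
        assert n > 30
        L = 30_000_000
        sd = L * math.sqrt(1 / 18)  # Var|X1-X2| = L^2/18
        assert abs(mean - L / 3) < 4 * sd / math.sqrt(n)
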