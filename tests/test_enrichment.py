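"""Random-null generation, mark association, chi-square and binomial tests."""

import math

import numpy as np
import pytest
from scipy import stats

from apobreak.enrichment import (
    ContingencyTable2x2,
    binomial_enrichment,
    chi_square_2x2,
    curated_list_enrichment,
    curated_list_enrichment_from_counts,
    mark_association,
    read_gene_list,
    simulate_random_peaks,
    standardize_marks,
)
from apobreak.intervals import GenomeIndex, GenomicInterval
from apobreak.peaks import Peak


def peak_at(center, chrom="chr1", width=400):
    return Peak(GenomicInterval(chrom, center - width // 2, center + width // 2),
                summit=center, tag_count=1, p_value=1e-6)


class TestRandomPeaks:
    def test_count_and_bounds(self, genome):
        peaks = simulate_random_peaks(1_000, genome, seed=1)
        assert len(peaks) == 1_000
        for p in peaks:
            assert 0 <= p.interval.start < p.interval.end <= genome[p.chrom]
            assert p.interval.width == 400

    def test_chromosome_exclusion(self):
        genome = GenomeIndex({"chr1": 500_000, "chrY": 500_000})
        peaks = simulate_random_peaks(2_000, genome, exclude_chroms={"chrY"}, seed=2)
        assert all(p.chrom != "chrY" for p in peaks)
        assert 0 < len(peaks) < 2_000  # some simulated sites were removed

    def test_mask_survivor_fraction(self):
        genome = GenomeIndex({"chr1": 1_000_000})
        mask = [GenomicInterval("chr1", 0, 100_000)]  # 10% of the chromosome
        peaks = simulate_random_peaks(100_000, genome, mask=mask, width=1, seed=3)
        frac = len(peaks) / 100_000
        assert abs(frac - 0.9) < 0.01  # binomial 3 sigma ~ 0.003

    def test_width_exceeding_shortest_chromosome_errors(self, genome):
        with pytest.raises(ValueError, match="width"):
            simulate_random_peaks(10, genome, width=600_000)

    def test_seeded_determinism(self, genome):
        a = simulate_random_peaks(500, genome, seed=7)
        b = simulate_random_peaks(500, genome, seed=7)
        assert [(p.chrom, p.interval.start) for p in a] == \
               [(p.chrom, p.interval.start) for p in b]


class TestMarkAssociation:
    def test_standardized_width_149(self):
        marks = [GenomicInterval("chr1", 1_000, 3_000)]
        (std,) = standardize_marks(marks)
        assert std.width == 149
        assert std.start == 2_000 - 74 and std.end == 2_000 + 75

    def test_center_at_mark_center_associates(self):
        marks = [GenomicInterval("chr1", 1_000, 3_000)]  # center 2000
        res = mark_association([peak_at(2_000)], marks)
        assert res.observed_k == 1

    def test_center_75bp_away_does_not(self):
        marks = [GenomicInterval("chr1", 1_000, 3_000)]
        # window reaches -74/+74 around the center
        assert mark_association([peak_at(2_000 + 74)], marks).observed_k == 1
        assert mark_association([peak_at(2_000 + 75)], marks).observed_k == 0
        assert mark_association([peak_at(2_000 - 74)], marks).observed_k == 1
        assert mark_association([peak_at(2_000 - 75)], marks).observed_k == 0

    def test_rate(self):
        marks = [GenomicInterval("chr1", 1_000, 3_000)]
        res = mark_association([peak_at(2_000), peak_at(50_000)], marks)
        assert res.n == 2 and res.rate == 0.5


class TestChiSquare:
    def test_no_association(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_closed_form_on_random_tables(self, rng):
        """Pearson statistic equals n(ad-bc)^2/((a+b)(c+d)(a+c)(b+d)) to
        1e-9 relative error on 10,000 random tables."""
        for _ in range(10_000):
            a, b, c, d = (int(x) for x in rng.integers(1, 1_000, size=4))
            stat, _ = chi_square_2x2(ContingencyTable2x2(a, b, c, d))
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert stat == pytest.approx(closed, rel=1e-9)

    def test_against_permutation_null(self, rng):
        """[[20,10],[10,20]]: chi-square tail probability agrees with a
        permutation null over row-label reshuffles."""
        stat, p = chi_square_2x2(ContingencyTable2x2(20, 10, 10, 20))
        n = 60
        labels = np.array([0] * 30 + [1] * 30)  # row membership
        outcome = np.array([1] * 30 + [0] * 30)  # column membership
        count = 0
        reps = 100_000
        rs = np.random.default_rng(99)
        for _ in range(reps):
            perm = rs.permutation(outcome)
            a = int(np.sum((labels == 0) & (perm == 1)))
            b = 30 - a
            c = int(np.sum((labels == 1) & (perm == 1)))
            d = 30 - c
            s = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            count += s >= stat - 1e-12
        perm_p = count / reps
        # chi-square(1) is the asymptotic null; agreement within MC noise + asymptotics
        assert abs(perm_p - p) < 0.01

    def test_degenerate_table_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2(ContingencyTable2x2(0, 5, 0, 5))

    def test_yates_switch_reduces_statistic(self):
        t = ContingencyTable2x2(20, 10, 10, 20)
        plain, _ = chi_square_2x2(t)
        yates, _ = chi_square_2x2(t, continuity_correction=True)
        assert yates < plain
        # cross-check both against scipy's contingency machinery
        obs = np.array([[20, 10], [10, 20]])
        assert plain == pytest.approx(
            stats.chi2_contingency(obs, correction=False).statistic, rel=1e-12
        )
        assert yates == pytest.approx(
            stats.chi2_contingency(obs, correction=True).statistic, rel=1e-12
        )


class TestBinomial:
    def test_zero_successes_p_one(self):
        assert binomial_enrichment(0, 100, 0.3).p_value == 1.0

    def test_all_successes_closed_form(self):
        res = binomial_enrichment(10, 10, 0.5)
        assert res.p_value == pytest.approx(2.0**-10, rel=1e-12)

    def test_matches_direct_summation(self, rng):
        """Upper tail equals direct pmf summation for n <= 1000."""
        for _ in range(200):
            n = int(rng.integers(1, 1_000))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.99))
            res = binomial_enrichment(k, n, p0)
            direct = float(sum(stats.binom.pmf(j, n, p0) for j in range(k, n + 1)))
            assert res.p_value == pytest.approx(min(direct, 1.0), rel=1e-9, abs=1e-300)

    def test_monotone_decreasing_in_k(self):
        ps = [binomial_enrichment(k, 50, 0.2).p_value for k in range(0, 51)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_extreme_tail_reported_in_log_space(self):
        # far beyond double-precision underflow for the plain tail
        res = binomial_enrichment(1_090, 7_413, 1_823 / 248_999)
        assert res.p_value == 0.0
        assert res.log10_p < -300
        assert math.isfinite(res.log10_p)

    def test_invalid_p0_errors(self):
        with pytest.raises(ValueError):
            binomial_enrichment(1, 10, 0.0)
        with pytest.raises(ValueError):
            binomial_enrichment(1, 10, 1.0)


class TestCuratedLists:
    def test_disjoint_hits(self):
        res, _ = curated_list_enrichment(
            ["a", "b"], ["x", "y"], ["a", "b", "x", "y", "z"]
        )
        assert res.observed_k == 0 and res.rate == 0.0

    def test_counts_and_table_construction(self):
        hits = [f"h{i}" for i in range(15)] + [f"c{i}" for i in range(5)]
        curated = [f"c{i}" for i in range(50)]
        universe = hits + [f"u{i}" for i in range(935)] + [f"c{i}" for i in range(5, 50)]
        res, table = curated_list_enrichment(hits, curated, universe)
        assert (res.observed_k, res.n) == (5, 20)
        assert res.rate == pytest.approx(0.25)
        assert (table.a, table.b, table.c, table.d) == (5, 15, 45, 935)
        # exact hypergeometric oracle: both routes flag the enrichment
        # (chi-square is asymptotic, so only order-of-magnitude agreement
        # is expected at counts this small)
        hyper_p = float(stats.hypergeom.sf(4, 1_000, 50, 20))
        assert res.p_value < 0.01 and hyper_p < 0.01

    def test_symbols_case_insensitive(self):
        res, _ = curated_list_enrichment(
            ["TP53 ", "myc"], ["tp53", "MYC"], ["TP53", "MYC", "EGFR", "KRAS"]
        )
        assert res.observed_k == 2

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            curated_list_enrichment(["a"], ["a"], [])

    def test_counts_form_matches_symbol_form(self):
        hits = [f"h{i}" for i in range(20)]
        curated = hits[:5] + [f"c{i}" for i in range(45)]
        universe = hits + [f"c{i}" for i in range(45)] + [f"u{i}" for i in range(935)]
        res_sym, t_sym = curated_list_enrichment(hits, curated, universe)
        res_cnt, t_cnt = curated_list_enrichment_from_counts(5, 20, 50, 1_000)
        assert t_sym == t_cnt
        assert res_sym.p_value == pytest.approx(res_cnt.p_value)

    def test_gene_list_io(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# curated\nTP53\n\nMYC\n")
        assert read_gene_list(p) == ["TP53", "MYC"]


class TestNullCalibrationAndPower:
    def test_type_one_error_controlled(self):
        """Uniform peaks vs random marks: fraction of binomial tests with
        p < alpha stays <= alpha + 3 sigma over 200 seeded runs."""
        genome = GenomeIndex({"chr1": 1_000_000})
        alpha = 0.05
        rejections = 0
        runs = 200
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            marks = [
                GenomicInterval("chr1", int(s), int(s) + 149)
                for s in rng.integers(0, 1_000_000 - 149, size=100)
            ]
            peaks = simulate_random_peaks(400, genome, seed=seed + 10_000)
            obs = mark_association(peaks, marks)
            # analytic background rate: standardized-mark coverage fraction
            covered = np.zeros(1_000_000, dtype=bool)
            for m in standardize_marks(marks):
                covered[m.start : m.end] = True
            p0 = covered.mean()
            res = binomial_enrichment(obs.observed_k, obs.n, p0)
            rejections += res.p_value < alpha
        sigma = math.sqrt(alpha * (1 - alpha) / runs)
        assert rejections / runs <= alpha + 3 * sigma

    def test_fold_ten_enrichment_always_detected(self):
        """Peaks drawn from a 10-fold mark-enriched landscape: binomial
        p < 1e-6 against a matched random null in 100/100 seeded runs."""
        import pandas as pd

        from apobreak.simulate import (
            SimConfig,
            build_cleavage_landscape,
            _sample_positions,
        )

        genome = GenomeIndex({"chr1": 1_000_000})
        empty_genes = pd.DataFrame(
            columns=["name", "chrom", "strand", "txStart", "txEnd",
                     "exonStarts", "exonEnds", "geneSymbol"]
        )
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            marks = [
                GenomicInterval("chr1", int(s), int(s) + 149)
                for s in rng.integers(0, 1_000_000 - 149, size=150)
            ]
            cfg = SimConfig(mark_enrichment_fold=10.0, seed=seed)
            land = build_cleavage_landscape(empty_genes, marks, cfg, genome)
            centers = _sample_positions(land, 5_000, rng)
            peaks = [
                Peak(GenomicInterval(c, max(0, p - 200), min(1_000_000, p + 200)),
                     summit=p, tag_count=1, p_value=1e-6)
                for c, p in centers
            ]
            obs = mark_association(peaks, marks)
            null = mark_association(
                simulate_random_peaks(5_000, genome, seed=seed + 50_000), marks
            )
            p0 = max(null.rate, 1.0 / 10_000)
            res = binomial_enrichment(obs.observed_k, obs.n, p0)
            detected += res.log10_p < -6
        assert detected == 100
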