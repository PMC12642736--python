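import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txrank.errors import ConsistencyError, ValidationError
from txrank.matrix import build_expression_matrix, compute_tpm
from txrank.stats import (
    GENE_TESTS,
    ISOFORM_TESTS,
    GeneBinCounts,
    allelic_imbalance_statistic,
    assign_bins,
    compute_all_statistics,
    cyclo_goe_statistic,
    nmd_rare_steady_state_statistic,
    nmd_statistic,
    noncyclo_goe_statistic,
    noncyclo_loe_statistic,
)
from tests.conftest import rec


class TestNmd:
    @pytest.mark.parametrize(
        "cyclo,noncyclo,expected",
        [
            (50, 50, 0.0),  # equal expression zeroes the log-ratio
            (7, 3, 3.169925),
            (3, 7, -2.321928),  # sign flips for destabilized features
        ],
    )
    def test_values(self, cyclo, noncyclo, expected):
        assert nmd_statistic(cyclo, noncyclo) == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_cyclo(self):
        grid = np.linspace(10, 1000, 200)
        vals = nmd_statistic(grid, 10.0)
        assert (np.diff(vals) >= 0).all()


class TestOutlierStatistics:
    @pytest.mark.parametrize(
        "fn,index,others,expected",
        [
            (noncyclo_loe_statistic, 64, [64, 100, 200], 0.0),
            (noncyclo_loe_statistic, 0, [64, 100, 200], 40.1838),
            (noncyclo_goe_statistic, 10, [5, 10, 3], 0.0),
            (noncyclo_goe_statistic, 100, [10, 5, 2], 8.98011),
            (noncyclo_goe_statistic, 0, [0, 0, 0], 0.0),
            (cyclo_goe_statistic, 63, [15, 14, 13], 8.0),
        ],
    )
    def test_values(self, fn, index, others, expected):
        assert fn(index, others) == pytest.approx(expected, abs=1e-4)

    def test_signs(self):
        assert noncyclo_loe_statistic(50, [10, 20, 30]) < 0  # above the min
        assert cyclo_goe_statistic(0, [1000, 500, 800]) < 0  # below the max

    def test_empty_context_rejected(self):
        with pytest.raises(ValidationError):
            noncyclo_loe_statistic(1.0, [])

    def test_monotone_in_index_expression(self):
        others = [5.0, 10.0, 3.0]
        grid = np.linspace(0, 500, 100)
        vals = [noncyclo_goe_statistic(x, others) for x in grid]
        assert (np.diff(vals) >= 0).all()


class TestBins:
    def test_threshold_is_strict_below_one_percent(self):
        # gene noncyclo total 1000; 9 reads -> rare bin, 10 reads -> common bin
        bins = assign_bins([9, 991], [0, 0])
        assert bins.noncyclo_bin1_count == 9
        bins = assign_bins([10, 990], [0, 0])
        assert bins.noncyclo_bin1_count == 0
        assert bins.noncyclo_bin2_count == 1000

    def test_assignment_uses_untreated_sample_only(self):
        # isoform absent untreated but abundant treated lands in bin 1
        bins = assign_bins([0, 200], [31, 269])
        assert bins.cyclo_bin1_count == 31
        assert bins.noncyclo_bin2_count == 200

    def test_zero_untreated_total_puts_everything_in_bin1(self):
        bins = assign_bins([0, 0], [40, 60])
        assert bins.cyclo_bin1_count == 100
        assert bins.noncyclo_bin2_count == 0

    def test_bin_partition_invariant(self):
        bins = assign_bins([3, 500, 7, 190], [1, 2, 3, 4])
        assert bins.noncyclo_bin1_count + bins.noncyclo_bin2_count == bins.noncyclo_total


class TestRareSteadyState:
    @pytest.mark.parametrize(
        "cb1,nb1,nb2,ct,nt,expected",
        [
            (0, 0, 200, 300, 200, 0.0),  # log2(0+1) factor kills the score
            (31, 0, 200, 300, 200, 3.9399),
        ],
    )
    def test_values(self, cb1, nb1, nb2, ct, nt, expected):
        bins = GeneBinCounts(cb1, nb1, nb2, ct, nt)
        assert nmd_rare_steady_state_statistic(bins) == pytest.approx(expected, abs=1e-4)

    def test_equal_proportions_vanish(self):
        # same totals and same rare-bin counts in both conditions
        bins = GeneBinCounts(25, 25, 175, 200, 200)
        assert nmd_rare_steady_state_statistic(bins) == 0.0


class TestAllelicImbalance:
    @pytest.mark.parametrize(
        "h1,h2,total,expected",
        [
            (20, 20, 40, 0.0),
            (30, 0, 30, 24.3097),
        ],
    )
    def test_values(self, h1, h2, total, expected):
        assert allelic_imbalance_statistic(h1, h2, total) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "h1,h2,total",
        [
            (4, 3, 100),  # 7 phased reads < 10
            (6, 5, 200),  # 11/200 phased fraction < 10%
            (0, 0, 50),
        ],
    )
    def test_filters(self, h1, h2, total):
        assert allelic_imbalance_statistic(h1, h2, total) is None

    def test_phased_exceeding_total_is_inconsistent(self):
        with pytest.raises(ConsistencyError):
            allelic_imbalance_statistic(30, 10, 20)

    @settings(max_examples=200, derandomize=True)
    @given(
        h1=st.integers(min_value=0, max_value=5_000),
        h2=st.integers(min_value=0, max_value=5_000),
        extra=st.integers(min_value=0, max_value=1_000),
    )
    def test_haplotype_swap_invariance(self, h1, h2, extra):
        total = h1 + h2 + extra
        a = allelic_imbalance_statistic(h1, h2, total)
        b = allelic_imbalance_statistic(h2, h1, total)
        if a is None:
            assert b is None
        else:
            assert a == pytest.approx(b, rel=1e-12)


class TestOracleEquivalence:
    """Each statistic matches a direct, independently coded transcription of
    its defining formula on randomized inputs."""

    def test_all_statistics_match_direct_transcriptions(self):
        rng = np.random.default_rng(2024)
        n = 1_000
        log2 = np.log2
        for _ in range(n):
            c, nc = rng.uniform(0, 1e5, 2)
            others = rng.uniform(0, 1e5, rng.integers(2, 12))
            expected = log2((c + 1) / (nc + 1)) * log2(c + 2)
            assert nmd_statistic(c, nc) == pytest.approx(expected, rel=1e-9, abs=1e-12)

            expected = log2((others.min() + 1) / (nc + 1)) * log2(np.median(others) + 2)
            assert noncyclo_loe_statistic(nc, others) == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )
            expected = log2((nc + 1) / (others.max() + 1)) * log2(np.median(others) + 2)
            assert noncyclo_goe_statistic(nc, others) == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )
            expected = log2((c + 1) / (others.max() + 1)) * log2(np.median(others) + 2)
            assert cyclo_goe_statistic(c, others) == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )

            cb1, nb1, nb2, ct = rng.integers(0, 10_000, 4)
            nt = nb1 + nb2
            bins = GeneBinCounts(int(cb1), int(nb1), int(nb2), int(ct), int(nt))
            expected = (cb1 / (ct + 1) - nb1 / (nt + 1)) * log2(cb1 + 1) * log2(nb2 + 1)
            assert nmd_rare_steady_state_statistic(bins) == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )

            h1, h2 = rng.integers(0, 5_000, 2)
            total = h1 + h2 + rng.integers(0, 1_000)
            got = allelic_imbalance_statistic(int(h1), int(h2), int(total))
            phased = h1 + h2
            if phased < 10 or (total > 0 and phased / total < 0.10):
                assert got is None
            else:
                expected = abs(log2((h1 + 1) / (h2 + 1))) * log2(phased)
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)


@pytest.fixture(scope="module")
def cohort():
    rows = []
    rng = np.random.default_rng(7)
    for ind in ("A", "B", "C"):
        for gene, isoforms in (("g1", ["i1", "i2"]), ("g2", ["i3"])):
            for iso in isoforms:
                for cond in ("cyclo", "noncyclo"):
                    for hap in ("H1", "H2", "unphased"):
                        rows.append(rec(iso, gene, ind, cond, hap, int(rng.integers(0, 200))))
    matrix = compute_tpm(build_expression_matrix(pd.DataFrame(rows)))
    return matrix, compute_all_statistics(matrix)


class TestComputeAll:
    def test_roster(self, cohort):
        _, stats = cohort
        gene_tests = set(stats.loc[stats["level"] == "gene", "test"])
        iso_tests = set(stats.loc[stats["level"] == "isoform", "test"])
        assert gene_tests == set(GENE_TESTS)
        assert iso_tests == set(ISOFORM_TESTS)
        assert "NMD_rare_steady_state" not in iso_tests

    def test_every_feature_individual_scored(self, cohort):
        matrix, stats = cohort
        counts = stats.groupby(["test", "level"]).size()
        n_ind = len(matrix.individuals)
        for (test, level), n in counts.items():
            n_feat = len(matrix.counts(level))
            assert n == n_feat * n_ind

    def test_matches_scalar_operations(self, cohort):
        matrix, stats = cohort
        inds = matrix.individuals
        gene_tpm = matrix.gene_tpm
        gene_stats = stats[stats["level"] == "gene"]
        sample = gene_stats.sample(min(40, len(gene_stats)), random_state=0)
        for _, row in sample.iterrows():
            ind, feat = row["individual_id"], row["feature_id"]
            c = gene_tpm.loc[feat, (ind, "cyclo")]
            n = gene_tpm.loc[feat, (ind, "noncyclo")]
            others_n = [gene_tpm.loc[feat, (j, "noncyclo")] for j in inds if j != ind]
            others_c = [gene_tpm.loc[feat, (j, "cyclo")] for j in inds if j != ind]
            if row["test"] == "NMD":
                expected = nmd_statistic(c, n)
            elif row["test"] == "noncyclo_LOE":
                expected = noncyclo_loe_statistic(n, others_n)
            elif row["test"] == "noncyclo_GOE":
                expected = noncyclo_goe_statistic(n, others_n)
            elif row["test"] == "cyclo_GOE":
                expected = cyclo_goe_statistic(c, others_c)
            elif row["test"] == "allelic_imbalance":
                hap = matrix.gene_hap
                expected = allelic_imbalance_statistic(
                    int(hap.loc[feat, (ind, "h1")]),
                    int(hap.loc[feat, (ind, "h2")]),
                    int(hap.loc[feat, (ind, "total")]),
                )
                if expected is None:
                    assert np.isnan(row["statistic"]) and row["filtered"]
                    continue
            else:  # NMD_rare_steady_state via the scalar bin pathway
                iso = matrix.iso_to_gene.index[matrix.iso_to_gene == feat]
                ncounts = matrix.isoform_counts.loc[iso, (ind, "noncyclo")].to_numpy()
                ccounts = matrix.isoform_counts.loc[iso, (ind, "cyclo")].to_numpy()
                expected = nmd_rare_steady_state_statistic(assign_bins(ncounts, ccounts))
            assert row["statistic"] == pytest.approx(float(expected), rel=1e-9, abs=1e-9)

    def test_filter_correctness(self, cohort):
        matrix, stats = cohort
        ai = stats[(stats["test"] == "allelic_imbalance")]
        for _, row in ai.iterrows():
            hap = matrix.hap(row["level"])
            h1 = int(hap.loc[row["feature_id"], (row["individual_id"], "h1")])
            h2 = int(hap.loc[row["feature_id"], (row["individual_id"], "h2")])
            tot = int(hap.loc[row["feature_id"], (row["individual_id"], "total")])
            phased = h1 + h2
            should_score = phased >= 10 and (tot > 0 and phased / tot >= 0.10)
            assert bool(row["filtered"]) is (not should_score)
            assert bool(np.isfinite(row["statistic"])) is should_score

    def test_two_individuals_is_minimum_cohort(self):
        rows = [
            rec("i1", "g1", "A", "cyclo", "H1", 5),
            rec("i1", "g1", "A", "noncyclo", "H1", 5),
        ]
        matrix = compute_tpm(build_expression_matrix(pd.DataFrame(rows)))
        with pytest.raises(ValidationError):
            compute_all_statistics(matrix)
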