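import numpy as np
import pytest
from scipy import stats

from stratqtl.association import (
    AlleleCounts2x2,
    allelic_chisq,
    assoc_test,
    chisq_p,
    hwe_test,
    minor_allele_and_counts,
    qc_filter,
    qt_linear_assoc,
)
from stratqtl.io_formats import MISSING_CALL
from stratqtl import synthetic_data

from conftest import make_dataset


class TestMinorAlleleAndCounts:
    def test_tie_breaks_lexicographically(self):
        # calls count allele G ("allele_b"); 4 of 8 alleles are G -> tie
        ds = make_dataset([[0], [1], [1], [2]], ["case", "case", "control", "control"])
        a1, a2, counts = minor_allele_and_counts(
            ds, ds.case_indices, ds.control_indices, 0
        )
        assert (a1, a2) == ("A", "G")

    def test_all_missing_is_an_error(self):
        ds = make_dataset([[MISSING_CALL], [MISSING_CALL]], ["case", "control"])
        with pytest.raises(ValueError, match="missing"):
            minor_allele_and_counts(ds, ds.case_indices, ds.control_indices, 0)

    def test_counts_match_brute_force_tally(self, rng):
        calls = rng.integers(-1, 3, size=(20, 4)).astype(np.int8)
        statuses = ["case"] * 9 + ["control"] * 11
        ds = make_dataset(calls, statuses)
        for j in range(4):
            col = calls[:, j]
            if (col != MISSING_CALL).sum() == 0:
                continue
            a1, a2, counts = minor_allele_and_counts(
                ds, ds.case_indices, ds.control_indices, j
            )
            # brute force: count allele tokens per person
            tallies = {"case": {"A": 0, "G": 0}, "control": {"A": 0, "G": 0}}
            for i, status in enumerate(statuses):
                if col[i] == MISSING_CALL:
                    continue
                tallies[status]["G"] += int(col[i])
                tallies[status]["A"] += 2 - int(col[i])
            total = sum(sum(t.values()) for t in tallies.values())
            freq = {
                al: (tallies["case"][al] + tallies["control"][al]) / total
                for al in "AG"
            }
            expect_a1 = min(sorted(freq), key=lambda al: (freq[al], al))
            assert a1 == expect_a1
            assert counts.case_minor == tallies["case"][a1]
            assert counts.case_major == tallies["case"][a2]
            assert counts.control_minor == tallies["control"][a1]
            assert counts.control_major == tallies["control"][a2]
            n_case_nonmiss = sum(
                1 for i, s in enumerate(statuses) if s == "case" and col[i] != MISSING_CALL
            )
            assert counts.case_minor + counts.case_major == 2 * n_case_nonmiss


class TestAllelicChisq:
    def test_proportional_counts_are_null(self):
        res = allelic_chisq(AlleleCounts2x2(10, 30, 20, 60))
        assert res["chisq"] == pytest.approx(0.0, abs=1e-12)
        assert res["or_a1"] == pytest.approx(1.0)
        assert res["p_unadj"] == pytest.approx(1.0)

    def test_matches_observed_expected_formula(self, rng):
        """N(ad-bc)^2/margins equals the textbook sum over 4 cells of (O-E)^2/E."""
        for _ in range(200):
            a, b, c, d = rng.integers(1, 200, size=4)
            res = allelic_chisq(AlleleCounts2x2(a, b, c, d))
            table = np.array([[a, b], [c, d]], dtype=float)
            rowsum = table.sum(axis=1, keepdims=True)
            colsum = table.sum(axis=0, keepdims=True)
            expected = rowsum * colsum / table.sum()
            oracle = ((table - expected) ** 2 / expected).sum()
            assert res["chisq"] == pytest.approx(oracle, abs=1e-10)
            # and scipy's uncorrected Pearson test agrees
            sp = stats.chi2_contingency(table, correction=False)
            assert res["chisq"] == pytest.approx(sp.statistic, abs=1e-10)
            assert res["p_unadj"] == pytest.approx(sp.pvalue, abs=1e-12)

    def test_published_moderate_subtype_row(self):
        """Allele counts rebuilt from printed MAFs reproduce the printed OR and chi-square."""
        # 363 cases at minor-allele frequency 0.256, 2438 controls at 0.326
        a = round(2 * 363 * 0.256)
        c = round(2 * 2438 * 0.326)
        counts = AlleleCounts2x2(a, 2 * 363 - a, c, 2 * 2438 - c)
        res = allelic_chisq(counts)
        assert res["or_a1"] == pytest.approx(0.71, abs=0.01)
        assert res["chisq"] == pytest.approx(14.2, rel=0.05)

    def test_allele_swap_inverts_or_and_preserves_chisq(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            res = allelic_chisq(AlleleCounts2x2(a, b, c, d))
            swapped = allelic_chisq(AlleleCounts2x2(b, a, d, c))
            assert swapped["or_a1"] == pytest.approx(1 / res["or_a1"])
            assert swapped["chisq"] == pytest.approx(res["chisq"], abs=1e-10)
            assert swapped["p_unadj"] == pytest.approx(res["p_unadj"], abs=1e-12)

    def test_zero_cell_or_undefined_unless_haldane(self):
        counts = AlleleCounts2x2(0, 100, 10, 90)
        assert np.isnan(allelic_chisq(counts)["or_a1"])
        hal = allelic_chisq(counts, haldane=True)["or_a1"]
        assert np.isfinite(hal) and hal > 0

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            allelic_chisq(AlleleCounts2x2(0, 0, 10, 90))
        with pytest.raises(ValueError, match="margin"):
            allelic_chisq(AlleleCounts2x2(0, 10, 0, 90))


class TestChisqP:
    def test_zero_statistic_gives_p_one(self):
        assert chisq_p(0.0) == 1.0

    @pytest.mark.parametrize(
        "chisq,expected",
        [(13.71, 0.0002), (7.61, 0.0058)],
    )
    def test_published_values_at_4dp(self, chisq, expected):
        assert round(chisq_p(chisq, 1), 4) == expected

    def test_monotone_decreasing(self):
        grid = np.linspace(0, 30, 50)
        p = [chisq_p(x, 1) for x in grid]
        assert all(p[i] > p[i + 1] for i in range(len(p) - 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chisq_p(-1.0)
        with pytest.raises(ValueError):
            chisq_p(1.0, 0)


class TestQTLinearAssoc:
    def test_constant_trait(self):
        res = qt_linear_assoc([0, 1, 2, 1], [5.0, 5.0, 5.0, 5.0])
        assert res.beta == 0.0 and res.p_unadj == 1.0

    def test_exact_additive_fit(self):
        res = qt_linear_assoc([0, 1, 2], [1.0, 3.0, 5.0])
        assert res.beta == pytest.approx(2.0, abs=1e-12)

    def test_monomorphic_is_untestable(self):
        res = qt_linear_assoc([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])
        assert not res.testable

    def test_missing_pairs_dropped(self):
        res = qt_linear_assoc(
            [0, 1, 2, MISSING_CALL, 0], [1.0, 3.0, 5.0, 9.0, np.nan]
        )
        assert res.n_used == 3
        assert res.beta == pytest.approx(2.0, abs=1e-12)

    def test_p_close_to_permutation_oracle(self):
        """The t-based p agrees with a 10,000-draw permutation p at n=50."""
        rng = np.random.default_rng(42)
        g = rng.binomial(2, 0.3, size=50).astype(float)
        y = 0.3 * g + rng.normal(0, 2.0, size=50)
        res = qt_linear_assoc(g, y)
        # permutation null of |slope| under shuffled traits
        n_perm = 10_000
        gc = g - g.mean()
        denom = (gc**2).sum()
        observed = abs((gc * (y - y.mean())).sum() / denom)
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            slope = abs((gc * (yp - yp.mean())).sum() / denom)
            if slope >= observed - 1e-15:
                count += 1
        p_perm = count / n_perm
        assert res.p_unadj == pytest.approx(p_perm, rel=0.10)


class TestHWE:
    def test_perfect_equilibrium(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_maximal_disequilibrium(self):
        assert hwe_test(50, 0, 50) < 1e-20

    def test_matches_expected_count_formula(self):
        hom_a, het, hom_b = 12, 40, 48
        n = hom_a + het + hom_b
        p = (2 * hom_a + het) / (2 * n)
        q = 1 - p
        exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
        obs = np.array([hom_a, het, hom_b])
        oracle = stats.chi2.sf(((obs - exp) ** 2 / exp).sum(), 1)
        assert hwe_test(hom_a, het, hom_b) == pytest.approx(oracle, abs=1e-10)

    def test_monomorphic_sample_is_in_equilibrium(self):
        assert hwe_test(100, 0, 0) == 1.0


class TestQCFilter:
    def test_missingness_rule(self):
        calls = np.ones((100, 1), dtype=np.int8)
        calls[:11, 0] = MISSING_CALL  # 11% missing
        ds = make_dataset(calls, ["case"] * 50 + ["control"] * 50)
        filtered, report = qc_filter(ds)
        assert filtered.n_variants == 0
        assert "missingness" in report["rs1"]

    def test_low_maf_rule(self):
        rng = np.random.default_rng(0)
        calls = np.zeros((1000, 1), dtype=np.int8)
        carriers = rng.choice(1000, size=18, replace=False)
        calls[carriers, 0] = 1  # MAF 0.009
        ds = make_dataset(calls, ["case"] * 500 + ["control"] * 500)
        filtered, report = qc_filter(ds)
        assert "maf" in report["rs1"]

    def test_hwe_rule_evaluated_in_controls_only(self):
        # controls in perfect HWE; cases wildly out of it -> SNP kept
        case_calls = np.array([0] * 50 + [2] * 50, dtype=np.int8)
        ctrl_calls = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)
        calls = np.concatenate([case_calls, ctrl_calls])[:, None]
        ds = make_dataset(calls, ["case"] * 100 + ["control"] * 100)
        filtered, report = qc_filter(ds)
        assert filtered.n_variants == 1 and report == {}
        # and the reverse: out-of-HWE controls are excluded
        calls2 = np.concatenate([ctrl_calls, case_calls])[:, None]
        ds2 = make_dataset(calls2, ["case"] * 100 + ["control"] * 100)
        _, report2 = qc_filter(ds2)
        assert "hwe" in report2["rs1"]

    def test_hwe_false_positive_rate_calibrated(self):
        """On HWE-true data ~0.1% of SNPs fail the HWE rule (within 3 SE)."""
        config = synthetic_data.SimulationConfig(
            n_cases_per_subtype=(5, 5, 5, 5),
            n_controls=1000,
            n_snps=1000,
            maf_range=(0.2, 0.5),
            seed=77,
        )
        ds, _ = synthetic_data.simulate_genotypes(config)
        _, report = qc_filter(ds, min_maf=0.001)
        n_hwe = sum("hwe" in reasons for reasons in report.values())
        # Binomial(1000, 0.001): mean 1, 3 SE ~ 3
        assert n_hwe <= 4

    def test_thresholds_validated(self):
        ds = make_dataset([[0], [1]], ["case", "control"])
        with pytest.raises(ValueError):
            qc_filter(ds, max_missing=0.0)


def test_assoc_test_end_to_end(rng):
    calls = rng.binomial(2, 0.3, size=(200, 1)).astype(np.int8)
    ds = make_dataset(calls, ["case"] * 100 + ["control"] * 100)
    row = assoc_test(ds, ds.case_indices, ds.control_indices, 0)
    assert 0 <= row.f_a <= 0.5 + 1e-12 and 0 <= row.f_u <= 1
    assert row.p_unadj == pytest.approx(chisq_p(row.chisq, 1))
    assert row.n_case_used == 100 and row.n_control_used == 100
    # OR recomputed from the row frequencies matches the reported OR
    odds = (row.f_a / (1 - row.f_a)) / (row.f_u / (1 - row.f_u))
    assert row.or_a1 == pytest.approx(odds, abs=1e-12)
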