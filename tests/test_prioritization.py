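"""MAF gate, Weir-Cockerham Fst, chi-square + Bonferroni, and the combined
prioritisation scan with its power/false-positive behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitipop import (
    PopulationSpec,
    SimulationConfig,
    allele_frequencies,
    bonferroni_adjust,
    chi_square_test,
    maf_filter,
    prioritize,
    simulate_cohort,
    wc_fst,
)
from vitipop.prioritization import Thresholds


def freq_table(rows):
    """rows: (variant, group, maf)"""
    return pd.DataFrame(
        [
            {"variant": v, "group": g, "n_chromosomes": 100,
             "alt_count": int(100 * (1 - m)), "alt_freq": 1 - m, "maf": m}
            for v, g, m in rows
        ]
    )


class TestMafFilter:
    def test_threshold_is_inclusive(self):
        # alt freq 0.95 in every group -> MAF exactly 0.05, retained
        ft = freq_table([(0, "A", 0.05), (0, "B", 0.05)])
        assert maf_filter(ft, 0.05, "all_groups") == {0}

    def test_all_groups_mode_drops_on_any_failure(self):
        ft = freq_table([(0, "A", 0.05), (0, "B", 0.03)])
        assert maf_filter(ft, 0.05, "all_groups") == set()
        assert maf_filter(ft, 0.05, "any_group") == {0}

    def test_target_group_mode(self):
        ft = freq_table([(0, "SAS", 0.03), (0, "EUR", 0.4),
                         (1, "SAS", 0.2), (1, "EUR", 0.01)])
        assert maf_filter(ft, 0.05, "target_group", target_group="SAS") == {1}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            maf_filter(freq_table([(0, "A", 0.1)]), mode="bogus")

    def test_matches_naive_recount(self, two_pop_cohort):
        gm, panel, _ = two_pop_cohort
        ft = allele_frequencies(gm, panel, level="sub")
        kept = maf_filter(ft, 0.05, "all_groups")
        # independent oracle: recompute MAF per group from raw dosages
        expected = set()
        for v in range(gm.n_variants):
            ok = True
            for _, samples in panel.groups("sub").items():
                cols = [gm.sample_ids.index(s) for s in samples]
                f = gm.dosages[v, cols].mean() / 2
                if min(f, 1 - f) < 0.05:
                    ok = False
            if ok:
                expected.add(v)
        assert kept == expected


class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        r = wc_fst([50, 50], [1.0, 0.0], [0.0, 0.0])
        assert r.a == pytest.approx(0.5)
        assert r.b == pytest.approx(0.0, abs=1e-12)
        assert r.c == 0.0
        assert r.theta == pytest.approx(1.0)

    def test_equal_frequencies_give_small_nonpositive_theta(self):
        p = 0.4
        r = wc_fst([80, 80], [p, p], [2 * p * (1 - p)] * 2)
        assert r.theta <= 0

    def test_symmetry_under_population_swap(self):
        a = wc_fst([30, 70], [0.2, 0.6], [0.3, 0.45])
        b = wc_fst([70, 30], [0.6, 0.2], [0.45, 0.3])
        assert a.theta == b.theta

    def test_monomorphic_everywhere_is_undefined(self):
        r = wc_fst([50, 50], [0.0, 0.0], [0.0, 0.0])
        assert not r.defined

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            wc_fst([1, 50], [0.5, 0.5], [0.5, 0.5])

    def test_hwe_fallback_matches_observed_het_at_hwe(self):
        n, p = [60, 60], [0.3, 0.7]
        h = [2 * 0.3 * 0.7, 2 * 0.7 * 0.3]
        assert wc_fst(n, p, h).theta == pytest.approx(wc_fst(n, p).theta)


class TestChiSquare:
    def test_observed_equal_expected(self):
        r = chi_square_test((30, 70, 30, 70))
        assert r.statistic == 0.0 and r.p == 1.0

    def test_strong_departure(self):
        # all expected counts are 50; 4 cells x 40^2/50
        r = chi_square_test((90, 10, 10, 90))
        assert r.statistic == pytest.approx(128.0)
        assert np.allclose(r.expected, 50.0)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_test((0, 0, 5, 5))

    @given(st.integers(1, 200), st.integers(1, 200),
           st.integers(1, 200), st.integers(1, 200))
    @settings(deadline=None, max_examples=100)
    def test_matches_textbook_formula(self, a, b, c, d):
        # independent oracle: explicit margin products, no matrix algebra
        n = a + b + c + d
        exp = [
            (a + b) * (a + c) / n, (a + b) * (b + d) / n,
            (c + d) * (a + c) / n, (c + d) * (b + d) / n,
        ]
        stat = sum((o - e) ** 2 / e for o, e in zip((a, b, c, d), exp))
        r = chi_square_test((a, b, c, d))
        assert r.statistic == pytest.approx(stat, abs=1e-10, rel=1e-10)
        assert r.statistic >= 0

    def test_agrees_with_fisher_calls_on_large_balanced_tables(self):
        # same alpha=0.05 decisions as Fisher's exact in the asymptotic
        # regime (large balanced null tables, all expected counts >= 20)
        from vitipop import fisher_exact

        rng = np.random.default_rng(0)
        agree = total = 0
        for _ in range(1000):
            n1 = n2 = 500
            p = rng.uniform(0.3, 0.7)
            a = rng.binomial(n1, p)
            c = rng.binomial(n2, p)
            t = (int(a), int(n1 - a), int(c), int(n2 - c))
            r = chi_square_test(t)
            if min(r.expected.ravel()) < 20:
                continue
            total += 1
            agree += (r.p <= 0.05) == (fisher_exact(t) <= 0.05)
        assert total > 900
        assert agree / total >= 0.99


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.001, 100, 0.1), (0.5, 10, 1.0),
                                              (0.03, 1, 0.03)])
    def test_formula(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.1, 0)


def planted_cohort(seed=17):
    """2000 neutral SNPs at F=0.02 plus 20 planted at exactly 0.9 vs 0.1,
    n=200 per population."""
    from vitipop.simulate import concat_cohorts

    pops = [PopulationSpec("A", "A", 200), PopulationSpec("B", "B", 200)]
    neutral_cfg = SimulationConfig(
        populations=pops, n_snps=2000, ancestral_freq=(0.1, 0.9),
        fst=0.02, seed=seed,
    )
    planted_cfg = SimulationConfig(
        populations=pops, n_snps=20, ancestral_freq=[0.5] * 20, fst=0.0,
        planted_shifts=[(i, "A", 0.4) for i in range(20)]
        + [(i, "B", -0.4) for i in range(20)],
        seed=seed + 1, chrom="chr2",
    )
    neutral, panel, _ = simulate_cohort(neutral_cfg)
    planted, _, _ = simulate_cohort(planted_cfg)
    gm = concat_cohorts(neutral, planted)
    return gm, panel, set(range(2000, 2020))


class TestPrioritize:
    def test_recovers_planted_differentiated_snps(self):
        gm, panel, planted = planted_cohort()
        hits = prioritize(gm, panel, [("A", "B")], level="super")
        found = set(hits["variant"])
        assert len(found & planted) >= 18
        assert len(found - planted) <= 1

    def test_identical_populations_yield_nothing(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec("A", "A", 100), PopulationSpec("B", "B", 100)],
            n_snps=300, fst=0.0, seed=4,
        )
        gm, panel, _ = simulate_cohort(cfg)
        hits = prioritize(gm, panel, [("A", "B")], level="super")
        assert hits.empty

    def test_thresholds_recorded_in_metadata(self):
        gm, panel, _ = planted_cohort()
        hits = prioritize(gm, panel, [("A", "B")], level="super")
        th = hits.attrs["thresholds"]
        assert th["maf_min"] == 0.05 and th["fst_min"] == 0.5 and th["alpha"] == 0.05

    def test_raising_thresholds_never_adds_snps(self):
        gm, panel, _ = planted_cohort()
        base = set(prioritize(gm, panel, [("A", "B")], level="super")["variant"])
        for th in (
            Thresholds(maf_min=0.2), Thresholds(fst_min=0.7), Thresholds(alpha=0.001)
        ):
            stricter = set(
                prioritize(gm, panel, [("A", "B")], thresholds=th, level="super")["variant"]
            )
            assert stricter <= base

    def test_audit_trail_consistent_with_gates(self):
        gm, panel, _ = planted_cohort()
        audit = prioritize(gm, panel, [("A", "B")], level="super", audit=True)
        assert len(audit) == gm.n_variants
        expected = audit["pass_maf"] & audit["pass_fst"] & audit["pass_chi2"]
        assert (audit["prioritised"] == expected).all()

    def test_audit_matches_independent_gate_recomputation(self):
        gm, panel, _ = planted_cohort()
        audit = prioritize(gm, panel, [("A", "B")], level="super", audit=True)
        # brute-force oracle: apply the three gates independently per variant
        from scipy.stats import chi2 as chi2_dist

        cols_a = gm.sample_indices(panel.groups("super")["A"])
        cols_b = gm.sample_indices(panel.groups("super")["B"])
        m = int(audit["m_tests"].iloc[0])
        for v in np.random.default_rng(0).choice(gm.n_variants, 40, replace=False):
            da, db = gm.dosages[v, cols_a], gm.dosages[v, cols_b]
            pa, pb = da.mean() / 2, db.mean() / 2
            maf_ok = min(pa, 1 - pa) >= 0.05 and min(pb, 1 - pb) >= 0.05
            fst = wc_fst(
                [len(da), len(db)], [pa, pb],
                [(da == 1).mean(), (db == 1).mean()],
            ).theta
            row = audit[audit["variant"] == v].iloc[0]
            assert row["pass_maf"] == maf_ok
            assert row["fst"] == pytest.approx(fst, nan_ok=True)
            if not np.isnan(fst):
                assert row["pass_fst"] == (fst >= 0.5)
            t = (int(da.sum()), int(2 * len(da) - da.sum()),
                 int(db.sum()), int(2 * len(db) - db.sum()))
            try:
                stat = chi_square_test(t).statistic
                p_b = min(1.0, m * float(chi2_dist.sf(stat, 1)))
                assert row["chi2"] == pytest.approx(stat)
                assert row["pass_chi2"] == (p_b <= 0.05)
            except ValueError:
                assert np.isnan(row["chi2"])
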