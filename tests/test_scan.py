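import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tagseq import (
    SynthConfig,
    TagAssociation,
    bh_adjust,
    compare_scans,
    simulate_dataset,
    tag_scan,
)

from oracles import oracle_bh, oracle_overlap_patterns

pvector = st.lists(
    st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60
)


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03, abs=1e-15)

    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    @given(pvector)
    def test_matches_quadratic_oracle(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), oracle_bh(pvals), atol=1e-12
        )

    @given(pvector)
    def test_never_decreases_input_or_under_readjustment(self, pvals):
        # note: step-up adjustment is NOT idempotent (e.g. [1.0, 0.25]
        # adjusts to [1.0, 0.5], which re-adjusts to [1.0, 1.0]); what does
        # hold is that adjusting never lowers any value
        adjusted = bh_adjust(pvals)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-15)
        assert np.all(bh_adjust(adjusted) >= adjusted - 1e-15)

    def test_nan_passthrough_excluded_from_m(self):
        adjusted = bh_adjust([0.01, np.nan, 0.02, 0.03])
        assert np.isnan(adjusted[1])
        np.testing.assert_allclose(
            adjusted[[0, 2, 3]], bh_adjust([0.01, 0.02, 0.03]), atol=1e-15
        )

    def test_out_of_range_raises_with_index(self):
        with pytest.raises(ValueError, match="index 2"):
            bh_adjust([0.1, 0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        pvals = rng.uniform(size=200)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(pvals), ref, atol=1e-12)


@pytest.fixture(scope="module")
def covariate_dataset():
    counts, phenotype, truth = simulate_dataset(
        SynthConfig(n_genes=120, n_samples=35, n_tags=4, seed=21,
                    binary_covariate_effect=2.0,
                    continuous_covariate_effect=1.0)
    )
    return counts, phenotype, truth


class TestScanMatchesPerGeneFits:
    """The batched scan must reproduce the reference per-gene code path."""

    @pytest.mark.parametrize("method", ["ols", "huber"])
    def test_with_covariates(self, covariate_dataset, method):
        counts, phenotype, _ = covariate_dataset
        model = TagAssociation.from_counts(
            counts, phenotype, covariates=["sex", "age"])
        table = model.fit(method=method, adjust="none").table
        rng = np.random.default_rng(1)
        for gene in rng.choice(counts.index, size=15, replace=False):
            fit = model.fit_gene(gene, method=method)
            row = table.loc[gene]
            assert row["beta1"] == pytest.approx(fit.beta1, rel=1e-8, abs=1e-10)
            assert row["se_beta1"] == pytest.approx(fit.se_beta1, rel=1e-8)
            assert row["statistic"] == pytest.approx(fit.statistic, rel=1e-8)
            assert row["pvalue"] == pytest.approx(fit.pvalue, rel=1e-6, abs=1e-12)
            if method == "huber":
                assert row["n_iter"] == fit.n_iter
                assert bool(row["converged"]) == fit.converged


class TestTagScan:
    def test_recovers_strong_drivers_with_controlled_fdr(self):
        # one strong driver per dataset (marginal trait-driver correlation
        # ~0.7, t ~ 8) pooled over many datasets so the empirical false
        # discovery proportion has enough calls to be stable
        n_found = n_tags = n_called = n_false = 0
        for rep in range(40):
            counts, phenotype, truth = simulate_dataset(
                SynthConfig(n_genes=500, n_samples=89, n_tags=1,
                            effect_size=3.0, seed=300 + rep)
            )
            res = tag_scan(_expr(counts), phenotype, method="ols",
                           alpha=0.1, adjust="fdr")
            called = set(res.significant_genes())
            tags = set(truth.tag_genes)
            n_found += len(called & tags)
            n_tags += len(tags)
            n_called += len(called)
            n_false += len(called - tags)
        assert n_found / n_tags > 0.8
        assert n_false / max(n_called, 1) < 0.2

    def test_null_data_calls_near_alpha(self):
        counts, phenotype, _ = simulate_dataset(
            SynthConfig(n_genes=2000, n_samples=89, n_tags=0,
                        effect_size=0.0, seed=32)
        )
        res = tag_scan(_expr(counts), phenotype, method="ols",
                       alpha=0.05, adjust="none")
        assert abs(res.n_significant - 100) <= 30

    def test_rerun_is_byte_identical(self, tmp_path, small_dataset):
        counts, phenotype, _ = small_dataset
        for method in ("ols", "huber"):
            paths = []
            for run in (1, 2):
                model = TagAssociation.from_counts(counts, phenotype)
                res = model.fit(method=method)
                out = tmp_path / f"{method}_{run}.tsv"
                res.to_tsv(out)
                paths.append(out.read_bytes())
            assert paths[0] == paths[1]

    def test_gene_order_does_not_change_values(self, small_dataset):
        counts, phenotype, _ = small_dataset
        expr = _expr(counts)
        shuffled = expr.sample(frac=1.0, random_state=9)
        r1 = tag_scan(expr, phenotype, method="huber").table
        r2 = tag_scan(shuffled, phenotype, method="huber").table
        for col in ("beta1", "se_beta1", "statistic", "pvalue", "fdr"):
            pd.testing.assert_series_equal(
                r1[col].sort_index(), r2[col].sort_index(), atol=1e-12,
                rtol=1e-12,
            )

    def test_huber_with_huge_k_equals_ols_scan(self, small_dataset):
        counts, phenotype, _ = small_dataset
        model = TagAssociation.from_counts(counts, phenotype)
        ols = model.fit(method="ols").table
        hub = model.fit(method="huber", k=1e6).table
        for col in ("beta1", "se_beta1", "statistic", "pvalue", "fdr"):
            np.testing.assert_allclose(
                hub[col].sort_index(), ols[col].sort_index(),
                rtol=1e-6, atol=1e-9,
            )

    def test_flagged_gene_does_not_abort_scan(self, small_dataset):
        counts, phenotype, _ = small_dataset
        expr = _expr(counts)
        expr.iloc[0] = 3.14  # constant expression: unusable design
        res = tag_scan(expr, phenotype)
        row = res.table.loc[expr.index[0]]
        assert bool(row["flagged"])
        assert np.isnan(row["pvalue"])
        assert res.table["flagged"].sum() == 1

    def test_fdr_column_invariants(self, small_dataset):
        counts, phenotype, _ = small_dataset
        table = tag_scan(_expr(counts), phenotype).table
        clean = table.dropna(subset=["pvalue"])
        assert np.all(clean["fdr"] >= clean["pvalue"] - 1e-15)
        # ordered by ascending p-value, fdr must be non-decreasing
        assert np.all(np.diff(clean["fdr"].to_numpy()) >= -1e-15)

    def test_summary_reports_counts(self, small_dataset):
        counts, phenotype, _ = small_dataset
        res = TagAssociation.from_counts(counts, phenotype).fit()
        text = res.summary()
        assert "method:       ols" in text
        assert f"significant:  {res.n_significant}" in text


def _expr(counts):
    from tagseq import log2_cpm, tmm_factors

    return log2_cpm(counts, tmm_factors(counts))


class TestNormalityScreen:
    def test_gaussian_noise_rarely_rejected(self):
        # independent single-gene datasets; trait noise is Gaussian
        rng = np.random.default_rng(41)
        rejected = 0
        n_repeats = 200
        for rep in range(n_repeats):
            expr = pd.DataFrame(
                rng.normal(size=(1, 89)),
                index=["g"], columns=[f"s{i}" for i in range(89)])
            phenotype = pd.DataFrame(
                {"trait": rng.normal(size=89)}, index=expr.columns)
            screen = TagAssociation(expr, phenotype).check_normality()
            rejected += int(screen.table["pvalue"].iloc[0] < 0.05)
        assert rejected / n_repeats < 0.08  # ~5% expected under H0

    def test_heavy_tailed_noise_detected(self):
        rng = np.random.default_rng(42)
        rejected = 0
        n_repeats = 100
        for rep in range(n_repeats):
            expr = pd.DataFrame(
                rng.normal(size=(1, 89)),
                index=["g"], columns=[f"s{i}" for i in range(89)])
            phenotype = pd.DataFrame(
                {"trait": rng.standard_t(1, size=89)}, index=expr.columns)
            screen = TagAssociation(expr, phenotype).check_normality()
            rejected += int(screen.table["pvalue"].iloc[0] < 0.05)
        assert rejected / n_repeats > 0.9

    def test_clean_synthetic_dataset_passes_screen(self, default_dataset):
        counts, phenotype, _ = default_dataset
        model = TagAssociation.from_counts(counts, phenotype)
        screen = model.check_normality()
        assert screen.n_significant(0.05, adjusted=True) == 0
        assert "No significant genes" in screen.summary()


class TestCompareScans:
    @staticmethod
    def _as_series(sig, universe):
        return pd.Series(
            [0.01 if g in sig else 0.9 for g in universe], index=universe
        )

    def test_identical_sets_all_common(self):
        genes = pd.Index([f"g{i}" for i in range(6)])
        a = self._as_series({"g0", "g1"}, genes)
        comp = compare_scans({"m1": a, "m2": a.copy()}, alpha=0.05)
        assert comp.pattern_counts["m1+m2"] == 2
        assert comp.pattern_counts["none"] == 4

    def test_disjoint_sets_have_empty_intersection(self):
        genes = pd.Index([f"g{i}" for i in range(6)])
        comp = compare_scans(
            {"m1": self._as_series({"g0"}, genes),
             "m2": self._as_series({"g1"}, genes)},
            alpha=0.05,
        )
        assert "m1+m2" not in comp.pattern_counts.index

    def test_three_sets_match_brute_force_enumeration(self):
        genes = pd.Index([f"g{i}" for i in range(10)])
        sigs = {"a": {"g0", "g1", "g2"}, "b": {"g1", "g2", "g5"},
                "c": {"g2", "g7"}}
        comp = compare_scans(
            {k: self._as_series(v, genes) for k, v in sigs.items()},
            alpha=0.05,
        )
        expected = oracle_overlap_patterns(sigs, genes)
        assert comp.pattern_counts.to_dict() == expected

    def test_mismatched_universes_report_difference(self):
        a = self._as_series(set(), pd.Index(["g0", "g1"]))
        b = self._as_series(set(), pd.Index(["g0", "g2"]))
        with pytest.raises(ValueError, match="g2"):
            compare_scans({"m1": a, "m2": b})

    def test_am_em_sm_rm_categories(self):
        genes = pd.Index([f"g{i}" for i in range(5)])
        comp = compare_scans(
            {
                "deseq": self._as_series({"g0", "g1"}, genes),
                "ols": self._as_series({"g0", "g2"}, genes),
                "huber": self._as_series({"g0", "g2", "g3"}, genes),
            },
            alpha=0.05,
        )
        cats = comp.categorize(existing=["deseq"], suggesting=["ols", "huber"],
                               robust="huber")
        assert cats["g0"] == "AM"   # everywhere
        assert cats["g1"] == "EM"   # two-group method only
        assert cats["g2"] == "SM"   # both association methods only
        assert cats["g3"] == "RM"   # robust only
        assert cats["g4"] == "NS"
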