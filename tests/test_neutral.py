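"""Neutral community model: prediction formula, Wilson bands, fitting,
multi-source attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from pneumotyper.containers import CountTable
from pneumotyper.neutral import (
    fit_multi_source,
    fit_neutral,
    fit_neutral_profile,
    predict_occurrence,
    wilson_interval,
)
from pneumotyper.validate import neutral_recovery


class TestPredictOccurrence:
    def test_matches_quadrature_oracle(self):
        p, m, n_t, d = 0.01, 0.05, 1000.0, 0.001
        a, b = n_t * m * p, n_t * m * (1 - p)
        expected, _ = integrate.quad(lambda x: stats.beta.pdf(x, a, b), d, 1.0)
        assert abs(predict_occurrence(p, m, n_t, d) - expected) <= 1e-8

    def test_monotone_in_abundance(self):
        grid = np.linspace(0.001, 0.5, 100)
        f = predict_occurrence(grid, 0.05, 1000, 0.001)
        assert np.all(np.diff(f) >= 0)

    def test_large_m_limits(self):
        d = 0.01
        assert predict_occurrence(0.05, 1e4, 1000, d) > 0.999
        assert predict_occurrence(0.001, 1e4, 1000, d) < 1e-3

    def test_monotone_in_migration_above_detection(self):
        f = [predict_occurrence(0.05, m, 1000, 0.001) for m in (0.01, 0.05, 0.2, 1.0)]
        assert np.all(np.diff(f) > 0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_degenerate_abundance_rejected(self, p):
        with pytest.raises(ValueError):
            predict_occurrence(p, 0.05, 1000, 0.001)


class TestWilsonInterval:
    def test_closed_form_value(self):
        lo, hi = wilson_interval(0.5, 100)
        assert round(float(lo), 3) == 0.404
        assert round(float(hi), 3) == 0.596

    def test_zero_proportion_boundary(self):
        lo, hi = wilson_interval(0.0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_width_decreases_with_n(self):
        widths = [np.subtract(*wilson_interval(0.3, n)[::-1]) for n in (10, 50, 200, 1000)]
        assert np.all(np.diff(widths) < 0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for phat, n in [(0.2, 37), (0.5, 100), (0.91, 12)]:
            lo, hi = wilson_interval(phat, n)
            ref_lo, ref_hi = proportion_confint(phat * n, n, method="wilson")
            assert abs(lo - ref_lo) < 1e-9 and abs(hi - ref_hi) < 1e-9

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0.5, 0)


def _presence_table(f_target: np.ndarray, n_sinks: int, depth: int) -> CountTable:
    """Sink table whose occurrence frequencies quantise the targets and whose
    every sample has the stated depth (a filler taxon absorbs the rest)."""
    n_taxa = f_target.size
    counts = np.zeros((n_sinks, n_taxa + 1), dtype=int)
    for j, f in enumerate(f_target):
        k = int(round(f * n_sinks))
        counts[:k, j] = 1
    counts[:, -1] = depth - counts[:, :-1].sum(axis=1)
    cols = [f"t{j}" for j in range(n_taxa)] + ["filler"]
    return CountTable(
        pd.DataFrame(counts, index=[f"s{i}" for i in range(n_sinks)], columns=cols)
    )


class TestFitNeutral:
    def test_recovers_migration_rate(self):
        out = neutral_recovery(0.05, seed=7)
        assert abs(out["relative_error"]) <= 0.25
        assert out["r2"] >= 0.7

    def test_near_perfect_fit_when_frequencies_match_predictions(self):
        m0, n_sinks, depth = 0.05, 500, 1000
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(0.0005, 0.2, 40))
        profile = pd.Series(p, index=[f"t{j}" for j in range(40)])
        f_hat = predict_occurrence(p, m0, depth, 1.0 / depth)
        sinks = _presence_table(f_hat, n_sinks, depth)
        fit = fit_neutral_profile(profile, sinks)
        assert fit.r2 > 0.999
        assert abs(fit.m - m0) / m0 < 0.05

    def test_shuffled_frequencies_destroy_fit(self):
        m0, n_sinks, depth = 0.05, 500, 1000
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(0.0005, 0.2, 40))
        f_hat = predict_occurrence(p, m0, depth, 1.0 / depth)
        sinks = _presence_table(rng.permutation(f_hat), n_sinks, depth)
        profile = pd.Series(p, index=[f"t{j}" for j in range(40)])
        fit = fit_neutral_profile(profile, sinks)
        assert fit.r2 <= 0.5

    def test_r2_equals_independent_oracle(self):
        out = neutral_recovery(0.05, seed=7)
        # refit and recompute R2 with a one-line oracle on (F, Fhat)
        from pneumotyper import simulate

        _, truth = simulate.simulate_sources(n_taxa=300, n_subjects=200, overlap=0.6, seed=7)
        truth.n_t = truth.depth = 1000
        truth = simulate.assign_groups_and_weights(truth, seed=7, hi_fraction=1.0, m_hi=0.05, m_lo=0.05)
        truth.n_t = truth.depth = 1000
        lungs = simulate.simulate_lung_cohort(truth, seed=7)
        pool = np.mean([truth.mixed_pool(s) for s in truth.subjects], axis=0)
        fit = fit_neutral_profile(pd.Series(pool, index=truth.taxon_ids), lungs)
        f, fhat = fit.taxa["F"].to_numpy(), fit.taxa["Fhat"].to_numpy()
        oracle = 1 - ((f - fhat) ** 2).sum() / ((f - f.mean()) ** 2).sum()
        assert abs(fit.r2 - oracle) < 1e-12

    def test_partition_respects_band(self):
        out = neutral_recovery(0.01, seed=11)
        from pneumotyper import simulate

        _, truth = simulate.simulate_sources(n_taxa=300, n_subjects=200, overlap=0.6, seed=11)
        truth.n_t = truth.depth = 1000
        truth = simulate.assign_groups_and_weights(truth, seed=11, hi_fraction=1.0, m_hi=0.01, m_lo=0.01)
        truth.n_t = truth.depth = 1000
        lungs = simulate.simulate_lung_cohort(truth, seed=11)
        pool = np.mean([truth.mixed_pool(s) for s in truth.subjects], axis=0)
        fit = fit_neutral_profile(pd.Series(pool, index=truth.taxon_ids), lungs)
        t = fit.taxa
        neutral_mask = (t["F"] >= t["ci_lo"]) & (t["F"] <= t["ci_hi"])
        assert ((t["partition"] == "neutral") == neutral_mask).all()
        assert ((t["partition"] == "above") == (t["F"] > t["ci_hi"])).all()

    def test_too_few_taxa_rejected(self):
        profile = pd.Series({"t0": 0.5, "t1": 0.5})
        sinks = _presence_table(np.array([0.5, 0.5]), 20, 100)
        with pytest.raises(ValueError, match="taxa"):
            fit_neutral_profile(profile, sinks)


def _block_tables(rng):
    """Two sources with disjoint taxon blocks and a 70/30 mixed sink."""
    taxa = [f"t{j}" for j in range(40)]
    prof_a = np.zeros(40)
    prof_a[:20] = rng.dirichlet(np.ones(20))
    prof_b = np.zeros(40)
    prof_b[20:] = rng.dirichlet(np.ones(20))
    src_a = CountTable(
        pd.DataFrame(
            [rng.multinomial(5000, prof_a) for _ in range(15)],
            index=[f"a{i}" for i in range(15)],
            columns=taxa,
        )
    )
    src_b = CountTable(
        pd.DataFrame(
            [rng.multinomial(5000, prof_b) for _ in range(15)],
            index=[f"b{i}" for i in range(15)],
            columns=taxa,
        )
    )
    mix = 0.7 * prof_a + 0.3 * prof_b
    sinks = CountTable(
        pd.DataFrame(
            [rng.multinomial(2000, mix) for _ in range(40)],
            index=[f"k{i}" for i in range(40)],
            columns=taxa,
        )
    )
    return src_a, src_b, sinks


class TestMultiSource:
    def test_single_source_reduces_to_plain_fit(self, rng):
        src_a, _, sinks = _block_tables(rng)
        plain = fit_neutral(src_a, sinks, min_taxa=10)
        multi, attribution = fit_multi_source({"siteA": src_a}, sinks, min_taxa=10)
        assert np.isclose(plain.m, multi.m)
        assert np.isclose(plain.r2, multi.r2)
        assert (attribution.attribution == "siteA").all()

    def test_disjoint_blocks_attributed_to_true_source(self, rng):
        src_a, src_b, sinks = _block_tables(rng)
        _, attribution = fit_multi_source(
            {"siteA": src_a, "siteB": src_b}, sinks, min_taxa=10
        )
        for taxon, site in attribution.attribution.items():
            expected = "siteA" if int(taxon[1:]) < 20 else "siteB"
            assert site == expected

    def test_contribution_table_matches_enumeration(self, rng):
        src_a, src_b, sinks = _block_tables(rng)
        fit, attribution = fit_multi_source(
            {"siteA": src_a, "siteB": src_b}, sinks, min_taxa=10
        )
        assert attribution.contribution.to_numpy().sum() == len(fit.taxa)
        f = fit.taxa["F"]
        q1, q3 = np.quantile(f, [0.25, 0.75])
        for taxon in fit.taxa.index:
            grp = attribution.freq_group[taxon]
            if f[taxon] <= q1:
                assert grp == "lower-quartile"
            elif f[taxon] >= q3:
                assert grp == "upper-quartile"
            else:
                assert grp == "interquartile"
        # cross-tab cell check against direct enumeration
        for site in ("siteA", "siteB"):
            for grp in attribution.contribution.columns:
                manual = sum(
                    1
                    for t in fit.taxa.index
                    if attribution.attribution[t] == site
                    and attribution.freq_group[t] == grp
                )
                assert attribution.contribution.loc[site, grp] == manual

    def test_tie_break_deterministic(self):
        taxa = ["t0", "t1"] + [f"f{j}" for j in range(25)]
        rng = np.random.default_rng(0)
        base = rng.dirichlet(np.ones(27))
        counts = pd.DataFrame(
            [np.maximum((base * 1000).astype(int), 1) for _ in range(12)],
            index=[f"s{i}" for i in range(12)],
            columns=taxa,
        )
        src = CountTable(counts)
        sinks = CountTable(
            pd.DataFrame(
                [rng.multinomial(2000, base) for _ in range(30)],
                index=[f"k{i}" for i in range(30)],
                columns=taxa,
            )
        )
        # identical tables for both sites: every taxon ties; lexicographic wins
        out1 = fit_multi_source({"zeta": src, "alpha": src}, sinks, min_taxa=10)[1]
        out2 = fit_multi_source({"zeta": src, "alpha": src}, sinks, min_taxa=10)[1]
        assert (out1.attribution == "alpha").all()
        assert out1.attribution.equals(out2.attribution)
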