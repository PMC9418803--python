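"""Synthetic cohort generator: catalogs, mutation, rendering, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from fmtstrains.profiles import FilterParams, filter_profile
from fmtstrains.synthetic import CohortConfig, generate_catalog, \
    generate_fmt_cohort, generate_unrelated_pairs, mutate_strain, \
    random_genotype, render_sample, simulate_case_table
from fmtstrains.synthetic.catalog import FEATURES


class TestCatalog:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            generate_catalog(0)

    def test_zero_missing_rate_complete(self):
        cat = generate_catalog(100, feature_missing_rate=0.0, seed=1)
        assert len(cat) == 100
        assert not cat.table[FEATURES].isna().any().any()

    def test_missing_rate_within_binomial_interval(self):
        cat = generate_catalog(100, feature_missing_rate=0.3, seed=1)
        n = 100 * len(FEATURES)
        observed = int(cat.table[FEATURES].isna().sum().sum())
        lo, hi = stats.binom.interval(0.99, n, 0.3)
        assert lo <= observed <= hi

    def test_deterministic_and_structured(self):
        a = generate_catalog(50, seed=9)
        b = generate_catalog(50, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.marker_bounds == b.marker_bounds
        # every species has a genus; most alignments exceed 5 kb
        assert a.table["genus"].notna().all()
        assert (a.table["marker_length"] >= 5000).mean() >= 0.8


class TestMutateStrain:
    def test_zero_divergence_identity(self):
        g = random_genotype("sp", 500, 1, "lin")
        m = mutate_strain(g, 0.0, seed=2)
        np.testing.assert_array_equal(g.alleles, m.alleles)

    def test_full_divergence(self):
        g = random_genotype("sp", 100, 1, "lin")
        m = mutate_strain(g, 1.0, seed=2)
        assert (g.alleles != m.alleles).sum() == 100

    def test_out_of_range_rejected(self):
        g = random_genotype("sp", 100, 1, "lin")
        with pytest.raises(ValueError):
            mutate_strain(g, 1.5)

    def test_binomial_mean_over_seeds(self):
        # divergence 0.01 over L=10,000: mean differing positions ~ 100,
        # sd of the mean over 1,000 seeds = sqrt(100*0.99/1000) ~ 0.31
        g = random_genotype("sp", 10_000, 1, "lin")
        diffs = [(g.alleles != mutate_strain(g, 0.01, seed=s).alleles).sum()
                 for s in range(1000)]
        se = np.sqrt(10_000 * 0.01 * 0.99 / 1000)
        assert abs(np.mean(diffs) - 100) < 3 * se


class TestRenderSample:
    def test_zero_abundance_species_omitted(self):
        g = random_genotype("a", 200, 1, "lin")
        out = render_sample({"a": 1.0, "b": 0.0},
                            {"a": [(g, 1.0)]}, 30, 0.0, seed=1)
        assert set(out) == {"a"}

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            render_sample({}, {}, -1, 0.0)

    def test_unnormalized_community_rejected(self):
        g = random_genotype("a", 100, 1, "lin")
        with pytest.raises(ValueError, match="sum to 1"):
            render_sample({"a": 0.5}, {"a": [(g, 1.0)]}, 30, 0.0, seed=1)

    def test_mixture_shows_both_alleles(self):
        # 50/50 mixture diverged at 1% of sites, 50x, 0.1% error:
        # >=95% of covered divergent sites show both alleles at >=10%
        L = 20_000
        g1 = random_genotype("a", L, 1, "l1")
        g2 = mutate_strain(g1, 0.01, seed=2, lineage_id="l2")
        div = np.flatnonzero(g1.alleles != g2.alleles)
        prof = render_sample({"a": 1.0}, {"a": [(g1, 0.5), (g2, 0.5)]},
                             depth=50, error_rate=0.001, seed=3)["a"]
        covered = div[prof.mask[div]]
        both = 0
        for pos in covered:
            tot = prof.counts[:, pos].sum()
            c1 = prof.counts[g1.alleles[pos], pos]
            c2 = prof.counts[g2.alleles[pos], pos]
            if c1 >= 0.1 * tot and c2 >= 0.1 * tot:
                both += 1
        assert both / len(covered) >= 0.95

    def test_deterministic_given_seed(self):
        g = random_genotype("a", 500, 1, "lin")
        p1 = render_sample({"a": 1.0}, {"a": [(g, 1.0)]}, 30, 0.001, seed=5)
        p2 = render_sample({"a": 1.0}, {"a": [(g, 1.0)]}, 30, 0.001, seed=5)
        np.testing.assert_array_equal(p1["a"].counts, p2["a"].counts)


class TestCohortGenerator:
    def test_empty_cohort(self):
        coh = generate_fmt_cohort(CohortConfig(n_cases=0, n_donors=1,
                                               n_species=10), seed=1)
        assert coh.cases == [] and len(coh.truth) == 0

    def test_null_beta_engraftment_frequency_half(self):
        # logit^-1(0) = 0.5: with all coefficients zero, engraftment of
        # non-ambiguous donor species is a fair coin
        beta = {k: 0.0 for k in ["intercept", "abx", "lavage", "n_fmts",
                                 "recipient_shannon", "donor_shannon",
                                 "recipient_dist_to_controls",
                                 "recipient_donor_distance"]}
        cfg = CohortConfig(n_cases=100, n_donors=8, n_species=80,
                           depth=0.5, beta_case=beta, posts_per_case=(1, 1))
        coh = generate_fmt_cohort(cfg, seed=3)
        events = coh.truth[coh.truth["in_donor"] & ~coh.truth["ambiguous"]]
        n = len(events)
        assert n >= 2000
        freq = events["engrafted"].mean()
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_abx_effect_recovered_as_log_odds_difference(self):
        beta = {"intercept": 0.0, "abx": 2.0}
        cfg = CohortConfig(n_cases=80, n_donors=8, n_species=80, depth=0.5,
                           beta_case=beta, posts_per_case=(1, 1))
        coh = generate_fmt_cohort(cfg, seed=4)
        meta = {c.case_id: c.covariates["abx"] for c in coh.cases}
        ev = coh.truth[coh.truth["in_donor"] & ~coh.truth["ambiguous"]].copy()
        ev["abx"] = ev["case_id"].map(meta)
        p1 = ev.loc[ev["abx"] == 1, "engrafted"].mean()
        p0 = ev.loc[ev["abx"] == 0, "engrafted"].mean()
        n1 = (ev["abx"] == 1).sum()
        n0 = (ev["abx"] == 0).sum()
        diff = logit(p1) - logit(p0)
        se = np.sqrt(1 / (n1 * p1 * (1 - p1)) + 1 / (n0 * p0 * (1 - p0)))
        assert abs(diff - 2.0) < 3 * se

    def test_determinism(self):
        cfg = CohortConfig(n_cases=2, n_donors=2, n_species=20)
        a = generate_fmt_cohort(cfg, seed=8)
        b = generate_fmt_cohort(cfg, seed=8)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        sa = a.cases[0].post_samples[0]
        sb = b.cases[0].post_samples[0]
        for sp in sa.profiles:
            np.testing.assert_array_equal(sa.profiles[sp].counts,
                                          sb.profiles[sp].counts)

    def test_truth_render_consistency(self, small_cohort):
        """Labels match what was rendered: lost species absent post,
        donor species carry the donor lineage."""
        truth = small_cohort.truth
        by_case = {c.case_id: c for c in small_cohort.cases}
        for _, row in truth.iterrows():
            case = by_case[row["case_id"]]
            post = case.post_samples[0]
            present = post.community[row["species_id"]] > 0
            if row["origin"] == "lost":
                assert not present
            else:
                assert present


class TestUnrelatedPairs:
    def test_zero_floor_warns(self, catalog20):
        with pytest.warns(UserWarning, match="resolving power"):
            generate_unrelated_pairs(1, catalog20, seed=1, n_species=3,
                                     depth=5, divergence_floor=0.0)

    def test_no_true_shared_lineages(self, catalog20):
        up = generate_unrelated_pairs(2, catalog20, seed=2, n_species=5,
                                      depth=10, divergence_floor=0.01)
        assert up.true_shared_per_pair == [0, 0]
        # conspecific genotypes truly diverge: consensus of pair members
        # differs at >= 1% of jointly covered sites
        from fmtstrains.comparison import CallParams, compare
        fa, fb = up.pairs[0]
        for sp in set(fa) & set(fb):
            a = filter_profile(fa[sp], FilterParams())
            b = filter_profile(fb[sp], FilterParams())
            r = compare(a, b, CallParams(min_overlap_bp=100))
            if r.overlap_bp >= 100:
                assert r.consensus_similarity <= 0.995

    def test_n_pairs_validated(self, catalog20):
        with pytest.raises(ValueError):
            generate_unrelated_pairs(0, catalog20)


class TestCaseTableSimulator:
    def test_shapes_and_determinism(self):
        t1, tr1 = simulate_case_table(n_cases=20, n_studies=3, seed=6)
        t2, _ = simulate_case_table(n_cases=20, n_studies=3, seed=6)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["successes"] + t1["failures"] >= 1).all()
        assert t1["case_id"].nunique() == 20
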