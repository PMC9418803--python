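"""Origin attribution, donor pooling, summaries, competition outcomes."""

import numpy as np
import pandas as pd
import pytest

from fmtstrains import attribution as attr
from fmtstrains.comparison import CallParams
from fmtstrains.metrics import close, shannon
from fmtstrains.profiles import FilterParams
from fmtstrains.synthetic import random_genotype, render_sample


class FakeSample:
    def __init__(self, sample_id, community, profiles):
        self.sample_id = sample_id
        self.community = community
        self.profiles = profiles
        self.post_abx = False


def render_subject(species_lengths, strains, community, seed, sample_id,
                   depth=40):
    assignment = {sp: [(g, 1.0)] for sp, g in strains.items()}
    profs = render_sample(community, assignment, depth, 0.001, seed=seed,
                          sample_id=sample_id)
    comm = pd.Series(0.0, index=sorted(species_lengths))
    for sp, a in community.items():
        comm[sp] = a
    return FakeSample(sample_id, comm, profs)


@pytest.fixture(scope="module")
def toy_world():
    """Three species with distinct recipient/donor lineages."""
    rng = np.random.default_rng(10)
    lengths = {"spA": 8000, "spB": 8000, "spC": 8000}
    recip, donor = {}, {}
    for sp, L in lengths.items():
        root = random_genotype(sp, L, rng, f"{sp}:root")
        from fmtstrains.synthetic import mutate_strain
        recip[sp] = mutate_strain(root, 0.01, seed=rng,
                                  lineage_id=f"{sp}:R")
        donor[sp] = mutate_strain(root, 0.01, seed=rng,
                                  lineage_id=f"{sp}:D")
    return lengths, recip, donor


class TestPoolDonorSamples:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            attr.pool_donor_samples([])

    def test_single_donor_identity(self, toy_world):
        lengths, recip, donor = toy_world
        s = render_subject(lengths, donor, {"spA": 1.0}, 1, "d0")
        pooled = attr.pool_donor_samples([s])
        np.testing.assert_array_equal(pooled.profiles["spA"].counts,
                                      s.profiles["spA"].counts)

    def test_two_identical_donors_double_counts(self, toy_world):
        lengths, recip, donor = toy_world
        s = render_subject(lengths, donor, {"spA": 1.0}, 1, "d0")
        pooled = attr.pool_donor_samples([s, s])
        np.testing.assert_array_equal(pooled.profiles["spA"].counts,
                                      2 * s.profiles["spA"].counts)
        # Shannon of identical communities is unchanged by averaging
        assert pooled.mean_shannon == pytest.approx(
            shannon(close(s.community.values + 1e-12)))

    def test_disjoint_species_union(self, toy_world):
        lengths, recip, donor = toy_world
        a = render_subject(lengths, donor, {"spA": 1.0}, 1, "d0")
        b = render_subject(lengths, donor, {"spB": 1.0}, 2, "d1")
        pooled = attr.pool_donor_samples([a, b])
        assert set(pooled.profiles) == {"spA", "spB"}

    def test_order_invariance(self, toy_world):
        lengths, recip, donor = toy_world
        a = render_subject(lengths, donor, {"spA": 0.6, "spB": 0.4}, 1, "d0")
        b = render_subject(lengths, donor, {"spA": 1.0}, 2, "d1")
        p1 = attr.pool_donor_samples([a, b])
        p2 = attr.pool_donor_samples([b, a])
        np.testing.assert_array_equal(p1.profiles["spA"].counts,
                                      p2.profiles["spA"].counts)
        assert p1.mean_shannon == pytest.approx(p2.mean_shannon)


class TestAttributeOrigins:
    def test_no_fmt_effect_all_recipient(self, toy_world):
        """Post == pre, donor unrelated: every resolvable species is
        recipient-derived."""
        lengths, recip, donor = toy_world
        comm = {"spA": 0.5, "spB": 0.5}
        pre = render_subject(lengths, recip, comm, 3, "pre")
        post = render_subject(lengths, recip, comm, 4, "post")
        don = attr.pool_donor_samples(
            [render_subject(lengths, donor, comm, 5, "d0")], FilterParams())
        tab = attr.attribute_origins(pre, don, post)
        labels = tab.set_index("species_id")["label"]
        assert (labels[["spA", "spB"]] == "recipient").all()

    def test_new_species(self, toy_world):
        lengths, recip, donor = toy_world
        rng = np.random.default_rng(6)
        new_strain = {"spC": random_genotype("spC", 8000, rng, "spC:N")}
        pre = render_subject(lengths, recip, {"spA": 1.0}, 3, "pre")
        post = render_subject(lengths, {**recip, **new_strain},
                              {"spA": 0.5, "spC": 0.5}, 4, "post")
        don = attr.pool_donor_samples(
            [render_subject(lengths, donor, {"spA": 1.0}, 5, "d0")],
            FilterParams())
        tab = attr.attribute_origins(pre, don, post).set_index("species_id")
        assert tab.loc["spC", "label"] == "new"

    def test_donor_engraftment_and_lost(self, toy_world):
        lengths, recip, donor = toy_world
        pre = render_subject(lengths, recip, {"spA": 0.5, "spB": 0.5},
                             3, "pre")
        # spB replaced by donor strain; spA persists; donor spC not taken
        post = render_subject(lengths, {"spA": recip["spA"],
                                        "spB": donor["spB"]},
                              {"spA": 0.5, "spB": 0.5}, 4, "post")
        don = attr.pool_donor_samples(
            [render_subject(lengths, donor,
                            {"spB": 0.5, "spC": 0.5}, 5, "d0")],
            FilterParams())
        tab = attr.attribute_origins(pre, don, post).set_index("species_id")
        assert tab.loc["spB", "label"] == "donor"
        assert tab.loc["spA", "label"] == "recipient"
        assert tab.loc["spC", "label"] == "lost"

    def test_partition_property(self, small_cohort):
        """Each species present post-FMT gets exactly one label."""
        case = small_cohort.cases[0]
        donor = attr.pool_donor_samples(small_cohort.donor_samples(case),
                                        FilterParams())
        tab = attr.attribute_origins(case.pre_samples[0], donor,
                                     case.post_samples[0])
        assert tab["species_id"].is_unique
        post_species = set(
            case.post_samples[0].community.index[
                case.post_samples[0].community.values > 0])
        labelled = set(tab.loc[tab["label"] != "lost", "species_id"])
        assert labelled == post_species

    def test_missing_post_rejected(self, toy_world):
        lengths, recip, donor = toy_world
        pre = render_subject(lengths, recip, {"spA": 1.0}, 3, "pre")
        don = attr.pool_donor_samples(
            [render_subject(lengths, donor, {"spA": 1.0}, 5, "d0")],
            FilterParams())
        with pytest.raises(ValueError):
            attr.attribute_origins(pre, don, None)


class TestEngraftmentSummary:
    def _table(self, labels, sample_id="s1"):
        return pd.DataFrame({
            "sample_id": sample_id,
            "species_id": [f"sp{i}" for i in range(len(labels))],
            "label": labels,
            "rel_abundance": [0.1] * len(labels),
            "species_shared_pre": True, "species_shared_donor": True,
        })

    def test_fraction_arithmetic(self):
        tab = self._table(["donor"] * 3 + ["recipient"])
        out = attr.engraftment_summary({"s1": tab})
        assert out.loc[0, "donor_fraction"] == pytest.approx(0.75)

    def test_zero_denominator_missing(self):
        tab = self._table(["new", "lost"])
        out = attr.engraftment_summary({"s1": tab})
        assert np.isnan(out.loc[0, "donor_fraction"])

    def test_latest_and_exclusions(self):
        tabs = {"s1": self._table(["donor"], "s1"),
                "s2": self._table(["recipient"], "s2"),
                "s3": self._table(["donor"], "s3")}
        days = {"s1": 10, "s2": 30, "s3": 200}
        out = attr.engraftment_summary(tabs, days, which="latest",
                                       max_day=120)
        assert list(out["sample_id"]) == ["s2"]
        out2 = attr.engraftment_summary(tabs, days, {"s1": True},
                                        exclude_post_abx=True)
        assert "s1" not in set(out2["sample_id"])


class TestCompetitionOutcomes:
    def test_partition_sums(self):
        tab = pd.DataFrame({
            "sample_id": "s", "species_id": [f"sp{i}" for i in range(6)],
            "label": ["new", "recipient", "donor", "coexist", "lost",
                      "ambiguous"],
            "rel_abundance": 0.1,
            "species_shared_pre": [True] * 6,
            "species_shared_donor": [True] * 6,
        })
        counts = attr.classify_competition_outcomes({"s": tab})
        assert counts.sum() == 6
        assert counts["species_lost"] == 1
        assert counts["unresolved"] == 1  # ambiguous folded in

    def test_only_qualifying_species_counted(self):
        tab = pd.DataFrame({
            "sample_id": "s", "species_id": ["a", "b"],
            "label": ["donor", "donor"], "rel_abundance": 0.1,
            "species_shared_pre": [True, False],
            "species_shared_donor": [True, True],
        })
        counts = attr.classify_competition_outcomes({"s": tab})
        assert counts.sum() == 1

    def test_truth_agreement_on_cohort(self, small_cohort):
        """Planted coexistence shows up in the six-way table."""
        fp = FilterParams()
        tables = {}
        for case in small_cohort.cases:
            donor = attr.pool_donor_samples(
                small_cohort.donor_samples(case), fp)
            post = case.latest_post
            tables[post.sample_id] = attr.attribute_origins(
                case.pre_samples[0], donor, post)
        counts = attr.classify_competition_outcomes(tables)
        truth = small_cohort.truth
        qual = truth[truth["in_pre"] & truth["in_donor"]]
        assert counts.sum() == len(qual)


class TestDonorSpeciesFate:
    def test_fractions(self):
        tab = pd.DataFrame({
            "sample_id": "s", "species_id": list("abcd"),
            "label": ["donor", "donor", "lost", "coexist"],
            "rel_abundance": 0.1,
            "species_shared_pre": [False, True, True, True],
            "species_shared_donor": [True] * 4,
        })
        out = attr.donor_species_fate(tab)
        assert out["engrafted_new_species"] == pytest.approx(0.25)
        assert out["engrafted_replacement"] == pytest.approx(0.25)
        assert out["not_engrafted"] == pytest.approx(0.25)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_donor_set(self):
        tab = pd.DataFrame({"sample_id": [], "species_id": [], "label": [],
                            "rel_abundance": [],
                            "species_shared_pre": [],
                            "species_shared_donor": []})
        assert attr.donor_species_fate(tab).isna().all()


class TestFalsePositives:
    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            attr.false_positive_assessment([])

    def test_identical_pair_positive_control(self, toy_world):
        lengths, recip, donor = toy_world
        s = render_subject(lengths, recip, {"spA": 0.5, "spB": 0.5}, 9, "x")
        summary, per_pair = attr.false_positive_assessment(
            [(s.profiles, s.profiles)])
        assert summary["mean"] >= 2  # self-pair shares everything covered


class TestShamExclusion:
    def test_empty_cohort(self):
        class Empty:
            cases = []
        out = attr.exclude_sham_cases(Empty())
        assert out.empty

    def test_sham_case_flagged(self):
        from fmtstrains.synthetic import CohortConfig, generate_fmt_cohort
        # high engraftment pressure + no pre-shared lineages, so sham
        # status and donor-shared strain counts separate cleanly
        cfg = CohortConfig(n_cases=4, n_donors=2, n_species=30, n_sham=2,
                           posts_per_case=(1, 1), new_strain_rate=0.0,
                           ambiguous_fraction=0.0,
                           beta_case={"intercept": 2.0})
        coh = generate_fmt_cohort(cfg, seed=19)
        sham_truth = {c.case_id: c.covariates["sham"] for c in coh.cases}
        out = attr.exclude_sham_cases(coh).set_index("case_id")
        for cid, is_sham in sham_truth.items():
            if is_sham:
                assert out.loc[cid, "sham"]
            else:
                assert not out.loc[cid, "sham"]
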