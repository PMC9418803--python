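"""Full FMT cohort generation: communities, strains, pileups, ground truth.

A cohort consists of donors and FMT cases grouped into studies.  Each case
has a pre-FMT recipient sample, an assigned donor, and one or more post-FMT
samples.  Per-species donor engraftment is drawn from a binomial-logit
generative model whose covariates are the same quantities the analysis
models use (clinical pretreatment flags and z-scored community metrics of
the actual generated communities).  The post-FMT community is then
assembled from engrafted donor strains, persisting recipient strains,
newly acquired strains, and losses; every decision is recorded in the
truth-label table.  Finally, every sample's marker pileups are rendered
with Poisson coverage and multinomial base counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ..metrics import aitchison_distance, close, distance_to_reference, shannon
from .catalog import SpeciesCatalog, generate_catalog
from .render import render_sample
from .strains import StrainGenotype, mutate_strain, random_genotype
from .tables import default_beta_case


@dataclass
class Sample:
    sample_id: str
    subject_id: str
    kind: str                  # 'pre' | 'post' | 'donor'
    day: float
    community: pd.Series       # species -> relative abundance (closed)
    profiles: dict             # species -> NucleotideProfile (unfiltered)
    post_abx: bool = False


@dataclass
class FMTCase:
    """One FMT case: pre-FMT sample(s), donor link, timed post-FMT samples."""

    case_id: str
    study_id: str
    donor_id: str
    covariates: dict
    pre_samples: list = field(default_factory=list)
    post_samples: list = field(default_factory=list)

    @property
    def latest_post(self) -> Sample:
        return max(self.post_samples, key=lambda s: s.day)


@dataclass
class Cohort:
    catalog: SpeciesCatalog
    cases: list
    donors: dict               # donor_id -> list of Sample
    controls: pd.DataFrame     # control samples x species abundances
    truth: pd.DataFrame
    beta_case: dict
    config: "CohortConfig"

    def donor_samples(self, case: FMTCase) -> list:
        return self.donors[case.donor_id]

    def all_samples(self):
        for case in self.cases:
            yield from case.pre_samples
            yield from case.post_samples
        for samples in self.donors.values():
            yield from samples


@dataclass
class CohortConfig:
    """Study conditions for the synthetic FMT cohort.

    Defaults mirror the meta-cohort ranges the analysis assumes: Bernoulli
    antibiotic/lavage pretreatment, 1/2/many FMT rounds, post-FMT sampling
    days uniform on 5-120, heavy-tailed (log-normal) community abundances,
    1-2% strain divergence between conspecific lineages, 30x mean coverage
    with 0.1% per-base error, a 10% new-strain injection rate, and a 5%
    ambiguous fraction in which recipient and donor share a lineage
    pre-FMT.
    """

    n_cases: int = 50
    n_donors: int = 10
    n_studies: int = 4
    n_species: int = 100
    depth: float = 30.0
    error_rate: float = 0.001
    divergence_range: tuple = (0.01, 0.02)
    new_strain_rate: float = 0.10
    ambiguous_fraction: float = 0.05
    coexist_prob: float = 0.25
    coexist_frac_range: tuple = (0.3, 0.7)
    loss_rate: float = 0.15
    abx_loss_boost: float = 0.25
    prevalence_mean: float = 0.35
    lognormal_sigma: float = 1.0
    posts_per_case: tuple = (1, 3)
    day_range: tuple = (5, 120)
    abx_p: float = 0.5
    lavage_p: float = 0.5
    n_fmts_probs: tuple = (0.6, 0.25, 0.15)
    post_abx_rate: float = 0.05
    feature_missing_rate: float = 0.1
    n_controls: int = 30
    n_sham: int = 0
    beta_case: dict | None = None

    def resolved_beta(self) -> dict:
        return dict(self.beta_case or default_beta_case())


class _LineageFactory:
    """Caches one root genotype per species and derives named lineages."""

    def __init__(self, catalog, divergence_range, rng):
        self.catalog = catalog
        self.div = divergence_range
        self.rng = rng
        self.roots = {}
        self.cache = {}

    def get(self, species_id: str, owner: str) -> StrainGenotype:
        key = (species_id, owner)
        if key not in self.cache:
            if species_id not in self.roots:
                self.roots[species_id] = random_genotype(
                    species_id, self.catalog.marker_length(species_id),
                    self.rng, f"{species_id}:root")
            d = self.rng.uniform(*self.div)
            self.cache[key] = mutate_strain(
                self.roots[species_id], d, seed=self.rng,
                lineage_id=f"{species_id}:{owner}")
        return self.cache[key]

    def alias(self, species_id: str, owner: str, other: str):
        """Make `owner` carry the same lineage as `other` (ambiguous pairs)."""
        self.cache[(species_id, owner)] = self.get(species_id, other)


def _communities(rng, n, species, prevalence, sigma):
    present = rng.random((n, len(species))) < prevalence[None, :]
    for i in np.flatnonzero(~present.any(axis=1)):
        present[i, rng.integers(len(species))] = True
    raw = np.where(present, rng.lognormal(0.0, sigma, (n, len(species))), 0.0)
    return pd.DataFrame(close(raw), columns=species)


def generate_fmt_cohort(config: CohortConfig = CohortConfig(), seed=None
                        ) -> Cohort:
    """Generate a complete FMT cohort with rendered samples and truth labels.

    Deterministic given ``(config, seed)``.  Truth-label origins:

    - ``donor``      engrafted donor strain only (empty niche or replacement)
    - ``recipient``  persisting recipient strain only
    - ``coexist``    both strains post-FMT (mixture fraction recorded)
    - ``new``        strain from neither pre-FMT recipient nor donor
    - ``lost``       species present pre-FMT (or in donor) but absent post

    Species where recipient and donor were seeded with the same lineage are
    flagged ``ambiguous`` — their strain origin is unidentifiable by design.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    catalog = generate_catalog(cfg.n_species, cfg.feature_missing_rate,
                               seed=int(rng.integers(2**31)))
    species = catalog.table.index
    prevalence = np.clip(
        rng.beta(2.0, 2.0 * (1 - cfg.prevalence_mean) / cfg.prevalence_mean,
                 size=cfg.n_species), 0.02, 0.95)

    donor_comm = _communities(rng, cfg.n_donors, species, prevalence,
                              cfg.lognormal_sigma)
    donor_comm.index = [f"d{j:03d}" for j in range(cfg.n_donors)]
    recip_comm = _communities(rng, cfg.n_cases, species, prevalence,
                              cfg.lognormal_sigma)
    recip_comm.index = [f"c{c:03d}" for c in range(cfg.n_cases)]
    controls = _communities(rng, cfg.n_controls, species, prevalence,
                            cfg.lognormal_sigma)
    controls.index = [f"ctrl{j:03d}" for j in range(cfg.n_controls)]
    control_mat = controls.values

    # generative covariates: clinical draws + z-scored metrics of the
    # actual communities
    beta = cfg.resolved_beta()
    donor_study = rng.integers(0, cfg.n_studies, size=cfg.n_donors)
    donor_of_case = rng.integers(0, cfg.n_donors, size=cfg.n_cases)
    d_sh = donor_comm.apply(lambda r: shannon(close(r.values + 1e-12)), axis=1)
    r_sh = recip_comm.apply(lambda r: shannon(close(r.values + 1e-12)), axis=1)
    r_dist = pd.Series(
        [distance_to_reference(recip_comm.values[c], control_mat)
         for c in range(cfg.n_cases)], index=recip_comm.index)
    rd_dist = pd.Series(
        [aitchison_distance(recip_comm.values[c],
                            donor_comm.values[donor_of_case[c]])
         for c in range(cfg.n_cases)], index=recip_comm.index)

    def z(series):
        return (series - series.mean()) / (series.std() + 1e-9)

    d_sh_z, r_sh_z = z(d_sh), z(r_sh)
    r_dist_z, rd_dist_z = z(r_dist), z(rd_dist)

    abx = (rng.random(cfg.n_cases) < cfg.abx_p).astype(float)
    lavage = (rng.random(cfg.n_cases) < cfg.lavage_p).astype(float)
    n_fmts = rng.choice([0.0, 1.0, 2.0], size=cfg.n_cases, p=cfg.n_fmts_probs)
    sham_cases = set(rng.choice(cfg.n_cases, size=cfg.n_sham, replace=False)
                     ) if cfg.n_sham else set()

    lineages = _LineageFactory(catalog, cfg.divergence_range, rng)
    cases, donors, truth_rows = [], {}, []

    # render donor samples once per donor
    for j, donor_id in enumerate(donor_comm.index):
        comm = donor_comm.loc[donor_id]
        assignment = {sp: [(lineages.get(sp, donor_id), 1.0)]
                      for sp in species[comm.values > 0]}
        profiles = render_sample(comm[comm > 0].to_dict(), assignment,
                                 cfg.depth, cfg.error_rate,
                                 seed=rng, catalog=catalog,
                                 sample_id=f"{donor_id}_s0")
        donors[donor_id] = [Sample(f"{donor_id}_s0", donor_id, "donor",
                                   0.0, comm, profiles)]

    for c in range(cfg.n_cases):
        case_id = recip_comm.index[c]
        donor_id = donor_comm.index[donor_of_case[c]]
        study_id = f"st{donor_study[donor_of_case[c]]:02d}"
        sham = c in sham_cases
        pre = recip_comm.loc[case_id]
        don = donor_comm.loc[donor_id]
        pre_set = set(species[pre.values > 0])
        donor_set = set(species[don.values > 0])

        # ambiguous pairs: recipient seeded with the donor's lineage
        ambiguous = set()
        for sp in sorted(pre_set & donor_set):
            if rng.random() < cfg.ambiguous_fraction:
                lineages.alias(sp, case_id, donor_id)
                ambiguous.add(sp)

        # engraftment outcomes for every donor species
        eta_case = (beta["intercept"]
                    + beta.get("abx", 0) * abx[c]
                    + beta.get("lavage", 0) * lavage[c]
                    + beta.get("n_fmts", 0) * n_fmts[c]
                    + beta.get("recipient_shannon", 0) * r_sh_z[case_id]
                    + beta.get("donor_shannon", 0) * d_sh_z[donor_id]
                    + beta.get("recipient_dist_to_controls", 0) * r_dist_z[case_id]
                    + beta.get("recipient_donor_distance", 0) * rd_dist_z[case_id])
        engrafted = {}
        for sp in sorted(donor_set):
            if sham or sp in ambiguous:
                engrafted[sp] = False
            else:
                engrafted[sp] = bool(rng.random() < expit(eta_case))

        # assemble the post-FMT community
        loss_p = min(cfg.loss_rate + cfg.abx_loss_boost * abx[c], 0.9)
        post_abund, post_assignment = {}, {}
        origin, mixture = {}, {}
        # coexistence is only planted where both parent strains are
        # observable: expected coverage at the nominal depth in pre-FMT
        # recipient and donor (abundance >= community mean) and a marker
        # alignment long enough to clear the comparison overlap threshold.
        # A 30/70 minor strain in a shallow species or a sub-5kb alignment
        # is undetectable by construction, not an attribution property.
        pre_floor = 1.0 / max(len(pre_set), 1)
        don_floor = 1.0 / max(len(donor_set), 1)

        def coexist_plantable(sp):
            return (pre[sp] >= pre_floor and don[sp] >= don_floor
                    and catalog.marker_length(sp) >= 6000)
        for sp in sorted(pre_set | donor_set):
            in_pre, in_don = sp in pre_set, sp in donor_set
            if sp in ambiguous:
                if rng.random() >= loss_p:
                    origin[sp] = "recipient"   # unidentifiable; flagged below
                    post_abund[sp] = pre[sp]
                    post_assignment[sp] = [(lineages.get(sp, case_id), 1.0)]
                else:
                    origin[sp] = "lost"
                continue
            if in_don and engrafted[sp]:
                if in_pre and coexist_plantable(sp) and \
                        rng.random() < cfg.coexist_prob:
                    f = rng.uniform(*cfg.coexist_frac_range)
                    origin[sp] = "coexist"
                    mixture[sp] = f
                    post_abund[sp] = pre[sp]
                    post_assignment[sp] = [
                        (lineages.get(sp, donor_id), f),
                        (lineages.get(sp, case_id), 1.0 - f)]
                else:
                    origin[sp] = "donor"
                    post_abund[sp] = don[sp]
                    post_assignment[sp] = [(lineages.get(sp, donor_id), 1.0)]
            elif in_pre:
                if rng.random() >= loss_p:
                    origin[sp] = "recipient"
                    post_abund[sp] = pre[sp]
                    post_assignment[sp] = [(lineages.get(sp, case_id), 1.0)]
                else:
                    origin[sp] = "lost"
            else:
                origin[sp] = "lost"    # donor species that did not engraft

        # inject new strains (previously undetected species preferred)
        n_new = int(round(cfg.new_strain_rate * max(len(post_abund), 1)))
        candidates = [sp for sp in species
                      if sp not in pre_set and sp not in donor_set]
        rng.shuffle(candidates)
        for sp in candidates[:n_new]:
            origin[sp] = "new"
            post_abund[sp] = float(np.median(list(post_abund.values()))
                                   if post_abund else 1.0) * \
                float(rng.lognormal(-0.5, 0.5))
            post_assignment[sp] = [(lineages.get(sp, f"{case_id}_new"), 1.0)]

        post_comm = pd.Series(0.0, index=species)
        if post_abund:
            vals = close(np.array(list(post_abund.values())))
            for sp, v in zip(post_abund, vals):
                post_comm[sp] = v

        for sp in sorted(origin):
            truth_rows.append({
                "case_id": case_id, "species_id": sp,
                "origin": origin[sp],
                "engrafted": bool(engrafted.get(sp, False)),
                "mixture_frac": mixture.get(sp, np.nan),
                "ambiguous": sp in ambiguous,
                "in_pre": sp in pre_set, "in_donor": sp in donor_set,
                "post_abundance": float(post_comm[sp]),
            })

        # render samples
        pre_assignment = {sp: [(lineages.get(sp, case_id), 1.0)]
                          for sp in pre_set}
        pre_profiles = render_sample(pre[pre > 0].to_dict(), pre_assignment,
                                     cfg.depth, cfg.error_rate, seed=rng,
                                     catalog=catalog,
                                     sample_id=f"{case_id}_pre")
        pre_sample = Sample(f"{case_id}_pre", case_id, "pre", -7.0,
                            pre, pre_profiles)
        n_posts = int(rng.integers(cfg.posts_per_case[0],
                                   cfg.posts_per_case[1] + 1))
        days = np.sort(rng.uniform(*cfg.day_range, size=n_posts))
        post_samples = []
        for k, day in enumerate(days):
            pp = render_sample(post_comm[post_comm > 0].to_dict(),
                               post_assignment, cfg.depth, cfg.error_rate,
                               seed=rng, catalog=catalog,
                               sample_id=f"{case_id}_post{k}")
            post_samples.append(Sample(
                f"{case_id}_post{k}", case_id, "post", float(day),
                post_comm, pp,
                post_abx=bool(rng.random() < cfg.post_abx_rate)))

        cases.append(FMTCase(
            case_id=case_id, study_id=study_id, donor_id=donor_id,
            covariates={
                "abx": abx[c], "lavage": lavage[c], "n_fmts": n_fmts[c],
                "sham": sham, "pooled_donor": 0.0,
                "recipient_shannon": float(r_sh_z[case_id]),
                "donor_shannon": float(d_sh_z[donor_id]),
                "recipient_dist_to_controls": float(r_dist_z[case_id]),
                "recipient_donor_distance": float(rd_dist_z[case_id]),
            },
            pre_samples=[pre_sample], post_samples=post_samples))

    truth = pd.DataFrame(truth_rows)
    return Cohort(catalog, cases, donors, controls, truth, beta, cfg)


@dataclass
class UnrelatedPairs:
    """Rendered sample pairs with conspecific lineages forced apart."""

    pairs: list                # list of (profiles_a, profiles_b)
    divergence_floor: float
    true_shared_per_pair: list


def generate_unrelated_pairs(n_pairs: int, catalog: SpeciesCatalog,
                             seed=None, n_species: int = 50,
                             depth: float = 30.0, error_rate: float = 0.001,
                             divergence_floor: float = 0.01,
                             lognormal_sigma: float = 1.0) -> UnrelatedPairs:
    """Render pairs of samples with no shared strains by construction.

    Every conspecific genotype pair across the two samples of a pair is
    forced to differ at >= ``divergence_floor`` of alignment positions
    (exact substitution counts), so the true shared-lineage count is zero
    for every pair.  A floor at or below twice the calling threshold's
    complement (0.2% for a 99.9% MVS cutoff) triggers a warning: such pairs
    are within the caller's resolving power and false positives are
    expected.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if divergence_floor <= 2 * 0.001:
        warnings.warn(
            "divergence floor at or below the MVS threshold's resolving "
            "power; unrelated pairs may be indistinguishable from shared "
            "strains")
    rng = np.random.default_rng(seed)
    all_species = list(catalog.table.index)
    pairs = []
    for i in range(n_pairs):
        chosen = list(rng.choice(all_species,
                                 size=min(n_species, len(all_species)),
                                 replace=False))
        pair_profiles = []
        genotypes_a = {}
        for which in ("a", "b"):
            raw = rng.lognormal(0.0, lognormal_sigma, size=len(chosen))
            comm = dict(zip(chosen, close(raw)))
            assignment = {}
            for sp in chosen:
                L = catalog.marker_length(sp)
                if which == "a":
                    g = random_genotype(sp, L, rng, f"p{i}:{sp}:a")
                    genotypes_a[sp] = g
                else:
                    d = rng.uniform(divergence_floor, 1.5 * divergence_floor)
                    n_mut = int(np.ceil(d * L))
                    g = mutate_strain(genotypes_a[sp], n_mut / L, seed=rng,
                                      lineage_id=f"p{i}:{sp}:b", exact=True)
                assignment[sp] = [(g, 1.0)]
            pair_profiles.append(render_sample(
                comm, assignment, depth, error_rate, seed=rng,
                catalog=catalog, sample_id=f"pair{i}_{which}"))
        pairs.append(tuple(pair_profiles))
    return UnrelatedPairs(pairs, divergence_floor, [0] * n_pairs)
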