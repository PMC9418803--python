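"""Table-level generative simulators for the engraftment mixed models.

These simulators draw model-ready tables directly from the binomial-logit
generative process (covariates on their final, model scale; known fixed
effects; Gaussian random intercepts), bypassing sequence rendering.  They
are the workhorses for parameter-recovery and donor-swap experiments, where
hundreds of cohorts must be drawn cheaply.

Default fixed-effect magnitudes are of the scale reported for clinical
FMT cohorts (antibiotic pretreatment ~ +2.1 log-odds, bowel lavage +1.8,
repeated FMTs +0.7, donor alpha-diversity +0.8, recipient
alpha-diversity -0.6, and so on), so the synthetic cohorts pose a
realistically scaled estimation problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ..metrics import close, shannon

CASE_COVARIATES = [
    "abx", "lavage", "n_fmts", "pooled_donor",
    "recipient_shannon", "donor_shannon",
    "recipient_dist_to_controls", "recipient_donor_distance",
    "days_since_fmt",
]

STRAIN_COVARIATES = [
    "donor_abundance", "recipient_abundance", "abundance_interaction",
    "oral_habitat", "spore_forming", "oxygen_tolerant", "gram_positive",
    "abx", "lavage", "n_fmts", "recipient_shannon", "donor_shannon",
]


def default_beta_case() -> dict:
    """Generative case-level coefficients (logit scale)."""
    return {
        "intercept": -1.0,
        "abx": 2.09,
        "lavage": 1.83,
        "n_fmts": 0.71,
        "pooled_donor": 0.44,
        "recipient_shannon": -0.61,
        "donor_shannon": 0.83,
        "recipient_dist_to_controls": 0.46,
        "recipient_donor_distance": 0.13,
        "days_since_fmt": -0.01,
    }


def default_beta_strain() -> dict:
    """Generative strain-level coefficients (logit scale)."""
    return {
        "intercept": -2.0,
        "donor_abundance": 1.51,
        "recipient_abundance": -0.06,
        "abundance_interaction": -0.07,
        "oral_habitat": -0.81,
        "spore_forming": -0.12,
        "oxygen_tolerant": -0.11,
        "gram_positive": -0.20,
        "abx": 1.0,
        "lavage": 0.8,
        "n_fmts": 0.4,
        "recipient_shannon": -0.5,
        "donor_shannon": 0.5,
    }


def _clinical_covariates(rng, n):
    return {
        "abx": (rng.random(n) < 0.5).astype(float),
        "lavage": (rng.random(n) < 0.5).astype(float),
        "n_fmts": rng.choice([0.0, 1.0, 2.0], size=n, p=[0.6, 0.25, 0.15]),
        "pooled_donor": (rng.random(n) < 0.3).astype(float),
    }


def simulate_case_table(n_cases: int = 200, n_studies: int = 8,
                        beta: dict | None = None, tau_case: float = 0.8,
                        tau_study: float = 0.5, mean_strains: float = 40,
                        max_posts: int = 3, seed=None):
    """Simulate a case-level model table (one row per post-FMT sample).

    Each case belongs to a study, carries clinical covariates and z-scored
    microbiota covariates, and contributes 1..max_posts post-FMT samples.
    Per sample, ``successes`` donor-derived strains out of
    ``successes + failures`` donor+recipient strains are drawn
    Binomial(n, logit^-1(beta'x + u_case + u_study)).

    Returns ``(table, truth)`` where truth holds the generative beta and
    random-intercept SDs.
    """
    beta = dict(beta or default_beta_case())
    rng = np.random.default_rng(seed)
    study_of = rng.integers(0, n_studies, size=n_cases)
    u_study = rng.normal(0, tau_study, size=n_studies)
    u_case = rng.normal(0, tau_case, size=n_cases)
    cov = _clinical_covariates(rng, n_cases)
    for name in ("recipient_shannon", "donor_shannon",
                 "recipient_dist_to_controls", "recipient_donor_distance"):
        cov[name] = rng.normal(0, 1, size=n_cases)
    rows = []
    for c in range(n_cases):
        for s in range(int(rng.integers(1, max_posts + 1))):
            day = float(rng.uniform(5, 120))
            day_z = (day - 62.5) / 33.2  # moments of U(5, 120)
            x = {k: cov[k][c] for k in cov}
            x["days_since_fmt"] = day_z
            eta = beta["intercept"] + u_case[c] + u_study[study_of[c]]
            eta += sum(beta.get(k, 0.0) * v for k, v in x.items())
            n_strains = 1 + int(rng.poisson(mean_strains))
            successes = int(rng.binomial(n_strains, expit(eta)))
            rows.append({
                "case_id": f"c{c:03d}", "study_id": f"st{study_of[c]:02d}",
                "sample_id": f"c{c:03d}_p{s}", "day": day,
                "successes": successes, "failures": n_strains - successes,
                **x,
            })
    table = pd.DataFrame(rows)
    truth = {"beta": beta, "tau_case": tau_case, "tau_study": tau_study}
    return table, truth


@dataclass
class StrainCohort:
    """A strain-level synthetic cohort: donors, recipients, outcomes.

    Holds everything needed to rebuild model rows for arbitrary
    recipient/donor pairings (donor-swap simulation): per-donor and
    per-case species abundance profiles, species features, clinical
    covariates, and the abundance z-scoring constants used throughout.
    """

    table: pd.DataFrame
    cases: pd.DataFrame
    donor_abund: pd.DataFrame      # donors x species relative abundance
    recip_abund: pd.DataFrame      # cases x species relative abundance
    features: pd.DataFrame         # species x (+1/-1 coded, imputed) features
    genus: pd.Series
    beta: dict
    taus: dict
    abund_scaling: tuple           # (mean, sd) of log10(a + 1e-5)
    shannon_scaling: dict          # per-role (mean, sd)
    u_case: pd.Series = None
    u_study: pd.Series = None
    u_donor: pd.Series = None

    def abund_z(self, a):
        m, s = self.abund_scaling
        return (np.log10(np.asarray(a, dtype=float) + 1e-5) - m) / s

    def pairing_rows(self, case_id: str, donor_id: str) -> pd.DataFrame:
        """Model rows for a (possibly counterfactual) recipient/donor pair."""
        case = self.cases.loc[case_id]
        dab = self.donor_abund.loc[donor_id]
        species = dab.index[dab.values > 0]
        rab = self.recip_abund.loc[case_id, species]
        dz = self.abund_z(dab[species].values)
        rz = self.abund_z(rab.values)
        m, s = self.shannon_scaling["donor"]
        donor_sh = (shannon(close(self.donor_abund.loc[donor_id].values
                                  + 1e-12)) - m) / s
        rows = pd.DataFrame({
            "case_id": case_id, "study_id": case["study_id"],
            "donor_id": donor_id, "species_id": species,
            "genus": self.genus[species].values,
            "donor_abundance": dz, "recipient_abundance": rz,
            "abundance_interaction": dz * rz,
            "abx": case["abx"], "lavage": case["lavage"],
            "n_fmts": case["n_fmts"],
            "recipient_shannon": case["recipient_shannon"],
            "donor_shannon": donor_sh,
        })
        for f in ("oral_habitat", "spore_forming", "oxygen_tolerant",
                  "gram_positive"):
            rows[f] = self.features.loc[species, f].values
        return rows

    def add_super_donor(self, donor_id: str = "super") -> str:
        """Engineer a donor carrying every donor-observed species at the
        maximum abundance seen in any donor (closed), i.e. a uniformly
        high-propagule, gut-adapted inoculum."""
        best = self.donor_abund.max(axis=0)
        self.donor_abund.loc[donor_id] = close(best.values)
        return donor_id


def _lognormal_communities(rng, n, species, prevalence, sigma):
    """n communities over `species` with per-species presence probability."""
    present = rng.random((n, len(species))) < prevalence[None, :]
    # guarantee non-empty communities
    for i in np.flatnonzero(~present.any(axis=1)):
        present[i, rng.integers(len(species))] = True
    raw = np.where(present, rng.lognormal(0.0, sigma, (n, len(species))), 0.0)
    return pd.DataFrame(close(raw), columns=species)


def simulate_strain_cohort(n_cases: int = 60, n_donors: int = 20,
                           n_studies: int = 4, n_species: int = 120,
                           beta: dict | None = None,
                           tau_case: float = 0.5, tau_study: float = 0.3,
                           tau_donor: float = 0.3,
                           prevalence_mean: float = 0.35,
                           lognormal_sigma: float = 1.0,
                           feature_missing_rate: float = 0.1,
                           seed=None) -> StrainCohort:
    """Simulate a strain-level cohort with known engraftment coefficients.

    One model row per species detected in the case's donor; the engraftment
    indicator is Bernoulli(logit^-1(beta'x + u_case + u_study + u_donor)).
    Species features are coded +1/-1 with missing values replaced by the
    feature's mean (so imputation carries no information), and abundances
    enter as z-scored log10 values, mirroring the analysis model.
    """
    from .catalog import FEATURES, generate_catalog

    beta = dict(beta or default_beta_strain())
    rng = np.random.default_rng(seed)
    catalog = generate_catalog(n_species, feature_missing_rate,
                               seed=rng.integers(2**31))
    species = catalog.table.index
    feats = catalog.table[FEATURES].copy()
    feats = feats.fillna(feats.mean())

    prevalence = np.clip(
        rng.beta(2.0, 2.0 * (1 - prevalence_mean) / prevalence_mean,
                 size=n_species), 0.02, 0.95)
    donor_abund = _lognormal_communities(rng, n_donors, species, prevalence,
                                         lognormal_sigma)
    donor_abund.index = [f"d{j:03d}" for j in range(n_donors)]
    recip_abund = _lognormal_communities(rng, n_cases, species, prevalence,
                                         lognormal_sigma)
    recip_abund.index = [f"c{c:03d}" for c in range(n_cases)]

    la = np.log10(donor_abund.values[donor_abund.values > 0] + 1e-5)
    abund_scaling = (float(la.mean()), float(la.std()))
    d_sh = np.array([shannon(close(v + 1e-12))
                     for v in donor_abund.values])
    r_sh = np.array([shannon(close(v + 1e-12))
                     for v in recip_abund.values])
    shannon_scaling = {
        "donor": (float(d_sh.mean()), float(d_sh.std() + 1e-9)),
        "recipient": (float(r_sh.mean()), float(r_sh.std() + 1e-9)),
    }

    donor_study = rng.integers(0, n_studies, size=n_donors)
    u_study = rng.normal(0, tau_study, size=n_studies)
    u_case = rng.normal(0, tau_case, size=n_cases)
    u_donor = rng.normal(0, tau_donor, size=n_donors)
    clin = _clinical_covariates(rng, n_cases)

    cases = []
    for c in range(n_cases):
        d = int(rng.integers(n_donors))
        st = donor_study[d]
        m, s = shannon_scaling["recipient"]
        cases.append({
            "case_id": f"c{c:03d}", "study_id": f"st{st:02d}",
            "donor_id": f"d{d:03d}",
            "abx": clin["abx"][c], "lavage": clin["lavage"][c],
            "n_fmts": clin["n_fmts"][c],
            "recipient_shannon": (r_sh[c] - m) / s,
        })
    cases = pd.DataFrame(cases).set_index("case_id", drop=False)

    cohort = StrainCohort(
        table=None, cases=cases, donor_abund=donor_abund,
        recip_abund=recip_abund, features=feats,
        genus=catalog.table["genus"], beta=beta,
        taus={"case": tau_case, "study": tau_study, "donor": tau_donor},
        abund_scaling=abund_scaling, shannon_scaling=shannon_scaling,
        u_case=pd.Series(u_case, index=cases.index),
        u_study=pd.Series(u_study, index=[f"st{j:02d}"
                                          for j in range(n_studies)]),
        u_donor=pd.Series(u_donor, index=donor_abund.index),
    )
    parts = []
    for case_id in cases.index:
        rows = cohort.pairing_rows(case_id, cases.loc[case_id, "donor_id"])
        eta = (beta["intercept"]
               + cohort.u_case[case_id]
               + cohort.u_study[rows["study_id"].iloc[0]]
               + cohort.u_donor[rows["donor_id"].iloc[0]])
        eta = eta + sum(beta.get(k, 0.0) * rows[k].values
                        for k in STRAIN_COVARIATES)
        rows["p_true"] = expit(eta)
        rows["engrafted"] = (rng.random(len(rows)) < rows["p_true"]).astype(int)
        parts.append(rows)
    cohort.table = pd.concat(parts, ignore_index=True)
    return cohort


def simulate_metric_cohort(seed=None, shift: float = 0.0,
                           n_control_studies: int = 9,
                           n_fmt_studies: int = 9,
                           controls_per_study: int = 8,
                           cases_per_study: int = 6,
                           samples_per_case: int = 2,
                           tau_study: float = 0.3, tau_case: float = 0.5,
                           sigma: float = 1.0):
    """Simulate one continuous-metric table for group-vs-control testing.

    Emulates the reference-cohort design: control samples come from their
    own studies (one sample per subject), post-FMT samples from separate
    studies with repeated sampling per case.  ``shift`` is added to the
    post-FMT group mean (0 gives the null).  Returns
    ``(metric_table, sample_type, study, case)`` aligned on sample id.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for st in range(n_control_studies):
        u_st = rng.normal(0, tau_study)
        for i in range(controls_per_study):
            sid = f"ctl{st}_{i}"
            rows.append((sid, "control", f"cs{st}", sid,
                         rng.normal(u_st, sigma)))
    for st in range(n_fmt_studies):
        u_st = rng.normal(0, tau_study)
        for c in range(cases_per_study):
            u_c = rng.normal(0, tau_case)
            for s in range(samples_per_case):
                sid = f"p{st}_{c}_{s}"
                rows.append((sid, "post", f"ps{st}", f"p{st}_{c}",
                             rng.normal(shift + u_st + u_c, sigma)))
    df = pd.DataFrame(rows, columns=["sample_id", "sample_type", "study",
                                     "case", "metric"]).set_index("sample_id")
    return (df[["metric"]], df["sample_type"], df["study"], df["case"])
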