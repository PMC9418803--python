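"""Origin attribution of post-FMT strains and engraftment summaries.

For every species detected in a post-FMT sample the strain is classified,
by pairwise shared-strain comparisons against the pre-FMT recipient and the
(pooled) donor, as donor-derived, recipient-derived, coexisting (shared
with both while pre-FMT recipient and donor carried distinct strains), new
(shared with neither), or ambiguous (pre-FMT recipient and donor already
shared the strain, so the origin is unidentifiable).  Species whose
comparisons lack the required alignment overlap are reported as unresolved
with a species-level fallback; species present before FMT but absent after
are reported as lost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparison import INSUFFICIENT_OVERLAP, CallParams, compare, \
    pairwise_shared_strains
from .metrics import close, shannon
from .profiles import FilterParams, filter_profile

ORIGIN_LABELS = ["donor", "recipient", "coexist", "new", "lost",
                 "unresolved", "ambiguous"]

COMPETITION_OUTCOMES = ["new", "recipient_only", "donor_only", "coexist",
                        "species_lost", "unresolved"]


class PooledDonor:
    """Donor samples pooled for one case: summed counts, averaged metrics."""

    def __init__(self, profiles: dict, community: pd.Series,
                 mean_shannon: float, n_samples: int):
        self.profiles = profiles
        self.community = community
        self.mean_shannon = mean_shannon
        self.n_samples = n_samples


def pool_donor_samples(samples, filter_params: FilterParams | None = None
                       ) -> PooledDonor:
    """Pool several donor samples of one case.

    Variant profiles are pooled by summing allele counts position-wise
    (masks become the union of coverage); the species set is the union.
    Scalar community metrics are averaged across the samples, and the
    pooled community is the mean abundance vector re-closed.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty donor sample set")
    pooled = {}
    for s in samples:
        for sp, p in s.profiles.items():
            if sp not in pooled:
                pooled[sp] = p
            else:
                q = pooled[sp]
                counts = q.counts + p.counts
                from dataclasses import replace
                pooled[sp] = replace(q, counts=counts,
                                     mask=q.mask | p.mask, filtered=False)
    if filter_params is not None:
        pooled = {sp: filter_profile(p, filter_params)
                  for sp, p in pooled.items()}
    comm = pd.concat([s.community for s in samples], axis=1).fillna(0.0)
    community = pd.Series(close(comm.mean(axis=1).values), index=comm.index)
    mean_sh = float(np.mean([shannon(close(s.community.values + 1e-12))
                             for s in samples]))
    return PooledDonor(pooled, community, mean_sh, len(samples))


def _species_set(community: pd.Series) -> set:
    return set(community.index[community.values > 0])


def attribute_origins(pre, donor: PooledDonor, post,
                      params: CallParams = CallParams(),
                      filter_params: FilterParams = FilterParams()
                      ) -> pd.DataFrame:
    """Classify the origin of every species in one post-FMT sample.

    Parameters
    ----------
    pre, post : Sample-like with ``.profiles`` (dict) and ``.community``
        (Series); profiles may be raw (they are filtered here).
    donor : PooledDonor with already-filtered profiles.

    Returns
    -------
    OriginTable: one row per species present in the post sample plus one
    row per lost species (present pre/donor, absent post), with columns
    species_id, label, rel_abundance, species_shared_pre,
    species_shared_donor.  Labels partition the species set.
    """
    if post is None or post.profiles is None:
        raise ValueError("missing post-FMT profile set")

    def prep(profiles):
        return {sp: (p if p.filtered else filter_profile(p, filter_params))
                for sp, p in profiles.items()}

    pre_prof = prep(pre.profiles)
    post_prof = prep(post.profiles)
    donor_prof = prep(donor.profiles)

    pre_set = _species_set(pre.community)
    donor_set = _species_set(donor.community)
    post_set = _species_set(post.community)

    def shared(prof_a, prof_b, sp):
        """True/False/None(=insufficient overlap or missing profile)."""
        if sp not in prof_a or sp not in prof_b:
            return None
        r = compare(prof_a[sp], prof_b[sp], params)
        return None if r.shared_call == INSUFFICIENT_OVERLAP else r.shared_call

    rows = []
    for sp in sorted(post_set):
        in_pre, in_don = sp in pre_set, sp in donor_set
        s_pre = shared(post_prof, pre_prof, sp) if in_pre else False
        s_don = shared(post_prof, donor_prof, sp) if in_don else False
        if (in_pre and s_pre is None) or (in_don and s_don is None):
            label = "unresolved"
        elif s_pre and s_don:
            s_pd = shared(pre_prof, donor_prof, sp)
            label = "ambiguous" if s_pd in (True, None) else "coexist"
        elif s_pre:
            label = "recipient"
        elif s_don:
            label = "donor"
        else:
            label = "new"
        rows.append({
            "species_id": sp, "label": label,
            "rel_abundance": float(post.community[sp]),
            "species_shared_pre": in_pre, "species_shared_donor": in_don,
        })
    for sp in sorted((pre_set | donor_set) - post_set):
        rows.append({
            "species_id": sp, "label": "lost", "rel_abundance": 0.0,
            "species_shared_pre": sp in pre_set,
            "species_shared_donor": sp in donor_set,
        })
    out = pd.DataFrame(rows, columns=["species_id", "label", "rel_abundance",
                                      "species_shared_pre",
                                      "species_shared_donor"])
    out.insert(0, "sample_id", getattr(post, "sample_id", ""))
    return out


def engraftment_summary(origin_tables: dict, days: dict | None = None,
                        post_abx: dict | None = None, which: str = "all",
                        exclude_post_abx: bool = False,
                        max_day: float | None = None) -> pd.DataFrame:
    """Per-sample engraftment fractions from origin tables.

    ``origin_tables`` maps sample_id -> OriginTable.  The donor fraction is
    n_donor / (n_donor + n_recipient); the coexist fraction is reported
    relative to the same denominator.  Ambiguous strains are excluded from
    the denominator.  Abundance-weighted analogs sum relative abundances.
    With ``which='latest'`` only the sample with the largest day offset is
    kept; ``max_day`` restricts to samples collected no later than that
    day; ``exclude_post_abx`` drops samples flagged as antibiotic-exposed
    after FMT.
    """
    days = days or {}
    post_abx = post_abx or {}
    ids = list(origin_tables)
    if exclude_post_abx:
        ids = [s for s in ids if not post_abx.get(s, False)]
    if max_day is not None:
        ids = [s for s in ids if days.get(s, 0) <= max_day]
    if which == "latest" and ids:
        ids = [max(ids, key=lambda s: days.get(s, 0))]
    rows = []
    for sid in ids:
        tab = origin_tables[sid]
        n = tab["label"].value_counts()
        ab = tab.groupby("label")["rel_abundance"].sum()
        n_d, n_r = int(n.get("donor", 0)), int(n.get("recipient", 0))
        n_c = int(n.get("coexist", 0))
        denom = n_d + n_r
        rows.append({
            "sample_id": sid, "day": days.get(sid, np.nan),
            "n_donor": n_d, "n_recipient": n_r, "n_coexist": n_c,
            "n_new": int(n.get("new", 0)),
            "n_unresolved": int(n.get("unresolved", 0)),
            "n_ambiguous": int(n.get("ambiguous", 0)),
            "donor_fraction": n_d / denom if denom else np.nan,
            "recipient_fraction": n_r / denom if denom else np.nan,
            "coexist_fraction": n_c / denom if denom else np.nan,
            "donor_abundance": float(ab.get("donor", 0.0)),
            "recipient_abundance": float(ab.get("recipient", 0.0)),
            "coexist_abundance": float(ab.get("coexist", 0.0)),
            "new_abundance": float(ab.get("new", 0.0)),
            "unresolved_abundance": float(ab.get("unresolved", 0.0)),
        })
    return pd.DataFrame(rows)


def classify_competition_outcomes(origin_tables) -> pd.Series:
    """Six-way outcome counts for species present in BOTH pre and donor.

    Given per-case origin tables (latest post-FMT sample per case), counts
    how conspecific recipient/donor strain competition resolved: a new
    strain, recipient only, donor only, coexistence, species loss, or
    unresolved (which also absorbs ambiguous pre-shared lineages, keeping
    the table an exact partition of the qualifying species).
    """
    mapping = {"new": "new", "recipient": "recipient_only",
               "donor": "donor_only", "coexist": "coexist",
               "lost": "species_lost", "unresolved": "unresolved",
               "ambiguous": "unresolved"}
    counts = {k: 0 for k in COMPETITION_OUTCOMES}
    tables = origin_tables.values() if isinstance(origin_tables, dict) \
        else origin_tables
    for tab in tables:
        qual = tab[tab["species_shared_pre"] & tab["species_shared_donor"]]
        for label in qual["label"]:
            counts[mapping[label]] += 1
    return pd.Series(counts)


def donor_species_fate(origin_table: pd.DataFrame) -> pd.Series:
    """Fate fractions over all species detected in the donor.

    ``engrafted_new_species``: donor strain engrafted into a species niche
    empty before FMT; ``engrafted_replacement``: donor strain displaced a
    pre-existing recipient strain; ``not_engrafted``: donor species with no
    donor strain post-FMT (including species loss).  The remainder
    (coexisting, ambiguous, and unresolved donor species) brings the sum
    to 1.
    """
    don = origin_table[origin_table["species_shared_donor"]]
    total = len(don)
    if total == 0:
        return pd.Series({"not_engrafted": np.nan,
                          "engrafted_new_species": np.nan,
                          "engrafted_replacement": np.nan,
                          "remainder": np.nan})
    is_donor = don["label"] == "donor"
    new_niche = int((is_donor & ~don["species_shared_pre"]).sum())
    replacement = int((is_donor & don["species_shared_pre"]).sum())
    not_eng = int(don["label"].isin(["recipient", "new", "lost"]).sum())
    rem = total - new_niche - replacement - not_eng
    return pd.Series({
        "not_engrafted": not_eng / total,
        "engrafted_new_species": new_niche / total,
        "engrafted_replacement": replacement / total,
        "remainder": rem / total,
    })


def false_positive_assessment(pairs, params: CallParams = CallParams(),
                              filter_params: FilterParams = FilterParams()):
    """Shared-strain counts across unrelated sample pairs.

    ``pairs`` is an iterable of (profiles_a, profiles_b) dicts.  Returns
    ``(summary, per_pair)``: mean and SD of called shared strains per pair,
    plus the per-pair counts table.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    counts = []
    for profiles_a, profiles_b in pairs:
        fa = {sp: filter_profile(p, filter_params)
              for sp, p in profiles_a.items()}
        fb = {sp: filter_profile(p, filter_params)
              for sp, p in profiles_b.items()}
        _, n_shared = pairwise_shared_strains(fa, fb, params)
        counts.append(n_shared)
    per_pair = pd.DataFrame({"pair": range(len(counts)),
                             "shared_strains": counts})
    summary = {"mean": float(np.mean(counts)),
               "sd": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
               "n_pairs": len(counts)}
    return summary, per_pair


def exclude_sham_cases(cohort, params: CallParams = CallParams(),
                       filter_params: FilterParams = FilterParams()
                       ) -> pd.DataFrame:
    """Flag cases with zero donor-shared strains in every post-FMT sample.

    Mirrors the exclusion of sham/placebo arms when donor assignment is
    uncertain: a case is flagged iff no post-FMT sample shares a single
    strain with the (pooled) donor.
    """
    rows = []
    for case in cohort.cases:
        donor = pool_donor_samples(cohort.donor_samples(case), filter_params)
        total = 0
        for post in case.post_samples:
            fp = {sp: filter_profile(p, filter_params)
                  for sp, p in post.profiles.items()}
            _, n = pairwise_shared_strains(fp, donor.profiles, params)
            total += n
        rows.append({"case_id": case.case_id, "donor_shared_strains": total,
                     "sham": total == 0})
    return pd.DataFrame(rows)
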