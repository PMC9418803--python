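"""Case-level and strain-level binomial-logit mixed engraftment models.

The case model regresses per-sample donor-derived strain fractions
(successes = donor strains, failures = recipient strains) on centered and
scaled microbiota and clinical covariates with random intercepts for case
and study.  The strain model regresses the per-donor-species engraftment
indicator on abundances (log10, z-scored), their interaction, +/-1 coded
lifestyle features (mean-imputed when missing), and the clinical
covariates, with random intercepts for case, study, and donor.  On top of
the fits sit the marginal-effect, abundance-substitution, pairing
prediction, and donor-swap simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .glmm import GLMMFit, MixedGLM
from .synthetic.tables import CASE_COVARIATES, STRAIN_COVARIATES

FEATURE_COLS = ["oral_habitat", "spore_forming", "oxygen_tolerant",
                "gram_positive"]


@dataclass
class ModelFit:
    """A fitted engraftment GLMM plus the bookkeeping to use it.

    ``scaling`` maps covariate -> (mean, sd) applied before fitting, so
    predictions can accept covariates on their natural scale and estimates
    can be back-transformed.
    """

    glmm: GLMMFit
    covariates: list
    scaling: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)
    groups: list = field(default_factory=list)

    @property
    def params(self):
        return self.glmm.params

    @property
    def converged(self):
        return self.glmm.converged

    def summary(self) -> pd.DataFrame:
        return self.glmm.summary()

    def design(self, table: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(table))]
        for c in self.covariates:
            v = table[c].astype(float).values
            if c in self.scaling:
                m, s = self.scaling[c]
                v = (v - m) / s
            cols.append(v)
        return np.column_stack(cols)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Population-level predictions (random effects at zero)."""
        return expit(self.design(table) @ self.params.values)

    def save(self, path) -> None:
        """Serialize coefficients, covariances, scaling, and metadata."""
        import json
        payload = {
            "params": self.params.to_dict(),
            "se": self.glmm.se.to_dict(),
            "cov_params": self.glmm.cov_params.values.tolist(),
            "param_order": list(self.params.index),
            "re_sd": self.glmm.re_sd,
            "family": self.glmm.family,
            "loglik": self.glmm.loglik,
            "converged": self.glmm.converged,
            "covariates": self.covariates,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "dropped": self.dropped,
            "groups": self.groups,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelFit":
        import json
        with open(path) as fh:
            d = json.load(fh)
        order = d["param_order"]
        glmm = GLMMFit(
            params=pd.Series(d["params"]).reindex(order),
            se=pd.Series(d["se"]).reindex(order),
            re_sd=d["re_sd"], scale=None, loglik=d["loglik"],
            converged=d["converged"], message="loaded",
            family=d["family"],
            cov_params=pd.DataFrame(d["cov_params"], index=order,
                                    columns=order))
        return cls(glmm, d["covariates"],
                   {k: tuple(v) for k, v in d["scaling"].items()},
                   d["dropped"], d["groups"])

    def predict_ci(self, table: pd.DataFrame, alpha: float = 0.05):
        """Mean predicted probability with a Wald CI (delta method)."""
        X = self.design(table)
        eta = X @ self.params.values
        p = expit(eta)
        grad = (p * (1 - p))[:, None] * X
        g = grad.mean(axis=0)
        var = float(g @ self.glmm.cov_params.values @ g)
        q = norm.ppf(1 - alpha / 2)
        half = q * np.sqrt(max(var, 0))
        return float(p.mean()), float(p.mean() - half), float(p.mean() + half)


def _scale_columns(table: pd.DataFrame, cols, scale: bool):
    scaling, dropped, kept = {}, [], []
    for c in cols:
        v = table[c].astype(float)
        if v.std() == 0 or v.isna().all():
            warnings.warn(f"covariate '{c}' has zero variance; dropped")
            dropped.append(c)
            continue
        kept.append(c)
        if scale:
            scaling[c] = (float(v.mean()), float(v.std()))
    return kept, scaling, dropped


def build_case_table(cohort, summaries: pd.DataFrame,
                     metrics: pd.DataFrame | None = None,
                     scale: bool = True,
                     exclude_post_abx: bool = True) -> pd.DataFrame:
    """Assemble the case-level model table from attribution summaries.

    One row per non-excluded post-FMT sample with successes/failures and
    the case covariates.  Cases flagged ``impute_pre`` get their pre-FMT
    microbiota metrics replaced by the mean over antibiotically pretreated
    cases (the handling used when pre-treatment baselines are missing).
    Covariates are centered and scaled; the scaling constants are attached
    as ``table.attrs['scaling']``.
    """
    rows = []
    for case in cohort.cases:
        cov = case.covariates
        for post in case.post_samples:
            if exclude_post_abx and post.post_abx:
                continue
            summ = summaries[summaries["sample_id"] == post.sample_id]
            if summ.empty:
                continue
            r = summ.iloc[0]
            if r["n_donor"] + r["n_recipient"] < 1:
                continue
            rows.append({
                "case_id": case.case_id, "study_id": case.study_id,
                "sample_id": post.sample_id, "day": post.day,
                "successes": int(r["n_donor"]),
                "failures": int(r["n_recipient"]),
                "impute_pre": bool(cov.get("impute_pre", False)),
                "abx": cov["abx"], "lavage": cov["lavage"],
                "n_fmts": cov["n_fmts"],
                "pooled_donor": cov.get("pooled_donor", 0.0),
                "recipient_shannon": cov["recipient_shannon"],
                "donor_shannon": cov["donor_shannon"],
                "recipient_dist_to_controls": cov["recipient_dist_to_controls"],
                "recipient_donor_distance": cov["recipient_donor_distance"],
                "days_since_fmt": post.day,
            })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    pre_metric_cols = ["recipient_shannon", "recipient_dist_to_controls",
                       "recipient_donor_distance"]
    if table["impute_pre"].any():
        # means over observed (non-imputed) antibiotically pretreated cases
        abx_mask = (table["abx"] > 0) & ~table["impute_pre"]
        means = table.loc[abx_mask, pre_metric_cols].mean()
        for c in pre_metric_cols:
            table.loc[table["impute_pre"], c] = means[c]
    if scale:
        kept, scaling, _ = _scale_columns(table, CASE_COVARIATES, True)
        for c in kept:
            m, s = scaling[c]
            table[c] = (table[c] - m) / s
        table.attrs["scaling"] = scaling
    return table


def _fit(table, response_cols, covariates, groups, scale_in_fit):
    kept, scaling, dropped = _scale_columns(table, covariates, scale_in_fit)
    X = np.column_stack(
        [np.ones(len(table))] +
        [((table[c].astype(float) - scaling[c][0]) / scaling[c][1]
          if c in scaling else table[c].astype(float)).values
         for c in kept])
    names = ["intercept"] + kept
    grp = {g: table[g].values for g in groups}
    if len(response_cols) == 2:
        y = table[response_cols[0]].values
        trials = y + table[response_cols[1]].values
    else:
        y = table[response_cols[0]].values
        trials = None
    model = MixedGLM(X, y, grp, family="binomial", trials=trials,
                     names=names)
    fit = model.fit()
    return ModelFit(fit, kept, scaling, dropped, list(groups))


def fit_case_glmm(table: pd.DataFrame, covariates=None,
                  scale_in_fit: bool = False) -> ModelFit:
    """Fit the case-level engraftment GLMM.

    Response: successes (donor strains) / failures (recipient strains) per
    post-FMT sample; random intercepts for case and study.  With fewer
    than two studies the study intercept is dropped (logged via warning).
    Set ``scale_in_fit`` if the table's covariates are not already
    centered/scaled.
    """
    covariates = [c for c in (covariates or CASE_COVARIATES)
                  if c in table.columns]
    groups = ["case_id", "study_id"]
    if table["study_id"].nunique() < 2:
        warnings.warn("fewer than 2 studies: dropping study random effect")
        groups = ["case_id"]
    if table["case_id"].nunique() < 2:
        warnings.warn("single case: dropping case random effect")
        groups = [g for g in groups if g != "case_id"]
    return _fit(table, ("successes", "failures"), covariates, groups,
                scale_in_fit)


def fit_strain_glmm(table: pd.DataFrame, covariates=None,
                    scale_in_fit: bool = False) -> ModelFit:
    """Fit the strain-level engraftment GLMM.

    Response: per-donor-species engraftment indicator; random intercepts
    for case, study, and donor.  Feature columns are expected +/-1 coded
    with mean imputation already applied (all-missing features have zero
    variance and are dropped with a warning).
    """
    covariates = [c for c in (covariates or STRAIN_COVARIATES)
                  if c in table.columns]
    groups = [g for g in ("case_id", "study_id", "donor_id")
              if g in table.columns and table[g].nunique() > 1]
    return _fit(table, ("engrafted",), covariates, groups, scale_in_fit)


def marginal_effect(fit: ModelFit, table: pd.DataFrame, variable: str,
                    values) -> pd.DataFrame:
    """Predicted engraftment probability as one covariate is varied.

    For each value, the covariate is set to that value in every row (all
    other covariates at their observed values, random effects at zero) and
    predictions are averaged; Wald CIs by the delta method.  Values are on
    the covariate's natural scale when the fit stored scaling constants.
    """
    if variable not in fit.covariates:
        raise ValueError(f"'{variable}' is not a fixed effect of this model")
    rows = []
    for v in np.atleast_1d(values):
        mod = table.copy()
        mod[variable] = v
        p, lo, hi = fit.predict_ci(mod)
        rows.append({"value": float(v), "probability": p,
                     "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


def genus_probability(fit: ModelFit, table: pd.DataFrame, genus: str,
                      abundance_mode: str = "observed") -> float:
    """Median predicted engraftment probability for one genus.

    ``abundance_mode`` 'min'/'max' substitutes the minimum/maximum donor
    abundance observed for that genus anywhere in the cohort for every row
    (all other covariates held), emulating donor-sample supplementation.
    """
    sub = table[table["genus"] == genus]
    if sub.empty:
        raise ValueError(f"genus '{genus}' absent from table")
    if abundance_mode != "observed":
        col = sub["donor_abundance"].astype(float)
        v = col.min() if abundance_mode == "min" else col.max()
        sub = sub.copy()
        sub["donor_abundance"] = v
        sub["abundance_interaction"] = (
            sub["donor_abundance"] * sub["recipient_abundance"])
    return float(np.median(fit.predict_proba(sub)))


def predict_pairing(fit: ModelFit, rows: pd.DataFrame) -> float:
    """Expected engrafted donor strain count for one recipient/donor pair.

    ``rows`` holds one model row per species detected in the donor (as
    built by e.g. ``StrainCohort.pairing_rows``); the expectation is the
    sum of per-species predicted engraftment probabilities.
    """
    if rows.empty:
        return 0.0
    return float(fit.predict_proba(rows).sum())


@dataclass
class SwapResult:
    """All-pairs donor-swap simulation output."""

    matrix: pd.DataFrame          # recipients x donors expected counts
    actual: pd.Series             # expected count for the true pairing
    log2_fold_change: pd.DataFrame
    best_donor: pd.Series
    worst_donor: pd.Series
    variance_between_donors: float
    variance_between_pairs: float


def donor_swap_matrix(fit: ModelFit, cohort) -> SwapResult:
    """Predict engrafted strain counts for every recipient/donor pairing.

    ``cohort`` must provide ``cases`` (with a ``donor_id`` column),
    ``donor_abund`` and ``pairing_rows(case_id, donor_id)`` (see
    ``StrainCohort``).  Log2 fold-changes are taken against the predicted
    count for the actual pairing, so the actual pairing's fold-change is
    exactly 0, and identical donors produce identical columns.
    """
    case_ids = list(cohort.cases.index)
    donor_ids = list(cohort.donor_abund.index)
    mat = pd.DataFrame(index=case_ids, columns=donor_ids, dtype=float)
    for cid in case_ids:
        for did in donor_ids:
            mat.loc[cid, did] = predict_pairing(
                fit, cohort.pairing_rows(cid, did))
    actual = pd.Series(
        {cid: mat.loc[cid, cohort.cases.loc[cid, "donor_id"]]
         for cid in case_ids})
    eps = 1e-9
    l2fc = np.log2(mat.add(eps).div(actual + eps, axis=0))
    donor_means = mat.mean(axis=0)
    between_donors = float(donor_means.var(ddof=1))
    between_pairs = float(mat.sub(donor_means, axis=1).stack().var(ddof=1))
    return SwapResult(
        matrix=mat, actual=actual, log2_fold_change=l2fc,
        best_donor=mat.astype(float).idxmax(axis=1),
        worst_donor=mat.astype(float).idxmin(axis=1),
        variance_between_donors=between_donors,
        variance_between_pairs=between_pairs,
    )
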