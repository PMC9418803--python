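"""End-to-end pipeline: simulate -> profile -> compare -> attribute ->
metrics -> fit -> swap-simulate, with a manifest and reproducible config.

Every run writes its resolved configuration and a manifest (artifact paths
with SHA-256 checksums) next to its outputs, so reruns with the same
config and seed are bit-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from .comparison import CallParams
from .metrics import metrics_table
from .models import build_case_table, donor_swap_matrix, fit_case_glmm, \
    fit_strain_glmm, predict_pairing
from .profiles import FilterParams, write_profile_tsv
from .synthetic import CohortConfig, generate_fmt_cohort, \
    simulate_strain_cohort


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filter_params: FilterParams = field(default_factory=FilterParams)
    call_params: CallParams = field(default_factory=CallParams)
    latest_only: bool = True
    exclude_post_abx: bool = True
    max_day: float | None = 120.0
    write_profiles: bool = False
    strain_cohort_kwargs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in d["cohort"].items()}
            d["cohort"] = CohortConfig(**c)
        if "filter_params" in d and isinstance(d["filter_params"], dict):
            d["filter_params"] = FilterParams(**d["filter_params"])
        if "call_params" in d and isinstance(d["call_params"], dict):
            d["call_params"] = CallParams(**d["call_params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort_tables(cohort, out: Path, write_profiles: bool = False):
    """Write the cohort's external TSV representation.

    Emits the merged relative-abundance table (species x samples), sample
    metadata, truth labels, and optionally every per-sample per-species
    variant-profile TSV.
    """
    out.mkdir(parents=True, exist_ok=True)
    comm = {}
    meta = []
    for case in cohort.cases:
        for s in case.pre_samples + case.post_samples:
            comm[s.sample_id] = s.community
            meta.append({
                "sample_id": s.sample_id, "subject_id": s.subject_id,
                "case_id": case.case_id, "study_id": case.study_id,
                "donor_id": case.donor_id, "kind": s.kind, "day": s.day,
                "post_abx": s.post_abx, **case.covariates,
            })
    for donor_id, samples in cohort.donors.items():
        for s in samples:
            comm[s.sample_id] = s.community
            meta.append({"sample_id": s.sample_id, "subject_id": donor_id,
                         "case_id": "", "study_id": "", "donor_id": donor_id,
                         "kind": "donor", "day": s.day, "post_abx": False})
    pd.DataFrame(comm).to_csv(out / "abundance.tsv", sep="\t")
    pd.DataFrame(meta).to_csv(out / "metadata.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    cohort.controls.to_csv(out / "controls_abundance.tsv", sep="\t")
    cohort.catalog.table.to_csv(out / "species_catalog.tsv", sep="\t")
    if write_profiles:
        pdir = out / "profiles"
        pdir.mkdir(exist_ok=True)
        for s in cohort.all_samples():
            for sp, p in s.profiles.items():
                write_profile_tsv(p, pdir / f"{s.sample_id}.{sp}.tsv")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Stage failures raise :class:`StageError` naming the stage; artifacts
    written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": {}, "artifacts": {}}
    t_start = time.time()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:   # noqa: BLE001 - re-raised with stage
                raise StageError(name, exc) from exc
            manifest["stages"][name] = round(time.time() - t0, 3)
        return deco

    state = {}
    rng = np.random.default_rng(config.seed)

    @stage("simulate")
    def _simulate():
        state["cohort"] = generate_fmt_cohort(
            config.cohort, seed=int(rng.integers(2**31)))
        write_cohort_tables(state["cohort"], out,
                            write_profiles=config.write_profiles)

    @stage("attribute")
    def _attribute():
        cohort = state["cohort"]
        tables, summaries = {}, []
        for case in cohort.cases:
            donor = attr.pool_donor_samples(cohort.donor_samples(case),
                                            config.filter_params)
            days, post_abx = {}, {}
            case_tables = {}
            for post in case.post_samples:
                tab = attr.attribute_origins(case.pre_samples[0], donor,
                                             post, config.call_params,
                                             config.filter_params)
                tab.insert(0, "case_id", case.case_id)
                case_tables[post.sample_id] = tab
                days[post.sample_id] = post.day
                post_abx[post.sample_id] = post.post_abx
            summ = attr.engraftment_summary(
                case_tables, days, post_abx,
                which="latest" if config.latest_only else "all",
                exclude_post_abx=config.exclude_post_abx,
                max_day=config.max_day)
            summ.insert(0, "case_id", case.case_id)
            summaries.append(summ)
            tables.update(case_tables)
        state["origin_tables"] = tables
        state["summaries"] = pd.concat(summaries, ignore_index=True)
        pd.concat(tables.values(), ignore_index=True).to_csv(
            out / "origin_tables.tsv", sep="\t", index=False)
        state["summaries"].to_csv(out / "engraftment_summary.tsv",
                                  sep="\t", index=False)
        attr.classify_competition_outcomes(
            {s: t for s, t in tables.items()
             if s in set(state["summaries"]["sample_id"])}
        ).rename("count").to_csv(out / "competition_outcomes.tsv", sep="\t")

    @stage("metrics")
    def _metrics():
        cohort = state["cohort"]
        comm = pd.DataFrame({s.sample_id: s.community
                             for s in cohort.all_samples()}).T
        mt = metrics_table(comm, annotations=cohort.catalog.table,
                           reference=cohort.controls.values)
        mt.to_csv(out / "community_metrics.tsv", sep="\t")
        state["metrics"] = mt

    @stage("fit_case_model")
    def _fit_case():
        cohort = state["cohort"]
        # all (non-excluded) post samples enter the model
        all_summ = []
        for case in cohort.cases:
            sub = {s: t for s, t in state["origin_tables"].items()
                   if t["case_id"].iloc[0] == case.case_id}
            days = {p.sample_id: p.day for p in case.post_samples}
            abx = {p.sample_id: p.post_abx for p in case.post_samples}
            summ = attr.engraftment_summary(
                sub, days, abx, which="all",
                exclude_post_abx=config.exclude_post_abx)
            all_summ.append(summ)
        table = build_case_table(cohort, pd.concat(all_summ,
                                                   ignore_index=True))
        state["case_table"] = table
        fit = fit_case_glmm(table)
        state["case_fit"] = fit
        fit.summary().to_csv(out / "case_model_coefficients.tsv", sep="\t")
        json.dump({"re_sd": fit.glmm.re_sd, "converged": fit.converged,
                   "loglik": fit.glmm.loglik,
                   "scaling": {k: list(v) for k, v in fit.scaling.items()}},
                  open(out / "case_model_meta.json", "w"), indent=1)

    @stage("fit_strain_model")
    def _fit_strain():
        sc = simulate_strain_cohort(
            seed=int(rng.integers(2**31)), **config.strain_cohort_kwargs)
        state["strain_cohort"] = sc
        fit = fit_strain_glmm(sc.table)
        state["strain_fit"] = fit
        fit.summary().to_csv(out / "strain_model_coefficients.tsv", sep="\t")

    @stage("swap_sim")
    def _swap():
        sc, fit = state["strain_cohort"], state["strain_fit"]
        swap = donor_swap_matrix(fit, sc)
        swap.matrix.to_csv(out / "swap_matrix.tsv", sep="\t")
        swap.log2_fold_change.to_csv(out / "swap_log2fc.tsv", sep="\t")
        pred = swap.actual
        real = sc.table.groupby("case_id")["engrafted"].sum().reindex(
            pred.index)
        r = float(np.corrcoef(pred, real)[0, 1])
        json.dump({"pairing_correlation": r,
                   "variance_between_donors": swap.variance_between_donors,
                   "variance_between_pairs": swap.variance_between_pairs},
                  open(out / "swap_meta.json", "w"), indent=1)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
    manifest["elapsed"] = round(time.time() - t_start, 3)
    manifest["config_sha256"] = _sha256(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def report(run_dir) -> dict:
    """Collect a completed run's summary tables into one dictionary.

    Mirrors the structure of the headline analyses: per-case origin
    fractions, the competition-outcome partition, model coefficient
    tables, and the donor-swap summary.  Raises if the run is incomplete.
    """
    run = Path(run_dir)
    required = ["engraftment_summary.tsv", "competition_outcomes.tsv",
                "case_model_coefficients.tsv",
                "strain_model_coefficients.tsv", "swap_meta.json"]
    missing = [f for f in required if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing: {missing}")
    out = {
        "engraftment_summary": pd.read_csv(run / "engraftment_summary.tsv",
                                           sep="\t"),
        "competition_outcomes": pd.read_csv(
            run / "competition_outcomes.tsv", sep="\t", index_col=0),
        "case_model": pd.read_csv(run / "case_model_coefficients.tsv",
                                  sep="\t", index_col=0),
        "strain_model": pd.read_csv(run / "strain_model_coefficients.tsv",
                                    sep="\t", index_col=0),
        "swap": json.load(open(run / "swap_meta.json")),
    }
    if (run / "truth_labels.tsv").exists():
        out["truth_labels"] = pd.read_csv(run / "truth_labels.tsv", sep="\t")
    return out
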