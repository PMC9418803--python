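"""Compositional and ecological community metrics.

All logarithms are natural (Shannon in nats, clr and dysbiosis score in
natural-log units).  Compositions are closed (re-normalized) before any
transform; zeros are replaced by an additive pseudocount of half the
smallest nonzero abundance in the matrix unless a pseudocount is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def close(p) -> np.ndarray:
    """Normalize a non-negative vector (or matrix rows) to sum to 1."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    s = p.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("cannot close an all-zero profile")
    return p / s


def shannon(p) -> float:
    """Shannon diversity H = -sum p ln p (nats) of a closed profile."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("profile must be closed (sum to 1)")
    return float(stats.entropy(p))


def _replace_zeros(mat: np.ndarray, pseudocount=None) -> np.ndarray:
    nz = mat[mat > 0]
    if nz.size == 0:
        raise ValueError("all-zero composition")
    if not (mat == 0).any():
        return mat
    if pseudocount is None:
        pseudocount = nz.min() / 2.0
    return close(mat + pseudocount)


def clr_transform(p, pseudocount=None) -> np.ndarray:
    """Centered log-ratio transform; rows sum to zero.

    Accepts a single composition or a samples x species matrix.  Zeros are
    replaced additively (half the minimum nonzero value by default) and the
    composition re-closed before taking logs.
    """
    mat = np.atleast_2d(np.asarray(p, dtype=float))
    mat = _replace_zeros(close(mat), pseudocount)
    logm = np.log(mat)
    out = logm - logm.mean(axis=1, keepdims=True)
    return out[0] if np.asarray(p).ndim == 1 else out


def aitchison_distance(a, b, pseudocount=None) -> float:
    """Euclidean distance between clr-transformed compositions.

    The two profiles must live on a common species universe (align them
    first, filling absent species with zero).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share a species universe")
    mat = clr_transform(np.vstack([a, b]), pseudocount)
    return float(np.linalg.norm(mat[0] - mat[1]))


def distance_to_reference(sample, reference: pd.DataFrame | np.ndarray,
                          pseudocount=None) -> float:
    """Mean Aitchison distance from ``sample`` to each reference profile."""
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if ref.shape[0] == 0:
        raise ValueError("empty reference set")
    sample = np.asarray(sample, dtype=float)
    mat = clr_transform(np.vstack([sample[None, :], ref]), pseudocount)
    return float(np.mean(np.linalg.norm(mat[1:] - mat[0], axis=1)))


def pca_clr(matrix, n_components=None):
    """PCA of clr-transformed compositions.

    Returns ``(scores, loadings, explained_variance)``.  With all
    components kept, pairwise Euclidean distances between scores equal the
    Aitchison distances between the rows (PCA is an isometry).
    """
    from sklearn.decomposition import PCA

    mat = np.atleast_2d(np.asarray(matrix, dtype=float))
    if mat.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = clr_transform(mat)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.components_, pca.explained_variance_


@dataclass
class DysbiosisConfig:
    """Taxa lists for the dysbiosis log-ratio score.

    ``up_taxa`` were positively, ``down_taxa`` negatively associated with
    the disease state; the score is log((sum up + eps) / (sum down + eps)).
    """

    up_taxa: list = field(default_factory=list)
    down_taxa: list = field(default_factory=list)
    pseudocount: float = 1e-6

    def __post_init__(self):
        if set(self.up_taxa) & set(self.down_taxa):
            raise ValueError("up/down taxa lists overlap")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def dysbiosis_score(p: pd.Series, cfg: DysbiosisConfig) -> float:
    """Log-ratio of cumulative disease-associated vs protective abundance."""
    if not cfg.up_taxa or not cfg.down_taxa:
        raise ValueError("dysbiosis taxa lists must be non-empty")
    up = float(p.reindex(cfg.up_taxa).fillna(0).sum())
    down = float(p.reindex(cfg.down_taxa).fillna(0).sum())
    return float(np.log((up + cfg.pseudocount) / (down + cfg.pseudocount)))


def lifestyle_burden(p: pd.Series, annotations: pd.DataFrame) -> dict:
    """Cumulative relative abundance of oral / oxygen-tolerant / spore taxa.

    ``annotations`` holds +1 / -1 / NaN per species and feature; species
    with a missing annotation are excluded from the numerator.
    """
    out = {}
    for feature, key in [("oral_habitat", "oral_abundance"),
                         ("oxygen_tolerant", "oxygen_tolerant_abundance"),
                         ("spore_forming", "spore_abundance")]:
        if feature in annotations.columns:
            ann = annotations[feature].reindex(p.index)
            out[key] = float(p[ann == 1].sum())
        else:
            out[key] = 0.0
    return out


def metrics_table(communities: pd.DataFrame, annotations=None,
                  dysbiosis_cfg=None, reference=None) -> pd.DataFrame:
    """Per-sample metric table over a samples x species abundance matrix."""
    rows = {}
    for sid, p in communities.iterrows():
        row = {"shannon": shannon(close(p.values))}
        if annotations is not None:
            row.update(lifestyle_burden(p, annotations))
        if dysbiosis_cfg is not None:
            row["dysbiosis"] = dysbiosis_score(p, dysbiosis_cfg)
        if reference is not None:
            row["dist_to_controls"] = distance_to_reference(
                p.values, reference)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def variance_inflation(X: pd.DataFrame, threshold: float = 5.0) -> pd.Series:
    """Variance inflation factors of model covariates; warns above threshold."""
    X = X.astype(float)
    vifs = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        if others.shape[1] == 0:
            vifs[col] = 1.0
            continue
        A = np.column_stack([np.ones(len(X)), others.values])
        coef, *_ = np.linalg.lstsq(A, X[col].values, rcond=None)
        resid = X[col].values - A @ coef
        tss = np.var(X[col].values) * len(X)
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        vifs[col] = float(1.0 / max(1.0 - r2, 1e-12))
    out = pd.Series(vifs)
    high = out[out > threshold]
    if len(high):
        warnings.warn(f"high multicollinearity (VIF > {threshold}): "
                      f"{', '.join(high.index)}")
    return out


def compare_to_controls(metric_table: pd.DataFrame, sample_type: pd.Series,
                        study: pd.Series, case: pd.Series,
                        metrics=None, proportion_metrics=(),
                        min_day: float = 5.0, day: pd.Series | None = None,
                        proportion_trials: int = 100,
                        reference_type: str = "control") -> pd.DataFrame:
    """Mixed-model comparison of each metric against healthy controls.

    For each metric, fits sample type as a fixed effect (controls as the
    reference level) with random intercepts for study and case: a Gaussian
    identity model for continuous metrics and a binomial logit model (with
    ``proportion_trials`` effective trials) for proportion metrics.
    Post-FMT samples collected fewer than ``min_day`` days after treatment
    are excluded when a ``day`` series is supplied.

    Returns a tidy frame with one row per (metric, sample type): estimate,
    SE, z, p relative to the control reference.
    """
    from .glmm import MixedGLM

    df = metric_table.copy()
    df["_type"] = sample_type.reindex(df.index)
    df["_study"] = study.reindex(df.index).astype(str)
    df["_case"] = case.reindex(df.index).astype(str)
    if day is not None:
        d = day.reindex(df.index)
        keep = (df["_type"] != "post") | (d >= min_day)
        df = df[keep]
    types = df["_type"].unique()
    if reference_type not in types:
        raise ValueError(f"no '{reference_type}' samples in input")
    if len(types) < 2:
        raise ValueError("need at least two sample types")
    metrics = list(metrics if metrics is not None else metric_table.columns)
    levels = [t for t in sorted(types) if t != reference_type]
    results = []
    for metric in metrics:
        sub = df.dropna(subset=[metric])
        X = np.column_stack(
            [np.ones(len(sub))] +
            [(sub["_type"] == t).astype(float).values for t in levels])
        names = ["intercept"] + [f"type[{t}]" for t in levels]
        groups = {"study": sub["_study"].values, "case": sub["_case"].values}
        if metric in proportion_metrics:
            y = np.round(sub[metric].values * proportion_trials)
            model = MixedGLM(X, y, groups, family="binomial",
                             trials=np.full(len(sub), proportion_trials),
                             names=names)
        else:
            model = MixedGLM(X, sub[metric].values, groups,
                             family="gaussian", names=names)
        fit = model.fit()
        for name in names:
            if name == "intercept":
                continue
            results.append({
                "metric": metric,
                "sample_type": name[5:-1],
                "estimate": fit.params[name],
                "se": fit.se[name],
                "z": fit.z[name],
                "p": fit.pvalues[name],
                "converged": fit.converged,
            })
    return pd.DataFrame(results)
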