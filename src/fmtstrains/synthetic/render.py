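"""Render observed marker pileups (SNV profiles) from communities + strains.

Coverage at each alignment position of species *s* is Poisson with mean
``depth * abundance_s * n_present``, i.e. ``depth`` is the mean per-species
coverage a uniform community would receive, and relatively abundant species
are sequenced deeper, as in real shotgun data.  Observed base counts at a
position are multinomial over the within-species strain mixture blended
with a uniform sequencing-error component.  Zero-coverage positions are
masked.
"""

from __future__ import annotations

import numpy as np

from ..profiles import NucleotideProfile


def _multinomial_columns(rng, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Column-wise multinomial: n (L,), p (4, L) -> counts (4, L).

    Uses the successive-binomial decomposition so positions with different
    probability vectors are drawn in one vectorized pass.
    """
    L = n.shape[0]
    counts = np.zeros((4, L), dtype=np.int64)
    remaining = n.astype(np.int64).copy()
    ptail = p.sum(axis=0)
    for k in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(ptail > 0, p[k] / ptail, 0.0)
        cond = np.clip(cond, 0.0, 1.0)
        counts[k] = rng.binomial(remaining, cond)
        remaining -= counts[k]
        ptail = ptail - p[k]
    counts[3] = remaining
    return counts


def render_sample(community, strain_assignment, depth: float,
                  error_rate: float, seed=None, catalog=None,
                  sample_id: str = "sample") -> dict:
    """Render one sample's per-species nucleotide profiles.

    Parameters
    ----------
    community : mapping species_id -> relative abundance (sums to 1)
    strain_assignment : mapping species_id -> list of (StrainGenotype, fraction)
        Within-species fractions must sum to 1 for each species.
    depth : float
        Mean per-species coverage for a uniform community (see module doc).
    error_rate : float
        Per-base probability that a read base is drawn uniformly from the
        four alleles instead of the strain allele.
    catalog : SpeciesCatalog, optional
        Supplies marker boundaries for the emitted profiles.

    Returns
    -------
    dict species_id -> NucleotideProfile (unfiltered); species with zero
    abundance are omitted.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if not (0 <= error_rate <= 1):
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    items = [(s, a) for s, a in dict(community).items() if a > 0]
    total = sum(a for _, a in items)
    if items and abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances must sum to 1 (got {total:.6f})")
    scale = len(items)
    profiles = {}
    for species_id, abundance in items:
        strains = strain_assignment.get(species_id)
        if not strains:
            continue
        fracs = np.array([f for _, f in strains], dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-6:
            raise ValueError(f"strain fractions for {species_id} must sum to 1")
        L = strains[0][0].L
        # mixture allele probabilities per position
        p = np.zeros((4, L))
        for geno, frac in strains:
            onehot = np.zeros((4, L))
            onehot[geno.alleles, np.arange(L)] = 1.0
            p += frac * onehot
        p = (1.0 - error_rate) * p + error_rate * 0.25
        coverage = rng.poisson(depth * abundance * scale, size=L)
        counts = _multinomial_columns(rng, coverage, p)
        bounds = catalog.bounds(species_id) if catalog is not None else None
        profiles[species_id] = NucleotideProfile(
            sample_id, species_id, counts, coverage > 0,
            marker_bounds=list(bounds or []))
    return profiles
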