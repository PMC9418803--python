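"""Pairwise shared-strain detection by maximum variant profile similarity.

Two samples share a strain of a species when their SNV profiles, restricted
to jointly usable alignment positions, agree almost everywhere in the
co-occurrence sense: at each position the sets of alleles observed at >= 10%
within-position frequency must intersect.  The fraction of jointly usable
positions with intersecting allele sets is the maximum variant profile
similarity (MVS).  A shared strain is called when the joint overlap spans at
least ``min_overlap_bp`` alignment columns (default 5,000) and the MVS is at
least ``min_mvs`` (default 99.9%).  Because polymorphic positions contribute
their full allele set, a sample carrying a mixture of two strains still
reaches MVS 1.0 against a sample carrying either strain alone -- this is
what lets the downstream attribution detect conspecific donor/recipient
coexistence.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .profiles import ALLELES, NucleotideProfile

INSUFFICIENT_OVERLAP = "insufficient_overlap"


@dataclass(frozen=True)
class CallParams:
    """Shared-strain calling thresholds (alignment columns, proportion)."""

    min_overlap_bp: int = 5000
    min_mvs: float = 0.999
    min_allele_frequency: float = 0.10

    def __post_init__(self):
        if self.min_overlap_bp <= 0:
            raise ValueError("min_overlap_bp must be positive")
        if not (0 < self.min_mvs <= 1):
            raise ValueError("min_mvs must be in (0, 1]")


@dataclass
class ComparisonResult:
    """Per-species outcome of one pairwise profile comparison.

    ``shared_call`` is True/False when the overlap is sufficient and the
    string ``"insufficient_overlap"`` otherwise; ``mvs`` and
    ``consensus_similarity`` are None when the overlap is empty.
    """

    species_id: str
    sample_a: str
    sample_b: str
    overlap_bp: int
    mvs: float | None
    consensus_similarity: float | None
    shared_call: object

    @property
    def is_shared(self) -> bool:
        return self.shared_call is True


def _allele_presence(counts: np.ndarray, min_freq: float) -> np.ndarray:
    """Boolean (4, L) matrix: allele at >= min_freq within-position frequency.

    Uses the integer cross-multiplication ``count * 1 >= total * min_freq``
    expressed over a rational threshold, avoiding float division.
    """
    total = counts.sum(axis=0)
    frac = Fraction(str(min_freq))
    # count / total >= num/den  <=>  count * den >= total * num
    return (counts * frac.denominator >= total[None, :] * frac.numerator) & (counts > 0)


def allele_set(p: NucleotideProfile, pos: int, min_freq: float = 0.10) -> set:
    """Alleles observed at position ``pos`` at >= ``min_freq`` frequency.

    Raises on masked positions: allele sets are only defined for usable
    positions of a filtered profile.
    """
    if not p.mask[pos]:
        raise ValueError(f"position {pos} is masked")
    present = _allele_presence(p.counts[:, [pos]], min_freq)[:, 0]
    return {ALLELES[i] for i in np.flatnonzero(present)}


def compare(a: NucleotideProfile, b: NucleotideProfile,
            params: CallParams = CallParams()) -> ComparisonResult:
    """Compare two same-species profiles over jointly usable positions.

    Returns the overlap length, the MVS (allele-set co-occurrence), the
    consensus similarity (equal major alleles), and the shared-strain call.
    The MVS threshold is applied by exact integer cross-multiplication
    (``n_intersect * den >= num * overlap``) so that e.g. an MVS of exactly
    0.999 passes a 99.9% cutoff without floating-point edge effects.
    """
    if a.species_id != b.species_id:
        raise ValueError("profiles are for different species")
    if a.L != b.L:
        raise ValueError("profiles have different alignment lengths")
    joint = a.mask & b.mask
    overlap = int(joint.sum())
    if overlap == 0:
        return ComparisonResult(a.species_id, a.sample_id, b.sample_id,
                                0, None, None, INSUFFICIENT_OVERLAP)
    pa = _allele_presence(a.counts[:, joint], params.min_allele_frequency)
    pb = _allele_presence(b.counts[:, joint], params.min_allele_frequency)
    n_intersect = int((pa & pb).any(axis=0).sum())
    major_a = np.argmax(a.counts[:, joint], axis=0)
    major_b = np.argmax(b.counts[:, joint], axis=0)
    n_consensus = int((major_a == major_b).sum())
    mvs = n_intersect / overlap
    cons = n_consensus / overlap
    if overlap < params.min_overlap_bp:
        call = INSUFFICIENT_OVERLAP
    else:
        frac = Fraction(str(params.min_mvs))
        call = n_intersect * frac.denominator >= frac.numerator * overlap
    return ComparisonResult(a.species_id, a.sample_id, b.sample_id,
                            overlap, mvs, cons, call)


def pairwise_shared_strains(profiles_a: dict, profiles_b: dict,
                            params: CallParams = CallParams()):
    """Compare two samples species by species.

    Parameters
    ----------
    profiles_a, profiles_b : dict species_id -> NucleotideProfile
        Filtered profiles of the two samples.

    Returns
    -------
    (results, n_shared) : list of ComparisonResult over the common species,
        and the number of species with a positive shared-strain call.
    """
    common = sorted(set(profiles_a) & set(profiles_b))
    results = [compare(profiles_a[s], profiles_b[s], params) for s in common]
    n_shared = sum(r.is_shared for r in results)
    return results, n_shared
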