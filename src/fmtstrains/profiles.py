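"""Per-species nucleotide-variant profiles over concatenated marker alignments.

A :class:`NucleotideProfile` stores, for one sample and one species, the
observed allele counts at every position of the species' concatenated
clade-specific marker alignment (a 4 x L integer matrix in fixed allele order
A, C, G, T) together with a boolean usability mask.  Profiles are built from
position/allele count tables, denoised with :func:`filter_profile`, and
consumed by the pairwise strain comparison.

Positions are 0-based over the concatenated alignment; marker boundaries are
carried as half-open ``(start, end)`` ranges so that marker ends can be
trimmed during filtering.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace

import numpy as np

ALLELES = "ACGT"
ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}


@dataclass
class NucleotideProfile:
    """Allele counts and usability mask for one sample x species.

    Attributes
    ----------
    sample_id, species_id : str
        Identifiers of the source sample and the species.
    counts : ndarray of shape (4, L)
        Non-negative read counts per allele (rows A, C, G, T) and position.
    mask : ndarray of shape (L,), bool
        True where the position is usable; masked positions are excluded
        from every downstream statistic.
    marker_bounds : list of (int, int)
        Half-open ranges of the individual markers in the concatenation.
        Defaults to a single marker spanning the whole alignment.
    filtered : bool
        Set by :func:`filter_profile`; records filter provenance.
    """

    sample_id: str
    species_id: str
    counts: np.ndarray
    mask: np.ndarray
    marker_bounds: list = field(default_factory=list)
    filtered: bool = False

    def __post_init__(self):
        # int32 keeps whole-cohort profile sets comfortably in memory;
        # read depths are far below the overflow range
        self.counts = np.asarray(self.counts, dtype=np.int32)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, L)")
        if (self.counts < 0).any():
            raise ValueError("negative allele counts")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.counts.shape[1],):
            raise ValueError("mask length must equal alignment length")
        if not self.marker_bounds:
            self.marker_bounds = [(0, self.L)]

    @property
    def L(self) -> int:
        return self.counts.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        """Per-position read depth (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def covered_length(self) -> int:
        """Number of usable positions."""
        return int(self.mask.sum())


@dataclass(frozen=True)
class FilterParams:
    """Denoising thresholds for SNV profiles.

    ``min_allele_frequency`` implements the polymorphic-site rule (alleles
    below 10% within-position frequency are treated as noise); the remaining
    thresholds are conservative defaults for marker-based strain calling.
    """

    min_position_coverage: int = 5
    min_allele_count: int = 2
    min_allele_frequency: float = 0.10
    end_trim: int = 20

    def __post_init__(self):
        if not (0 < self.min_allele_frequency < 0.5):
            raise ValueError("min_allele_frequency must be in (0, 0.5)")
        if self.min_position_coverage < 1 or self.min_allele_count < 0:
            raise ValueError("coverage/count thresholds must be positive")
        if self.end_trim < 0:
            raise ValueError("end_trim must be non-negative")


def build_profile(count_table, species_id: str, sample_id: str, L: int,
                  marker_bounds=None) -> NucleotideProfile:
    """Build an (unfiltered) profile from a position x allele count table.

    Parameters
    ----------
    count_table : iterable of (position, count_A, count_C, count_G, count_T)
        Rows may list any subset of positions in any order; unlisted
        positions get zero counts and are masked.
    L : int
        Total alignment length.

    Raises
    ------
    ValueError
        On negative counts, duplicate positions, or positions outside [0, L).
    """
    rows = np.asarray(list(count_table), dtype=np.int64)
    counts = np.zeros((4, L), dtype=np.int64)
    mask = np.zeros(L, dtype=bool)
    if rows.size:
        if rows.ndim != 2 or rows.shape[1] != 5:
            raise ValueError("count table rows must be (pos, A, C, G, T)")
        pos = rows[:, 0]
        if (pos < 0).any() or (pos >= L).any():
            raise ValueError("position outside [0, L)")
        if len(np.unique(pos)) != len(pos):
            raise ValueError("duplicate positions in count table")
        if (rows[:, 1:] < 0).any():
            raise ValueError("negative allele counts")
        counts[:, pos] = rows[:, 1:].T
        mask[pos] = rows[:, 1:].sum(axis=1) > 0
    return NucleotideProfile(sample_id, species_id, counts, mask,
                             marker_bounds=list(marker_bounds or []))


def filter_profile(p: NucleotideProfile, params: FilterParams = FilterParams()
                   ) -> NucleotideProfile:
    """Denoise a profile: trim marker ends, drop minor alleles, mask low depth.

    Steps, in order:

    1. mask ``end_trim`` positions at each end of every marker;
    2. zero alleles whose count is below ``min_allele_count`` or whose
       within-position frequency is below ``min_allele_frequency``;
    3. mask positions whose remaining depth is below
       ``min_position_coverage``.

    Depth is re-checked after allele zeroing (step 3 after step 2) so the
    operation is exactly idempotent: alleles surviving one pass have
    frequency at least the threshold of a column total that can only shrink,
    hence survive every later pass unchanged.
    """
    counts = p.counts.copy()
    mask = p.mask.copy()
    for start, end in p.marker_bounds:
        t = params.end_trim
        mask[start:min(start + t, end)] = False
        mask[max(end - t, start):end] = False
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
    drop = (counts < params.min_allele_count) | (freq < params.min_allele_frequency)
    counts[drop] = 0
    mask &= counts.sum(axis=0) >= params.min_position_coverage
    counts[:, ~mask] = 0
    return replace(p, counts=counts, mask=mask, filtered=True)


def merge_profiles(profiles) -> "MergedProfiles":
    """Stack same-species profiles into an aligned multi-sample tensor."""
    return MergedProfiles(list(profiles))


class MergedProfiles:
    """Aligned tensor of several samples' profiles for one species.

    Provides O(1) joint-coverage lookups between any two samples via the
    stacked mask matrix.
    """

    def __init__(self, profiles):
        if not profiles:
            raise ValueError("no profiles to merge")
        species = {p.species_id for p in profiles}
        if len(species) != 1:
            raise ValueError(f"mixed species in merge: {sorted(species)}")
        lengths = {p.L for p in profiles}
        if len(lengths) != 1:
            raise ValueError(f"mismatched alignment lengths: {sorted(lengths)}")
        self.species_id = profiles[0].species_id
        self.sample_ids = [p.sample_id for p in profiles]
        self.counts = np.stack([p.counts for p in profiles])   # (S, 4, L)
        self.masks = np.stack([p.mask for p in profiles])      # (S, L)
        self.profiles = profiles

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def joint_coverage(self, i: int, j: int) -> int:
        """Number of positions usable in both samples i and j."""
        return int((self.masks[i] & self.masks[j]).sum())


def consensus_sequence(p: NucleotideProfile) -> str:
    """Major-allele consensus; masked positions are N.

    Ties are broken by the fixed allele order A < C < G < T (argmax returns
    the first maximum).
    """
    major = np.argmax(p.counts, axis=0)
    out = np.array(list(ALLELES))[major]
    out[~p.mask] = "N"
    return "".join(out)


# ---------------------------------------------------------------------------
# TSV round-trip.  One file per sample x species; '#key\tvalue' header lines
# record identifiers and filter provenance, then a column header and one row
# per covered position.

def write_profile_tsv(p: NucleotideProfile, path) -> None:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(f"#species_id\t{p.species_id}\n")
        fh.write(f"#sample_id\t{p.sample_id}\n")
        fh.write(f"#L\t{p.L}\n")
        bounds = ";".join(f"{s}-{e}" for s, e in p.marker_bounds)
        fh.write(f"#marker_bounds\t{bounds}\n")
        fh.write(f"#filtered\t{int(p.filtered)}\n")
        fh.write("position\tcount_A\tcount_C\tcount_G\tcount_T\n")
        idx = np.flatnonzero(p.mask | (p.counts.sum(axis=0) > 0))
        for i in idx:
            a, c, g, t = p.counts[:, i]
            fh.write(f"{i}\t{a}\t{c}\t{g}\t{t}\n")


def read_profile_tsv(path) -> NucleotideProfile:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    meta = {}
    rows = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta[key] = val
            elif line.startswith("position"):
                continue
            else:
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns")
                try:
                    rows.append([int(x) for x in parts])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
    for key in ("species_id", "sample_id", "L"):
        if key not in meta:
            raise ValueError(f"{path}: missing #{key} header")
    L = int(meta["L"])
    bounds = []
    for chunk in meta.get("marker_bounds", "").split(";"):
        if chunk:
            s, _, e = chunk.partition("-")
            bounds.append((int(s), int(e)))
    p = build_profile(rows, meta["species_id"], meta["sample_id"], L,
                      marker_bounds=bounds)
    p.filtered = bool(int(meta.get("filtered", "0")))
    return p
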