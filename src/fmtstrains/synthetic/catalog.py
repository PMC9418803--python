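"""Species catalog: taxonomy, marker alignment geometry, lifestyle features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHYLA = ["Bacteroidetes", "Firmicutes", "Proteobacteria", "Actinobacteria"]
PHYLUM_WEIGHTS = [0.25, 0.45, 0.15, 0.15]

FEATURES = ["gram_positive", "spore_forming", "oxygen_tolerant", "oral_habitat"]
# Rough gut-community prevalences of each trait among annotated species.
FEATURE_PREVALENCE = {
    "gram_positive": 0.55,
    "spore_forming": 0.30,
    "oxygen_tolerant": 0.30,
    "oral_habitat": 0.15,
}


@dataclass
class SpeciesCatalog:
    """Table of species with genus/phylum labels, marker geometry, features.

    ``table`` columns: species_id (index), genus, phylum, marker_length,
    and one column per lifestyle feature holding +1.0 / -1.0 / NaN (missing).
    ``marker_bounds`` maps species_id to the half-open marker ranges of the
    concatenated alignment.
    """

    table: pd.DataFrame
    marker_bounds: dict = field(default_factory=dict)
    feature_missing_rate: float = 0.0

    def __len__(self):
        return len(self.table)

    @property
    def species_ids(self):
        return list(self.table.index)

    def marker_length(self, species_id: str) -> int:
        return int(self.table.loc[species_id, "marker_length"])

    def bounds(self, species_id: str):
        return self.marker_bounds[species_id]

    def features_frame(self) -> pd.DataFrame:
        return self.table[FEATURES]


def _split_markers(length: int, rng: np.random.Generator):
    """Split an alignment of `length` columns into 3-8 contiguous markers."""
    k = int(rng.integers(3, 9))
    w = rng.dirichlet(np.full(k, 3.0))
    sizes = np.maximum((w * length).astype(int), 120)
    sizes[-1] = length - sizes[:-1].sum()
    if sizes[-1] < 120:  # re-balance a degenerate tail
        sizes = np.full(k, length // k)
        sizes[-1] += length - sizes.sum()
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(k)]


def generate_catalog(n_species: int, feature_missing_rate: float = 0.1,
                     seed=None, short_marker_fraction: float = 0.1,
                     ) -> SpeciesCatalog:
    """Generate a deterministic species catalog.

    Genus sizes follow a skewed (Zipf-like) distribution so that a few
    genera hold many species, as in real gut communities.  Marker alignment
    lengths are drawn so that most species (about 90%) comfortably exceed
    the 5 kb comparison overlap threshold; a minority get short alignments
    (2-5 kb) to exercise the insufficient-overlap path.

    Raises ``ValueError`` for non-positive ``n_species``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not (0 <= feature_missing_rate <= 1):
        raise ValueError("feature_missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_genera = max(1, n_species // 4)
    ranks = np.arange(1, n_genera + 1, dtype=float)
    genus_p = (1.0 / ranks) / (1.0 / ranks).sum()
    genus_of = rng.choice(n_genera, size=n_species, p=genus_p)
    genus_phylum = rng.choice(len(PHYLA), size=n_genera, p=PHYLUM_WEIGHTS)

    short = rng.random(n_species) < short_marker_fraction
    lengths = np.where(
        short,
        rng.integers(2000, 5000, size=n_species),
        rng.integers(6000, 20001, size=n_species),
    )

    feats = {}
    for f in FEATURES:
        val = np.where(rng.random(n_species) < FEATURE_PREVALENCE[f], 1.0, -1.0)
        missing = rng.random(n_species) < feature_missing_rate
        feats[f] = np.where(missing, np.nan, val)

    ids = [f"s{i:04d}" for i in range(n_species)]
    table = pd.DataFrame(
        {
            "genus": [f"g{genus_of[i]:03d}" for i in range(n_species)],
            "phylum": [PHYLA[genus_phylum[g]] for g in genus_of],
            "marker_length": lengths,
            **feats,
        },
        index=pd.Index(ids, name="species_id"),
    )
    bounds = {sid: _split_markers(int(L), rng)
              for sid, L in zip(ids, lengths)}
    return SpeciesCatalog(table, bounds, feature_missing_rate)
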