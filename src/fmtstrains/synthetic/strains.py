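"""Strain genotypes over marker alignments and their mutation model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class StrainGenotype:
    """One strain's allele sequence over a species' concatenated markers.

    ``alleles`` holds integer codes 0..3 for A, C, G, T.  Divergence between
    two genotypes of the same species is Hamming distance / length.
    """

    species_id: str
    alleles: np.ndarray
    lineage_id: str

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)

    @property
    def L(self) -> int:
        return self.alleles.shape[0]

    def divergence(self, other: "StrainGenotype") -> float:
        if self.L != other.L:
            raise ValueError("genotype lengths differ")
        return float(np.mean(self.alleles != other.alleles))


def random_genotype(species_id: str, length: int, rng, lineage_id: str
                    ) -> StrainGenotype:
    rng = np.random.default_rng(rng)
    return StrainGenotype(species_id, rng.integers(0, 4, size=length,
                                                   dtype=np.int8), lineage_id)


def mutate_strain(parent: StrainGenotype, divergence: float, seed=None,
                  lineage_id: str | None = None, exact: bool = False
                  ) -> StrainGenotype:
    """Derive a new lineage from ``parent`` at the given divergence.

    The number of substituted positions is Binomial(L, divergence)
    (or exactly ``round(divergence * L)`` when ``exact``); substituted
    alleles are drawn uniformly from the three alternatives, so every
    substituted position differs from the parent.
    """
    if not (0 <= divergence <= 1):
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = parent.L
    n_mut = int(round(divergence * L)) if exact else int(rng.binomial(L, divergence))
    alleles = parent.alleles.copy()
    if n_mut:
        pos = rng.choice(L, size=n_mut, replace=False)
        # shift by 1..3 mod 4: uniform over the three non-parent alleles
        shift = rng.integers(1, 4, size=n_mut, dtype=np.int8)
        alleles[pos] = (alleles[pos] + shift) % 4
    return StrainGenotype(parent.species_id, alleles,
                          lineage_id or f"{parent.lineage_id}.m")
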