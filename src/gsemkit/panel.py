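"""Aligned multi-trait container shared by the estimation stages.

A :class:`HarmonizedPanel` holds, over one common set of variants, the
Z-score matrix for all traits, per-trait sample sizes, the LD scores for
every (population, pair) context needed, and the contiguous jackknife
block assignment.  It is produced either by merging harmonized summary
statistics with LD score panels, or directly by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HarmonizedPanel", "context_key"]


def context_key(pop_t: str, pop_u: str):
    """Canonical LD context key: the population for within-population
    pairs, a sorted tuple for cross-population pairs."""
    if pop_t == pop_u:
        return pop_t
    return tuple(sorted((pop_t, pop_u)))


@dataclass
class HarmonizedPanel:
    snp: np.ndarray                 # (M,) variant ids, sorted lexicographically
    z: np.ndarray                   # (M, T) aligned Z-scores
    n: np.ndarray                   # (T,) per-trait sample sizes
    traits: list                    # trait labels
    populations: list               # per-trait population label
    ld: dict                        # context key -> (M,) LD scores
    m_ref: dict                     # context key -> reference variant count
    blocks: np.ndarray = None       # (M,) contiguous block ids for jackknife

    def __post_init__(self):
        self.snp = np.asarray(self.snp)
        self.z = np.asarray(self.z, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        M, T = self.z.shape
        if len(self.snp) != M:
            raise ValueError("snp/z row mismatch")
        if len(self.traits) != T or len(self.populations) != T or len(self.n) != T:
            raise ValueError("trait metadata length mismatch")
        if self.blocks is None:
            self.blocks = default_blocks(M, min(200, M))
        self.blocks = np.asarray(self.blocks, dtype=int)

    @property
    def n_variants(self) -> int:
        return self.z.shape[0]

    @property
    def n_traits(self) -> int:
        return self.z.shape[1]

    def index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"trait {trait!r} not in panel ({self.traits})") from None

    def context(self, t: int, u: int):
        return context_key(self.populations[t], self.populations[u])

    def ld_for(self, t: int, u: int) -> np.ndarray:
        key = self.context(t, u)
        if key not in self.ld:
            raise KeyError(
                f"LD panel missing required context {key!r} for trait pair "
                f"({self.traits[t]}, {self.traits[u]})"
            )
        return self.ld[key]

    def m_for(self, t: int, u: int) -> int:
        return self.m_ref[self.context(t, u)]

    def is_cross(self, t: int, u: int) -> bool:
        return self.populations[t] != self.populations[u]


def default_blocks(n_variants: int, n_blocks: int) -> np.ndarray:
    """Contiguous, near-equal block assignment in variant order."""
    if n_blocks < 1 or n_blocks > n_variants:
        raise ValueError("n_blocks must be in [1, n_variants]")
    edges = np.linspace(0, n_variants, n_blocks + 1).astype(int)
    out = np.empty(n_variants, dtype=int)
    for b in range(n_blocks):
        out[edges[b]:edges[b + 1]] = b
    return out
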