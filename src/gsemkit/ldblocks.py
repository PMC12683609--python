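"""Block-structured LD designs and the LD score panels they imply.

The reference genome is modelled as ``n_blocks`` independent blocks of
``m`` variants each.  Within a block every pair of variants has genotype
correlation ``r`` (possibly block-specific), so the LD score of a variant
in block *b* has the closed form

    l_within = 1 + (m - 1) * r_b**2

and, for a pair of populations with block correlations ``r1_b`` and
``r2_b`` (same block boundaries, same sign convention),

    l_cross = 1 + (m - 1) * r1_b * r2_b.

Blocks double as jackknife resampling units: variants are independent
across blocks by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LdBlockDesign", "LdScorePanel", "build_ld_panels", "InvalidDesignError"]


class InvalidDesignError(ValueError):
    """Raised for LD block designs that cannot describe a genome."""


def _as_block_array(r, n_blocks: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(r, dtype=float))
    if arr.size == 1:
        arr = np.full(n_blocks, arr.item())
    if arr.shape != (n_blocks,):
        raise InvalidDesignError(
            f"{name} must be a scalar or a length-{n_blocks} array, got shape {arr.shape}"
        )
    if np.any(np.abs(arr) >= 1.0):
        raise InvalidDesignError(f"{name} entries must satisfy |r| < 1")
    return arr


@dataclass(frozen=True)
class LdBlockDesign:
    """Block LD structure shared by the two populations.

    Parameters
    ----------
    n_blocks : number of independent LD blocks.
    m : variants per block; ``M = n_blocks * m``.
    r1, r2 : intra-block genotype correlation per population; scalar or
        per-block array, each entry in (-1, 1).
    """

    n_blocks: int
    m: int
    r1: object = 0.0
    r2: object = 0.0

    def __post_init__(self):
        if self.n_blocks < 1 or self.m < 1:
            raise InvalidDesignError("n_blocks and m must be positive")
        if self.M < 2:
            raise InvalidDesignError("design must contain at least two variants")
        object.__setattr__(self, "r1", _as_block_array(self.r1, self.n_blocks, "r1"))
        object.__setattr__(self, "r2", _as_block_array(self.r2, self.n_blocks, "r2"))

    @property
    def M(self) -> int:
        return self.n_blocks * self.m

    def variant_ids(self) -> np.ndarray:
        """Lexicographically ordered ids; ordering preserves block contiguity."""
        width = len(str(self.M - 1))
        return np.array([f"rs{i:0{width}d}" for i in range(self.M)])

    def block_ids(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_blocks), self.m)

    def ld_scores(self, context: str) -> np.ndarray:
        """Per-variant LD scores for ``context`` in {'pop1', 'pop2', 'cross'}."""
        if context == "pop1":
            per_block = 1.0 + (self.m - 1) * self.r1**2
        elif context == "pop2":
            per_block = 1.0 + (self.m - 1) * self.r2**2
        elif context == "cross":
            per_block = 1.0 + (self.m - 1) * self.r1 * self.r2
        else:
            raise ValueError(f"unknown LD context {context!r}")
        return np.repeat(per_block, self.m)


@dataclass
class LdScorePanel:
    """LD scores for one population (or a cross-population pair).

    ``table`` has columns CHR, SNP, BP, L2; ``m_ref`` is the reference
    variant count M used to scale regression slopes.
    """

    table: pd.DataFrame
    m_ref: int
    context: str = ""

    def __post_init__(self):
        missing = {"CHR", "SNP", "BP", "L2"} - set(self.table.columns)
        if missing:
            raise ValueError(f"LD score panel missing columns: {sorted(missing)}")
        if self.m_ref < 2:
            raise ValueError("reference variant count M must be >= 2")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def write(self, path, m_path=None) -> None:
        self.table.to_csv(path, sep="\t", index=False)
        if m_path is not None:
            with open(m_path, "w") as fh:
                fh.write(f"{self.m_ref}\n")

    @classmethod
    def read(cls, path, m_path, context: str = "") -> "LdScorePanel":
        table = pd.read_csv(path, sep=r"\s+")
        with open(m_path) as fh:
            m_ref = int(float(fh.read().strip()))
        return cls(table=table, m_ref=m_ref, context=context)


def build_ld_panels(design: LdBlockDesign):
    """Materialize the three LD score panels implied by a block design.

    Returns (pop1, pop2, cross) :class:`LdScorePanel` objects sharing one
    set of variant ids.
    """
    ids = design.variant_ids()
    bp = np.arange(design.M, dtype=int) * 1000 + 1

    def panel(context):
        table = pd.DataFrame(
            {
                "CHR": np.ones(design.M, dtype=int),
                "SNP": ids,
                "BP": bp,
                "L2": design.ld_scores(context),
            }
        )
        return LdScorePanel(table=table, m_ref=design.M, context=context)

    return panel("pop1"), panel("pop2"), panel("cross")
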