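"""Univariate and bivariate LD score regression with block-jackknife SEs.

Heritability: per-variant chi-square is regressed on the LD score,

    E[chi2_j] = a + (N h2 / M) * l_j,

with a free intercept ``a`` absorbing confounding.  Genetic covariance:
the product of the two traits' Z-scores is regressed on the (within- or
cross-population) LD score,

    E[z_t z_u] = c + (sqrt(N_t N_u) rho_g / M) * l_j,

with the cross-trait intercept ``c`` free for within-population pairs
(it absorbs sample overlap, c ~ rho_ph N_s / sqrt(N_t N_u)) and fixed
to 0 for cross-population pairs.  Genetic correlation is
rg = rho_g / sqrt(h2_t h2_u).

Weights follow standard practice: a first unweighted pass yields
provisional estimates, then one reweighting iteration with
heteroskedasticity/overcounting weights 1 / (l_j * mu_j^2) where mu_j
is the provisional regression mean.  Standard errors come from a
delete-one-block jackknife over contiguous blocks with the final
weights held fixed; the delete-one values are retained so a joint
sampling covariance across many cells can be assembled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .panel import HarmonizedPanel

__all__ = [
    "H2Estimate",
    "RgEstimate",
    "DegenerateDesignError",
    "estimate_h2",
    "estimate_rg",
    "block_jackknife",
]


class DegenerateDesignError(ValueError):
    """LD scores carry no information to identify the slope."""


# ---------------------------------------------------------------------------
# weighted two-parameter regression with closed-form block deletion


def _block_sums(x, y, w, blocks, n_blocks):
    """Per-block sufficient statistics of the weighted regression."""
    stats = np.empty((5, n_blocks))
    for i, v in enumerate([w, w * x, w * x * x, w * y, w * x * y]):
        stats[i] = np.bincount(blocks, weights=v, minlength=n_blocks)
    return stats  # rows: sw, swx, swxx, swy, swxy


def _solve(sw, swx, swxx, swy, swxy, free_intercept):
    if free_intercept:
        det = sw * swxx - swx * swx
        slope = (sw * swxy - swx * swy) / det
        intercept = (swy - slope * swx) / sw
    else:
        slope = swxy / swxx
        intercept = np.zeros_like(np.asarray(slope, dtype=float))
    return intercept, slope


def _wls_with_jackknife(x, y, w, blocks, free_intercept):
    """Full fit plus delete-one-block (intercept, slope) arrays."""
    n_blocks = int(blocks.max()) + 1
    stats = _block_sums(x, y, w, blocks, n_blocks)
    totals = stats.sum(axis=1)
    a, b = _solve(*totals, free_intercept)
    deleted = totals[:, None] - stats
    a_del, b_del = _solve(*deleted, free_intercept)
    return float(a), float(b), np.asarray(a_del, float), np.asarray(b_del, float)


def _jackknife_se(delete_values: np.ndarray) -> float:
    n = len(delete_values)
    mean = delete_values.mean()
    return float(np.sqrt((n - 1) / n * np.sum((delete_values - mean) ** 2)))


def block_jackknife(statistic: Callable, n_items: int, blocks: np.ndarray):
    """Generic delete-one-block jackknife.

    ``statistic`` maps an index array to a scalar (or vector).  Returns
    (estimate, SE, pseudovalues); delete-one values are the pseudovalue
    complements and can be recovered as
    ``(n * estimate - pseudovalues) / (n - 1)``.
    """
    blocks = np.asarray(blocks)
    if blocks.shape[0] != n_items:
        raise ValueError("blocks length must match item count")
    labels = np.unique(blocks)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 blocks")
    counts = np.bincount(blocks, minlength=labels.max() + 1)
    if np.any(counts[labels] == 0):
        raise ValueError("empty jackknife block")
    idx = np.arange(n_items)
    full = np.asarray(statistic(idx), dtype=float)
    deletes = np.stack([np.asarray(statistic(idx[blocks != lab]), dtype=float)
                        for lab in labels])
    pseudo = n * full - (n - 1) * deletes
    mean_del = deletes.mean(axis=0)
    se = np.sqrt((n - 1) / n * np.sum((deletes - mean_del) ** 2, axis=0))
    return full, se, pseudo


# ---------------------------------------------------------------------------
# result containers


@dataclass
class H2Estimate:
    """Observed-scale SNP heritability from univariate LDSC."""

    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    n_blocks: int
    m_ref: int
    n_variants: int
    mean_chisq: float
    weights_mode: str = "ldsc"
    intercept_mode: str = "free"
    # delete-one-block estimates, retained for joint covariance assembly
    h2_delete: np.ndarray = field(default=None, repr=False)
    intercept_delete: np.ndarray = field(default=None, repr=False)
    # provisional regression means that generated the weights; reused by
    # the bivariate fit so a trait paired with itself reproduces the
    # univariate regression exactly
    weight_mu: np.ndarray = field(default=None, repr=False)

    def to_dict(self):
        return {
            "h2": self.h2, "h2_se": self.se_h2,
            "intercept": self.intercept, "intercept_se": self.se_intercept,
            "n_blocks": self.n_blocks, "M": self.m_ref,
            "n_variants": self.n_variants, "mean_chisq": self.mean_chisq,
        }


@dataclass
class RgEstimate:
    """Genetic covariance / correlation for one trait pair."""

    rho_g: float
    rg: Optional[float]
    intercept: Optional[float]
    se_rho_g: float
    se_rg: Optional[float]
    se_intercept: Optional[float]
    cross_population: bool
    n_blocks: int
    m_ref: int
    n_variants: int
    reason: Optional[str] = None
    rho_g_delete: np.ndarray = field(default=None, repr=False)
    rg_delete: np.ndarray = field(default=None, repr=False)

    def to_dict(self):
        return {
            "rho_g": self.rho_g, "rho_g_se": self.se_rho_g,
            "rg": self.rg, "rg_se": self.se_rg,
            "intercept": self.intercept, "intercept_se": self.se_intercept,
            "cross_population": self.cross_population,
            "n_blocks": self.n_blocks, "M": self.m_ref,
            "n_variants": self.n_variants, "reason": self.reason,
        }


# ---------------------------------------------------------------------------
# estimators

_MIN_VARIANTS = 200


def _check_design(x, free_intercept):
    if np.any(x <= 0):
        raise ValueError("LD scores must be positive")
    if free_intercept and np.ptp(x) < 1e-12:
        raise DegenerateDesignError(
            "LD scores are constant; slope and intercept are not jointly identifiable"
        )
    if not free_intercept and np.max(np.abs(x)) < 1e-12:
        raise DegenerateDesignError("LD scores are identically zero")


def _ldsc_weights(x, mu):
    """1 / (l * mu^2) with guards against vanishing denominators."""
    mu = np.maximum(mu, 0.05)
    return 1.0 / (np.maximum(x, 1.0) * mu * mu)


def estimate_h2(panel: HarmonizedPanel, trait, weights_mode: str = "ldsc",
                intercept_mode: str = "free", max_ld: float = None) -> H2Estimate:
    """Univariate LDSC fit for one trait of a harmonized panel.

    ``max_ld`` optionally caps LD scores (no truncation by default).
    """
    t = panel.index(trait) if isinstance(trait, str) else int(trait)
    x = panel.ld_for(t, t)
    if max_ld is not None:
        x = np.minimum(x, max_ld)
    y = panel.z[:, t] ** 2
    if len(x) < _MIN_VARIANTS:
        raise ValueError(f"need >= {_MIN_VARIANTS} variants, got {len(x)}")
    free = intercept_mode == "free"
    _check_design(x, free)
    N, M = panel.n[t], panel.m_for(t, t)
    blocks = panel.blocks

    if free:
        a0, b0 = _solve(*_block_sums(x, y, np.ones_like(x), blocks,
                                     int(blocks.max()) + 1).sum(axis=1), True)
    else:
        y0 = y - 1.0
        b0 = float(np.sum(x * y0) / np.sum(x * x))
        a0 = 1.0
    mu = None
    if weights_mode == "uniform":
        w = np.ones_like(x)
    elif weights_mode == "ldsc":
        h2_0 = float(np.clip(b0 * M / N, 0.0, 1.0))
        mu = a0 + N * h2_0 * x / M
        w = _ldsc_weights(x, mu)
    else:
        raise ValueError(f"unknown weights_mode {weights_mode!r}")

    if free:
        a, b, a_del, b_del = _wls_with_jackknife(x, y, w, blocks, True)
    else:
        a, b, a_del, b_del = _wls_with_jackknife(x, y - 1.0, w, blocks, False)
        a, a_del = 1.0, a_del + 1.0

    scale = M / N
    return H2Estimate(
        h2=b * scale,
        intercept=a,
        se_h2=_jackknife_se(b_del * scale),
        se_intercept=_jackknife_se(a_del) if free else 0.0,
        n_blocks=len(b_del),
        m_ref=int(M),
        n_variants=len(x),
        mean_chisq=float(y.mean()),
        weights_mode=weights_mode,
        intercept_mode=intercept_mode,
        h2_delete=b_del * scale,
        intercept_delete=a_del,
        weight_mu=mu,
    )


def estimate_rg(panel: HarmonizedPanel, trait_t, trait_u,
                weights_mode: str = "ldsc", intercept_mode: str = "auto",
                h2_t: H2Estimate = None, h2_u: H2Estimate = None,
                max_ld: float = None) -> RgEstimate:
    """Bivariate LDSC fit for a trait pair.

    ``intercept_mode``: 'auto' frees the cross-trait intercept within a
    population and fixes it to 0 across populations; 'free'/'fixed'
    override.  Univariate fits are computed on the same panel (or
    passed in) to normalize rho_g to rg; their delete-one values enter
    the rg jackknife so the SE reflects h2 uncertainty.
    """
    t = panel.index(trait_t) if isinstance(trait_t, str) else int(trait_t)
    u = panel.index(trait_u) if isinstance(trait_u, str) else int(trait_u)
    cross = panel.is_cross(t, u)
    x = panel.ld_for(t, u)
    if max_ld is not None:
        x = np.minimum(x, max_ld)
    y = panel.z[:, t] * panel.z[:, u]
    if intercept_mode == "auto":
        free = not cross
    else:
        free = intercept_mode == "free"
    _check_design(x, free)
    Nt, Nu, M = panel.n[t], panel.n[u], panel.m_for(t, u)
    blocks = panel.blocks
    scale = M / np.sqrt(Nt * Nu)

    if h2_t is None:
        h2_t = estimate_h2(panel, t, weights_mode=weights_mode)
    if h2_u is None:
        h2_u = estimate_h2(panel, u, weights_mode=weights_mode)

    ones = np.ones_like(x)
    c0, b0 = _solve(*_block_sums(x, y, ones, blocks,
                                 int(blocks.max()) + 1).sum(axis=1), free)
    if weights_mode == "uniform":
        w = ones
    else:
        if h2_t.weight_mu is not None and len(h2_t.weight_mu) == len(x):
            mu_t = h2_t.weight_mu
        else:
            mu_t = h2_t.intercept + Nt * max(h2_t.h2, 0.0) * panel.ld_for(t, t) / h2_t.m_ref
        if h2_u.weight_mu is not None and len(h2_u.weight_mu) == len(x):
            mu_u = h2_u.weight_mu
        else:
            mu_u = h2_u.intercept + Nu * max(h2_u.h2, 0.0) * panel.ld_for(u, u) / h2_u.m_ref
        mu_tu = c0 + b0 * x
        w = 1.0 / (np.maximum(x, 1.0) * np.maximum(mu_t * mu_u + mu_tu**2, 0.05))

    c, b, c_del, b_del = _wls_with_jackknife(x, y, w, blocks, free)
    rho_g = b * scale
    rho_del = b_del * scale

    result = RgEstimate(
        rho_g=rho_g,
        rg=None,
        intercept=c if free else None,
        se_rho_g=_jackknife_se(rho_del),
        se_rg=None,
        se_intercept=_jackknife_se(c_del) if free else None,
        cross_population=cross,
        n_blocks=len(b_del),
        m_ref=int(M),
        n_variants=len(x),
        rho_g_delete=rho_del,
    )
    if h2_t.h2 <= 0 or h2_u.h2 <= 0:
        result.reason = (
            f"rg undefined: non-positive heritability "
            f"(h2[{panel.traits[t]}]={h2_t.h2:.4g}, h2[{panel.traits[u]}]={h2_u.h2:.4g})"
        )
        return result
    result.rg = rho_g / np.sqrt(h2_t.h2 * h2_u.h2)
    if (h2_t.h2_delete is not None and h2_u.h2_delete is not None
            and len(h2_t.h2_delete) == len(rho_del)):
        denom = np.sqrt(np.clip(h2_t.h2_delete * h2_u.h2_delete, 1e-12, None))
        result.rg_delete = rho_del / denom
        result.se_rg = _jackknife_se(result.rg_delete)
    else:
        # delta-method fallback when block maps differ
        result.se_rg = result.se_rho_g / np.sqrt(h2_t.h2 * h2_u.h2)
    return result
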