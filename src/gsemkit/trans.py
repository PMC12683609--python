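"""Cross-population genetic-effect correlation from summary statistics.

For a trait pair measured in two different populations the product of
Z-scores is regressed on the cross-population LD score with the
intercept fixed at 0 (no shared samples across ancestries):

    E[z_t z_u] = (sqrt(N_t N_u) / M) * rho_ge * sqrt(h2_t h2_u) * l_cross,j

The slope recovers the cross-population genetic covariance
rho_g = rho_ge * sqrt(h2_t h2_u); dividing by the two within-population
heritabilities gives the genetic-effect correlation rho_ge.  This is a
method-of-moments estimator of the same estimand as likelihood-based
trans-ancestry methods under the polygenic model, and it shares the
block jackknife with the within-population machinery so a joint
sampling covariance can be assembled.  Estimates outside [-1, 1] are
reported and flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ldsc import H2Estimate, _jackknife_se, estimate_h2, estimate_rg
from .panel import HarmonizedPanel

__all__ = ["TransRgEstimate", "estimate_trans_rg"]


@dataclass
class TransRgEstimate:
    """Cross-population genetic-effect correlation for one trait pair."""

    rho_ge: Optional[float]
    se: Optional[float]
    rho_g: float
    se_rho_g: float
    h2_t: float
    h2_u: float
    n_variants: int
    n_blocks: int
    out_of_range: bool = False
    reason: Optional[str] = None
    rho_ge_delete: np.ndarray = field(default=None, repr=False)
    rho_g_delete: np.ndarray = field(default=None, repr=False)

    def to_dict(self):
        return {
            "rho_ge": self.rho_ge, "rho_ge_se": self.se,
            "rho_g": self.rho_g, "rho_g_se": self.se_rho_g,
            "h2_t": self.h2_t, "h2_u": self.h2_u,
            "n_variants": self.n_variants, "n_blocks": self.n_blocks,
            "out_of_range": self.out_of_range, "reason": self.reason,
        }


def estimate_trans_rg(panel: HarmonizedPanel, trait_t, trait_u,
                      weights_mode: str = "ldsc",
                      h2_t: H2Estimate = None,
                      h2_u: H2Estimate = None) -> TransRgEstimate:
    """Moment estimator of rho_ge for a cross-population trait pair."""
    t = panel.index(trait_t) if isinstance(trait_t, str) else int(trait_t)
    u = panel.index(trait_u) if isinstance(trait_u, str) else int(trait_u)
    if not panel.is_cross(t, u):
        raise ValueError(
            f"traits ({panel.traits[t]}, {panel.traits[u]}) are from the same "
            "population; use the within-population estimator"
        )
    if h2_t is None:
        h2_t = estimate_h2(panel, t, weights_mode=weights_mode)
    if h2_u is None:
        h2_u = estimate_h2(panel, u, weights_mode=weights_mode)

    pair = estimate_rg(panel, t, u, weights_mode=weights_mode,
                       intercept_mode="fixed", h2_t=h2_t, h2_u=h2_u)

    result = TransRgEstimate(
        rho_ge=None, se=None,
        rho_g=pair.rho_g, se_rho_g=pair.se_rho_g,
        h2_t=h2_t.h2, h2_u=h2_u.h2,
        n_variants=pair.n_variants, n_blocks=pair.n_blocks,
        rho_g_delete=pair.rho_g_delete,
    )
    if h2_t.h2 <= 0 or h2_u.h2 <= 0:
        result.reason = (
            f"rho_ge undefined: non-positive heritability "
            f"(h2[{panel.traits[t]}]={h2_t.h2:.4g}, h2[{panel.traits[u]}]={h2_u.h2:.4g})"
        )
        return result
    result.rho_ge = pair.rho_g / np.sqrt(h2_t.h2 * h2_u.h2)
    result.out_of_range = abs(result.rho_ge) > 1.0
    if (h2_t.h2_delete is not None and h2_u.h2_delete is not None
            and len(h2_t.h2_delete) == len(pair.rho_g_delete)):
        denom = np.sqrt(np.clip(h2_t.h2_delete * h2_u.h2_delete, 1e-12, None))
        result.rho_ge_delete = pair.rho_g_delete / denom
        result.se = _jackknife_se(result.rho_ge_delete)
    else:
        result.se = pair.se_rho_g / np.sqrt(h2_t.h2 * h2_u.h2)
    return result
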