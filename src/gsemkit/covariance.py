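"""Assemble the genetic covariance matrix S and its sampling covariance V.

S is T x T: diagonal cells are LDSC heritabilities, within-population
off-diagonals are LDSC genetic covariances, cross-population cells come
from the trans-ancestry moment estimator (all on the covariance scale,
so cross cells equal rho_ge * sqrt(h2_t h2_u)).  V is the t* x t*
(t* = T(T+1)/2) sampling covariance of vech(S), computed from the joint
delete-one-block estimates of every cell over a common block map, so
sampling dependence between cells (shared samples, shared variants) is
captured.

vech ordering is column-major over the lower triangle:
(0,0), (1,0), ..., (T-1,0), (1,1), (2,1), ..., (T-1,T-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ldsc import estimate_h2, estimate_rg
from .panel import HarmonizedPanel
from .trans import estimate_trans_rg

__all__ = [
    "GeneticCovarianceStructure",
    "StandardizedStructure",
    "vech",
    "vech_indices",
    "unvech",
    "build_S_V",
    "smooth_to_psd",
    "standardize",
]

logger = logging.getLogger(__name__)


def vech_indices(T: int):
    """(row, col) pairs of the lower triangle in column-major order."""
    return [(i, j) for j in range(T) for i in range(j, T)]


def vech(mat: np.ndarray) -> np.ndarray:
    T = mat.shape[0]
    return np.array([mat[i, j] for i, j in vech_indices(T)])


def unvech(v: np.ndarray) -> np.ndarray:
    t_star = len(v)
    T = int((np.sqrt(8 * t_star + 1) - 1) / 2)
    out = np.zeros((T, T))
    for val, (i, j) in zip(v, vech_indices(T)):
        out[i, j] = out[j, i] = val
    return out


@dataclass
class GeneticCovarianceStructure:
    """Multi-trait genetic covariance S with jackknife sampling covariance V."""

    traits: list
    populations: list
    S: np.ndarray
    V: np.ndarray
    n_blocks: int
    provenance: dict = field(default_factory=dict)
    h2_estimates: dict = field(default_factory=dict)
    pair_estimates: dict = field(default_factory=dict)
    # delete-one-block vech(S) estimates, (n_blocks, t*)
    delete_values: np.ndarray = field(default=None, repr=False)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def t_star(self) -> int:
        T = self.n_traits
        return T * (T + 1) // 2

    def standardized_delete_values(self, diag_mode: str = "unit") -> np.ndarray:
        """Delete-one-block estimates of vech(S_corr).

        Off-diagonal cells are each deletion's rho_g divided by that
        deletion's own sqrt(h2_t h2_u) (the rg ratio).  Diagonal cells
        are exactly 1 under ``diag_mode="unit"``; ``diag_mode="fixed"``
        scales each deletion's h2 by the full-data 1/h2 instead, so
        diagonal sampling variance is retained on the rescaled scale.
        """
        if self.delete_values is None:
            raise ValueError("delete-one values not retained")
        T = self.n_traits
        idx = vech_indices(T)
        diag_pos = {j: idx.index((j, j)) for j in range(T)}
        dele = self.delete_values
        corr = np.empty_like(dele)
        for k, (i, j) in enumerate(idx):
            if i == j:
                if diag_mode == "unit":
                    corr[:, k] = 1.0
                elif diag_mode == "fixed":
                    corr[:, k] = dele[:, k] / self.S[i, i]
                else:
                    raise ValueError(f"unknown diag_mode {diag_mode!r}")
            else:
                denom = np.sqrt(np.clip(dele[:, diag_pos[i]] * dele[:, diag_pos[j]],
                                        1e-12, None))
                corr[:, k] = dele[:, k] / denom
        return corr

    def correlation_jackknife_V(self, diag_mode: str = "unit") -> np.ndarray:
        """V of vech(S_corr) by jackknifing the standardized cells
        directly (each delete-one S is standardized by its own
        diagonal), the alternative to fixed-factor rescaling.  Being a
        jackknife covariance it is positive semidefinite by
        construction."""
        return _jackknife_cov(self.standardized_delete_values(diag_mode))


@dataclass
class StandardizedStructure:
    """Correlation-scale S with consistently rescaled V."""

    traits: list
    populations: list
    S_corr: np.ndarray
    V_corr: np.ndarray
    scale_factors: np.ndarray  # per-trait 1/sqrt(h2)

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def _jackknife_cov(deletes: np.ndarray) -> np.ndarray:
    n = deletes.shape[0]
    centered = deletes - deletes.mean(axis=0)
    return (n - 1) / n * centered.T @ centered


def build_S_V(panel: HarmonizedPanel, weights_mode: str = "ldsc") -> GeneticCovarianceStructure:
    """Fit every cell of S on a shared block map and jackknife V jointly."""
    T = panel.n_traits
    n_blocks = int(panel.blocks.max()) + 1
    S = np.zeros((T, T))
    idx = vech_indices(T)
    deletes = np.empty((n_blocks, len(idx)))
    provenance = {}
    h2_fits = {}
    pair_fits = {}

    for t in range(T):
        fit = estimate_h2(panel, t, weights_mode=weights_mode)
        if len(fit.h2_delete) != n_blocks:
            raise ValueError("mismatched block maps across cells")
        h2_fits[panel.traits[t]] = fit
        S[t, t] = fit.h2

    for k, (i, j) in enumerate(idx):
        ti, tj = panel.traits[i], panel.traits[j]
        if i == j:
            deletes[:, k] = h2_fits[ti].h2_delete
            provenance[(ti, tj)] = "ldsc_h2"
            continue
        if panel.is_cross(i, j):
            fit = estimate_trans_rg(panel, i, j, weights_mode=weights_mode,
                                    h2_t=h2_fits[ti], h2_u=h2_fits[tj])
            provenance[(ti, tj)] = "trans_moment"
        else:
            fit = estimate_rg(panel, i, j, weights_mode=weights_mode,
                              h2_t=h2_fits[ti], h2_u=h2_fits[tj])
            provenance[(ti, tj)] = "ldsc_rg"
        if len(fit.rho_g_delete) != n_blocks:
            raise ValueError("mismatched block maps across cells")
        pair_fits[(ti, tj)] = fit
        S[i, j] = S[j, i] = fit.rho_g
        deletes[:, k] = fit.rho_g_delete

    V = _jackknife_cov(deletes)
    return GeneticCovarianceStructure(
        traits=list(panel.traits),
        populations=list(panel.populations),
        S=S,
        V=V,
        n_blocks=n_blocks,
        provenance=provenance,
        h2_estimates=h2_fits,
        pair_estimates=pair_fits,
        delete_values=deletes,
    )


def smooth_to_psd(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nearest-PSD smoothing by eigenvalue clipping.

    Eigenvalues below ``eps`` are raised to ``eps`` and the matrix is
    reconstructed; if the input was correlation-scale (unit diagonal)
    the diagonal is re-normalized to 1.  The maximum elementwise change
    is logged.
    """
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("smooth_to_psd requires a symmetric matrix")
    was_correlation = np.allclose(np.diag(mat), 1.0, atol=1e-10)
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= eps:
        return mat.copy()
    out = (vecs * np.maximum(vals, eps)) @ vecs.T
    out = (out + out.T) / 2
    if was_correlation:
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    delta = np.max(np.abs(out - mat))
    logger.info("smooth_to_psd: min eigenvalue %.3e raised to %.1e; max elementwise change %.3e",
                vals.min(), eps, delta)
    return out


def standardize(structure: GeneticCovarianceStructure,
                v_method: str = "fixed") -> StandardizedStructure:
    """Rescale S to correlation scale with a consistently rescaled V.

    Each cell (i, j) of S is divided by sqrt(S_ii S_jj).  For V,
    ``v_method="fixed"`` multiplies the matching rows/columns by the
    same factors, treating the diagonal scaling as known (h2 estimation
    error in the scale factors is ignored).  ``v_method="jackknife"``
    re-standardizes every delete-one-block S by its own diagonal, so
    the ratio noise of rg = rho_g / sqrt(h2_t h2_u) propagates into V;
    diagonal cells — exactly 1 in every deletion, hence with zero
    jackknife variance — keep the fixed-factor variance so DWLS weights
    stay finite.  The jackknife variant is better calibrated for SEM
    standard errors (see the methods note).
    """
    d = np.diag(structure.S)
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive heritability for trait(s) "
            f"{[structure.traits[i] for i in bad]}; cannot standardize"
        )
    inv_sd = 1.0 / np.sqrt(d)
    S_corr = structure.S * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(S_corr, np.diag(structure.S) * inv_sd**2)  # exactly 1
    f = np.array([inv_sd[i] * inv_sd[j] for i, j in vech_indices(structure.n_traits)])
    V_corr = structure.V * np.outer(f, f)
    if v_method == "jackknife":
        V_corr = structure.correlation_jackknife_V(diag_mode="fixed")
    elif v_method != "fixed":
        raise ValueError(f"unknown v_method {v_method!r}")
    return StandardizedStructure(
        traits=list(structure.traits),
        populations=list(structure.populations),
        S_corr=S_corr,
        V_corr=V_corr,
        scale_factors=inv_sd,
    )
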