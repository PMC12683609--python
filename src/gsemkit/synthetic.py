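"""Two-population, multi-trait GWAS summary-statistic generator.

True per-variant effects follow a latent factor model: the T x T genetic
correlation matrix is ``S_corr = Lambda Psi Lambda' + Theta`` with
standardized loadings ``Lambda``, factor correlations ``Psi`` and
diagonal residual genetic variances ``Theta``.  On the covariance scale
``S[t,u] = S_corr[t,u] * sqrt(h2_t h2_u)``, and cells that pair traits
from different populations are additionally attenuated by the
cross-population effect correlation ``rho_ge``.

Z-scores are sampled directly from the LD score regression moment
conditions: for each variant j, independently across variants,

    Cov[z_t, z_u] = sqrt(N_t N_u) * l_j(t,u) * S[t,u] / M + delta(t,u)

where ``l_j`` is the within- or cross-population LD score and ``delta``
is 1 on the diagonal, ``rho_ph * N_s / sqrt(N_t N_u)`` for overlapping
within-population pairs, and 0 across populations (no shared samples
across ancestries).  Sampling the moment model directly makes LDSC
consistent by construction, so parameter-recovery tests are sharp; it
does not exercise between-variant dependence (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldblocks import LdBlockDesign, LdScorePanel, build_ld_panels
from .panel import HarmonizedPanel, context_key

__all__ = [
    "SyntheticScenario",
    "TruthRecord",
    "InvalidScenarioError",
    "true_cov_structure",
    "simulate_sumstats",
    "simulate_panel",
    "scramble_table",
]

_UNIT_DIAG_TOL = 1e-8


class InvalidScenarioError(ValueError):
    """Raised when a scenario violates its own invariants."""


@dataclass
class SyntheticScenario:
    """Ground-truth configuration for the generator.

    ``loadings`` is T x K, ``psi`` K x K with unit diagonal, ``theta``
    the length-T residual genetic variances (defaults to
    ``1 - diag(Lambda Psi Lambda')`` so the genetic correlation matrix
    has unit diagonal).  ``n_overlap`` / ``rho_ph`` describe shared
    samples within a population; ``rho_ge`` the cross-population effect
    correlation applied to every cross-ancestry pair.
    """

    traits: list
    populations: list
    loadings: np.ndarray
    psi: np.ndarray
    h2: np.ndarray
    n: np.ndarray
    design: LdBlockDesign
    seed: int
    theta: np.ndarray = None
    n_overlap: np.ndarray = None        # (T, T) shared sample counts
    rho_ph: np.ndarray = None           # (T, T) phenotypic correlations
    rho_ge: float = 1.0
    population_order: tuple = None      # maps (pop1, pop2) of the design

    def __post_init__(self):
        T = len(self.traits)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        if self.loadings.shape[0] != T:
            raise InvalidScenarioError("loadings must have one row per trait")
        K = self.loadings.shape[1]
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if self.psi.shape != (K, K):
            raise InvalidScenarioError("psi must be K x K")
        if not np.allclose(self.psi, self.psi.T, atol=1e-12):
            raise InvalidScenarioError("psi must be symmetric")
        if np.any(np.abs(np.diag(self.psi) - 1.0) > _UNIT_DIAG_TOL):
            raise InvalidScenarioError("psi must have unit diagonal")
        if np.linalg.eigvalsh(self.psi).min() < -1e-10:
            raise InvalidScenarioError("psi must be positive semidefinite")
        self.h2 = np.asarray(self.h2, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if np.any((self.h2 <= 0) | (self.h2 > 1)):
            raise InvalidScenarioError("h2 must lie in (0, 1]")
        common = self.loadings @ self.psi @ self.loadings.T
        if self.theta is None:
            self.theta = 1.0 - np.diag(common)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(np.abs(np.diag(common) + self.theta - 1.0) > 1e-6):
            raise InvalidScenarioError(
                "Lambda Psi Lambda' + Theta must have unit diagonal"
            )
        if self.n_overlap is None:
            self.n_overlap = np.zeros((T, T))
        if self.rho_ph is None:
            self.rho_ph = np.zeros((T, T))
        self.n_overlap = np.asarray(self.n_overlap, dtype=float)
        self.rho_ph = np.asarray(self.rho_ph, dtype=float)
        for t in range(T):
            for u in range(T):
                if self.n_overlap[t, u] > min(self.n[t], self.n[u]) + 1e-9:
                    raise InvalidScenarioError(
                        f"overlap N_s for ({self.traits[t]}, {self.traits[u]}) "
                        "exceeds the smaller sample"
                    )
        pops = list(dict.fromkeys(self.populations))
        if len(pops) > 2:
            raise InvalidScenarioError("at most two populations supported")
        if self.population_order is None:
            self.population_order = tuple(pops) if len(pops) == 2 else (pops[0], pops[0])

    @property
    def n_traits(self) -> int:
        return len(self.traits)


@dataclass
class TruthRecord:
    """Ground truth carried alongside generated summary statistics."""

    s_cov: np.ndarray       # covariance scale, rho_ge folded into cross cells
    s_corr: np.ndarray      # Lambda Psi Lambda' + Theta, unit diagonal
    rg: np.ndarray          # normalized s_cov (equals s_corr when rho_ge = 1)
    h2: np.ndarray
    loadings: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    seed: int
    traits: list = field(default_factory=list)


def _cross_mask(populations) -> np.ndarray:
    pops = np.asarray(populations)
    return pops[:, None] != pops[None, :]


def true_cov_structure(scenario: SyntheticScenario) -> TruthRecord:
    """Expected genetic covariance/correlation structure of a scenario."""
    s_corr = scenario.loadings @ scenario.psi @ scenario.loadings.T + np.diag(scenario.theta)
    scale = np.sqrt(np.outer(scenario.h2, scenario.h2))
    s_cov = s_corr * scale
    cross = _cross_mask(scenario.populations)
    s_cov = np.where(cross, s_cov * scenario.rho_ge, s_cov)
    rg = s_cov / scale
    np.fill_diagonal(rg, 1.0)
    return TruthRecord(
        s_cov=s_cov,
        s_corr=s_corr,
        rg=rg,
        h2=scenario.h2.copy(),
        loadings=scenario.loadings.copy(),
        psi=scenario.psi.copy(),
        theta=scenario.theta.copy(),
        seed=scenario.seed,
        traits=list(scenario.traits),
    )


def _noise_cov(scenario: SyntheticScenario) -> np.ndarray:
    """The per-variant error covariance delta(t, u)."""
    T = scenario.n_traits
    delta = np.eye(T)
    cross = _cross_mask(scenario.populations)
    denom = np.sqrt(np.outer(scenario.n, scenario.n))
    off = scenario.rho_ph * scenario.n_overlap / denom
    delta = np.where(np.eye(T, dtype=bool), 1.0, np.where(cross, 0.0, off))
    return delta


def _block_ld_matrix(scenario: SyntheticScenario, block: int) -> np.ndarray:
    """T x T matrix of LD scores l_b(t, u) for one block."""
    d = scenario.design
    pop1, pop2 = scenario.population_order
    r = np.array(
        [d.r1[block] if p == pop1 else d.r2[block] for p in scenario.populations]
    )
    return 1.0 + (d.m - 1) * np.outer(r, r)


def simulate_panel(scenario: SyntheticScenario) -> tuple:
    """Sample Z-scores from the moment model; return (panel, truth).

    The returned :class:`HarmonizedPanel` is the exact panel that
    merging the written sumstats and LD panels would produce (variant
    ids are zero-padded so lexicographic order is generation order).
    """
    truth = true_cov_structure(scenario)
    d = scenario.design
    T = scenario.n_traits
    delta = _noise_cov(scenario)
    nn = np.sqrt(np.outer(scenario.n, scenario.n))
    rng = np.random.default_rng(scenario.seed)

    z = np.empty((d.M, T))
    for b in range(d.n_blocks):
        lmat = _block_ld_matrix(scenario, b)
        cov = nn * lmat * truth.s_cov / d.M + delta
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            # locate the most extreme implied correlation for the diagnostic
            dd = np.sqrt(np.abs(np.diag(cov)))
            corr = cov / np.outer(dd, dd)
            np.fill_diagonal(corr, 0.0)
            t, u = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
            raise InvalidScenarioError(
                f"per-variant Z covariance not positive definite in block {b}; "
                f"most extreme implied correlation {corr[t, u]:.4f} for pair "
                f"({scenario.traits[t]}, {scenario.traits[u]})"
            ) from None
        z[b * d.m:(b + 1) * d.m] = rng.standard_normal((d.m, T)) @ chol.T

    pop1, pop2 = scenario.population_order
    ld = {pop1: d.ld_scores("pop1")}
    m_ref = {pop1: d.M}
    if pop2 != pop1:
        ld[pop2] = d.ld_scores("pop2")
        ld[context_key(pop1, pop2)] = d.ld_scores("cross")
        m_ref[pop2] = d.M
        m_ref[context_key(pop1, pop2)] = d.M
    panel = HarmonizedPanel(
        snp=d.variant_ids(),
        z=z,
        n=scenario.n.copy(),
        traits=list(scenario.traits),
        populations=list(scenario.populations),
        ld=ld,
        m_ref=m_ref,
        blocks=d.block_ids(),
    )
    return panel, truth


def simulate_sumstats(scenario: SyntheticScenario, scramble: bool = False,
                      scramble_fraction: float = 0.2,
                      ambiguous_fraction: float = 0.05) -> tuple:
    """Generate one sumstats table per trait plus the truth record.

    Tables follow the munged layout (SNP, A1, A2, Z, N) with canonical
    alleles A1=A, A2=G.  ``scramble`` exercises harmonization: a
    fraction of records get swapped alleles (Z negated) or strand
    flips, and a small fraction become strand-ambiguous pairs.
    """
    panel, truth = simulate_panel(scenario)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0xA11E1E]))
    tables = []
    for t in range(scenario.n_traits):
        tab = pd.DataFrame(
            {
                "SNP": panel.snp,
                "A1": "A",
                "A2": "G",
                "Z": panel.z[:, t],
                "N": int(scenario.n[t]),
            }
        )
        if scramble:
            tab = scramble_table(tab, rng, scramble_fraction, ambiguous_fraction)
        tables.append(tab)
    return tables, truth


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def scramble_table(table: pd.DataFrame, rng, swap_fraction: float = 0.2,
                   ambiguous_fraction: float = 0.05) -> pd.DataFrame:
    """Randomly swap A1/A2 (negating Z), strand-flip, and inject
    strand-ambiguous allele pairs, to exercise harmonization."""
    out = table.copy()
    n = len(out)
    u = rng.random(n)
    swap = u < swap_fraction
    flip = (u >= swap_fraction) & (u < 2 * swap_fraction)
    amb = rng.random(n) < ambiguous_fraction

    a1, a2 = out["A1"].to_numpy().copy(), out["A2"].to_numpy().copy()
    z = out["Z"].to_numpy().copy()
    a1[swap], a2[swap] = out["A2"].to_numpy()[swap], out["A1"].to_numpy()[swap]
    z[swap] = -z[swap]
    a1[flip] = [_COMPLEMENT[a] for a in a1[flip]]
    a2[flip] = [_COMPLEMENT[a] for a in a2[flip]]
    amb_pair = rng.random(amb.sum()) < 0.5
    a1[amb] = np.where(amb_pair, "A", "C")
    a2[amb] = np.where(amb_pair, "T", "G")
    out["A1"], out["A2"], out["Z"] = a1, a2, z
    return out
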