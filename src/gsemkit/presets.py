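"""Canned synthetic scenarios.

``fourfactor9`` mirrors the structure of a nine-trait, two-ancestry
psychiatric panel (SCZ/BD1/BD2/MDD in Europeans; SCZ x2, BD1, BD2, MDD
in East Asians) loading on four correlated latent factors:

    F1  European psychosis   (SCZ_EUR, BD1_EUR; small negative BD2_JPN)
    F2  Asian psychosis      (SCZ_EAS, SCZ_JPN, BD2_JPN)
    F3  Bipolar              (BD1_EUR, BD2_EUR, BD1_JPN)
    F4  Depression           (MDD_EUR, MDD_EAS, BD1_JPN)

Per-trait SNP heritability 0.4, N = 50,000 per trait, M = 20,000
variants in 200 LD blocks (the blocks double as jackknife units).
Intra-block genotype correlations vary across blocks so LD scores span
a wide range and the LDSC regression design is well conditioned.
"""

from __future__ import annotations

import numpy as np

from .ldblocks import LdBlockDesign
from .synthetic import SyntheticScenario

__all__ = [
    "fourfactor9",
    "FOURFACTOR9_TRAITS",
    "FOURFACTOR9_MODEL_TEXT",
    "default_design",
    "single_trait_scenario",
    "overlap_pair_scenario",
    "cross_pair_scenario",
]

FOURFACTOR9_TRAITS = [
    "SCZ_EUR", "BD1_EUR", "BD2_EUR", "MDD_EUR",
    "SCZ_EAS", "SCZ_JPN", "BD1_JPN", "BD2_JPN", "MDD_EAS",
]
_POPULATIONS = ["EUR"] * 4 + ["EAS"] * 5

# rows: traits (order above); columns: F1, F2, F3, F4
_LOADINGS = np.array(
    [
        [0.85, 0.00, 0.00, 0.00],   # SCZ_EUR
        [0.55, 0.00, 0.45, 0.00],   # BD1_EUR
        [0.00, 0.00, 0.70, 0.00],   # BD2_EUR
        [0.00, 0.00, 0.00, 0.75],   # MDD_EUR
        [0.00, 0.80, 0.00, 0.00],   # SCZ_EAS
        [0.00, 0.75, 0.00, 0.00],   # SCZ_JPN
        [0.00, 0.00, 0.40, 0.55],   # BD1_JPN
        [-0.25, 0.65, 0.00, 0.00],  # BD2_JPN (negative cross-loading)
        [0.00, 0.00, 0.00, 0.65],   # MDD_EAS
    ]
)

_PSI = np.array(
    [
        [1.00, 0.45, 0.50, 0.30],
        [0.45, 1.00, 0.40, 0.35],
        [0.50, 0.40, 1.00, 0.45],
        [0.30, 0.35, 0.45, 1.00],
    ]
)

# Confirmatory model matching the generating structure, in the model grammar.
FOURFACTOR9_MODEL_TEXT = """\
factor F1: SCZ_EUR BD1_EUR BD2_JPN
factor F2: SCZ_EAS SCZ_JPN BD2_JPN
factor F3: BD1_EUR BD2_EUR BD1_JPN
factor F4: MDD_EUR MDD_EAS BD1_JPN
covary F1 F2
covary F1 F3
covary F1 F4
covary F2 F3
covary F2 F4
covary F3 F4
"""


# Restricted comparison model: one merged psychosis factor instead of
# population-specific F1/F2.
THREEFACTOR9_MODEL_TEXT = """\
factor F1: SCZ_EUR BD1_EUR SCZ_EAS SCZ_JPN BD2_JPN
factor F3: BD1_EUR BD2_EUR BD1_JPN
factor F4: MDD_EUR MDD_EAS BD1_JPN
covary F1 F3
covary F1 F4
covary F3 F4
"""


def default_design(n_blocks: int = 200, m: int = 100) -> LdBlockDesign:
    """Block design with per-block LD so the regression is identifiable."""
    r1 = np.linspace(0.05, 0.50, n_blocks)
    r2 = np.linspace(0.10, 0.45, n_blocks)
    return LdBlockDesign(n_blocks=n_blocks, m=m, r1=r1, r2=r2)


def fourfactor9(seed: int, h2: float = 0.4, n: float = 50_000,
                rho_ge: float = 1.0, design: LdBlockDesign = None) -> SyntheticScenario:
    T = len(FOURFACTOR9_TRAITS)
    return SyntheticScenario(
        traits=list(FOURFACTOR9_TRAITS),
        populations=list(_POPULATIONS),
        loadings=_LOADINGS.copy(),
        psi=_PSI.copy(),
        h2=np.full(T, h2),
        n=np.full(T, float(n)),
        design=design or default_design(),
        seed=seed,
        rho_ge=rho_ge,
        population_order=("EUR", "EAS"),
    )


def single_trait_scenario(seed: int, h2: float = 0.4, n: float = 50_000,
                          design: LdBlockDesign = None) -> SyntheticScenario:
    """One trait, one population: the univariate h2 recovery setting."""
    return SyntheticScenario(
        traits=["T1"],
        populations=["POP"],
        loadings=np.array([[0.0]]),  # residual-only trait
        psi=np.array([[1.0]]),
        h2=np.array([max(h2, 1e-12)]),
        n=np.array([float(n)]),
        design=design or default_design(),
        seed=seed,
        theta=np.array([1.0]),
    )


def overlap_pair_scenario(seed: int, rg: float = 0.5, h2: float = 0.4,
                          n: float = 50_000, overlap_fraction: float = 0.3,
                          rho_ph: float = 0.3,
                          design: LdBlockDesign = None) -> SyntheticScenario:
    """Two same-population traits with true rg and overlapping samples."""
    lam = np.sqrt(abs(rg))
    loadings = np.array([[lam], [np.sign(rg) * lam]])
    n_s = overlap_fraction * n
    return SyntheticScenario(
        traits=["T1", "T2"],
        populations=["POP", "POP"],
        loadings=loadings,
        psi=np.array([[1.0]]),
        h2=np.array([h2, h2]),
        n=np.array([float(n), float(n)]),
        design=design or default_design(),
        seed=seed,
        n_overlap=np.array([[n, n_s], [n_s, n]]),
        rho_ph=np.array([[1.0, rho_ph], [rho_ph, 1.0]]),
    )


def cross_pair_scenario(seed: int, rho_ge: float, h2: float = 0.4,
                        n: float = 50_000,
                        design: LdBlockDesign = None) -> SyntheticScenario:
    """The same trait measured in two populations; within-population
    genetic correlation 1, cross-population effect correlation rho_ge."""
    return SyntheticScenario(
        traits=["TR_P1", "TR_P2"],
        populations=["P1", "P2"],
        loadings=np.array([[1.0], [1.0]]),
        psi=np.array([[1.0]]),
        h2=np.array([h2, h2]),
        n=np.array([float(n), float(n)]),
        design=design or default_design(),
        seed=seed,
        theta=np.array([0.0, 0.0]),
        rho_ge=rho_ge,
        population_order=("P1", "P2"),
    )
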