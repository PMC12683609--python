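"""Confirmatory genomic SEM by diagonally weighted least squares.

A factor model (loadings Lambda, factor correlations Psi with unit
factor variances, diagonal residual variances Theta) is fitted to the
genetic correlation matrix S_corr with sampling covariance V by
minimizing

    F(theta) = (s - sigma(theta))' diag(V)^-1 (s - sigma(theta)),

s = vech(S_corr), sigma(theta) = vech(Lambda Psi Lambda' + Theta).
Parameter uncertainty uses the full V through the sandwich estimator

    cov(theta) = (D'WD)^-1 D'W V W D (D'WD)^-1,   W = diag(V)^-1,

with the Jacobian D = d sigma / d theta by central finite differences.
Model fit: chi2 = (s - sigma)' V^+ (s - sigma) with df = t* - q, CFI
against the independence (free-diagonal, zero off-diagonal) model,
SRMR over the lower triangle including the diagonal, AIC = chi2 + 2q.

Negative residual variances are allowed and flagged rather than
constrained; real genetic correlation matrices routinely produce small,
non-significant negative residuals.

Model text grammar (one statement per line, '#' comments):

    factor F1: SCZ_EUR BD1_EUR BD2_JPN
    covary F1 F2          # free factor covariance (default fixed at 0)
    fix F1->BD2_JPN -0.25 # fix a loading instead of freeing it
    saturated             # all t* moments free (df = 0)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariance import unvech, vech, vech_indices

__all__ = [
    "FactorModelSpec",
    "SemFit",
    "ModelSpecError",
    "ConvergenceError",
    "parse_model",
    "fit_dwls",
    "sandwich_se",
    "fit_indices",
    "compare_models",
]


class ModelSpecError(ValueError):
    """Malformed or unidentified model specification."""


class ConvergenceError(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class FactorModelSpec:
    """Which traits load on which factors, and what is free vs fixed."""

    traits: list
    factors: list
    # (factor, trait) -> "free" | fixed float
    loadings: dict
    covary: set = field(default_factory=set)        # frozenset({f1, f2}) free
    fixed_cov: dict = field(default_factory=dict)   # frozenset -> value
    saturated: bool = False

    def __post_init__(self):
        if self.saturated:
            return
        for (f, t) in self.loadings:
            if f not in self.factors:
                raise ModelSpecError(f"unknown factor {f!r}")
            if t not in self.traits:
                raise ModelSpecError(
                    f"trait {t!r} not among S labels {list(self.traits)}"
                )
        t_star = self.t_star
        if self.q > t_star:
            raise ModelSpecError(
                f"model not identified: {self.q} free parameters exceed "
                f"{t_star} observed moments"
            )

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def t_star(self) -> int:
        T = self.n_traits
        return T * (T + 1) // 2

    # --- free parameter bookkeeping (fixed order: loadings, factor
    # correlations, residual variances) -------------------------------
    @property
    def free_loadings(self) -> list:
        return [(f, t) for (f, t), v in self.loadings.items() if v == "free"]

    @property
    def free_covs(self) -> list:
        pairs = []
        for i, f1 in enumerate(self.factors):
            for f2 in self.factors[i + 1:]:
                if frozenset({f1, f2}) in self.covary:
                    pairs.append((f1, f2))
        return pairs

    @property
    def q(self) -> int:
        if self.saturated:
            return self.t_star
        return len(self.free_loadings) + len(self.free_covs) + self.n_traits

    def param_names(self) -> list:
        if self.saturated:
            return [f"s[{i},{j}]" for i, j in vech_indices(self.n_traits)]
        return (
            [f"{f}->{t}" for f, t in self.free_loadings]
            + [f"corr({f1},{f2})" for f1, f2 in self.free_covs]
            + [f"resid({t})" for t in self.traits]
        )

    def matrices(self, theta: np.ndarray):
        """(Lambda, Psi, Theta_diag) for a free-parameter vector."""
        T, K = self.n_traits, len(self.factors)
        lam = np.zeros((T, K))
        fidx = {f: k for k, f in enumerate(self.factors)}
        tidx = {t: i for i, t in enumerate(self.traits)}
        pos = 0
        for (f, t), v in self.loadings.items():
            if v != "free":
                lam[tidx[t], fidx[f]] = float(v)
        for f, t in self.free_loadings:
            lam[tidx[t], fidx[f]] = theta[pos]
            pos += 1
        psi = np.eye(K)
        for pair, v in self.fixed_cov.items():
            f1, f2 = tuple(pair)
            psi[fidx[f1], fidx[f2]] = psi[fidx[f2], fidx[f1]] = float(v)
        for f1, f2 in self.free_covs:
            psi[fidx[f1], fidx[f2]] = psi[fidx[f2], fidx[f1]] = theta[pos]
            pos += 1
        theta_d = theta[pos:pos + T]
        return lam, psi, theta_d

    def implied_sigma(self, theta: np.ndarray) -> np.ndarray:
        if self.saturated:
            return np.asarray(theta, dtype=float)
        lam, psi, theta_d = self.matrices(theta)
        return vech(lam @ psi @ lam.T + np.diag(theta_d))


def parse_model(text: str, traits) -> FactorModelSpec:
    """Parse the plain-text model grammar against the S trait labels."""
    if not text or not text.strip():
        raise ModelSpecError("empty model specification")
    traits = list(traits)
    factors, loadings, covary, fixed_cov = [], {}, set(), {}
    fixes = []
    saturated = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, _, rest = line.partition(":")
        tokens = line.split()
        if tokens[0] == "saturated":
            saturated = True
        elif tokens[0] == "factor":
            name = head.split()[1]
            members = rest.split()
            if not members:
                raise ModelSpecError(f"line {lineno}: factor {name!r} has no indicators")
            if name in factors:
                raise ModelSpecError(f"line {lineno}: duplicate factor {name!r}")
            factors.append(name)
            for t in members:
                if t not in traits:
                    raise ModelSpecError(
                        f"line {lineno}: trait {t!r} not among S labels"
                    )
                loadings[(name, t)] = "free"
        elif tokens[0] == "covary":
            if len(tokens) != 3:
                raise ModelSpecError(f"line {lineno}: expected 'covary F1 F2'")
            covary.add(frozenset(tokens[1:3]))
        elif tokens[0] == "fix":
            if len(tokens) != 3 or "->" not in tokens[1]:
                raise ModelSpecError(f"line {lineno}: expected 'fix F->trait value'")
            f, t = tokens[1].split("->")
            fixes.append((f, t, float(tokens[2])))
        else:
            raise ModelSpecError(f"line {lineno}: unknown statement {tokens[0]!r}")
    if saturated:
        return FactorModelSpec(traits=traits, factors=[], loadings={}, saturated=True)
    for f, t, v in fixes:
        if f not in factors:
            raise ModelSpecError(f"fix refers to unknown factor {f!r}")
        if t not in traits:
            raise ModelSpecError(f"fix refers to unknown trait {t!r}")
        loadings[(f, t)] = v
    for pair in covary:
        for f in pair:
            if f not in factors:
                raise ModelSpecError(f"covary refers to unknown factor {f!r}")
    return FactorModelSpec(traits=traits, factors=factors, loadings=loadings,
                           covary=covary)


@dataclass
class SemFit:
    spec: FactorModelSpec
    theta: np.ndarray
    se: Optional[np.ndarray]
    chi2: float
    df: int
    cfi: float
    srmr: float
    aic: float
    cost: float
    grad_norm: float
    converged: bool
    implied: np.ndarray                  # model-implied correlation matrix
    s_observed: np.ndarray               # vech(S_corr)
    v_diag: np.ndarray
    negative_residuals: list = field(default_factory=list)
    n_starts_used: int = 1
    warnings: list = field(default_factory=list)

    @property
    def q(self) -> int:
        return self.spec.q

    def params(self) -> pd.DataFrame:
        names = self.spec.param_names()
        se = self.se if self.se is not None else np.full(len(names), np.nan)
        z = np.where(se > 0, self.theta / se, np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
        kinds = (["loading"] * len(self.spec.free_loadings)
                 + ["factor_corr"] * len(self.spec.free_covs)
                 + ["residual"] * self.spec.n_traits
                 ) if not self.spec.saturated else ["moment"] * len(names)
        return pd.DataFrame({
            "parameter": names, "kind": kinds, "estimate": self.theta,
            "se": se, "z": z, "p": p,
        })

    def standardized_loadings(self) -> np.ndarray:
        """Loadings rescaled so implied variances are exactly 1."""
        lam, psi, _ = self.spec.matrices(self.theta)
        d = np.sqrt(np.diag(self.implied))
        return lam / d[:, None]


def _default_start(spec: FactorModelSpec) -> np.ndarray:
    return np.concatenate([
        np.full(len(spec.free_loadings), 0.5),
        np.full(len(spec.free_covs), 0.2),
        np.full(spec.n_traits, 0.5),
    ])


def _efa_start(spec: FactorModelSpec, S_corr: np.ndarray) -> np.ndarray:
    """Initialize free parameters from an EFA of the same rank, with EFA
    factors matched to spec factors through the loading pattern."""
    from scipy.optimize import linear_sum_assignment

    from .efa import efa_fit

    K = len(spec.factors)
    res = efa_fit(S_corr, K, traits=spec.traits)
    tidx = {t: i for i, t in enumerate(spec.traits)}
    score = np.zeros((K, K))  # spec factor x EFA factor
    for a, f in enumerate(spec.factors):
        members = [tidx[t] for (ff, t) in spec.loadings if ff == f]
        for b in range(K):
            score[a, b] = np.sum(np.abs(res.loadings[members, b]))
    rows, cols = linear_sum_assignment(-score)
    assign = dict(zip(rows, cols))
    theta = []
    for f, t in spec.free_loadings:
        b = assign[spec.factors.index(f)]
        theta.append(np.clip(res.loadings[tidx[t], b], -0.95, 0.95))
    for f1, f2 in spec.free_covs:
        b1, b2 = assign[spec.factors.index(f1)], assign[spec.factors.index(f2)]
        theta.append(np.clip(res.factor_corr[b1, b2], -0.8, 0.8))
    resid = np.clip(1.0 - res.communalities, 0.05, 1.0)
    theta.extend(resid.tolist())
    return np.asarray(theta)


def fit_dwls(spec: FactorModelSpec, S_corr: np.ndarray, V: np.ndarray,
             n_starts: int = 5, seed: int = 0, efa_start: bool = True,
             nonneg_residuals: bool = False,
             compute_se: bool = True) -> SemFit:
    """Fit a confirmatory factor model to (S_corr, V) by DWLS.

    Multi-start: an EFA-informed start plus jittered restarts with
    fixed seeds; the minimum-objective solution is returned.  Negative
    residual variances are flagged (set ``nonneg_residuals`` to bound
    them at 0).
    """
    S_corr = np.asarray(S_corr, dtype=float)
    V = np.asarray(V, dtype=float)
    s = vech(S_corr)
    t_star = len(s)
    if V.shape != (t_star, t_star):
        raise ValueError(f"V must be {t_star}x{t_star}, got {V.shape}")
    v_diag = np.diag(V).copy()
    if np.any(v_diag <= 0):
        raise ValueError("diag(V) must be positive for DWLS")
    if spec.t_star != t_star:
        raise ValueError("spec trait count does not match S_corr")
    df = spec.t_star - spec.q
    if df < 0:
        raise ModelSpecError("negative degrees of freedom")

    if spec.saturated:
        theta = s.copy()
        fit = SemFit(
            spec=spec, theta=theta, se=np.sqrt(v_diag), chi2=0.0, df=0,
            cfi=1.0, srmr=0.0, aic=2.0 * spec.q, cost=0.0, grad_norm=0.0,
            converged=True, implied=unvech(theta), s_observed=s, v_diag=v_diag,
        )
        return fit

    w = 1.0 / v_diag
    sw = np.sqrt(w / w.mean())  # normalized weights keep the objective O(1)

    def residuals(theta):
        return sw * (spec.implied_sigma(theta) - s)

    nl = len(spec.free_loadings)
    nc = len(spec.free_covs)
    T = spec.n_traits
    lower = np.concatenate([
        np.full(nl, -5.0), np.full(nc, -0.999),
        np.zeros(T) if nonneg_residuals else np.full(T, -5.0),
    ])
    upper = np.concatenate([np.full(nl, 5.0), np.full(nc, 0.999), np.full(T, 5.0)])

    starts = []
    if efa_start:
        try:
            starts.append(_efa_start(spec, S_corr))
        except Exception:
            pass
    starts.append(_default_start(spec))
    rng = np.random.default_rng(seed)
    base = starts[0]
    while len(starts) < n_starts:
        starts.append(base + rng.normal(0.0, 0.1, size=base.shape))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-6, upper - 1e-6)
        res = optimize.least_squares(
            residuals, x0, bounds=(lower, upper), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=5000,
        )
        if best is None or res.cost < best.cost:
            best = res
    cost = 2.0 * best.cost  # scipy cost = 0.5 * sum r^2
    grad_norm = float(np.max(np.abs(best.grad))) if best.grad is not None else np.inf
    converged = best.status > 0
    if not converged:
        raise ConvergenceError(
            f"DWLS did not converge after {len(starts)} starts "
            f"(best objective {cost:.3e}, gradient norm {grad_norm:.3e})",
            best=best,
        )

    theta = best.x
    sigma_hat = spec.implied_sigma(theta)
    implied = unvech(sigma_hat)
    _, _, theta_d = spec.matrices(theta)
    neg = [spec.traits[i] for i in range(T) if theta_d[i] < 0]

    fit = SemFit(
        spec=spec, theta=theta, se=None, chi2=np.nan, df=df, cfi=np.nan,
        srmr=np.nan, aic=np.nan, cost=cost, grad_norm=grad_norm,
        converged=converged, implied=implied, s_observed=s, v_diag=v_diag,
        negative_residuals=neg, n_starts_used=len(starts),
    )
    chi2, df, cfi, srmr, aic = fit_indices(fit, S_corr, V)
    fit.chi2, fit.df, fit.cfi, fit.srmr, fit.aic = chi2, df, cfi, srmr, aic
    if compute_se:
        fit.se = sandwich_se(fit, V)
    return fit


def _jacobian(spec: FactorModelSpec, theta: np.ndarray, step: float = 1e-6,
              scheme: str = "central") -> np.ndarray:
    q = len(theta)
    t_star = spec.t_star
    J = np.empty((t_star, q))
    f0 = spec.implied_sigma(theta) if scheme == "forward" else None
    for k in range(q):
        e = np.zeros(q)
        e[k] = step
        if scheme == "central":
            J[:, k] = (spec.implied_sigma(theta + e) - spec.implied_sigma(theta - e)) / (2 * step)
        else:
            J[:, k] = (spec.implied_sigma(theta + e) - f0) / step
    return J


def sandwich_se(fit: SemFit, V: np.ndarray, step: float = 1e-6) -> np.ndarray:
    """Sandwich standard errors using the full sampling covariance V."""
    spec, theta = fit.spec, fit.theta
    if spec.saturated:
        return np.sqrt(np.diag(V))
    delta = _jacobian(spec, theta, step=step, scheme="central")
    delta_fwd = _jacobian(spec, theta, step=step, scheme="forward")
    if np.max(np.abs(delta - delta_fwd)) > 1e-3 * (1 + np.max(np.abs(delta))):
        fit.warnings.append("central vs forward finite-difference Jacobians disagree")
    q = delta.shape[1]
    if np.linalg.matrix_rank(delta, tol=1e-8) < q:
        _, r = np.linalg.qr(delta)
        aliased = [fit.spec.param_names()[k] for k in range(q)
                   if abs(r[k, k]) < 1e-8]
        raise ValueError(f"Jacobian rank deficient; aliased parameters: {aliased}")
    w = 1.0 / np.diag(V)
    bread = np.linalg.inv(delta.T @ (delta * w[:, None]))
    wd = delta * w[:, None]
    meat = wd.T @ V @ wd
    cov = bread @ meat @ bread
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def fit_indices(fit: SemFit, S_corr: np.ndarray, V: np.ndarray):
    """(chi2, df, CFI, SRMR, AIC) for a converged fit."""
    s = fit.s_observed
    sigma_hat = vech(fit.implied)
    resid = s - sigma_hat
    vp = np.linalg.pinv(V)
    cond = np.linalg.cond(V)
    if cond > 1e12:
        fit.warnings.append(f"V nearly singular (condition number {cond:.2e})")
    chi2 = float(resid @ vp @ resid)
    df = fit.spec.t_star - fit.spec.q

    # independence model: free diagonal, zero off-diagonals; under DWLS
    # the diagonal parameters match their own moments exactly
    T = fit.spec.n_traits
    sigma_ind = vech(np.diag(np.diag(S_corr)))
    resid_ind = s - sigma_ind
    chi2_ind = float(resid_ind @ vp @ resid_ind)
    df_ind = fit.spec.t_star - T

    num = max(chi2 - df, 0.0)
    den = max(chi2_ind - df_ind, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    cfi = float(np.clip(cfi, 0.0, 1.0))
    srmr = float(np.sqrt(np.mean((vech(S_corr) - sigma_hat) ** 2)))
    aic = chi2 + 2.0 * fit.spec.q
    return chi2, df, cfi, srmr, float(aic)


def compare_models(fits: list) -> pd.DataFrame:
    """Rank converged fits on identical (S_corr, V) by AIC."""
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0].s_observed
    for f in fits[1:]:
        if (len(f.s_observed) != len(ref)
                or not np.allclose(f.s_observed, ref, atol=1e-12)):
            raise ValueError("fits were not computed on identical inputs")
    rows = [{
        "model": "+".join(f.spec.factors) if f.spec.factors else "saturated",
        "n_factors": len(f.spec.factors),
        "q": f.q, "chi2": f.chi2, "df": f.df,
        "cfi": f.cfi, "srmr": f.srmr, "aic": f.aic,
    } for f in fits]
    table = pd.DataFrame(rows).sort_values(["aic", "q"], kind="mergesort")
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table.reset_index(drop=True)
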