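"""Exploratory factor analysis of a genetic correlation matrix.

Principal-axis factoring with iterated communalities followed by an
oblique promax rotation (varimax then power-4 target).  Maximum
likelihood EFA is deliberately avoided: no sample size is well defined
for a jackknifed genetic correlation matrix, whereas principal-axis
factoring only needs the matrix itself.

Factor indeterminacy is resolved canonically: factors are ordered by
descending sum of squared pattern loadings and each factor's sign is
chosen so its largest-|loading| entry is positive; the factor
correlation matrix is permuted/reflected consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EfaResult", "efa_fit", "efa_scan", "tucker_congruence", "match_factors"]

_HEYWOOD_TOL = 1e-6


@dataclass
class EfaResult:
    loadings: np.ndarray            # T x k pattern matrix (oblique)
    factor_corr: np.ndarray         # k x k
    communalities: np.ndarray       # diag of L Phi L'
    var_explained: np.ndarray       # per-factor proportion of total variance
    k: int
    heywood: bool = False
    n_iter: int = 0
    traits: list = field(default_factory=list)

    def thresholded(self, cutoff: float = 0.25) -> np.ndarray:
        """Display copy with |loadings| below ``cutoff`` blanked to 0."""
        out = self.loadings.copy()
        out[np.abs(out) < cutoff] = 0.0
        return out


def _principal_axis(R: np.ndarray, k: int, tol: float = 1e-6, max_iter: int = 100):
    T = R.shape[0]
    # initial communalities: squared multiple correlations when R invertible
    try:
        h = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
        h = np.clip(h, 0.0, 1.0)
    except np.linalg.LinAlgError:
        h = np.full(T, 0.5)
    L = np.zeros((T, k))
    it = 0
    for it in range(1, max_iter + 1):
        Rh = R.copy()
        np.fill_diagonal(Rh, h)
        vals, vecs = np.linalg.eigh(Rh)
        order = np.argsort(vals)[::-1][:k]
        lam = np.clip(vals[order], 0.0, None)
        L = vecs[:, order] * np.sqrt(lam)
        h_new = np.sum(L**2, axis=1)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    return L, h, it


def _varimax(L: np.ndarray, eps: float = 1e-6, max_iter: int = 1000):
    T, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    sc = np.sqrt(np.sum(L**2, axis=1))
    sc[sc == 0] = 1.0
    x = L / sc[:, None]
    rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        z = x @ rot
        B = x.T @ (z**3 - z @ np.diag(np.sum(z**2, axis=0)) / T)
        u, s, vt = np.linalg.svd(B)
        rot = u @ vt
        d_old, d = d, s.sum()
        if d < d_old * (1 + eps):
            break
    return (x @ rot) * sc[:, None], rot


def _promax(L: np.ndarray, power: int = 4):
    """Oblique promax rotation; returns (pattern, factor_corr)."""
    k = L.shape[1]
    if k < 2:
        return L.copy(), np.eye(k)
    x, rotmat = _varimax(L)
    Q = x * np.abs(x) ** (power - 1)
    U, *_ = np.linalg.lstsq(x, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = x @ U
    U_full = rotmat @ U
    ui = np.linalg.inv(U_full)
    phi = ui @ ui.T
    return pattern, phi


def _canonicalize(pattern: np.ndarray, phi: np.ndarray):
    order = np.argsort(np.sum(pattern**2, axis=0))[::-1]
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    for j in range(pattern.shape[1]):
        i = np.argmax(np.abs(pattern[:, j]))
        if pattern[i, j] < 0:
            pattern[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    return pattern, phi


def efa_fit(S_corr: np.ndarray, k: int, traits=None, rotate: bool = True) -> EfaResult:
    """Principal-axis EFA with promax rotation on a correlation matrix."""
    S_corr = np.asarray(S_corr, dtype=float)
    T = S_corr.shape[0]
    if k >= T:
        raise ValueError(f"k must be smaller than the trait count ({k} >= {T})")
    L, h, n_iter = _principal_axis(S_corr, k)
    if rotate and k > 1 and np.any(np.abs(L) > 1e-8):
        pattern, phi = _promax(L)
    else:
        pattern, phi = L.copy(), np.eye(k)
    pattern, phi = _canonicalize(pattern, phi)
    comm = np.diag(pattern @ phi @ pattern.T)
    heywood = bool(np.any(comm > 1 + _HEYWOOD_TOL))
    var_exp = np.sum(pattern**2, axis=0) / T
    return EfaResult(
        loadings=pattern,
        factor_corr=phi,
        communalities=comm,
        var_explained=var_exp,
        k=k,
        heywood=heywood,
        n_iter=n_iter,
        traits=list(traits) if traits is not None else [],
    )


def efa_scan(S_corr: np.ndarray, k_list=(3, 4, 5), traits=None,
             cross_loading_cutoff: float = 0.3):
    """Fit EFA at several factor counts and summarize for model choice.

    Returns a list of dicts (one per k) with the fraction of total
    variance explained (mean communality under the oblique solution),
    the count of cross-loadings above the cutoff, Heywood flags, and a
    parsimony score: variance explained minus a complexity penalty of
    0.02 per factor (each factor buys roughly one more column of free
    loadings; gains smaller than the penalty signal overfactoring).
    The choice of k is advisory; nothing downstream auto-commits to it.
    """
    T = np.asarray(S_corr).shape[0]
    for k in k_list:
        if k >= T:
            raise ValueError(f"k={k} is not below the trait count T={T}")
    summaries = []
    for k in k_list:
        res = efa_fit(S_corr, k, traits=traits)
        primary = np.argmax(np.abs(res.loadings), axis=1)
        n_cross = int(sum(
            np.sum(np.abs(res.loadings[i]) >= cross_loading_cutoff) - 1
            for i in range(res.loadings.shape[0])
            if np.abs(res.loadings[i, primary[i]]) >= cross_loading_cutoff
        ))
        total_var = float(np.clip(res.communalities, 0, None).mean())
        summaries.append({
            "k": k,
            "var_explained": total_var,
            "n_cross_loadings": n_cross,
            "heywood": res.heywood,
            "parsimony": total_var - 0.02 * k,
            "result": res,
        })
    return summaries


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def match_factors(estimated: np.ndarray, truth: np.ndarray):
    """Optimal column matching (by |congruence|) of estimated loadings to
    a reference; returns (permuted_signed_estimate, per-factor |congruence|)."""
    from scipy.optimize import linear_sum_assignment

    k = truth.shape[1]
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            C[i, j] = tucker_congruence(estimated[:, i], truth[:, j])
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(k, dtype=int)
    signs = np.empty(k)
    for r, c in zip(rows, cols):
        perm[c] = r
        signs[c] = np.sign(C[r, c]) or 1.0
    matched = estimated[:, perm] * signs
    cong = np.array([abs(C[perm[j], j]) for j in range(k)])
    return matched, cong
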