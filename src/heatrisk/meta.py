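"""Multivariate random-effects meta-analysis of site curves, with BLUP.

Site-reduced coefficient vectors y_s with within-site covariances V_s are
pooled per subregion under y_s ~ N(mu, V_s + Psi), Psi estimated by
restricted maximum likelihood (the mvmeta convention for "constrained
maximum likelihood"), with a method-of-moments fallback.  Best linear
unbiased prediction shrinks each site curve toward the pooled mean;
heterogeneity is summarised by Cochran's Q and the multivariate I2
extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .dlnm import ExposureResponseCurve, find_mmhsi

__all__ = ["RegionPool", "pool", "blup", "heterogeneity", "region_curve"]


@dataclass
class RegionPool:
    """Pooled random-effects summary for one subregion."""

    region_id: str
    mu: np.ndarray  # pooled coefficient vector
    mu_vcov: np.ndarray  # covariance of the pooled mean
    psi: np.ndarray  # between-site covariance
    q_stat: float
    q_df: int
    q_pvalue: float
    i2: float  # percent
    n_sites: int
    converged: bool
    method: str  # 'reml' | 'mom'


def _check_inputs(ys, Vs):
    ys = [np.asarray(y, dtype=float) for y in ys]
    Vs = [np.asarray(V, dtype=float) for V in Vs]
    if len(ys) < 2:
        raise ValueError("pooling requires at least two site fits")
    p = ys[0].size
    for y, V in zip(ys, Vs):
        if y.size != p or V.shape != (p, p):
            raise ValueError("all sites must share one basis dimension")
        eig = np.linalg.eigvalsh(0.5 * (V + V.T))
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("within-site covariance is not PSD")
    return ys, Vs, p


def _gls_mean(ys, Vs, psi):
    """GLS mean and its covariance under total covariance V_s + psi."""
    p = ys[0].size
    W_sum = np.zeros((p, p))
    Wy_sum = np.zeros(p)
    Ws = []
    for y, V in zip(ys, Vs):
        W = np.linalg.inv(V + psi)
        Ws.append(W)
        W_sum += W
        Wy_sum += W @ y
    mu_vcov = np.linalg.inv(W_sum)
    mu = mu_vcov @ Wy_sum
    return mu, mu_vcov, Ws


def _neg_restricted_loglik(theta, ys, Vs, p):
    L = np.zeros((p, p))
    idx = np.tril_indices(p)
    L[idx] = theta
    # keep the scale of the diagonal positive via soft-plus free params
    diag = np.arange(p)
    L[diag, diag] = np.exp(np.clip(L[diag, diag], -30, 30))
    psi = L @ L.T
    try:
        mu, mu_vcov, Ws = _gls_mean(ys, Vs, psi)
    except np.linalg.LinAlgError:
        return 1e10
    ll = 0.0
    for y, V, W in zip(ys, Vs, Ws):
        sign, logdet = np.linalg.slogdet(V + psi)
        if sign <= 0:
            return 1e10
        r = y - mu
        ll += -0.5 * (logdet + r @ W @ r)
    sign, logdet_w = np.linalg.slogdet(np.linalg.inv(mu_vcov))
    ll += -0.5 * logdet_w
    return -ll


def _mom_psi(ys, Vs):
    """Multivariate DerSimonian-Laird style moment estimator, PSD-projected."""
    Y = np.stack(ys)
    S = np.cov(Y.T, ddof=1) if Y.shape[0] > 1 else np.zeros((Y.shape[1],) * 2)
    S = np.atleast_2d(S)
    psi = S - np.mean(np.stack(Vs), axis=0)
    w, U = np.linalg.eigh(0.5 * (psi + psi.T))
    return (U * np.clip(w, 0.0, None)) @ U.T


def pool(curves, region_id: str | None = None, maxiter: int = 500) -> RegionPool:
    """REML random-effects pooling of site overall-cumulative curves.

    ``curves`` is a list of ExposureResponseCurve (uncentred reduced
    coefficients are pooled; centring happens after BLUP) or of (y, V)
    pairs.
    """
    if isinstance(curves[0], ExposureResponseCurve):
        ys = [c.coef_reduced for c in curves]
        Vs = [c.vcov_reduced for c in curves]
        if region_id is None:
            region_id = curves[0].region_id or "region"
    else:
        ys = [c[0] for c in curves]
        Vs = [c[1] for c in curves]
        region_id = region_id or "region"
    ys, Vs, p = _check_inputs(ys, Vs)

    psi0 = _mom_psi(ys, Vs)
    L0 = np.linalg.cholesky(psi0 + 1e-8 * np.eye(p))
    theta0 = L0[np.tril_indices(p)].copy()
    diag_pos = np.cumsum(np.arange(1, p + 1)) - 1  # diagonal entries in tril order
    theta0[diag_pos] = np.log(np.maximum(np.diag(L0), 1e-6))

    res = optimize.minimize(
        _neg_restricted_loglik,
        theta0,
        args=(ys, Vs, p),
        method="Nelder-Mead",
        options={"maxiter": maxiter * p, "xatol": 1e-6, "fatol": 1e-8},
    )
    method = "reml"
    converged = bool(res.success)
    theta = res.x
    if not converged or not np.isfinite(res.fun):
        warnings.warn("REML did not converge; falling back to moment estimator")
        method = "mom"
    if method == "reml":
        L = np.zeros((p, p))
        L[np.tril_indices(p)] = theta
        d = np.arange(p)
        L[d, d] = np.exp(np.clip(L[d, d], -30, 30))
        psi = L @ L.T
    else:
        psi = psi0
    mu, mu_vcov, _ = _gls_mean(ys, Vs, psi)

    q, q_df, q_p, i2 = heterogeneity(ys, Vs)
    return RegionPool(
        region_id=region_id,
        mu=mu,
        mu_vcov=0.5 * (mu_vcov + mu_vcov.T),
        psi=0.5 * (psi + psi.T),
        q_stat=q,
        q_df=q_df,
        q_pvalue=q_p,
        i2=i2,
        n_sites=len(ys),
        converged=converged or method == "mom",
        method=method,
    )


def heterogeneity(ys, Vs) -> tuple[float, int, float, float]:
    """Cochran's Q at the fixed-effect mean, its df and p, and I2 (%).

    Q = sum_s (y_s - mu_FE)' V_s^-1 (y_s - mu_FE) with mu_FE the
    fixed-effect (psi = 0) GLS mean; df = (n_sites - 1) * dim;
    I2 = max(0, (Q - df) / Q) * 100.
    """
    ys = [np.asarray(y, float) for y in ys]
    Vs = [np.asarray(V, float) for V in Vs]
    p = ys[0].size
    mu_fe, _, Ws = _gls_mean(ys, Vs, np.zeros((p, p)))
    q = 0.0
    for y, W in zip(ys, Ws):
        r = y - mu_fe
        q += float(r @ W @ r)
    q_df = (len(ys) - 1) * p
    q_p = float(stats.chi2.sf(q, q_df))
    i2 = max(0.0, (q - q_df) / q) * 100.0 if q > 0 else 0.0
    return q, q_df, q_p, i2


def blup(curve: ExposureResponseCurve, pooled: RegionPool) -> ExposureResponseCurve:
    """Shrink one site curve toward the pooled mean (multivariate BLUP).

    blup = mu + Psi (Psi + V_s)^-1 (y_s - mu); its covariance combines the
    conditional variance Psi - Psi (Psi+V)^-1 Psi with the uncertainty of mu
    carried through the non-shrunk component.
    """
    y, V = curve.coef_reduced, curve.vcov_reduced
    p = y.size
    total = pooled.psi + V
    # A = psi (psi+V)^-1 computed as I - V (psi+V)^-1, which stays exact in
    # the V -> 0 (no shrinkage) and psi -> 0 (full shrinkage) limits even
    # when psi is numerically singular
    try:
        A = np.eye(p) - np.linalg.solve(total.T, V.T).T
    except np.linalg.LinAlgError:
        warnings.warn("singular psi + V; ridge-stabilised BLUP inverse")
        ridge = total + 1e-8 * max(np.trace(total), 1e-12) / p * np.eye(p)
        A = np.eye(p) - np.linalg.solve(ridge.T, V.T).T
    coef = pooled.mu + A @ (y - pooled.mu)
    I_A = np.eye(p) - A
    vcov = A @ V @ A.T + I_A @ pooled.mu_vcov @ I_A.T
    out = ExposureResponseCurve(
        basis=curve.basis,
        coef_reduced=coef,
        vcov_reduced=0.5 * (vcov + vcov.T),
        mmhsi=np.nan,
        hsi_range=curve.hsi_range,
        region_id=pooled.region_id,
    )
    out.mmhsi = (
        float(curve.basis.thr) if curve.basis.kind == "thr" else find_mmhsi(out, curve.hsi_range)
    )
    return out


def region_curve(
    pooled: RegionPool,
    template: ExposureResponseCurve,
    window: tuple[float, float] | None = None,
) -> ExposureResponseCurve:
    """Regional curve: the pooled mean evaluated on the template basis,
    re-centred at its own MMHSI."""
    out = ExposureResponseCurve(
        basis=template.basis,
        coef_reduced=pooled.mu.copy(),
        vcov_reduced=pooled.mu_vcov.copy(),
        mmhsi=np.nan,
        hsi_range=template.hsi_range,
        region_id=pooled.region_id,
    )
    out.mmhsi = (
        float(template.basis.thr)
        if template.basis.kind == "thr"
        else find_mmhsi(out, window or template.hsi_range)
    )
    return out
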