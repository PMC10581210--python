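"""Monte Carlo and ensemble uncertainty propagation.

Exposure-response uncertainty is propagated by drawing coefficient vectors
from a multivariate normal centred on the (BLUP) curve coefficients with its
covariance; climate-model uncertainty by evaluating each ensemble member and
taking the 2.5th-97.5th empirical percentiles of the pooled draw x model
distribution.  The reported central value is the ensemble mean of per-model
means.  Percentiles use linear interpolation between closest ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .attribution import af_from_rr
from .dlnm import ExposureResponseCurve

__all__ = ["UncertaintyEnvelope", "sample_coefficients", "ensemble_envelope", "heat_deaths_draws", "model_seeds"]


@dataclass(frozen=True)
class UncertaintyEnvelope:
    """Ensemble mean with an empirical 95% interval."""

    mean: float
    lo: float
    hi: float
    n_models: int
    n_draws: int


def _nearest_psd(V: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(0.5 * (V + V.T))
    return (U * np.clip(w, 0.0, None)) @ U.T


def sample_coefficients(
    curve: ExposureResponseCurve, n: int = 1000, seed=None
) -> np.ndarray:
    """``n`` MVN draws of the curve's reduced coefficients, shape (n, dim).

    A covariance that fails the PSD check is projected to the nearest PSD
    matrix with a warning.  ``seed`` may be an int or a Generator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    V = 0.5 * (curve.vcov_reduced + curve.vcov_reduced.T)
    eig_min = np.linalg.eigvalsh(V).min()
    if eig_min < -1e-10 * max(1.0, np.abs(V).max()):
        warnings.warn("covariance not PSD; projecting to nearest PSD matrix")
        V = _nearest_psd(V)
    return rng.multivariate_normal(curve.coef_reduced, V, size=n, method="svd")


def ensemble_envelope(values) -> UncertaintyEnvelope:
    """Envelope over per-model value collections.

    ``values`` is a sequence per model (each an array of Monte Carlo draws,
    or a scalar when no draws were taken).  The mean averages per-model
    means; the interval takes empirical percentiles of all values pooled.
    """
    per_model = [np.atleast_1d(np.asarray(v, dtype=float)) for v in values]
    if len(per_model) < 2:
        raise ValueError("need at least two models (or values) for an envelope")
    flat = np.concatenate(per_model)
    if flat.size < 40:
        warnings.warn("fewer than 40 values; 2.5/97.5 percentiles are poorly resolved")
    mean = float(np.mean([np.mean(v) for v in per_model]))
    lo, hi = np.percentile(flat, [2.5, 97.5], method="linear")
    return UncertaintyEnvelope(
        mean=mean, lo=float(lo), hi=float(hi), n_models=len(per_model), n_draws=int(flat.size)
    )


def model_seeds(master_seed: int, n_models: int) -> list[np.random.Generator]:
    """Independent per-model RNG substreams from one master seed.

    Results are then reproducible regardless of how models are scheduled
    across workers.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n_models)]


def heat_deaths_draws(
    hsi_days: np.ndarray,
    curve: ExposureResponseCurve,
    coef_draws: np.ndarray,
    mt: float,
    pop: float,
) -> np.ndarray:
    """Annual heat deaths per coefficient draw for one cell-year.

    The heat-day filter is held at the curve's stored MMHSI across draws (no
    per-draw re-centring); each draw's log-RR uses the drawn coefficients on
    the same basis.
    """
    hsi_days = np.asarray(hsi_days, dtype=float)
    hsi_ok = hsi_days[np.isfinite(hsi_days)]
    hot = hsi_ok[hsi_ok > curve.mmhsi]
    if hot.size == 0:
        return np.zeros(coef_draws.shape[0])
    db = curve.basis(hot) - curve.basis(curve.mmhsi)  # (n_hot, dim)
    log_rr = db @ coef_draws.T  # (n_hot, n_draws)
    af = af_from_rr(np.exp(log_rr))
    return mt * pop * af.sum(axis=0)
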