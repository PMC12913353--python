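"""Closed-form probabilistic machinery of the 2D causal-inference observer.

An observer receives four pieces of evidence on a bimodal trial: numerosity
evidence ``x_V``, ``x_A`` and onset evidence ``t_V``, ``t_A``.  Under a
common cause (C=1) both modalities' evidence in a dimension derives from one
latent source; under independent causes (C=2) each modality has its own
source.  With Gaussian likelihoods and Gaussian priors every marginal
likelihood integral has a closed form:

* C=1: the evidence pair is jointly Gaussian with mean ``(mu, mu)`` and
  covariance ``[[s1^2 + sp^2, sp^2], [sp^2, s2^2 + sp^2]]`` where ``sp`` is
  the prior SD — the shared latent source induces the off-diagonal term.
* C=2: the product of two univariate Gaussians ``N(x_i; mu, s_i^2 + sp^2)``.

The causal posterior multiplies the numerosity and temporal factors (the two
dimensions are conditionally independent given C) and mixes them with the
prior probability of a common cause.  Conditional estimates are
precision-weighted means; the reported estimate is their posterior-weighted
average (model averaging), discretized to the 0/1/2 response keys.

An optional log-normal numerosity likelihood family (evidence log-normal
around the latent source) is evaluated by numerical quadrature; it has no
closed form but shares every downstream step.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np

from .params import CausalPosterior, Estimates, ModelParams, SensorySample

__all__ = [
    "numerosity_likelihoods",
    "temporal_likelihoods",
    "posterior_common_cause",
    "estimate_segregated",
    "estimate_fused",
    "estimate_model_average",
    "discretize_response",
]

_TWO_PI = 2.0 * math.pi

Family = Literal["gaussian", "lognormal"]
Denominator = Literal["joint", "factorized"]


def _norm_pdf(x, mu, var):
    return np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(_TWO_PI * var)


def _pair_likelihoods(x1, x2, var1, var2, mu, var_prior):
    """(C=1, C=2) marginal likelihoods of an evidence pair, closed Gaussian form."""
    v1 = var1 + var_prior
    v2 = var2 + var_prior
    # expanded forms (all-nonnegative terms) avoid the cancellation the
    # textbook determinant/quadratic expressions suffer for extreme variances
    det = var1 * var2 + (var1 + var2) * var_prior
    d1 = x1 - mu
    d2 = x2 - mu
    quad = (var2 * d1 * d1 + var1 * d2 * d2 + var_prior * (d1 - d2) ** 2) / det
    L_c1 = np.exp(-0.5 * quad) / (_TWO_PI * np.sqrt(det))
    L_c2 = _norm_pdf(x1, mu, v1) * _norm_pdf(x2, mu, v2)
    return L_c1, L_c2


def _check_finite(**values: float) -> None:
    for name, value in values.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# log-normal numerosity family (quadrature; no closed form)

_LN_GRID_N = 2001


def _lognormal_grid(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature grid over the positive latent numerosity and its prior weight.

    The Gaussian numerosity prior is truncated to s > 0 and renormalized,
    since a log-normal likelihood is only defined for a positive source.
    """
    hi = max(params.mu_p + 8.0 * params.sigma_p, 8.0)
    s = np.linspace(1e-6, hi, _LN_GRID_N)
    prior = _norm_pdf(s, params.mu_p, params.sigma_p**2)
    prior = prior / np.trapezoid(prior, s)
    return s, prior


def _lognormal_pdf(x, s, sigma):
    """Density of evidence x with log evidence Gaussian around log s."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(s)))
    pos = np.broadcast_to(x > 0, out.shape)
    xb = np.broadcast_to(x, out.shape)
    sb = np.broadcast_to(s, out.shape)
    out[pos] = np.exp(-0.5 * ((np.log(xb[pos]) - np.log(sb[pos])) / sigma) ** 2) / (
        xb[pos] * sigma * math.sqrt(_TWO_PI)
    )
    return out


def _lognormal_pair_likelihoods(x_V, x_A, params: ModelParams):
    s, prior = _lognormal_grid(params)
    x_V = np.asarray(x_V, dtype=float)[..., None]
    x_A = np.asarray(x_A, dtype=float)[..., None]
    pV = _lognormal_pdf(x_V, s, params.sigma_V)
    pA = _lognormal_pdf(x_A, s, params.sigma_A)
    L_c1 = np.trapezoid(pV * pA * prior, s, axis=-1)
    L_c2 = np.trapezoid(pV * prior, s, axis=-1) * np.trapezoid(pA * prior, s, axis=-1)
    return L_c1, L_c2


def _lognormal_posterior_mean(weights: np.ndarray, s: np.ndarray) -> np.ndarray:
    num = np.trapezoid(weights * s, s, axis=-1)
    den = np.trapezoid(weights, s, axis=-1)
    return num / np.where(den > 0, den, 1.0)


# ---------------------------------------------------------------------------
# public operations


def numerosity_likelihoods(
    x_V: float, x_A: float, params: ModelParams, family: Family = "gaussian"
) -> tuple[float, float]:
    """Marginal likelihoods of the numerosity evidence pair under C=1 and C=2.

    Returns ``(L_num_c1, L_num_c2)``: the common-cause likelihood integrates
    the product of both modality likelihoods against the numerosity prior
    over a single shared source; the independent-cause likelihood is the
    product of the two single-cue marginals.
    """
    _check_finite(x_V=x_V, x_A=x_A)
    if family == "lognormal":
        L1, L2 = _lognormal_pair_likelihoods(x_V, x_A, params)
        return float(L1), float(L2)
    return _pair_likelihoods(
        x_V, x_A, params.sigma_V**2, params.sigma_A**2, params.mu_p, params.sigma_p**2
    )


def temporal_likelihoods(t_V: float, t_A: float, params: ModelParams) -> tuple[float, float]:
    """Marginal likelihoods of the onset-evidence pair under C=1 and C=2 (ms)."""
    _check_finite(t_V=t_V, t_A=t_A)
    return _pair_likelihoods(
        t_V, t_A, params.sigma_Vt**2, params.sigma_At**2, params.mu_tp, params.sigma_tp**2
    )


def _posterior_p_c1(
    L_num_c1,
    L_num_c2,
    L_t_c1,
    L_t_c2,
    p_common: float,
    denominator: Denominator = "joint",
):
    """Mix likelihood factors with the common-cause prior.

    ``denominator="joint"`` is the standard Bayes normalisation over the two
    causal structures.  ``"factorized"`` reproduces a per-dimension mixture
    denominator (product of the numerosity and temporal mixture marginals);
    that form is not a normalized posterior and is clipped to [0, 1] — it is
    provided only for sensitivity analyses.
    """
    num = L_num_c1 * L_t_c1 * p_common
    if denominator == "joint":
        den = num + L_num_c2 * L_t_c2 * (1.0 - p_common)
    elif denominator == "factorized":
        den = (L_num_c1 * p_common + L_num_c2 * (1.0 - p_common)) * (
            L_t_c1 * p_common + L_t_c2 * (1.0 - p_common)
        )
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown denominator form {denominator!r}")
    with np.errstate(invalid="ignore"):
        p = np.where(den > 0, num / np.where(den > 0, den, 1.0), p_common)
    return np.clip(p, 0.0, 1.0)


def posterior_common_cause(
    sample: SensorySample,
    params: ModelParams,
    use_temporal: bool = True,
    denominator: Denominator = "joint",
    family: Family = "gaussian",
) -> CausalPosterior:
    """Posterior probability that flashes and beeps share a single cause.

    Numerosity and onset evidence are conditionally independent given the
    causal structure, so the joint likelihood of each structure is the
    product of its numerosity and temporal factors.  With
    ``use_temporal=False`` the temporal factors are set to 1, reducing the
    model to causal inference on numerosity alone.
    """
    sample.require_bimodal()
    L_num_c1, L_num_c2 = numerosity_likelihoods(sample.x_V, sample.x_A, params, family=family)
    if use_temporal:
        L_t_c1, L_t_c2 = temporal_likelihoods(sample.t_V, sample.t_A, params)
    else:
        L_t_c1 = L_t_c2 = 1.0
    p_c1 = float(
        _posterior_p_c1(L_num_c1, L_num_c2, L_t_c1, L_t_c2, params.p_common, denominator)
    )
    return CausalPosterior(
        p_c1=p_c1,
        L_num_c1=float(L_num_c1),
        L_num_c2=float(L_num_c2),
        L_t_c1=float(L_t_c1),
        L_t_c2=float(L_t_c2),
    )


def estimate_segregated(x: float, sigma: float, params: ModelParams):
    """Single-cue numerosity estimate: precision-weighted mean of cue and prior."""
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be strictly positive")
    w_x = 1.0 / np.asarray(sigma, dtype=float) ** 2
    w_p = 1.0 / params.sigma_p**2
    return (np.asarray(x) * w_x + params.mu_p * w_p) / (w_x + w_p)


def estimate_fused(x_V, x_A, params: ModelParams, include_prior: bool = True):
    """Common-cause numerosity estimate: precision-weighted mean of both cues
    and (unless ``include_prior=False``, the flat-prior cue-combination rule)
    the numerosity prior."""
    w_V = 1.0 / params.sigma_V**2
    w_A = 1.0 / params.sigma_A**2
    num = np.asarray(x_V) * w_V + np.asarray(x_A) * w_A
    den = w_V + w_A
    if include_prior:
        w_p = 1.0 / params.sigma_p**2
        num = num + params.mu_p * w_p
        den = den + w_p
    return num / den


def estimate_model_average(
    sample: SensorySample,
    params: ModelParams,
    use_temporal: bool = True,
    denominator: Denominator = "joint",
    family: Family = "gaussian",
) -> Estimates:
    """Model-averaged numerosity estimates for a bimodal trial.

    Each modality's estimate is the posterior-probability-weighted mix of
    the fused (common cause) and segregated (independent causes) conditional
    estimates, the readout that minimises expected squared error.
    """
    sample.require_bimodal()
    post = posterior_common_cause(
        sample, params, use_temporal=use_temporal, denominator=denominator, family=family
    )
    p1 = post.p_c1
    if family == "lognormal":
        s, prior = _lognormal_grid(params)
        pV = _lognormal_pdf(np.asarray(sample.x_V)[..., None], s, params.sigma_V)
        pA = _lognormal_pdf(np.asarray(sample.x_A)[..., None], s, params.sigma_A)
        fused = float(_lognormal_posterior_mean(pV * pA * prior, s))
        seg_V = float(_lognormal_posterior_mean(pV * prior, s))
        seg_A = float(_lognormal_posterior_mean(pA * prior, s))
    else:
        fused = float(estimate_fused(sample.x_V, sample.x_A, params))
        seg_V = float(estimate_segregated(sample.x_V, params.sigma_V, params))
        seg_A = float(estimate_segregated(sample.x_A, params.sigma_A, params))
    return Estimates(
        s_hat_V=p1 * fused + (1.0 - p1) * seg_V,
        s_hat_A=p1 * fused + (1.0 - p1) * seg_A,
        s_hat_fused=fused,
        s_hat_V_seg=seg_V,
        s_hat_A_seg=seg_A,
        p_c1=p1,
    )


def discretize_response(s_hat):
    """Map a continuous numerosity estimate onto the 0/1/2 response keys.

    Nearest integer, ties (x.5) rounding up, clamped to [0, 2].
    """
    arr = np.asarray(s_hat, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("estimate must be finite")
    out = np.clip(np.floor(arr + 0.5), 0.0, 2.0).astype(np.int64)
    return int(out) if np.ndim(s_hat) == 0 else out
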