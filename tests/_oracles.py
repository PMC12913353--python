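"""Independent numerical oracles for the closed-form observer-model machinery.

Everything here evaluates the defining integrals by adaptive quadrature (or
plain arithmetic re-derivation) without touching the package's closed-form
code paths, so agreement is a genuine cross-check.
"""

import math

from scipy.integrate import quad


def norm_pdf(x: float, mu: float, var: float) -> float:
    return math.exp(-((x - mu) ** 2) / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)


def _range(centers, sds) -> tuple[float, float, float]:
    """Integration window for a product of Gaussians in the latent source.

    The product is itself proportional to a single Gaussian, centred on the
    precision-weighted mean of the factors with the combined precision, so a
    window of +/- 15 combined SDs captures the mass to machine precision.
    """
    weights = [1.0 / sd**2 for sd in sds]
    mean = sum(w * c for w, c in zip(weights, centers)) / sum(weights)
    sd_combined = math.sqrt(1.0 / sum(weights))
    return mean - 15.0 * sd_combined, mean + 15.0 * sd_combined, mean


def pair_likelihood_c1_quad(x1, x2, sd1, sd2, mu, sd_prior) -> float:
    """Common-cause marginal: integrate the three-Gaussian product over the source."""
    lo, hi, mid = _range([x1, x2, mu], [sd1, sd2, sd_prior])
    val, _ = quad(
        lambda s: norm_pdf(x1, s, sd1**2) * norm_pdf(x2, s, sd2**2) * norm_pdf(s, mu, sd_prior**2),
        lo,
        hi,
        epsabs=1e-13,
        epsrel=1e-11,
        limit=300,
        points=[mid],
    )
    return val


def single_cue_likelihood_quad(x, sd, mu, sd_prior) -> float:
    lo, hi, mid = _range([x, mu], [sd, sd_prior])
    val, _ = quad(
        lambda s: norm_pdf(x, s, sd**2) * norm_pdf(s, mu, sd_prior**2),
        lo,
        hi,
        epsabs=1e-13,
        epsrel=1e-11,
        limit=300,
        points=[mid],
    )
    return val


def pair_likelihood_c2_quad(x1, x2, sd1, sd2, mu, sd_prior) -> float:
    """Independent-cause marginal: product of two single-cue integrals."""
    return single_cue_likelihood_quad(x1, sd1, mu, sd_prior) * single_cue_likelihood_quad(
        x2, sd2, mu, sd_prior
    )


def posterior_c1_quad(x_V, x_A, t_V, t_A, params, use_temporal=True) -> float:
    """Causal posterior composed entirely from quadrature likelihoods."""
    L1n = pair_likelihood_c1_quad(x_V, x_A, params.sigma_V, params.sigma_A, params.mu_p, params.sigma_p)
    L2n = pair_likelihood_c2_quad(x_V, x_A, params.sigma_V, params.sigma_A, params.mu_p, params.sigma_p)
    if use_temporal:
        L1t = pair_likelihood_c1_quad(
            t_V, t_A, params.sigma_Vt, params.sigma_At, params.mu_tp, params.sigma_tp
        )
        L2t = pair_likelihood_c2_quad(
            t_V, t_A, params.sigma_Vt, params.sigma_At, params.mu_tp, params.sigma_tp
        )
    else:
        L1t = L2t = 1.0
    num = L1n * L1t * params.p_common
    den = num + L2n * L2t * (1.0 - params.p_common)
    return num / den


def segregated_estimate_arith(x, sd, mu_p, sd_p) -> float:
    """Direct re-derivation of the single-cue precision-weighted mean."""
    return (x / sd**2 + mu_p / sd_p**2) / (1.0 / sd**2 + 1.0 / sd_p**2)


def fused_estimate_arith(x_V, x_A, sd_V, sd_A, mu_p, sd_p) -> float:
    num = x_V / sd_V**2 + x_A / sd_A**2 + mu_p / sd_p**2
    den = 1.0 / sd_V**2 + 1.0 / sd_A**2 + 1.0 / sd_p**2
    return num / den
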