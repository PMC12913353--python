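"""Monte Carlo simulation of flash-beep trials from a parameterized observer.

A trial presents 0-2 flashes and 0-2 beeps; on bimodal trials the two
streams start at a stimulus-onset asynchrony (SOA) of 0, 150, 300 or 500 ms,
with the leading modality given by an explicit ``lead`` convention.  The
generative model draws numerosity evidence around the true counts and onset
evidence around the true first-stimulus onsets, runs causal inference and
model averaging, and discretizes the continuous estimates onto the 0/1/2
response keys.  A vectorized batch path (`simulate_batch`) evaluates whole
conditions at once and underlies both dataset generation and the Monte
Carlo response likelihood used in fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import core
from .params import ModelParams, SensorySample

__all__ = [
    "TrialCondition",
    "ResponseDistribution",
    "SOA_LEVELS",
    "VISUAL_FIRST",
    "AUDITORY_FIRST",
    "true_onsets",
    "sample_sensory",
    "simulate_trial",
    "simulate_batch",
    "BatchSimulator",
    "response_distribution",
]

SOA_LEVELS = (0, 150, 300, 500)
VISUAL_FIRST = "visual_first"
AUDITORY_FIRST = "auditory_first"
_LEADS = (VISUAL_FIRST, AUDITORY_FIRST)


@dataclass(frozen=True)
class TrialCondition:
    """Physical stimulus of one condition: counts, SOA and lead convention."""

    n_flashes: int
    n_beeps: int
    soa: int = 0
    lead: str = VISUAL_FIRST

    def __post_init__(self) -> None:
        if self.n_flashes not in (0, 1, 2) or self.n_beeps not in (0, 1, 2):
            raise ValueError("flash and beep counts must be 0, 1 or 2")
        if self.n_flashes + self.n_beeps < 1:
            raise ValueError("a condition must present at least one stimulus")
        if self.soa not in SOA_LEVELS:
            raise ValueError(f"soa must be one of {SOA_LEVELS}, got {self.soa!r}")
        if self.lead not in _LEADS:
            raise ValueError(f"lead must be one of {_LEADS}, got {self.lead!r}")
        if not self.is_bimodal and self.soa != 0:
            raise ValueError("unisensory conditions must carry soa = 0")

    @property
    def is_bimodal(self) -> bool:
        return self.n_flashes >= 1 and self.n_beeps >= 1

    def label(self) -> str:
        if self.is_bimodal:
            return f"{self.n_flashes}F{self.n_beeps}B_soa{self.soa}"
        return f"{self.n_flashes}F" if self.n_flashes else f"{self.n_beeps}B"


@dataclass(frozen=True)
class ResponseDistribution:
    """Empirical response distribution of one condition.

    ``table`` is a (3, 3) joint probability array over (flash report, beep
    report) for bimodal conditions, or a length-3 vector for unisensory
    conditions.  Entries are non-negative and sum to 1.
    """

    condition: TrialCondition
    table: np.ndarray
    n_mc: int
    seed: int | None = None

    def marginal(self, modality: str) -> np.ndarray:
        """Marginal report distribution for ``"visual"`` or ``"auditory"``."""
        if not self.condition.is_bimodal:
            return self.table
        return self.table.sum(axis=1) if modality == "visual" else self.table.sum(axis=0)


def true_onsets(condition: TrialCondition) -> tuple[float, float]:
    """True first-stimulus onsets (visual, auditory) in ms; leading stream at 0."""
    if not condition.is_bimodal:
        raise ValueError("true_onsets is defined only for bimodal conditions")
    if condition.lead == VISUAL_FIRST:
        return 0.0, float(condition.soa)
    return float(condition.soa), 0.0


def sample_sensory(
    condition: TrialCondition, params: ModelParams, rng: np.random.Generator
) -> SensorySample:
    """Draw one trial's internal evidence (independent Gaussian noise)."""
    has_V = condition.n_flashes >= 1
    has_A = condition.n_beeps >= 1
    if condition.is_bimodal:
        s_Vt, s_At = true_onsets(condition)
    else:
        s_Vt = s_At = 0.0
    x_V = t_V = x_A = t_A = np.nan
    if has_V:
        x_V = float(rng.normal(condition.n_flashes, params.sigma_V))
        t_V = float(rng.normal(s_Vt, params.sigma_Vt))
    if has_A:
        x_A = float(rng.normal(condition.n_beeps, params.sigma_A))
        t_A = float(rng.normal(s_At, params.sigma_At))
    return SensorySample(x_V=x_V, x_A=x_A, t_V=t_V, t_A=t_A, has_V=has_V, has_A=has_A)


def simulate_trial(
    condition: TrialCondition,
    params: ModelParams,
    rng: np.random.Generator,
    use_temporal: bool = True,
    force_fusion: bool = False,
    flat_prior: bool = False,
    family: core.Family = "gaussian",
) -> tuple[int | None, int | None]:
    """Simulate one trial: sensory sample -> inference -> (flash, beep) reports.

    Unisensory trials bypass causal inference and read out the single-cue
    estimate of the present modality; the absent modality's report is None.
    """
    sample = sample_sensory(condition, params, rng)
    if condition.is_bimodal:
        if flat_prior:
            s = float(core.estimate_fused(sample.x_V, sample.x_A, params, include_prior=False))
            est_V = est_A = s
        elif force_fusion:
            s = float(core.estimate_fused(sample.x_V, sample.x_A, params))
            est_V = est_A = s
        else:
            est = core.estimate_model_average(
                sample, params, use_temporal=use_temporal, family=family
            )
            est_V, est_A = est.s_hat_V, est.s_hat_A
        return core.discretize_response(est_V), core.discretize_response(est_A)
    if sample.has_V:
        est = sample.x_V if flat_prior else float(
            core.estimate_segregated(sample.x_V, params.sigma_V, params)
        )
        return core.discretize_response(est), None
    est = sample.x_A if flat_prior else float(
        core.estimate_segregated(sample.x_A, params.sigma_A, params)
    )
    return None, core.discretize_response(est)


# ---------------------------------------------------------------------------
# vectorized batch engine


def _logit(p: float) -> float:
    if p >= 1.0:
        return np.inf
    if p <= 0.0:
        return -np.inf
    return math.log(p / (1.0 - p))


def _log_likelihood_ratio(x1, x2, var1, var2, mu, var_prior):
    """log L(C=1) - log L(C=2) for a Gaussian evidence pair (no exp calls)."""
    v1 = var1 + var_prior
    v2 = var2 + var_prior
    # expanded, cancellation-free determinant and quadratic forms
    det = var1 * var2 + (var1 + var2) * var_prior
    d1 = x1 - mu
    d2 = x2 - mu
    quad_c1 = (var2 * d1 * d1 + var1 * d2 * d2 + var_prior * (d1 - d2) ** 2) / det
    quad_c2 = d1 * d1 / v1 + d2 * d2 / v2
    return 0.5 * (quad_c2 - quad_c1) + 0.5 * math.log(v1 * v2 / det)


class BatchSimulator:
    """Vectorized response simulation over a fixed condition set and noise draws.

    Precomputes per-condition constants and splits the standard-normal draw
    block ``z`` (shape ``(n_conditions, n, 4)``) into bimodal and unisensory
    groups once; `responses`/`tables` then evaluate any parameter values on
    the same draws.  Reusing one BatchSimulator across parameter proposals
    implements common random numbers, making Monte Carlo response
    probabilities deterministic, optimizer-safe functions of the parameters.
    """

    def __init__(self, conditions: Sequence[TrialCondition], z: np.ndarray) -> None:
        self.conditions = list(conditions)
        if z.ndim != 3 or z.shape[0] != len(self.conditions) or z.shape[2] != 4:
            raise ValueError("z must have shape (n_conditions, n, 4)")
        self.n = z.shape[1]
        self._bi = [i for i, c in enumerate(self.conditions) if c.is_bimodal]
        self._uni = [i for i, c in enumerate(self.conditions) if not c.is_bimodal]
        if self._bi:
            conds = [self.conditions[i] for i in self._bi]
            self._zb = np.ascontiguousarray(z[self._bi])
            self._nF = np.array([[c.n_flashes] for c in conds], dtype=float)
            self._nB = np.array([[c.n_beeps] for c in conds], dtype=float)
            onsets = np.array([true_onsets(c) for c in conds], dtype=float)
            self._sVt = onsets[:, :1]
            self._sAt = onsets[:, 1:]
        if self._uni:
            conds = [self.conditions[i] for i in self._uni]
            self._uni_visual = np.array([c.n_flashes >= 1 for c in conds])
            self._uni_count = np.array(
                [[max(c.n_flashes, c.n_beeps)] for c in conds], dtype=float
            )
            zu = z[self._uni]
            # visual-present rows consume the x_V column, auditory rows x_A
            self._zu = np.where(self._uni_visual[:, None], zu[:, :, 0], zu[:, :, 1])

    def _bimodal(
        self,
        params: ModelParams,
        use_temporal: bool,
        force_fusion: bool,
        flat_prior: bool,
    ) -> tuple[np.ndarray, np.ndarray]:
        z = self._zb
        x_V = self._nF + params.sigma_V * z[:, :, 0]
        x_A = self._nB + params.sigma_A * z[:, :, 1]
        w_V = 1.0 / params.sigma_V**2
        w_A = 1.0 / params.sigma_A**2
        if flat_prior:
            est = (x_V * w_V + x_A * w_A) / (w_V + w_A)
            return _clip_round(est), _clip_round(est)
        w_p = 1.0 / params.sigma_p**2
        fused = (x_V * w_V + x_A * w_A + params.mu_p * w_p) / (w_V + w_A + w_p)
        if force_fusion:
            return _clip_round(fused), _clip_round(fused)
        llr = _log_likelihood_ratio(
            x_V, x_A, params.sigma_V**2, params.sigma_A**2, params.mu_p, params.sigma_p**2
        )
        if use_temporal:
            t_V = self._sVt + params.sigma_Vt * z[:, :, 2]
            t_A = self._sAt + params.sigma_At * z[:, :, 3]
            llr = llr + _log_likelihood_ratio(
                t_V, t_A, params.sigma_Vt**2, params.sigma_At**2,
                params.mu_tp, params.sigma_tp**2,
            )
        p1 = _expit(_logit(params.p_common) + llr)
        seg_V = (x_V * w_V + params.mu_p * w_p) / (w_V + w_p)
        seg_A = (x_A * w_A + params.mu_p * w_p) / (w_A + w_p)
        est_V = p1 * fused + (1.0 - p1) * seg_V
        est_A = p1 * fused + (1.0 - p1) * seg_A
        return _clip_round(est_V), _clip_round(est_A)

    def _unisensory(self, params: ModelParams, flat_prior: bool) -> np.ndarray:
        sigma = np.where(self._uni_visual[:, None], params.sigma_V, params.sigma_A)
        x = self._uni_count + sigma * self._zu
        if flat_prior:
            return _clip_round(x)
        w_x = 1.0 / sigma**2
        w_p = 1.0 / params.sigma_p**2
        return _clip_round((x * w_x + params.mu_p * w_p) / (w_x + w_p))

    def responses(
        self,
        params: ModelParams,
        use_temporal: bool = True,
        force_fusion: bool = False,
        flat_prior: bool = False,
    ) -> list[tuple[np.ndarray | None, np.ndarray | None]]:
        """Per-condition (flash, beep) response arrays; None for absent modalities."""
        out: list = [None] * len(self.conditions)
        if self._bi:
            r_V, r_A = self._bimodal(params, use_temporal, force_fusion, flat_prior)
            for row, i in enumerate(self._bi):
                out[i] = (r_V[row], r_A[row])
        if self._uni:
            r = self._unisensory(params, flat_prior)
            for row, i in enumerate(self._uni):
                out[i] = (r[row], None) if self._uni_visual[row] else (None, r[row])
        return out

    def tables(
        self,
        params: ModelParams,
        use_temporal: bool = True,
        force_fusion: bool = False,
        flat_prior: bool = False,
    ) -> list[np.ndarray]:
        """Per-condition response-probability tables (3x3 joint or length-3)."""
        out: list = [None] * len(self.conditions)
        if self._bi:
            r_V, r_A = self._bimodal(params, use_temporal, force_fusion, flat_prior)
            flat = (3 * r_V + r_A) + 9 * np.arange(len(self._bi))[:, None]
            counts = np.bincount(flat.ravel(), minlength=9 * len(self._bi))
            counts = counts.reshape(len(self._bi), 3, 3) / self.n
            for row, i in enumerate(self._bi):
                out[i] = counts[row]
        if self._uni:
            r = self._unisensory(params, flat_prior)
            flat = r + 3 * np.arange(len(self._uni))[:, None]
            counts = np.bincount(flat.ravel(), minlength=3 * len(self._uni))
            counts = counts.reshape(len(self._uni), 3) / self.n
            for row, i in enumerate(self._uni):
                out[i] = counts[row]
        return out


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _clip_round(est: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(est + 0.5), 0.0, 2.0).astype(np.int64)


def _batch_responses(
    condition: TrialCondition,
    params: ModelParams,
    z: np.ndarray,
    use_temporal: bool,
    force_fusion: bool,
    flat_prior: bool,
    family: core.Family,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Responses for n standard-normal draws ``z`` of shape (n, 4).

    Columns of ``z`` feed (x_V, x_A, t_V, t_A); reusing a fixed ``z`` across
    parameter values yields common random numbers, making the Monte Carlo
    response probabilities a deterministic function of the parameters.
    """
    if condition.is_bimodal:
        x_V = condition.n_flashes + params.sigma_V * z[:, 0]
        x_A = condition.n_beeps + params.sigma_A * z[:, 1]
        if flat_prior:
            est_V = est_A = core.estimate_fused(x_V, x_A, params, include_prior=False)
        elif force_fusion:
            est_V = est_A = core.estimate_fused(x_V, x_A, params)
        else:
            if family == "lognormal":
                x_V = condition.n_flashes * np.exp(params.sigma_V * z[:, 0])
                x_A = condition.n_beeps * np.exp(params.sigma_A * z[:, 1])
                L1n, L2n = core._lognormal_pair_likelihoods(x_V, x_A, params)
                s, prior = core._lognormal_grid(params)
                pV = core._lognormal_pdf(x_V[:, None], s, params.sigma_V)
                pA = core._lognormal_pdf(x_A[:, None], s, params.sigma_A)
                fused = core._lognormal_posterior_mean(pV * pA * prior, s)
                seg_V = core._lognormal_posterior_mean(pV * prior, s)
                seg_A = core._lognormal_posterior_mean(pA * prior, s)
            else:
                L1n, L2n = core._pair_likelihoods(
                    x_V, x_A, params.sigma_V**2, params.sigma_A**2, params.mu_p, params.sigma_p**2
                )
                fused = core.estimate_fused(x_V, x_A, params)
                seg_V = core.estimate_segregated(x_V, params.sigma_V, params)
                seg_A = core.estimate_segregated(x_A, params.sigma_A, params)
            if use_temporal:
                s_Vt, s_At = true_onsets(condition)
                t_V = s_Vt + params.sigma_Vt * z[:, 2]
                t_A = s_At + params.sigma_At * z[:, 3]
                L1t, L2t = core._pair_likelihoods(
                    t_V, t_A, params.sigma_Vt**2, params.sigma_At**2,
                    params.mu_tp, params.sigma_tp**2,
                )
            else:
                L1t = L2t = 1.0
            p1 = core._posterior_p_c1(L1n, L2n, L1t, L2t, params.p_common)
            est_V = p1 * fused + (1.0 - p1) * seg_V
            est_A = p1 * fused + (1.0 - p1) * seg_A
        return core.discretize_response(est_V), core.discretize_response(est_A)
    # unisensory: single-cue readout for the present modality
    if condition.n_flashes >= 1:
        x_V = condition.n_flashes + params.sigma_V * z[:, 0]
        est = x_V if flat_prior else core.estimate_segregated(x_V, params.sigma_V, params)
        return core.discretize_response(est), None
    x_A = condition.n_beeps + params.sigma_A * z[:, 1]
    est = x_A if flat_prior else core.estimate_segregated(x_A, params.sigma_A, params)
    return None, core.discretize_response(est)


def _tabulate(resp_V: np.ndarray | None, resp_A: np.ndarray | None) -> np.ndarray:
    if resp_V is not None and resp_A is not None:
        counts = np.bincount(3 * resp_V + resp_A, minlength=9).reshape(3, 3)
    else:
        counts = np.bincount(resp_V if resp_V is not None else resp_A, minlength=3)
    return counts / counts.sum()


def simulate_batch(
    conditions: Sequence[TrialCondition],
    params: ModelParams,
    z: np.ndarray,
    use_temporal: bool = True,
    force_fusion: bool = False,
    flat_prior: bool = False,
    family: core.Family = "gaussian",
) -> list[tuple[np.ndarray | None, np.ndarray | None]]:
    """Vectorized responses per condition for pre-drawn standard normals.

    ``z`` has shape (n_conditions, n, 4).  Returns per-condition response
    arrays ``(resp_V, resp_A)`` with None for absent modalities.
    """
    if family == "gaussian":
        return BatchSimulator(conditions, z).responses(
            params, use_temporal=use_temporal, force_fusion=force_fusion, flat_prior=flat_prior
        )
    # the log-normal family needs per-sample quadrature; use the plain path
    return [
        _batch_responses(c, params, z[i], use_temporal, force_fusion, flat_prior, family)
        for i, c in enumerate(conditions)
    ]


def response_distribution(
    condition: TrialCondition,
    params: ModelParams,
    n_mc: int,
    seed: int | np.random.Generator | None = None,
    use_temporal: bool = True,
    force_fusion: bool = False,
    flat_prior: bool = False,
    family: core.Family = "gaussian",
) -> ResponseDistribution:
    """Monte Carlo response distribution of one condition (deterministic per seed)."""
    if n_mc < 1:
        raise ValueError("n_mc must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, 4))
    resp_V, resp_A = _batch_responses(
        condition, params, z, use_temporal, force_fusion, flat_prior, family
    )
    return ResponseDistribution(
        condition=condition,
        table=_tabulate(resp_V, resp_A),
        n_mc=n_mc,
        seed=seed if isinstance(seed, int) else None,
    )
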