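"""Response likelihood, maximum-likelihood fitting and goodness of fit.

Discrete (flash report, beep report) pairs enter the likelihood as a
multinomial over the 3x3 joint response cells of each bimodal condition (3
cells for unisensory conditions).  Cell probabilities are approximated by
Monte Carlo simulation of the observer model with common random numbers:
one fixed block of standard-normal draws is reused for every parameter
proposal, so the simulated likelihood surface is a deterministic function
of the parameters and safe to hand to a derivative-free optimizer.  Cell
probabilities are floored at a small epsilon and renormalized, which guards
log(0) and acts as a minimal lapse allowance.

Fitting maximizes the log-likelihood over the variant's free parameters by
Nelder-Mead simplex search in a transformed space (log-scale logistic for
SDs, logistic for p_common and mu_p, all within bounds), restarted from
Latin-hypercube starting points.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc
from scipy.special import expit, logit

from .design import ObserverDataset, build_design
from .params import FIXED_TEMPORAL, ModelParams
from .simulate import BatchSimulator, ResponseDistribution, TrialCondition
from .variants import ModelVariant, _resolve, apply_variant, bic

__all__ = [
    "FitConfig",
    "FitResult",
    "predict_response_probs",
    "log_likelihood",
    "fit_mle",
    "goodness_of_fit_r2",
    "DEFAULT_BOUNDS",
]

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "sigma_V": (0.05, 5.0),
    "sigma_A": (0.05, 5.0),
    "p_common": (0.01, 0.99),
    "sigma_p": (0.1, 10.0),
    "mu_p": (0.0, 3.0),
}

_LOG_SCALE = {"sigma_V", "sigma_A", "sigma_p"}


@dataclass
class FitConfig:
    """Settings for maximum-likelihood fitting.

    ``n_mc`` Monte Carlo draws per condition per likelihood evaluation;
    ``restarts`` independent Nelder-Mead starts (first from the centre of
    the bounded box, the rest Latin-hypercube); ``eps`` the per-cell
    probability floor; ``maxfev`` function-evaluation cap per restart.
    """

    n_mc: int = 10_000
    restarts: int = 10
    seed: int = 0
    eps: float = 1e-4
    maxfev: int = 500
    xatol: float = 0.02
    fatol: float = 0.02
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fixed_temporal: Mapping[str, float] = field(default_factory=lambda: dict(FIXED_TEMPORAL))

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        """Load settings from a flat JSON or TOML file (unknown keys rejected)."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown fit-config keys: {sorted(unknown)}")
        if "bounds" in raw:
            raw["bounds"] = {k: tuple(v) for k, v in raw["bounds"].items()}
        return cls(**raw)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    variant: str
    params_free: dict[str, float]
    fixed_temporal: dict[str, float]
    params: ModelParams
    loglik: float
    bic: float
    r_squared: float
    n_trials: int
    k: int
    restarts: int
    converged: bool
    seed: int
    n_mc: int

    def to_dict(self) -> dict:
        out = {
            "variant": self.variant,
            "loglik": self.loglik,
            "bic": self.bic,
            "r_squared": self.r_squared,
            "n_trials": self.n_trials,
            "k": self.k,
            "restarts": self.restarts,
            "converged": self.converged,
            "seed": self.seed,
            "n_mc": self.n_mc,
        }
        out.update({f"est_{k}": v for k, v in self.params_free.items()})
        out.update({f"fixed_{k}": v for k, v in self.fixed_temporal.items()})
        return out


# ---------------------------------------------------------------------------
# parameter transforms (unconstrained optimizer space <-> bounded natural space)


def _to_natural(u: np.ndarray, names: Sequence[str], bounds: Mapping) -> dict[str, float]:
    out = {}
    for ui, name in zip(u, names):
        lo, hi = bounds[name]
        if name in _LOG_SCALE:
            g = math.log(lo) + (math.log(hi) - math.log(lo)) * expit(ui)
            out[name] = math.exp(g)
        else:
            out[name] = lo + (hi - lo) * expit(ui)
    return out


def _to_unconstrained(values: Mapping[str, float], names: Sequence[str], bounds: Mapping) -> np.ndarray:
    u = np.empty(len(names))
    for i, name in enumerate(names):
        lo, hi = bounds[name]
        v = float(values[name])
        if name in _LOG_SCALE:
            frac = (math.log(v) - math.log(lo)) / (math.log(hi) - math.log(lo))
        else:
            frac = (v - lo) / (hi - lo)
        u[i] = logit(np.clip(frac, 1e-9, 1.0 - 1e-9))
    return u


# ---------------------------------------------------------------------------
# dataset aggregation and predicted tables


def _aggregate_counts(
    dataset: ObserverDataset,
) -> tuple[list[TrialCondition], list[np.ndarray]]:
    """Collapse trials into per-condition response-cell count tables."""
    if dataset.n_trials == 0:
        raise ValueError("dataset is empty")
    lead = dataset.trials["lead"].iloc[0]
    registered = set(build_design(lead=lead, reps=1, seed=None).conditions)
    conditions = dataset.conditions()
    for cond in conditions:
        if cond not in registered:
            raise ValueError(f"condition {cond} is not part of the registered design")
    index = {c: i for i, c in enumerate(conditions)}
    counts = [
        np.zeros((3, 3)) if c.is_bimodal else np.zeros(3) for c in conditions
    ]
    for row in dataset.trials.itertuples(index=False):
        cond = TrialCondition(int(row.n_flashes), int(row.n_beeps), int(row.soa_ms), row.lead)
        tab = counts[index[cond]]
        if cond.is_bimodal:
            tab[int(row.resp_flashes), int(row.resp_beeps)] += 1
        elif cond.n_flashes >= 1:
            tab[int(row.resp_flashes)] += 1
        else:
            tab[int(row.resp_beeps)] += 1
    return conditions, counts


def _floor(table: np.ndarray, eps: float) -> np.ndarray:
    p = np.maximum(table, eps)
    return p / p.sum()


def _predicted_tables(
    sim: BatchSimulator,
    params: ModelParams,
    variant: ModelVariant,
    eps: float,
) -> list[np.ndarray]:
    tables = sim.tables(
        params,
        use_temporal=variant.use_temporal,
        force_fusion=variant.force_fusion,
        flat_prior=variant.flat_prior,
    )
    return [_floor(t, eps) for t in tables]


def _draw_z(n_conditions: int, n_mc: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).standard_normal((n_conditions, n_mc, 4))


def predict_response_probs(
    params: ModelParams,
    design: Sequence[TrialCondition],
    variant: "str | ModelVariant" = "bci_2d",
    n_mc: int = 10_000,
    seed: int = 0,
    eps: float = 1e-4,
) -> dict[TrialCondition, ResponseDistribution]:
    """Monte Carlo response probabilities per condition, floored and renormalized.

    Deterministic given ``seed``: the same standard-normal draws are reused
    for any parameter values (common random numbers).
    """
    design = list(design)
    if not design:
        raise ValueError("design must contain at least one condition")
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000 for a usable likelihood")
    v = _resolve(variant)
    sim = BatchSimulator(design, _draw_z(len(design), n_mc, seed))
    tables = _predicted_tables(sim, params, v, eps)
    return {
        cond: ResponseDistribution(condition=cond, table=tab, n_mc=n_mc, seed=seed)
        for cond, tab in zip(design, tables)
    }


def log_likelihood(
    dataset: ObserverDataset,
    params: ModelParams,
    variant: "str | ModelVariant" = "bci_2d",
    n_mc: int = 10_000,
    seed: int = 0,
    eps: float = 1e-4,
) -> float:
    """Multinomial log-likelihood of the observed reports under the model."""
    v = _resolve(variant)
    conditions, counts = _aggregate_counts(dataset)
    sim = BatchSimulator(conditions, _draw_z(len(conditions), n_mc, seed))
    tables = _predicted_tables(sim, params, v, eps)
    return float(
        sum(np.sum(c * np.log(t)) for c, t in zip(counts, tables))
    )


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _start_points(
    names: Sequence[str], bounds: Mapping, restarts: int, seed: int
) -> np.ndarray:
    """Centre-of-box start plus Latin-hypercube starts, in unconstrained space."""
    k = len(names)
    fracs = [np.full(k, 0.5)]
    if restarts > 1:
        sampler = qmc.LatinHypercube(d=k, seed=seed)
        fracs.extend(0.05 + 0.9 * sampler.random(restarts - 1))
    starts = np.empty((restarts, k))
    for r, frac in enumerate(fracs):
        starts[r] = logit(frac)
    return starts


def fit_mle(
    dataset: ObserverDataset,
    variant: "str | ModelVariant" = "bci_2d",
    config: FitConfig | None = None,
) -> FitResult:
    """Maximum-likelihood estimate of a variant's free parameters.

    Temporal parameters stay fixed at ``config.fixed_temporal``.  The search
    runs ``config.restarts`` Nelder-Mead restarts in transformed space and
    returns the best; non-convergence of every restart is reported through
    ``converged=False``, never silently.
    """
    config = config or FitConfig()
    v = _resolve(variant)
    conditions, counts = _aggregate_counts(dataset)
    n_trials = int(sum(c.sum() for c in counts))
    sim = BatchSimulator(conditions, _draw_z(len(conditions), config.n_mc, config.seed))
    names = v.free_names
    fixed = dict(config.fixed_temporal)

    def negloglik(u: np.ndarray) -> float:
        free = _to_natural(u, names, config.bounds)
        params, _ = apply_variant(v, free, fixed_temporal=fixed)
        tables = _predicted_tables(sim, params, v, config.eps)
        return -float(sum(np.sum(c * np.log(t)) for c, t in zip(counts, tables)))

    best = None
    converged = False
    for u0 in _start_points(names, config.bounds, config.restarts, config.seed):
        # explicit initial simplex: the default one collapses near zero
        # coordinates (logit of mid-range values), stalling the search
        simplex = np.vstack([u0, u0 + 0.4 * np.eye(len(u0))])
        res = optimize.minimize(
            negloglik,
            u0,
            method="Nelder-Mead",
            options={
                "maxfev": config.maxfev,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "initial_simplex": simplex,
            },
        )
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    free_hat = _to_natural(best.x, names, config.bounds)
    params_hat, _ = apply_variant(v, free_hat, fixed_temporal=fixed)
    loglik = -float(best.fun)
    tables = _predicted_tables(sim, params_hat, v, config.eps)
    predictions = {
        cond: ResponseDistribution(cond, tab, config.n_mc, config.seed)
        for cond, tab in zip(conditions, tables)
    }
    r2 = goodness_of_fit_r2(dataset, predictions)
    return FitResult(
        variant=v.name,
        params_free={k: float(val) for k, val in free_hat.items()},
        fixed_temporal=fixed,
        params=params_hat,
        loglik=loglik,
        bic=bic(loglik, v.k, n_trials),
        r_squared=r2,
        n_trials=n_trials,
        k=v.k,
        restarts=config.restarts,
        converged=converged,
        seed=config.seed,
        n_mc=config.n_mc,
    )


def _proportion_vectors(
    dataset: ObserverDataset,
    predictions: Mapping[TrialCondition, "ResponseDistribution | np.ndarray"],
) -> tuple[np.ndarray, np.ndarray]:
    conditions, counts = _aggregate_counts(dataset)
    obs, pred = [], []
    for cond, cnt in zip(conditions, counts):
        if cond not in predictions:
            raise ValueError(f"predictions missing condition {cond}")
        table = predictions[cond]
        if isinstance(table, ResponseDistribution):
            table = table.table
        table = np.asarray(table)
        n = cnt.sum()
        if cond.is_bimodal:
            obs.extend(cnt.sum(axis=1) / n)  # flash-report categories
            pred.extend(table.sum(axis=1))
            obs.extend(cnt.sum(axis=0) / n)  # beep-report categories
            pred.extend(table.sum(axis=0))
        else:
            obs.extend(cnt / n)
            pred.extend(table)
    return np.asarray(obs), np.asarray(pred)


def goodness_of_fit_r2(
    dataset: ObserverDataset,
    predictions: Mapping[TrialCondition, "ResponseDistribution | np.ndarray"],
) -> float:
    """Variance explained, 1 - SS_res/SS_tot, over response-proportion vectors.

    The vector stacks, for every condition and present modality, the
    observed proportion of each response category (0, 1, 2) against the
    model-predicted probability; SS_tot is taken about the grand mean of the
    observed proportions.
    """
    obs, pred = _proportion_vectors(dataset, predictions)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return 1.0 - ss_res / ss_tot
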