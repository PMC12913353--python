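"""The four nested observer-model variants and BIC-based model comparison.

* ``bci_2d`` — full causal inference on numerosity and timing (5 free
  parameters: sigma_V, sigma_A, p_common, sigma_p, mu_p).
* ``bci_1d`` — causal inference on numerosity only; all temporal likelihood
  factors are 1 (same 5 free parameters).
* ``forced_fusion`` — the causal posterior is pinned at 1, so cues are always
  integrated with the numerosity prior (4 free parameters).
* ``mle_flat`` — forced fusion with an uninformative (flat) numerosity
  prior: pure precision-weighted cue combination (2 free parameters:
  sigma_V, sigma_A).

Lower BIC (= k ln n - 2 log L) indicates the better-supported model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import FIXED_TEMPORAL, ModelParams

__all__ = ["ModelVariant", "VARIANTS", "apply_variant", "bic", "compare_models", "ComparisonTable"]


@dataclass(frozen=True)
class ModelVariant:
    """A named observer-model variant: free parameters plus evaluation flags."""

    name: str
    free_names: tuple[str, ...]
    use_temporal: bool = True
    force_fusion: bool = False
    flat_prior: bool = False
    description: str = ""

    @property
    def k(self) -> int:
        """Number of free parameters (the k entering BIC)."""
        return len(self.free_names)


_FULL_FREE = ("sigma_V", "sigma_A", "p_common", "sigma_p", "mu_p")

VARIANTS: dict[str, ModelVariant] = {
    "bci_2d": ModelVariant(
        "bci_2d", _FULL_FREE,
        description="causal inference over numerosity and timing",
    ),
    "bci_1d": ModelVariant(
        "bci_1d", _FULL_FREE, use_temporal=False,
        description="causal inference over numerosity only",
    ),
    "forced_fusion": ModelVariant(
        "forced_fusion", ("sigma_V", "sigma_A", "sigma_p", "mu_p"), force_fusion=True,
        description="always integrates (common cause assumed)",
    ),
    "mle_flat": ModelVariant(
        "mle_flat", ("sigma_V", "sigma_A"), force_fusion=True, flat_prior=True,
        description="precision-weighted cue combination, flat numerosity prior",
    ),
}


def _resolve(variant: "str | ModelVariant") -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}") from None


def apply_variant(
    variant: "str | ModelVariant",
    free_params: "Mapping[str, float] | Sequence[float]",
    fixed_temporal: Mapping[str, float] | None = None,
) -> tuple[ModelParams, ModelVariant]:
    """Build full ModelParams from a variant's free-parameter values.

    ``free_params`` may be a mapping or a sequence ordered as the variant's
    ``free_names``.  Parameters the variant does not free are filled with
    neutral values: forced fusion pins the causal posterior at 1 (p_common
    irrelevant to evaluation but stored as 1), and the flat-prior variant
    drops the numerosity prior from the estimate (mu_p/sigma_p placeholders
    are never used).
    """
    v = _resolve(variant)
    if not isinstance(free_params, Mapping):
        values = list(free_params)
        if len(values) != v.k:
            raise ValueError(f"variant {v.name!r} expects {v.k} free parameters, got {len(values)}")
        free_params = dict(zip(v.free_names, values))
    extra = set(free_params) - set(v.free_names)
    missing = set(v.free_names) - set(free_params)
    if extra or missing:
        raise ValueError(
            f"variant {v.name!r} frees {list(v.free_names)}; "
            f"missing={sorted(missing)} unexpected={sorted(extra)}"
        )
    filled = dict(free_params)
    if v.force_fusion:
        filled.setdefault("p_common", 1.0)
    if v.flat_prior:
        filled.setdefault("mu_p", 0.0)
        filled.setdefault("sigma_p", 1.0)
    params = ModelParams(**filled, **dict(fixed_temporal or FIXED_TEMPORAL))
    return params, v


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, k ln(n) - 2 log-likelihood."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if k < 0:
        raise ValueError("k must be non-negative")
    return k * math.log(n) - 2.0 * loglik


@dataclass
class ComparisonTable:
    """Per-observer, per-variant fit table with group summary and paired tests."""

    rows: pd.DataFrame
    summary: pd.DataFrame
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def compare_models(
    datasets: Sequence,
    variants: Sequence[str] = ("bci_2d", "bci_1d", "forced_fusion", "mle_flat"),
    config=None,
    reference: str = "bci_2d",
) -> ComparisonTable:
    """Fit every variant to every observer and tabulate BIC.

    Pairwise comparisons are Bonferroni-corrected paired t-tests of the
    reference variant's BIC against each alternative, computed when at least
    two observers are available.  A fit failure is recorded in its row
    (NaN log-likelihood, converged=False) without aborting the run.
    """
    from scipy import stats

    from .inference import FitConfig, fit_mle

    config = config or FitConfig()
    resolved = [_resolve(v) for v in variants]
    variants = [v.name for v in resolved]
    if isinstance(reference, ModelVariant):
        reference = reference.name
    records = []
    for ds in datasets:
        for name, spec in zip(variants, resolved):
            try:
                fit = fit_mle(ds, spec, config)
                rec = {
                    "observer_id": ds.observer_id,
                    "variant": name,
                    "loglik": fit.loglik,
                    "k": fit.k,
                    "n_trials": fit.n_trials,
                    "bic": fit.bic,
                    "r_squared": fit.r_squared,
                    "converged": fit.converged,
                }
                rec.update({f"est_{p}": v for p, v in fit.params_free.items()})
            except Exception as exc:  # fit failure: keep the table going
                rec = {
                    "observer_id": ds.observer_id,
                    "variant": name,
                    "loglik": float("nan"),
                    "bic": float("nan"),
                    "converged": False,
                    "error": str(exc),
                }
            records.append(rec)
    rows = pd.DataFrame.from_records(records)
    summary = (
        rows.groupby("variant")["bic"]
        .agg(mean_bic="mean", sem_bic=lambda s: s.std(ddof=1) / math.sqrt(len(s)) if len(s) > 1 else float("nan"))
        .reset_index()
    )
    wide = rows.pivot(index="observer_id", columns="variant", values="bic")
    pair_records = []
    others = [v for v in variants if v != reference]
    if reference in wide.columns and len(wide) >= 2 and others:
        for other in others:
            diff = wide[reference] - wide[other]
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(wide[reference], wide[other])
            pair_records.append(
                {
                    "comparison": f"{reference} vs {other}",
                    "mean_bic_diff": float(diff.mean()),
                    "t": float(t),
                    "df": len(wide) - 1,
                    "p": float(p),
                    "p_bonferroni": float(min(1.0, p * len(others))),
                }
            )
    return ComparisonTable(rows=rows, summary=summary, pairwise=pd.DataFrame(pair_records))
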