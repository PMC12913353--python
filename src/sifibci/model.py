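"""Model/Results interface for fitting the causal-inference observer.

`FlashBeepBCI` wraps one observer's trial-level data together with a model
variant and Monte Carlo likelihood settings; `fit()` returns a `BCIResults`
carrying the estimates, fit statistics and a text `summary()`, in the style
of statsmodels estimators.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .design import ObserverDataset, accuracy_summary
from .inference import (
    FitConfig,
    FitResult,
    fit_mle,
    goodness_of_fit_r2,
    log_likelihood,
    predict_response_probs,
)
from .params import ModelParams
from .variants import _resolve, apply_variant

__all__ = ["FlashBeepBCI", "BCIResults"]


class FlashBeepBCI:
    """Causal-inference observer model bound to one observer's dataset.

    Parameters
    ----------
    dataset : ObserverDataset
        Trial-level flash/beep reports over the registered design.
    variant : str
        One of ``bci_2d``, ``bci_1d``, ``forced_fusion``, ``mle_flat``.
    config : FitConfig, optional
        Likelihood and optimizer settings (Monte Carlo sample count, seed,
        restarts, probability floor, bounds).
    """

    def __init__(
        self,
        dataset: ObserverDataset,
        variant: str = "bci_2d",
        config: FitConfig | None = None,
    ) -> None:
        self.dataset = dataset
        self.variant = _resolve(variant)
        self.config = config or FitConfig()
        self.exog_names = list(self.variant.free_names)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        observer_id: str | None = None,
        variant: str = "bci_2d",
        config: FitConfig | None = None,
    ) -> "FlashBeepBCI":
        """Build the model from a trial-level dataframe (dataset CSV schema)."""
        frame = df
        if observer_id is not None:
            frame = df[df["observer_id"] == observer_id]
            if frame.empty:
                raise ValueError(f"no trials for observer {observer_id!r}")
        elif "observer_id" in df.columns:
            ids = df["observer_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"dataframe holds several observers {list(ids)}; pass observer_id")
            observer_id = str(ids[0])
        trials = frame.drop(columns=["observer_id"], errors="ignore")
        return cls(ObserverDataset(observer_id=observer_id or "obs", trials=trials), variant, config)

    def loglike(self, free_params: "Mapping[str, float] | Sequence[float]") -> float:
        """Monte Carlo log-likelihood at the given free-parameter values."""
        params, _ = apply_variant(
            self.variant, free_params, fixed_temporal=self.config.fixed_temporal
        )
        return log_likelihood(
            self.dataset,
            params,
            self.variant,
            n_mc=self.config.n_mc,
            seed=self.config.seed,
            eps=self.config.eps,
        )

    def fit(self, **overrides) -> "BCIResults":
        """Maximize the likelihood over the variant's free parameters.

        Keyword overrides (e.g. ``restarts=4``, ``n_mc=5000``) are applied on
        top of the model's FitConfig for this call.
        """
        config = self.config
        if overrides:
            config = FitConfig(**{**config.__dict__, **overrides})
        return BCIResults(self, fit_mle(self.dataset, self.variant, config))


class BCIResults:
    """Fit results: estimates, log-likelihood, BIC, variance explained."""

    def __init__(self, model: FlashBeepBCI, raw: FitResult) -> None:
        self.model = model
        self._raw = raw
        self.params = pd.Series(raw.params_free, name="estimate")
        self.model_params: ModelParams = raw.params
        self.llf = raw.loglik
        self.bic = raw.bic
        self.rsquared = raw.r_squared
        self.nobs = raw.n_trials
        self.df_model = raw.k
        self.converged = raw.converged

    def predict(self, n_mc: int | None = None, seed: int | None = None):
        """Predicted response distributions per condition at the estimates."""
        return predict_response_probs(
            self.model_params,
            self.model.dataset.conditions(),
            self.model.variant,
            n_mc=n_mc or self.model.config.n_mc,
            seed=self.model.config.seed if seed is None else seed,
            eps=self.model.config.eps,
        )

    def rsquared_at(self, n_mc: int = 100_000, seed: int | None = None) -> float:
        """Variance explained recomputed with a larger prediction sample."""
        return goodness_of_fit_r2(self.model.dataset, self.predict(n_mc=n_mc, seed=seed))

    def observed_accuracy(self) -> pd.DataFrame:
        return accuracy_summary(self.model.dataset)

    def summary(self) -> str:
        raw = self._raw
        lines = [
            "Flash-beep causal-inference model fit",
            "=" * 54,
            f"Observer:        {self.model.dataset.observer_id}",
            f"Variant:         {raw.variant} ({self.model.variant.description})",
            f"Trials:          {self.nobs}",
            f"Free parameters: {self.df_model}",
            f"Log-likelihood:  {self.llf:.3f}",
            f"BIC:             {self.bic:.3f}",
            f"R-squared:       {self.rsquared:.4f}",
            f"Converged:       {self.converged}   (restarts={raw.restarts}, "
            f"n_mc={raw.n_mc}, seed={raw.seed})",
            "-" * 54,
            f"{'parameter':<12}{'estimate':>12}",
        ]
        for name, value in raw.params_free.items():
            lines.append(f"{name:<12}{value:>12.4f}")
        lines.append("-" * 54)
        lines.append("Fixed temporal parameters (ms): " + ", ".join(
            f"{k}={v:g}" for k, v in raw.fixed_temporal.items()
        ))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<BCIResults variant={self._raw.variant} llf={self.llf:.2f} bic={self.bic:.2f}>"
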