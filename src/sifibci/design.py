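"""Experimental design, synthetic cohorts, dataset I/O and accuracy summaries.

The default design mirrors the flash-beep numerosity-judgment task: the four
bimodal flash/beep pairings (1F1B, 1F2B, 2F1B, 2F2B) crossed with four
stimulus-onset asynchronies (0, 150, 300, 500 ms) plus the four unisensory
conditions (1F, 2F, 1B, 2B) — 20 unique conditions, presented 10 times each
in pseudorandom order for 200 trials per observer.  Synthetic cohorts are
generated from the observer model via `sifibci.simulate` and serialized as
flat CSV files, one observer per file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ModelParams, default_observer_params
from .simulate import (
    SOA_LEVELS,
    VISUAL_FIRST,
    TrialCondition,
    simulate_trial,
)
from .variants import _resolve

__all__ = [
    "Design",
    "CohortSpec",
    "ObserverDataset",
    "build_design",
    "generate_cohort",
    "accuracy_summary",
    "read_dataset",
    "write_dataset",
    "load_cohort",
    "DATASET_COLUMNS",
]

ISI_MS = 50  # inter-stimulus interval between double flashes/beeps (design metadata)

DATASET_COLUMNS = [
    "observer_id",
    "trial_index",
    "n_flashes",
    "n_beeps",
    "soa_ms",
    "lead",
    "resp_flashes",
    "resp_beeps",
]

_PAIRINGS = ((1, 1), (1, 2), (2, 1), (2, 2))
_UNISENSORY = ((1, 0), (2, 0), (0, 1), (0, 2))


@dataclass(frozen=True)
class Design:
    """An ordered trial list over the registered conditions."""

    conditions: tuple[TrialCondition, ...]
    trials: tuple[TrialCondition, ...]
    reps: int
    lead: str
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def build_design(lead: str = VISUAL_FIRST, reps: int = 10, seed: int | None = 0) -> Design:
    """Build the 20-condition design with ``reps`` repetitions per condition.

    Trial order is pseudorandomized with ``seed`` (None keeps the canonical
    condition order); the condition multiset is unaffected by the seed.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    conditions = [
        TrialCondition(nf, nb, soa, lead) for nf, nb in _PAIRINGS for soa in SOA_LEVELS
    ] + [TrialCondition(nf, nb, 0, lead) for nf, nb in _UNISENSORY]
    trials = [c for c in conditions for _ in range(reps)]
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(trials))
        trials = [trials[i] for i in order]
    return Design(
        conditions=tuple(conditions), trials=tuple(trials), reps=reps, lead=lead, seed=seed
    )


@dataclass
class ObserverDataset:
    """Ordered trial records (condition + discrete reports) for one observer."""

    observer_id: str
    trials: pd.DataFrame  # columns: DATASET_COLUMNS minus observer_id

    def __post_init__(self) -> None:
        self.trials = self.trials.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def conditions(self) -> list[TrialCondition]:
        """Unique conditions present, in canonical design order."""
        seen = {}
        for row in self.trials.itertuples(index=False):
            cond = TrialCondition(int(row.n_flashes), int(row.n_beeps), int(row.soa_ms), row.lead)
            seen[cond] = None
        full = build_design(lead=self.trials["lead"].iloc[0], reps=1, seed=None).conditions
        ordered = [c for c in full if c in seen]
        extras = [c for c in seen if c not in ordered]
        return ordered + extras

    def to_frame(self) -> pd.DataFrame:
        out = self.trials.copy()
        out.insert(0, "observer_id", self.observer_id)
        return out


def reference_between_observer_sd() -> dict[str, float]:
    """Between-observer SDs of the free parameters implied by group-mean
    standard errors in a 24-observer cohort (SE x sqrt(24))."""
    root_n = np.sqrt(24.0)
    return {
        "sigma_V": 0.07 * root_n,
        "sigma_A": 0.003 * root_n,
        "p_common": 0.06 * root_n,
        "sigma_p": 0.24 * root_n,
        "mu_p": 0.12 * root_n,
    }


@dataclass
class CohortSpec:
    """How to generate a synthetic cohort.

    ``param_sd`` maps free-parameter names to between-observer SDs; observers
    then draw their generating parameters from truncated normals around the
    base values.  With ``param_sd=None`` every observer shares ``params``.
    """

    n_observers: int = 24
    params: ModelParams = field(default_factory=default_observer_params)
    master_seed: int = 0
    variant: str = "bci_2d"
    param_sd: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ValueError("n_observers must be at least 1")


_PARAM_BOUNDS = {
    "sigma_V": (0.05, 5.0),
    "sigma_A": (0.05, 5.0),
    "p_common": (0.01, 0.99),
    "sigma_p": (0.1, 10.0),
    "mu_p": (0.0, 3.0),
}


def _draw_observer_params(
    base: ModelParams, param_sd: Mapping[str, float], rng: np.random.Generator
) -> ModelParams:
    changes = {}
    for name, sd in param_sd.items():
        lo, hi = _PARAM_BOUNDS[name]
        changes[name] = float(np.clip(rng.normal(getattr(base, name), sd), lo, hi))
    return base.replace(**changes)


def generate_cohort(spec: CohortSpec, design: Design | None = None) -> list[ObserverDataset]:
    """Simulate one dataset per observer, reproducible from the master seed.

    Per-observer random streams are spawned deterministically from the
    master seed and consumed in trial order.
    """
    design = design or build_design()
    variant = _resolve(spec.variant)
    children = np.random.SeedSequence(spec.master_seed).spawn(spec.n_observers)
    datasets = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = (
            _draw_observer_params(spec.params, spec.param_sd, rng)
            if spec.param_sd
            else spec.params
        )
        records = []
        for t, cond in enumerate(design.trials):
            resp_V, resp_A = simulate_trial(
                cond,
                params,
                rng,
                use_temporal=variant.use_temporal,
                force_fusion=variant.force_fusion,
                flat_prior=variant.flat_prior,
            )
            records.append(
                {
                    "trial_index": t,
                    "n_flashes": cond.n_flashes,
                    "n_beeps": cond.n_beeps,
                    "soa_ms": cond.soa,
                    "lead": cond.lead,
                    "resp_flashes": resp_V,
                    "resp_beeps": resp_A,
                }
            )
        trials = pd.DataFrame.from_records(records)
        for col in ("resp_flashes", "resp_beeps"):
            trials[col] = trials[col].astype("Int64")
        datasets.append(ObserverDataset(observer_id=f"obs{i + 1:02d}", trials=trials))
    return datasets


def accuracy_summary(data: "ObserverDataset | Sequence[ObserverDataset]") -> pd.DataFrame:
    """Per-condition flash and beep accuracy (report equals true count).

    For a cohort, trials are pooled across observers.  Unisensory rows carry
    NaN for the absent modality.
    """
    if isinstance(data, ObserverDataset):
        frames = [data.trials]
    else:
        datasets = list(data)
        if not datasets:
            raise ValueError("empty cohort")
        frames = [ds.trials for ds in datasets]
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        raise ValueError("empty dataset")
    rows = []
    for (nf, nb, soa, lead), grp in pooled.groupby(
        ["n_flashes", "n_beeps", "soa_ms", "lead"], sort=False
    ):
        cond = TrialCondition(int(nf), int(nb), int(soa), lead)
        rows.append(
            {
                "condition": cond.label(),
                "n_flashes": int(nf),
                "n_beeps": int(nb),
                "soa_ms": int(soa),
                "lead": lead,
                "n_trials": len(grp),
                "flash_accuracy": float((grp["resp_flashes"] == nf).mean()) if nf else np.nan,
                "beep_accuracy": float((grp["resp_beeps"] == nb).mean()) if nb else np.nan,
            }
        )
    order = {c.label(): i for i, c in enumerate(build_design(reps=1, seed=None).conditions)}
    rows.sort(key=lambda r: order.get(r["condition"], len(order)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset I/O (flat CSV, one observer per file)


def write_dataset(dataset: ObserverDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False, na_rep="NA")


def _validation_error(row: int, message: str) -> ValueError:
    return ValueError(f"row {row}: {message}")


def read_dataset(path) -> ObserverDataset:
    """Read one observer's trials from CSV, validating the schema row by row.

    Malformed rows (out-of-range counts or responses, unknown SOA, missing
    response for a present modality, response for an absent one) are
    rejected with the offending row number; row numbers count data rows
    starting at 1.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    observers = df["observer_id"].unique()
    if len(observers) != 1:
        raise ValueError(f"{path}: expected exactly one observer, found {list(observers)}")
    for col in ("resp_flashes", "resp_beeps"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            cond = TrialCondition(
                int(row.n_flashes), int(row.n_beeps), int(row.soa_ms), str(row.lead)
            )
        except (ValueError, TypeError) as exc:
            raise _validation_error(i, str(exc)) from None
        for label, count, resp in (
            ("flash", cond.n_flashes, row.resp_flashes),
            ("beep", cond.n_beeps, row.resp_beeps),
        ):
            if count >= 1:
                if pd.isna(resp):
                    raise _validation_error(i, f"missing {label} response for a present modality")
                if int(resp) not in (0, 1, 2):
                    raise _validation_error(i, f"{label} response {int(resp)} outside 0-2")
            elif not pd.isna(resp):
                raise _validation_error(i, f"{label} response given for an absent modality")
    trials = df[DATASET_COLUMNS[1:]].copy()
    return ObserverDataset(observer_id=str(observers[0]), trials=trials)


def load_cohort(paths: "Iterable | str | Path") -> list[ObserverDataset]:
    """Read a cohort from a directory of per-observer CSVs or a list of paths."""
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = sorted(root.glob("dataset_*.csv")) or sorted(root.glob("*.csv"))
    datasets = [read_dataset(p) for p in paths]
    if not datasets:
        raise ValueError("no dataset files found")
    return datasets
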