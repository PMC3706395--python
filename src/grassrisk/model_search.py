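"""All-subsets model selection ranked by AICc with Akaike weights.

Every unique combination of the candidate fixed-effect predictors (including
the empty, random-effect-only model) is fitted with the genus random
intercept retained throughout; with the nine impact predictors this is
2^9 = 512 models.  Models are ranked by AICc; ΔAICc is the gap to the best
model and the Akaike weight exp(-Δ/2) / Σ exp(-Δ/2) measures relative
support.  Fits are cached per dataset so the classifier-evaluation stage can
reuse them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from grassrisk.glmm_core import (
    IMPACT_PREDICTORS,
    PREDICTORS,
    FitResult,
    ModelSpec,
    fit_model,
)
from grassrisk.species_table import Dataset


def enumerate_models(predictors: Sequence[str], response: str) -> list[ModelSpec]:
    """All 2^p fixed-effect subsets (the empty subset is the random-only
    model), in deterministic order: by subset size, then lexicographic.

    Predictor legality is checked up front; requesting ``num_regions`` for a
    binary impact response raises immediately.
    """
    predictors = tuple(predictors)
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictors in pool")
    canon = tuple(p for p in PREDICTORS if p in predictors)
    if set(canon) != set(predictors):
        unknown = sorted(set(predictors) - set(PREDICTORS))
        raise ValueError(f"unknown predictor(s): {unknown}")
    specs = []
    for r in range(len(canon) + 1):
        for subset in sorted(combinations(sorted(canon), r)):
            ordered = tuple(p for p in canon if p in subset)
            specs.append(ModelSpec(response, ordered))
    return specs


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-Δ_i/2) / Σ_j exp(-Δ_j/2).

    Non-finite AICc values (failed fits) are excluded with a warning and get
    weight 0; the remaining weights are renormalised.
    """
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AICc values")
    if not finite.all():
        warnings.warn(f"{(~finite).sum()} non-finite AICc value(s) excluded from weights")
    w = np.zeros_like(a)
    delta = a[finite] - a[finite].min()
    ew = np.exp(-delta / 2.0)
    w[finite] = ew / ew.sum()
    return w


@dataclass
class RankedModel:
    rank: int
    spec: ModelSpec
    fit: FitResult
    delta_aicc: float
    akaike_weight: float


@dataclass
class ModelRanking:
    """Models sorted ascending by AICc (non-converged fits rank last)."""

    entries: list[RankedModel]

    @property
    def best(self) -> RankedModel:
        return self.entries[0]

    def __len__(self) -> int:
        return len(self.entries)

    def rank_of(self, predictors: Sequence[str]) -> int:
        target = frozenset(predictors)
        for e in self.entries:
            if frozenset(e.spec.fixed_predictors) == target:
                return e.rank
        raise KeyError(f"no model with predictors {sorted(target)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [e.rank for e in self.entries],
                "model": [
                    " + ".join(e.spec.fixed_predictors) or "(1 | genus)"
                    for e in self.entries
                ],
                "aicc": [e.fit.aicc for e in self.entries],
                "delta_aicc": [e.delta_aicc for e in self.entries],
                "akaike_weight": [e.akaike_weight for e in self.entries],
                "converged": [e.fit.converged for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class FitCache:
    """Memoises fits keyed by model spec for one dataset, so the AICc search
    and the leave-one-out classifier evaluation share full-data fits."""

    def __init__(self, dataset: Dataset):
        self.dataset = dataset
        self._fits: dict[ModelSpec, FitResult] = {}

    def fit(self, spec: ModelSpec, **kwargs) -> FitResult:
        if spec not in self._fits:
            self._fits[spec] = fit_model(self.dataset, spec, **kwargs)
        return self._fits[spec]


def search(
    dataset: Dataset,
    response: str,
    predictors: Optional[Sequence[str]] = None,
    cache: Optional[FitCache] = None,
) -> ModelRanking:
    """Fit every predictor subset and rank by AICc.

    Ties break deterministically: fewer predictors first, then lexicographic
    predictor names.  Non-converged fits are ranked after all converged ones
    and flagged in the output.
    """
    if predictors is None:
        predictors = IMPACT_PREDICTORS if response != "log_spread_rate" else PREDICTORS
    specs = enumerate_models(predictors, response)
    if cache is None:
        cache = FitCache(dataset)
    fits: list[FitResult] = []
    failures: dict[str, str] = {}
    for spec in specs:
        try:
            fits.append(cache.fit(spec))
        except Exception as exc:  # rank-deficiency etc.: record and skip
            failures[spec.formula] = str(exc)
    if not fits:
        raise RuntimeError(f"every model fit failed; diagnostics: {failures}")

    def sort_key(f: FitResult):
        return (
            not f.converged,
            f.aicc if np.isfinite(f.aicc) else np.inf,
            len(f.spec.fixed_predictors),
            f.spec.fixed_predictors,
        )

    fits.sort(key=sort_key)
    best_aicc = fits[0].aicc
    weights = akaike_weights([f.aicc for f in fits])
    entries = [
        RankedModel(
            rank=i + 1,
            spec=f.spec,
            fit=f,
            delta_aicc=f.aicc - best_aicc,
            akaike_weight=float(w),
        )
        for i, (f, w) in enumerate(zip(fits, weights))
    ]
    return ModelRanking(entries)
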