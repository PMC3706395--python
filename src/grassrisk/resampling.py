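"""Genus-stratified bootstrap, sector summaries and parametric checks.

Coefficient uncertainty for the best-supported impact model is estimated by
a bootstrap that resamples species with replacement *within* each genus, so
per-genus sample sizes (and the grouping structure the random effect needs)
are conserved on every draw.  Resamples containing too few high-impact
species (default fewer than 15) are rejected and redrawn, which keeps the
mixed-model refits away from the all-negative degenerate region.

The by-sector analyses re-run the AICc search on each sector's impact flag
(with the five-level introduction pathway dropped from the pool to limit the
parameter count) and guard against noise-fitting with a parametric
simulate–refit randomisation check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from grassrisk.glmm_core import ModelSpec, fit_binomial_glmm, fit_model
from grassrisk.model_search import ModelRanking, search
from grassrisk.species_table import Dataset

SECTORS = ("environmental", "pastoral", "agricultural")
_SECTOR_COLUMN = {
    "environmental": "impact_env",
    "pastoral": "impact_pastoral",
    "agricultural": "impact_agri",
}


def sector_response(sector: str) -> str:
    if sector not in _SECTOR_COLUMN:
        raise ValueError(f"unknown sector {sector!r}; expected one of {SECTORS}")
    return _SECTOR_COLUMN[sector]


class GenusResampler:
    """Reusable within-genus resampler; precomputes the genus partition once
    so repeated bootstrap draws stay cheap."""

    def __init__(self, dataset: Dataset):
        self.dataset = dataset
        genus = dataset.frame["genus"].to_numpy()
        self._order = np.argsort(genus, kind="stable")
        sorted_genus = genus[self._order]
        _, starts, counts = np.unique(sorted_genus, return_index=True, return_counts=True)
        self._slot_start = np.repeat(starts, counts)
        self._slot_size = np.repeat(counts, counts)
        self._genus_counts = dict(zip(*np.unique(genus, return_counts=True)))

    def draw(self, rng: np.random.Generator) -> Dataset:
        pos = self._slot_start + np.floor(
            rng.random(len(self._slot_start)) * self._slot_size
        ).astype(np.intp)
        take = self._order[pos]
        df = self.dataset.frame
        out = df.iloc[take].copy().reset_index(drop=True)
        dup = out.groupby("species_id").cumcount()
        out["species_id"] = np.where(
            dup > 0, out["species_id"] + "#" + dup.astype(str), out["species_id"]
        )
        resampled = Dataset(out, census_year=self.dataset.census_year, validate=False)
        counts = dict(zip(*np.unique(out["genus"].to_numpy(), return_counts=True)))
        assert counts == self._genus_counts, "per-genus counts must be conserved"
        return resampled


def genus_stratified_resample(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Resample species with replacement within each genus.

    Per-genus record counts are identical to the input (singleton genera are
    always carried over unchanged).  Species drawn more than once get a
    uniquified id suffix so the resample is still a valid Dataset; genus and
    all predictors are untouched.
    """
    return GenusResampler(dataset).draw(rng)


@dataclass
class BootstrapResult:
    """Percentile-bootstrap distributions of the refitted coefficients."""

    spec: ModelSpec
    n_reps: int
    n_rejected: int
    n_nonconverged: int
    coefficient_draws: dict[str, np.ndarray]
    genus_intercept_draws: pd.DataFrame  # one column per genus (fixed + conditional mode)
    means: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    seed: Optional[int] = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.means),
                "mean": list(self.means.values()),
                "ci_lower": [self.ci95[p][0] for p in self.means],
                "ci_upper": [self.ci95[p][1] for p in self.means],
            }
        )


def bootstrap_best_model(
    dataset: Dataset,
    spec: ModelSpec,
    n_reps: int = 10_000,
    min_positives: int = 15,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    max_attempts_factor: int = 100,
    fit_kwargs: Optional[dict] = None,
) -> BootstrapResult:
    """Genus-stratified rejection bootstrap of a fitted impact model.

    Each accepted resample (at least ``min_positives`` high-impact species;
    rejected draws are redrawn) is refitted, warm-started from the full-data
    fit; the fixed coefficients and each genus's intercept (fixed intercept
    plus conditional mode) are recorded.  Percentile 95% intervals are taken
    from the resulting distributions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    response = spec.response
    if int(dataset.frame[response].sum()) < min_positives:
        raise ValueError(
            f"dataset has {int(dataset.frame[response].sum())} positives, fewer than "
            f"min_positives={min_positives}: every resample would be rejected"
        )
    full_fit = fit_model(dataset, spec)
    start = full_fit.params if full_fit.converged else None
    genera = sorted(dataset.frame["genus"].unique())

    coef_names = list(full_fit.coefficients)
    draws = {name: np.empty(n_reps) for name in coef_names + ["genus_sd"]}
    genus_draws = np.empty((n_reps, len(genera)))
    n_rejected = 0
    n_nonconverged = 0
    accepted = 0
    max_attempts = max_attempts_factor * n_reps
    attempts = 0
    resampler = GenusResampler(dataset)
    while accepted < n_reps:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"rejection bootstrap exceeded {max_attempts} attempts "
                f"({accepted}/{n_reps} accepted): dataset too sparse in positives"
            )
        resample = resampler.draw(rng)
        if int(resample.frame[response].sum()) < min_positives:
            n_rejected += 1
            continue
        try:
            refit = fit_model(resample, spec, start_params=start, **(fit_kwargs or {}))
        except ValueError:  # e.g. a resample collapsed a predictor to a constant
            n_nonconverged += 1
            continue
        if not refit.converged:
            n_nonconverged += 1
            continue
        for name in coef_names:
            draws[name][accepted] = refit.coefficients[name]
        draws["genus_sd"][accepted] = refit.genus_sd
        intercept = refit.coefficients["(intercept)"]
        genus_draws[accepted] = [
            intercept + refit.genus_effects.get(g, 0.0) for g in genera
        ]
        accepted += 1

    means = {name: float(np.mean(v)) for name, v in draws.items()}
    ci95 = {
        name: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for name, v in draws.items()
    }
    return BootstrapResult(
        spec=spec,
        n_reps=n_reps,
        n_rejected=n_rejected,
        n_nonconverged=n_nonconverged,
        coefficient_draws=draws,
        genus_intercept_draws=pd.DataFrame(genus_draws, columns=genera),
        means=means,
        ci95=ci95,
        seed=seed,
    )


@dataclass
class SectorSummary:
    """Descriptive trait/history profile of one sector's high-impact species."""

    sector: str
    n_high_impact: int
    prop_perennial_or_both: float
    prop_semi_aquatic: float
    prop_contaminant: float
    prop_actively_spread: float
    spread_rate_mean: float
    spread_rate_se: float

    def to_dict(self) -> dict:
        return {
            "sector": self.sector,
            "n_high_impact": self.n_high_impact,
            "prop_perennial_or_both": self.prop_perennial_or_both,
            "prop_semi_aquatic": self.prop_semi_aquatic,
            "prop_contaminant": self.prop_contaminant,
            "prop_actively_spread": self.prop_actively_spread,
            "spread_rate_mean": self.spread_rate_mean,
            "spread_rate_se": self.spread_rate_se,
        }


def sector_summary(dataset: Dataset, sector: str) -> SectorSummary:
    """Counts, trait proportions and spread rate (mean ± SE, SE = sd/sqrt(n))
    over the species with high impact in ``sector``."""
    col = sector_response(sector)
    sub = dataset.frame[dataset.frame[col] == 1]
    n = len(sub)
    if n == 0:
        return SectorSummary(sector, 0, math.nan, math.nan, math.nan, math.nan, math.nan, math.nan)
    spread = sub["spread_rate"].to_numpy(float)
    se = float(np.std(spread, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return SectorSummary(
        sector=sector,
        n_high_impact=n,
        prop_perennial_or_both=float(sub["life_history"].isin(["perennial", "both"]).mean()),
        prop_semi_aquatic=float(sub["semi_aquatic"].mean()),
        prop_contaminant=float((sub["intro_pathway"] == "contaminant").mean()),
        prop_actively_spread=float(sub["actively_spread"].mean()),
        spread_rate_mean=float(spread.mean()),
        spread_rate_se=se,
    )


#: Predictor pool for the per-sector searches: the impact pool minus the
#: five-level introduction pathway (too many parameters for so few positives).
SECTOR_PREDICTORS = (
    "spread_rate",
    "naturalisation_year",
    "actively_spread",
    "semi_aquatic",
    "life_history",
    "tufted",
    "rhizomes",
    "stolons",
)


def sector_search(dataset: Dataset, sector: str) -> ModelRanking:
    """All-subsets AICc search on one sector's impact flag (256 models)."""
    col = sector_response(sector)
    if int(dataset.frame[col].sum()) == 0:
        raise ValueError(f"sector {sector!r} has no high-impact species")
    return search(dataset, col, SECTOR_PREDICTORS)


@dataclass
class RandomisationResult:
    spec: ModelSpec
    n_sims: int
    n_failed: int
    observed: dict[str, float]
    exceedance: dict[str, float]  # P(|simulated coef| >= |observed coef|) under the fit


def randomisation_check(
    dataset: Dataset,
    sector: str,
    spec: ModelSpec,
    n_sims: int = 500,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> RandomisationResult:
    """Parametric simulate–refit check against noise-fitting.

    Responses are simulated from the fitted model (fresh genus intercepts
    from Normal(0, sigma-hat), then Bernoulli), the model refitted, and for
    each coefficient the proportion of simulated |estimates| at or above the
    observed |estimate| reported, over the refits that converged.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    col = sector_response(sector)
    if spec.response != col:
        spec = ModelSpec(col, spec.fixed_predictors)
    fit = fit_binomial_glmm(dataset, spec)
    df = dataset.frame
    records = dataset.records
    eta_fixed = np.array([fit.linear_predictor(r, use_genus_effect=False) for r in records])
    genus_codes, genus_idx = np.unique(df["genus"].to_numpy(), return_inverse=True)

    names = list(fit.coefficients)
    counts = {name: 0 for name in names}
    n_ok = 0
    n_failed = 0
    sim_df = df.copy()
    for _ in range(n_sims):
        u = rng.normal(0.0, fit.genus_sd, len(genus_codes))
        y = (rng.random(len(df)) < expit(eta_fixed + u[genus_idx])).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            n_failed += 1
            continue
        sim_df[col] = y
        sim_df["high_impact"] = (
            sim_df["impact_env"] | sim_df["impact_pastoral"] | sim_df["impact_agri"]
        ).astype(int)
        try:
            refit = fit_binomial_glmm(
                Dataset(sim_df.copy(), census_year=dataset.census_year, validate=False),
                spec,
                start_params=fit.params,
            )
        except Exception:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        n_ok += 1
        for name in names:
            if abs(refit.coefficients[name]) >= abs(fit.coefficients[name]):
                counts[name] += 1
    if n_ok == 0:
        raise RuntimeError("no randomisation refit converged")
    return RandomisationResult(
        spec=spec,
        n_sims=n_sims,
        n_failed=n_failed,
        observed=dict(fit.coefficients),
        exceedance={name: counts[name] / n_ok for name in names},
    )
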