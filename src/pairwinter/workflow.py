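"""End-to-end analysis runs: raw tables -> events -> indices -> fitted models.

These convenience wrappers chain the pipeline stages the way a full analysis
of one focal winter would: classify pairs, detect flocking events, build the
daily index tables, fit the aggregate and over-time models, and attach
permutation p-values (status-label scheme for terms involving pair status;
within-pair day-shuffle scheme for temporal main effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dyadic_indices import daily_dyad_table, preferred_model_table, preferred_partner_table
from .flock_detection import EventDetectionConfig, detect_all_events
from .inference import (
    FitResult,
    ModelSpec,
    fit_binomial,
    fit_preferred_models,
    permutation_pvalues,
)
from .pair_status import (
    ANALYSED_STATUSES,
    classify_pairs,
    pairs_to_frame,
    winter_presence_from_visits,
)
from .synthetic_data import Population, SimConfig, simulate_dataset


@dataclass
class AnalysisResult:
    pairs: pd.DataFrame            # all classified dyads
    analysed_pairs: pd.DataFrame   # the four analysed statuses only
    daily: pd.DataFrame            # per pair-day index table
    wa_aggregate: FitResult
    wa_over_time: FitResult
    vai_aggregate: FitResult
    preferred: dict | None = None
    n_events: int = 0


def analyse_tables(
    pairs: pd.DataFrame,
    events,
    calendar,
    birds: pd.DataFrame | None = None,
    B: int = 999,
    seed: int = 0,
    fit_preferred: bool = False,
) -> AnalysisResult:
    """Fit the WA/VAI (and optionally preferred-partner) models for one winter."""
    analysed = pairs[pairs["status"].isin(ANALYSED_STATUSES)].reset_index(drop=True)
    daily = daily_dyad_table(events, analysed, calendar)

    wa_agg_spec = ModelSpec(response="wa", degree=0)
    wa_time_spec = ModelSpec(response="wa", degree=2)
    vai_agg_spec = ModelSpec(response="vai", degree=0, include_flock_size=True)

    wa_agg = fit_binomial(daily, wa_agg_spec)
    wa_agg.p_perm = permutation_pvalues(daily, wa_agg_spec, B=B, seed=seed)
    wa_time = fit_binomial(daily, wa_time_spec)
    wa_time.p_perm = permutation_pvalues(daily, wa_time_spec, B=B, seed=seed + 1)
    wa_time.p_perm.update(
        permutation_pvalues(
            daily, wa_time_spec, B=B, seed=seed + 2, scheme="day-within-pair"
        )
    )
    vai_agg = fit_binomial(daily, vai_agg_spec)
    vai_agg.p_perm = permutation_pvalues(daily, vai_agg_spec, B=B, seed=seed + 3)

    preferred = None
    if fit_preferred:
        if birds is None:
            raise ValueError("birds table required for the preferred-partner models")
        partner_map: dict[str, str] = {}
        for row in analysed.itertuples(index=False):
            partner_map[row.male_id] = row.female_id
            partner_map[row.female_id] = row.male_id
        pref_daily = preferred_partner_table(events, birds, partner_map, calendar)
        pref_table = preferred_model_table(pref_daily, analysed, birds)
        preferred = fit_preferred_models(pref_table, B=B, seed=seed + 4)

    return AnalysisResult(
        pairs=pairs,
        analysed_pairs=analysed,
        daily=daily,
        wa_aggregate=wa_agg,
        wa_over_time=wa_time,
        vai_aggregate=vai_agg,
        preferred=preferred,
        n_events=len(events) if hasattr(events, "__len__") else 0,
    )


def analyse_synthetic(
    seed: int,
    config: SimConfig | None = None,
    B: int = 999,
    detection: EventDetectionConfig | None = None,
    fit_preferred: bool = False,
) -> tuple[AnalysisResult, Population]:
    """Generate one synthetic winter and run the full pipeline on it."""
    config = config or SimConfig()
    population, visits = simulate_dataset(config, seed=seed)
    calendar = config.calendar()
    presence = winter_presence_from_visits(visits)
    pair_records = classify_pairs(
        population.breeding_t_minus_1,
        population.breeding_t_plus_1,
        presence,
        population.sightings,
        population.birds,
        focal_winter=config.winter_label,
        year_t_minus_1=config.year_t_minus_1,
        year_t_plus_1=config.year_t_plus_1,
    )
    pairs = pairs_to_frame(pair_records)
    events = detect_all_events(visits, detection, seed=seed)
    result = analyse_tables(
        pairs,
        events,
        calendar,
        birds=population.birds,
        B=B,
        seed=seed,
        fit_preferred=fit_preferred,
    )
    return result, population


def status_slope(fit: FitResult, status: str) -> float:
    """Linear day slope for one status (reference slope + interaction)."""
    slope = fit.coef("day")
    term = f"status[{status}]:day"
    if term in fit.terms:
        slope += fit.coef(term)
    return slope
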