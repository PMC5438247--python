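"""Concentration-dependence of response latencies.

For each simultaneously recorded population and odor, the mean response
latency per concentration (first-spike or per-trial KDF-peak latency,
trial-averaged per cell, cells requiring more than one measurable trial)
is regressed on log10 concentration by ordinary least squares.  Slope
distributions are then compared between regions with an unpaired t-test.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset
from .metrics import PSTHConfig, aligned_spikes, compute_kdf, \
    first_spike_latencies, peak_and_duration

LATENCY_TYPES = ("first-spike", "psth-peak")


@dataclasses.dataclass
class SlopeFit:
    population_id: str
    odorant: str
    region: str
    latency_type: str
    concentrations: np.ndarray
    mean_latency: np.ndarray      # s, per concentration
    slope: float                  # s per log10-concentration unit
    intercept: float
    n_cells: int


def ols_latency_slope(concentrations, mean_latencies,
                      log_axis: bool = True) -> tuple[float, float]:
    """OLS slope/intercept of mean latency versus (log10) concentration."""
    c = np.asarray(concentrations, float)
    y = np.asarray(mean_latencies, float)
    if len(c) < 2:
        raise ValueError("need at least two concentration points")
    x = np.log10(c) if log_axis else c
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def _trial_kdf_peaks(train, onsets, config: PSTHConfig) -> np.ndarray:
    """Per-trial single-trial KDF peak latency (NaN when undefined)."""
    out = np.full(len(onsets), np.nan)
    for i, sp in enumerate(aligned_spikes(train, onsets, config.window)):
        if not len(sp):
            continue
        grid, rate = compute_kdf([sp], config)
        out[i] = peak_and_duration(grid, rate)["peak_latency"]
    return out


def population_latency_slope(dataset: Dataset, odorant: str,
                             region: str = "PCx",
                             latency_type: str = "first-spike",
                             population_id: str = "pop0",
                             config: PSTHConfig | None = None,
                             log_axis: bool = True) -> SlopeFit | None:
    """Latency-versus-concentration slope for one population-odor pair.

    Per cell and concentration, latencies are measured trial-by-trial and
    averaged; a cell contributes only when the latency could be measured
    on more than one trial.  Cell latencies are then averaged per
    concentration and a regression line fit across concentrations.
    Returns ``None`` when no latencies are measurable for the pair.
    """
    if latency_type not in LATENCY_TYPES:
        raise ValueError(f"latency_type must be one of {LATENCY_TYPES}")
    config = config or PSTHConfig()
    trials = dataset.trials
    sel = trials[(trials["odorant"] == odorant) & (trials["is_blank"] == 0)]
    concs = sorted(sel["concentration"].unique())
    if len(concs) < 2:
        raise ValueError(f"odorant {odorant!r} has no concentration series")
    units = dataset.units
    if region is not None:
        units = units[units["region"] == region]
    trains = dataset.spike_trains()

    per_conc: dict[float, list] = {c: [] for c in concs}
    n_cells = 0
    for u in units["unit_id"]:
        train = trains[u]
        cell_means = {}
        for c in concs:
            onsets = sel.loc[np.isclose(sel["concentration"], c),
                             "inhalation_onset_s"].to_numpy()
            if latency_type == "first-spike":
                lat = first_spike_latencies(train, onsets, config.window)
            else:
                lat = _trial_kdf_peaks(train, onsets, config)
            if np.sum(np.isfinite(lat)) > 1:
                cell_means[c] = float(np.nanmean(lat))
        if cell_means:
            n_cells += 1
            for c, v in cell_means.items():
                per_conc[c].append(v)

    concs_used = [c for c in concs if per_conc[c]]
    if len(concs_used) < 2:
        return None
    means = np.array([np.mean(per_conc[c]) for c in concs_used])
    slope, intercept = ols_latency_slope(concs_used, means, log_axis)
    return SlopeFit(population_id, odorant, region or "all",
                    latency_type, np.asarray(concs_used), means, slope,
                    intercept, n_cells)


def slopes_table(datasets: Sequence[Dataset] | Dataset,
                 latency_type: str = "first-spike",
                 regions: Sequence[str] = ("PCx", "OB"),
                 config: PSTHConfig | None = None) -> pd.DataFrame:
    """Slope fits for every (population, region, series odorant).

    ``datasets`` may be a single session or a list of simultaneously
    recorded populations; pairs with no measurable latencies are dropped.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    rows = []
    for i, ds in enumerate(datasets):
        stim = ds.trials[ds.trials["is_blank"] == 0]
        series = [od for od, grp in stim.groupby("odorant")
                  if grp["concentration"].nunique() > 1]
        for region in regions:
            if not (ds.units["region"] == region).any():
                continue
            for od in series:
                fit = population_latency_slope(
                    ds, od, region=region, latency_type=latency_type,
                    population_id=f"pop{i}", config=config)
                if fit is None:
                    continue
                rows.append({
                    "population_id": fit.population_id, "odorant": od,
                    "region": region, "latency_type": latency_type,
                    "slope": fit.slope, "intercept": fit.intercept,
                    "n_cells": fit.n_cells,
                })
    return pd.DataFrame(rows)


def compare_regions(slopes_ob, slopes_pcx) -> dict:
    """Unpaired t-test on slope distributions (OB vs PCx).

    Returns the mean difference (PCx - OB), t statistic and two-sided p.
    """
    a = np.asarray(slopes_ob, float)
    b = np.asarray(slopes_pcx, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two slope fits per region")
    t, p = stats.ttest_ind(b, a)
    return {"mean_difference": float(b.mean() - a.mean()),
            "t": float(t), "p_value": float(p),
            "n_ob": len(a), "n_pcx": len(b)}
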