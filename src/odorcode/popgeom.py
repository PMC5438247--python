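"""Population response vectors and trial-by-trial correlation structure.

Response vectors are per-cell spike counts in the first sniff after odor
onset.  Trial-pair similarity uses Spearman's rank correlation (mid-rank
ties) because population spike counts are far from normal; Pearson is
available as an alternative and gives qualitatively similar but higher
values.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset
from .metrics import _trial_windows, spike_counts

logger = logging.getLogger(__name__)


def build_vectors(dataset: Dataset, count_window: float = 0.480,
                  region: str | None = None,
                  include_blanks: bool = False
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Trials x cells spike-count matrix over each trial's first sniff.

    Returns ``(counts, trial_info)`` where ``trial_info`` carries the
    trial metadata row-aligned with ``counts``.  Cells are ordered as in
    ``dataset.units`` (restricted to ``region`` when given).
    """
    trials = dataset.trials
    if not include_blanks:
        trials = trials[trials["is_blank"] == 0]
    trials = trials.reset_index(drop=True)
    units = dataset.units
    if region is not None:
        units = units[units["region"] == region]
    uids = list(units["unit_id"])
    onsets = trials["inhalation_onset_s"].to_numpy()
    windows = _trial_windows(trials, count_window)
    trains = dataset.spike_trains()
    counts = np.empty((len(trials), len(uids)), dtype=int)
    for j, u in enumerate(uids):
        counts[:, j] = spike_counts(trains[u], onsets, windows)
    return counts, trials


def _pair_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("zero-variance population vector; pair skipped")
        return np.nan
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def correlation_by_condition(counts: np.ndarray, trial_info: pd.DataFrame,
                             method: str = "spearman") -> pd.DataFrame:
    """Mean trial-pair correlation per stimulus-relation condition.

    Conditions: same stimulus (identical odorant and concentration; all
    unordered distinct trial pairs), same odorant at a concentration
    difference of 0.5/1.0/1.5 log10 units, and different odorant (any
    concentrations).  Returns one row per condition with the mean
    correlation and number of pairs.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    od = trial_info["odorant"].to_numpy()
    logc = np.log10(trial_info["concentration"].to_numpy(float))
    sums: dict[tuple, list] = {}
    n = len(trial_info)
    for i, j in itertools.combinations(range(n), 2):
        rho = _pair_corr(counts[i], counts[j], method)
        if not np.isfinite(rho):
            continue
        if od[i] != od[j]:
            key = ("different_odorant", np.nan)
        else:
            dlc = abs(logc[i] - logc[j])
            dlc = round(dlc * 2) / 2  # snap to the 0.5 log10 design grid
            key = ("same_stimulus", 0.0) if dlc == 0 else ("same_odorant", dlc)
        sums.setdefault(key, []).append(rho)
    rows = [{"condition": cond, "delta_log10_conc": dlc,
             "mean_rho": float(np.mean(v)), "n_pairs": len(v)}
            for (cond, dlc), v in sorted(sums.items(),
                                         key=lambda kv: (kv[0][0],
                                                         kv[0][1]))]
    return pd.DataFrame(rows)
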