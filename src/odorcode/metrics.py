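"""Per cell-odor response characterization.

Kernel density firing-rate estimates (10 ms Gaussian kernel on a 1 ms
grid), peak latency and response duration, auROC response indices with
rank-sum significance, polarity classes, tuning-curve shuffle nulls,
lifetime/population sparseness, population PSTH synchrony, and total
spiking output.

Conventions: spike counting windows are half-open ``[start, end)``;
latency peaks live on the closed window ``[0, 0.5]`` s and are undefined
when the KDF maximum sits at a window edge.  Significance is uncorrected
rank-sum at ``alpha = 0.05`` by default.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset

UNDEFINED = np.nan


@dataclasses.dataclass
class PSTHConfig:
    kernel_sd: float = 0.010      # s
    window: tuple = (0.0, 0.5)    # s, relative to inhalation onset
    grid_dt: float = 0.001        # s
    count_window: float = 0.480   # fallback first-sniff length, s

    def __post_init__(self):
        if self.kernel_sd <= 0:
            raise ValueError("kernel_sd must be positive")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede end")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.window[1] - self.window[0]) / self.grid_dt))
        return self.window[0] + self.grid_dt * np.arange(n + 1)


def aligned_spikes(train: np.ndarray, onsets: Sequence[float],
                   window: tuple[float, float]) -> list[np.ndarray]:
    """Spike times relative to each onset, restricted to ``[w0, w1)``."""
    train = np.asarray(train)
    out = []
    for t0 in onsets:
        i0, i1 = np.searchsorted(train, [t0 + window[0], t0 + window[1]])
        out.append(train[i0:i1] - t0)
    return out


def spike_counts(train: np.ndarray, onsets: Sequence[float],
                 windows) -> np.ndarray:
    """Per-onset spike counts in half-open windows.

    ``windows`` is either a single ``(w0, w1)`` tuple applied to every
    onset or a sequence of per-onset window lengths (taken as ``[0, w)``).
    """
    train = np.asarray(train)
    onsets = np.asarray(onsets, float)
    if isinstance(windows, tuple):
        lo = onsets + windows[0]
        hi = onsets + windows[1]
    else:
        lo = onsets
        hi = onsets + np.asarray(windows, float)
    return (np.searchsorted(train, hi) - np.searchsorted(train, lo))


def compute_kdf(trial_spikes: Sequence[np.ndarray],
                config: PSTHConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged Gaussian-kernel firing-rate estimate (Hz).

    Kernels are truncated at the window bounds without renormalization, so
    the integral of the KDF over the window equals the mean per-trial
    count of interior spikes (edge spikes lose the mass that falls
    outside).  Returns ``(grid, rate)``.
    """
    config = config or PSTHConfig()
    grid = config.grid
    n_trials = len(trial_spikes)
    if n_trials == 0:
        raise ValueError("need at least one trial")
    spikes = np.concatenate([np.asarray(s, float) for s in trial_spikes]) \
        if any(len(s) for s in trial_spikes) else np.empty(0)
    if len(spikes) == 0:
        return grid, np.zeros_like(grid)
    sd = config.kernel_sd
    diff = grid[None, :] - spikes[:, None]
    rate = np.exp(-0.5 * (diff / sd) ** 2).sum(axis=0)
    rate /= sd * np.sqrt(2 * np.pi) * n_trials
    return grid, rate


def peak_and_duration(grid: np.ndarray, rate: np.ndarray,
                      fractions: tuple = (0.25, 0.50)) -> dict:
    """Peak latency/rate and widths of the maximal peak.

    The peak is the KDF maximum; when it lies at a window edge (rising to
    or falling from a peak outside the window) the latency and durations
    are undefined (NaN).  ``duration<f>`` is the width of the maximal peak
    at ``f`` of its height, clipped at the window bounds when the flanks
    do not fall below threshold inside the window.
    """
    out = {"peak_latency": UNDEFINED, "peak_rate": UNDEFINED}
    for f in fractions:
        out[f"duration{int(round(f * 100))}"] = UNDEFINED
    if np.all(rate <= 0) or np.all(rate == rate[0]):
        return out
    i = int(np.argmax(rate))
    out["peak_rate"] = float(rate[i])
    if i == 0 or i == len(rate) - 1:
        return out
    out["peak_latency"] = float(grid[i])
    for f in fractions:
        thr = f * rate[i]
        j = i
        while j > 0 and rate[j] >= thr:
            j -= 1
        if rate[j] < thr:  # interpolate the crossing
            t_left = np.interp(thr, [rate[j], rate[j + 1]],
                               [grid[j], grid[j + 1]])
        else:
            t_left = grid[0]
        k = i
        while k < len(rate) - 1 and rate[k] >= thr:
            k += 1
        if rate[k] < thr:
            t_right = np.interp(-thr, [-rate[k - 1], -rate[k]],
                                [grid[k - 1], grid[k]])
        else:
            t_right = grid[-1]
        out[f"duration{int(round(f * 100))}"] = float(t_right - t_left)
    return out


def auroc(odor_counts, blank_counts) -> float:
    """Area under the ROC curve separating the two count distributions
    (probability that an odor-trial count exceeds a blank-trial count,
    ties counting one half), computed from the Mann-Whitney U statistic."""
    x = np.asarray(odor_counts, float)
    y = np.asarray(blank_counts, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty count distribution")
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(u) / (len(x) * len(y))


def response_index(odor_counts, blank_counts) -> tuple[float, float]:
    """auROC-based response index in [-1, 1] plus rank-sum p-value.

    index = 2*auROC - 1: -1 is unequivocal suppression, +1 unambiguous
    activation.  The p-value is the two-sided Wilcoxon rank-sum test on
    the same distributions (exact for small samples without ties,
    tie-corrected normal approximation otherwise).
    """
    x = np.asarray(odor_counts, float)
    y = np.asarray(blank_counts, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty count distribution")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    a = float(res.statistic) / (len(x) * len(y))
    return 2 * a - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# dataset-level response statistics

def _trial_windows(trials: pd.DataFrame, fallback: float) -> np.ndarray:
    if "sniff_duration_s" in trials.columns:
        w = trials["sniff_duration_s"].to_numpy(float)
        return np.where(np.isfinite(w) & (w > 0), w, fallback)
    return np.full(len(trials), fallback)


def response_stats_table(dataset: Dataset, alpha: float = 0.05,
                         config: PSTHConfig | None = None) -> pd.DataFrame:
    """One row per (unit, odorant, concentration): response index, rank-sum
    p, polarity, KDF peak latency/rate, durations, mean first-spike latency.

    Counts are taken over each trial's first full respiration cycle
    (``sniff_duration_s`` when present, else a fixed 480 ms window) and
    compared against the mineral-oil blank trials.
    """
    config = config or PSTHConfig()
    trials = dataset.trials
    blanks = trials[trials["is_blank"] == 1]
    if len(blanks) == 0:
        raise ValueError("blank trials required for response statistics")
    blank_onsets = blanks["inhalation_onset_s"].to_numpy()
    blank_windows = _trial_windows(blanks, config.count_window)

    stim = trials[trials["is_blank"] == 0]
    groups = [(od, c, grp) for (od, c), grp in
              stim.groupby(["odorant", "concentration"], sort=True)]
    trains = dataset.spike_trains()
    rows = []
    for u in dataset.unit_ids:
        train = trains[u]
        blank_counts = spike_counts(train, blank_onsets, blank_windows)
        for od, conc, grp in groups:
            onsets = grp["inhalation_onset_s"].to_numpy()
            windows = _trial_windows(grp, config.count_window)
            counts = spike_counts(train, onsets, windows)
            idx, p = response_index(counts, blank_counts)
            if p < alpha:
                polarity = "activated" if idx > 0 else (
                    "suppressed" if idx < 0 else "none")
            else:
                polarity = "none"
            aligned = aligned_spikes(train, onsets, config.window)
            grid, rate = compute_kdf(aligned, config)
            pk = peak_and_duration(grid, rate)
            fsl = first_spike_latencies(train, onsets, config.window)
            n_fsl = int(np.sum(np.isfinite(fsl)))
            rows.append({
                "unit_id": u, "odorant": od, "concentration": conc,
                "response_index": idx, "p_value": p, "polarity": polarity,
                "mean_count": float(np.mean(counts)),
                "peak_latency": pk["peak_latency"],
                "peak_rate": pk["peak_rate"],
                "duration25": pk["duration25"],
                "duration50": pk["duration50"],
                "first_spike_latency": (float(np.nanmean(fsl))
                                        if n_fsl > 1 else UNDEFINED),
                "n_trials_first_spike": n_fsl,
            })
    return pd.DataFrame(rows)


def first_spike_latencies(train: np.ndarray, onsets: Sequence[float],
                          window: tuple[float, float] = (0.0, 0.5)
                          ) -> np.ndarray:
    """Per-trial latency of the first spike after inhalation onset (NaN
    for trials without spikes in the window)."""
    out = np.full(len(onsets), np.nan)
    for k, sp in enumerate(aligned_spikes(train, onsets, window)):
        if len(sp):
            out[k] = sp[0]
    return out


def classify_polarity(stats_table: pd.DataFrame,
                      concentration: float | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Cell-level polarity classes from per-odor significant responses.

    A cell is ``activated`` (``suppressed``) when all of its significant
    responses are positive (negative), ``mixed`` when it has both signs,
    ``unresponsive`` otherwise.  Restricted to one concentration when
    ``concentration`` is given.
    """
    df = stats_table
    if concentration is not None:
        df = df[np.isclose(df["concentration"], concentration)]
    rows = []
    for u, grp in df.groupby("unit_id", sort=True):
        sig = grp[grp["p_value"] < alpha]
        n_pos = int((sig["response_index"] > 0).sum())
        n_neg = int((sig["response_index"] < 0).sum())
        if n_pos and n_neg:
            cls = "mixed"
        elif n_pos:
            cls = "activated"
        elif n_neg:
            cls = "suppressed"
        else:
            cls = "unresponsive"
        rows.append({"unit_id": u, "cell_class": cls,
                     "n_activated": n_pos, "n_suppressed": n_neg})
    return pd.DataFrame(rows)


def polarity_matrix(stats_table: pd.DataFrame,
                    concentration: float | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Cells x odors matrix with +1 (activated), -1 (suppressed), 0."""
    df = stats_table
    if concentration is not None:
        df = df[np.isclose(df["concentration"], concentration)]
    sign = np.where(df["p_value"] < alpha,
                    np.sign(df["response_index"]), 0).astype(int)
    return df.assign(sign=sign).pivot_table(
        index="unit_id", columns="odorant", values="sign", fill_value=0,
        aggfunc="first")


def tuning_shuffle_null(polarity: pd.DataFrame, n_shuffles: int = 100,
                        seed: int | None = None) -> dict:
    """Null tuning distribution from shuffling cell identities per odor.

    Each shuffle independently permutes every odor column of the polarity
    matrix (preserving each odor's response counts) and recomputes (a) the
    fraction of cells responding to k odors, for activation and
    suppression separately, and (b) the number of mixed-polarity cells.

    Returns per-k mean and 5th-95th percentile bands plus the array of
    mixed counts across shuffles.
    """
    rng = np.random.default_rng(seed)
    M = polarity.to_numpy()
    n_cells, n_odors = M.shape
    k_edges = np.arange(n_odors + 2) - 0.5
    act_h = np.empty((n_shuffles, n_odors + 1))
    sup_h = np.empty((n_shuffles, n_odors + 1))
    mixed = np.empty(n_shuffles, int)
    for s in range(n_shuffles):
        shuf = np.empty_like(M)
        for j in range(n_odors):
            shuf[:, j] = M[rng.permutation(n_cells), j]
        k_act = (shuf > 0).sum(axis=1)
        k_sup = (shuf < 0).sum(axis=1)
        act_h[s] = np.histogram(k_act, bins=k_edges)[0] / n_cells
        sup_h[s] = np.histogram(k_sup, bins=k_edges)[0] / n_cells
        mixed[s] = int(((k_act > 0) & (k_sup > 0)).sum())
    pct = (5, 95)
    return {
        "k": np.arange(n_odors + 1),
        "activated_mean": act_h.mean(axis=0),
        "activated_band": np.percentile(act_h, pct, axis=0),
        "suppressed_mean": sup_h.mean(axis=0),
        "suppressed_band": np.percentile(sup_h, pct, axis=0),
        "mixed_counts": mixed,
    }


def sparseness(r, n: int | None = None) -> float:
    """Lifetime/population sparseness S in [0, 1].

    S = (1 - [(sum r_i / n)^2 / sum(r_i^2 / n)]) / (1 - 1/n): 0 for a
    uniform response profile, 1 when a single entry is non-zero.  Negative
    entries (suppressed responses) are rectified to zero; an all-zero
    profile is undefined (NaN).
    """
    r = np.clip(np.asarray(r, float), 0.0, None)
    n = len(r) if n is None else n
    if n < 2:
        raise ValueError("need at least two responses")
    if np.all(r == 0):
        return UNDEFINED
    num = (r.sum() / n) ** 2
    den = (r ** 2).sum() / n
    return float((1 - num / den) / (1 - 1 / n))


def lifetime_sparseness_table(stats_table: pd.DataFrame,
                              concentration: float,
                              value: str = "mean_count") -> pd.DataFrame:
    """Per-cell lifetime sparseness over odors at one concentration."""
    df = stats_table[np.isclose(stats_table["concentration"], concentration)]
    rows = []
    for u, grp in df.groupby("unit_id", sort=True):
        rows.append({"unit_id": u,
                     "sparseness": sparseness(grp[value].to_numpy())})
    return pd.DataFrame(rows)


def population_sparseness_table(stats_table: pd.DataFrame,
                                concentration: float,
                                value: str = "mean_count") -> pd.DataFrame:
    """Per-odor population sparseness over cells at one concentration."""
    df = stats_table[np.isclose(stats_table["concentration"], concentration)]
    rows = []
    for od, grp in df.groupby("odorant", sort=True):
        rows.append({"odorant": od,
                     "sparseness": sparseness(grp[value].to_numpy())})
    return pd.DataFrame(rows)


def population_psth(dataset: Dataset, odorant: str, concentration: float,
                    config: PSTHConfig | None = None,
                    region: str | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Population mean firing rate (average of per-cell trial-averaged
    KDFs) for one stimulus."""
    config = config or PSTHConfig()
    trials = dataset.trials
    sel = trials[(trials["odorant"] == odorant)
                 & np.isclose(trials["concentration"], concentration)]
    onsets = sel["inhalation_onset_s"].to_numpy()
    units = dataset.units
    if region is not None:
        units = units[units["region"] == region]
    trains = dataset.spike_trains()
    grid = config.grid
    acc = np.zeros_like(grid)
    for u in units["unit_id"]:
        _, rate = compute_kdf(
            aligned_spikes(trains[u], onsets, config.window), config)
        acc += rate
    return grid, acc / max(len(units), 1)


def synchrony_ratio(trace: np.ndarray) -> float:
    """Peak/average ratio of a population rate trace (synchrony index);
    undefined for an all-zero trace."""
    trace = np.asarray(trace, float)
    m = trace.mean()
    if m == 0:
        return UNDEFINED
    return float(trace.max() / m)


def total_spiking_output(dataset: Dataset, region: str | None = None,
                         count_window: float = 0.480) -> pd.DataFrame:
    """Total first-sniff population spike count per concentration for the
    concentration-series odorants, normalized per odorant by its mean
    across concentrations (the normalization baseline is a package
    choice)."""
    trials = dataset.trials
    units = dataset.units
    if region is not None:
        units = units[units["region"] == region]
    uids = list(units["unit_id"])
    trains = dataset.spike_trains()
    stim = trials[trials["is_blank"] == 0]
    series = [od for od, grp in stim.groupby("odorant")
              if grp["concentration"].nunique() > 1]
    rows = []
    for od in series:
        sel = stim[stim["odorant"] == od]
        for c, grp in sel.groupby("concentration"):
            onsets = grp["inhalation_onset_s"].to_numpy()
            windows = _trial_windows(grp, count_window)
            total = sum(spike_counts(trains[u], onsets, windows).sum()
                        for u in uids)
            rows.append({"odorant": od, "concentration": float(c),
                         "total_count": float(total) / len(grp)})
    df = pd.DataFrame(rows)
    df["normalized"] = df.groupby("odorant")["total_count"].transform(
        lambda x: x / x.mean())
    return df
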