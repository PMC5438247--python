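"""Population decoding of odor identity and intensity.

Three feature encodings of the first-sniff response (0-480 ms after
inhalation onset):

``binary``
    per-cell membership: 1 when the trial's spike count exceeds the cell's
    blank-trial mean + k standard deviations (k = 1 by default), else 0;
``summed``
    per-cell spike counts over the whole window (a rate code);
``binned``
    per-cell spike counts in 16 concatenated 30 ms bins (a coarse
    temporal code).

Classification is leave-one-out nearest-class-mean with Euclidean
distance; accuracy is macro-averaged over classes.  Three tasks: 6-way
odorant identification at the nominal concentration, 4-way concentration
identification per concentration-series odorant (averaged over the two
series odorants), and identity generalization, where one concentration of
one series odorant is withheld from an 11-stimulus training set and the
decoder is scored on recovering the odorant identity of the withheld
trials regardless of concentration (chance 3/11, because 3 of the 11
training stimuli share the held-out identity).

Pseudopopulations are drawn by sampling cells without replacement within
a permutation (with replacement across permutations); permutation draws
depend only on the seed, so two encodings run with the same seed see the
same cell draws and can be compared pairwise.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Dataset

SCHEMES = ("binary", "summed", "binned")
TASKS = ("odorant", "concentration", "generalization")


@dataclasses.dataclass
class EncodingConfig:
    scheme: str = "binned"
    window: tuple = (0.0, 0.480)
    bin_width: float = 0.030
    binary_threshold_sd: float = 1.0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.binary_threshold_sd < 0:
            raise ValueError("threshold multiplier must be >= 0")
        span = self.window[1] - self.window[0]
        n = span / self.bin_width
        if self.scheme == "binned" and abs(n - round(n)) > 1e-9:
            raise ValueError("window length must be divisible by bin_width")

    @property
    def n_bins(self) -> int:
        return int(round((self.window[1] - self.window[0]) / self.bin_width))


@dataclasses.dataclass
class EncodedFeatures:
    """Trials x cells x bins feature tensor plus trial metadata."""

    tensor: np.ndarray          # (n_trials, n_cells, n_bins)
    trial_info: pd.DataFrame
    scheme: str
    cell_ids: list

    @property
    def matrix(self) -> np.ndarray:
        t = self.tensor
        return t.reshape(t.shape[0], -1)

    def subset_cells(self, idx: np.ndarray) -> np.ndarray:
        """Flattened feature matrix for a cell subset (trials x features)."""
        t = self.tensor[:, idx, :]
        return t.reshape(t.shape[0], -1)


def binned_counts(dataset: Dataset, window: tuple[float, float],
                  bin_width: float, region: str | None = None,
                  include_blanks: bool = True
                  ) -> tuple[np.ndarray, pd.DataFrame, list]:
    """Per-trial spike counts in consecutive bins aligned to inhalation."""
    trials = dataset.trials
    if not include_blanks:
        trials = trials[trials["is_blank"] == 0]
    trials = trials.reset_index(drop=True)
    units = dataset.units
    if region is not None:
        units = units[units["region"] == region]
    uids = list(units["unit_id"])
    onsets = trials["inhalation_onset_s"].to_numpy()
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    trains = dataset.spike_trains()
    tensor = np.empty((len(trials), len(uids), n_bins), dtype=np.int32)
    for j, u in enumerate(uids):
        train = trains[u]
        # searchsorted over the outer product of onsets and bin edges
        pts = onsets[:, None] + edges[None, :]
        idx = np.searchsorted(train, pts)
        tensor[:, j, :] = np.diff(idx, axis=1)
    return tensor, trials, uids


def encode(dataset: Dataset, config: EncodingConfig | None = None,
           region: str | None = None) -> EncodedFeatures:
    """Build the feature tensor for one encoding scheme.

    The binary scheme needs blank trials: each cell's threshold is the
    mean + k*SD (sample SD) of its blank-trial window counts, pooled over
    all blank trials, and a trial is coded 1 only when its count is
    strictly greater than the threshold.
    """
    config = config or EncodingConfig()
    tensor, trials, uids = binned_counts(
        dataset, config.window,
        config.bin_width if config.scheme == "binned"
        else (config.window[1] - config.window[0]),
        region=region, include_blanks=True)
    is_blank = trials["is_blank"].to_numpy() == 1
    if config.scheme == "binned":
        out = tensor[~is_blank]
    elif config.scheme == "summed":
        out = tensor[~is_blank]
    else:
        if not is_blank.any():
            raise ValueError("binary encoding requires blank trials")
        blank_counts = tensor[is_blank, :, 0].astype(float)
        mean = blank_counts.mean(axis=0)
        sd = blank_counts.std(axis=0, ddof=1) if is_blank.sum() > 1 \
            else np.zeros(len(uids))
        thr = mean + config.binary_threshold_sd * sd
        out = (tensor[~is_blank, :, 0] > thr[None, :]).astype(np.int8)
        out = out[:, :, None]
    info = trials[~is_blank].reset_index(drop=True)
    return EncodedFeatures(np.asarray(out, float), info, config.scheme, uids)


# ---------------------------------------------------------------------------
# classifiers

def nearest_mean_classify(X_train: np.ndarray, y_train: np.ndarray,
                          X_test: np.ndarray) -> np.ndarray:
    """Assign each test row to the class with nearest-mean Euclidean
    distance (ties break to the lowest class index)."""
    classes, yi = np.unique(y_train, return_inverse=True)
    M = np.vstack([X_train[yi == c].mean(axis=0)
                   for c in range(len(classes))])
    d2 = (np.square(X_test).sum(1)[:, None] - 2 * X_test @ M.T
          + np.square(M).sum(1)[None, :])
    return classes[np.argmin(d2, axis=1)]


def euclidean_loo(X: np.ndarray, y: np.ndarray,
                  tie_break: str = "lowest",
                  rng: np.random.Generator | None = None) -> float:
    """Leave-one-out nearest-class-mean accuracy, macro-averaged.

    For each held-out trial the class means are recomputed without it and
    the trial is assigned to the nearest mean.  Accuracy is the mean of
    per-class accuracies.  Requires >= 2 trials per class.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, yi = np.unique(y, return_inverse=True)
    n_c = np.bincount(yi, minlength=len(classes))
    if np.any(n_c < 2):
        raise ValueError("every class needs at least two trials")
    S = np.zeros((len(classes), X.shape[1]))
    np.add.at(S, yi, X)
    M = S / n_c[:, None]
    d2 = (np.square(X).sum(1)[:, None] - 2 * X @ M.T
          + np.square(M).sum(1)[None, :])
    loo_mean = (S[yi] - X) / (n_c[yi] - 1)[:, None]
    d2[np.arange(len(X)), yi] = np.square(X - loo_mean).sum(1)
    d2 = np.maximum(d2, 0.0)
    if tie_break == "lowest":
        pred = np.argmin(d2, axis=1)
    elif tie_break == "random":
        rng = rng or np.random.default_rng()
        jitter = rng.random(d2.shape) * 1e-12
        pred = np.argmin(d2 + jitter, axis=1)
    else:
        raise ValueError("tie_break must be 'lowest' or 'random'")
    correct = pred == yi
    per_class = np.array([correct[yi == c].mean()
                          for c in range(len(classes))])
    return float(per_class.mean())


def euclidean_loo_bruteforce(X: np.ndarray, y: np.ndarray) -> float:
    """Reference implementation: explicit per-fold recomputation of class
    means.  Used as an equivalence oracle in tests; O(trials^2)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    correct = {c: [] for c in classes}
    for i in range(len(X)):
        mask = np.ones(len(X), bool)
        mask[i] = False
        dists = []
        for c in classes:
            mc = X[mask & (y == c)].mean(axis=0)
            dists.append(np.sqrt(((X[i] - mc) ** 2).sum()))
        pred = classes[int(np.argmin(dists))]
        correct[y[i]].append(pred == y[i])
    return float(np.mean([np.mean(v) for c, v in sorted(correct.items())]))


def svm_loo(X: np.ndarray, y: np.ndarray) -> float:
    """Linear support-vector-machine leave-one-out accuracy (robustness
    check behind the same interface; not the default classifier)."""
    from sklearn.svm import LinearSVC
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, yi = np.unique(y, return_inverse=True)
    preds = np.empty(len(X), dtype=int)
    for i in range(len(X)):
        mask = np.ones(len(X), bool)
        mask[i] = False
        clf = LinearSVC(dual="auto", max_iter=5000)
        clf.fit(X[mask], yi[mask])
        preds[i] = clf.predict(X[i:i + 1])[0]
    correct = preds == yi
    return float(np.mean([correct[yi == c].mean()
                          for c in range(len(classes))]))


# ---------------------------------------------------------------------------
# tasks

@dataclasses.dataclass
class DecodeResult:
    task: str
    scheme: str
    population_sizes: list
    accuracies: np.ndarray            # (n_permutations, n_sizes)
    shuffled: np.ndarray | None       # same shape, label-shuffled control
    chance: float
    seed: int | None = None

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    @property
    def mean_shuffled(self) -> np.ndarray:
        return self.shuffled.mean(axis=0) if self.shuffled is not None \
            else None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "task": self.task, "scheme": self.scheme,
            "n_cells": self.population_sizes,
            "mean_accuracy": self.mean_accuracy,
            "chance": self.chance,
        })
        if self.shuffled is not None:
            df["mean_shuffled"] = self.mean_shuffled
        return df


def _series_odorants(trial_info: pd.DataFrame) -> list[str]:
    return sorted(od for od, grp in trial_info.groupby("odorant")
                  if grp["concentration"].nunique() > 1)


def _stimulus_labels(trial_info: pd.DataFrame) -> np.ndarray:
    return np.array([f"{o}@{c:g}" for o, c in
                     zip(trial_info["odorant"], trial_info["concentration"])])


def _task_accuracy(features: EncodedFeatures, task: str, cell_idx,
                   nominal: float, shuffle_rng=None, classifier="euclidean"
                   ) -> float:
    """Accuracy of one task on one pseudopopulation.

    With ``shuffle_rng``, trial (training) labels are randomly permuted
    first — the chance-level control.
    """
    info = features.trial_info
    X_all = features.subset_cells(cell_idx)
    loo = svm_loo if classifier == "svm" else euclidean_loo

    if task == "odorant":
        mask = np.isclose(info["concentration"].to_numpy(), nominal)
        y = info["odorant"].to_numpy()[mask]
        if shuffle_rng is not None:
            y = shuffle_rng.permutation(y)
        return loo(X_all[mask], y)

    if task == "concentration":
        accs = []
        for od in _series_odorants(info):
            mask = (info["odorant"] == od).to_numpy()
            y = info["concentration"].to_numpy()[mask]
            if shuffle_rng is not None:
                y = shuffle_rng.permutation(y)
            accs.append(loo(X_all[mask], y))
        return float(np.mean(accs))

    if task == "generalization":
        stim = _stimulus_labels(info)
        odorant = info["odorant"].to_numpy()
        series = _series_odorants(info)
        held_out = sorted({s for s, o in zip(stim, odorant) if o in series})
        accs = []
        for hs in held_out:
            test = stim == hs
            y_train = stim[~test]
            if shuffle_rng is not None:
                y_train = shuffle_rng.permutation(y_train)
            pred = nearest_mean_classify(X_all[~test], y_train, X_all[test])
            pred_odorant = np.array([p.split("@")[0] for p in pred])
            target = odorant[test][0]
            accs.append(float(np.mean(pred_odorant == target)))
        return float(np.mean(accs))

    raise ValueError(f"unknown task {task!r}")


def task_chance(task: str, features: EncodedFeatures | None = None) -> float:
    if task == "odorant":
        return 1 / 6 if features is None else \
            1 / features.trial_info["odorant"].nunique()
    if task == "concentration":
        return 1 / 4
    if task == "generalization":
        return 3 / 11
    raise ValueError(f"unknown task {task!r}")


def run_task(features: EncodedFeatures, task: str,
             population_sizes: Sequence[int], n_permutations: int = 200,
             seed: int | None = 0, nominal_concentration: float = 0.003,
             with_shuffled: bool = True, classifier: str = "euclidean"
             ) -> DecodeResult:
    """Decode one task across pseudopopulation sizes.

    For each permutation and size, cells are sampled without replacement
    and the leave-one-out accuracy computed; the label-shuffled control
    reuses the same pseudopopulation.  Cell draws are derived from
    ``seed`` alone, so runs with different encodings but the same seed
    are paired permutation-by-permutation.
    """
    n_cells = features.tensor.shape[1]
    sizes = list(population_sizes)
    if max(sizes) > n_cells:
        raise ValueError(f"population size {max(sizes)} exceeds "
                         f"{n_cells} available cells")
    draw_rng = np.random.default_rng(seed)
    shuf_rng = np.random.default_rng(
        None if seed is None else seed + 1_000_003)
    acc = np.empty((n_permutations, len(sizes)))
    shuf = np.empty_like(acc) if with_shuffled else None
    for p in range(n_permutations):
        for s, size in enumerate(sizes):
            idx = np.sort(draw_rng.choice(n_cells, size, replace=False))
            acc[p, s] = _task_accuracy(features, task, idx,
                                       nominal_concentration,
                                       classifier=classifier)
            if with_shuffled:
                shuf[p, s] = _task_accuracy(features, task, idx,
                                            nominal_concentration,
                                            shuffle_rng=shuf_rng,
                                            classifier=classifier)
    return DecodeResult(task, features.scheme, sizes, acc, shuf,
                        task_chance(task, features), seed)


def compare_encodings(result_a: DecodeResult, result_b: DecodeResult,
                      band: tuple = (2.5, 97.5)) -> pd.DataFrame:
    """Paired per-size accuracy differences (B - A) over permutations.

    Both results must come from ``run_task`` with the same seed and
    population sizes so each permutation used the same cells.  The
    difference is significant where the percentile band excludes zero.
    """
    if result_a.seed != result_b.seed:
        raise ValueError("results were run with different seeds; "
                         "permutations are not paired")
    if result_a.population_sizes != result_b.population_sizes:
        raise ValueError("population sizes differ")
    diff = result_b.accuracies - result_a.accuracies
    lo, hi = np.percentile(diff, band, axis=0)
    return pd.DataFrame({
        "n_cells": result_a.population_sizes,
        "mean_diff": diff.mean(axis=0),
        "lo": lo, "hi": hi,
        "significant": (lo > 0) | (hi < 0),
    })


def temporal_decoding(features: EncodedFeatures, task: str,
                      mode: str = "expanding", bin_width: float = 0.030,
                      nominal_concentration: float = 0.003,
                      classifier: str = "euclidean") -> pd.DataFrame:
    """Accuracy versus time using all cells of a binned encoding.

    ``expanding`` uses the first k bins (information accumulated up to
    k * bin_width); ``sliding`` a single bin stepped through the window.
    Deterministic: the pseudopopulation is the full recorded population.
    """
    if features.scheme != "binned":
        raise ValueError("temporal decoding requires the binned scheme")
    if mode not in ("expanding", "sliding"):
        raise ValueError("mode must be 'expanding' or 'sliding'")
    n_trials, n_cells, n_bins = features.tensor.shape
    rows = []
    for k in range(1, n_bins + 1):
        sl = slice(0, k) if mode == "expanding" else slice(k - 1, k)
        sub = EncodedFeatures(features.tensor[:, :, sl],
                              features.trial_info, "binned",
                              features.cell_ids)
        accv = _task_accuracy(sub, task, np.arange(n_cells),
                              nominal_concentration, classifier=classifier)
        rows.append({"task": task, "mode": mode, "k": k,
                     "time_s": k * bin_width if mode == "expanding"
                     else (k - 0.5) * bin_width,
                     "accuracy": accv})
    return pd.DataFrame(rows)
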