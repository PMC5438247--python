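"""Synthetic spike-train generator with a latency code for odor intensity.

Emulates the response structure of awake-mouse olfactory population
recordings so that every downstream stage has ground truth:

* log-normal spontaneous rates (arithmetic mean ~3.09 Hz) with weak,
  uniformly distributed sniff-phase preferences;
* disjoint activated-only / suppressed-only cell classes plus a small
  mixed-polarity class (~4% of cells); each odor activates ~6.7% and
  suppresses ~13.3% of cells;
* brief, Gaussian-in-time rate transients (full width at half maximum
  ~43 ms) whose spike count does not depend on concentration;
* a trimodal peak-latency structure: an early component whose timing is
  concentration-invariant, a late component whose mean shifts earlier at
  higher concentrations (cortex 206 -> 136 ms over 0.03 -> 1% v/v; bulb
  192 -> 151 ms), and a low-weight tail component;
* multiplicative suppression that deepens with concentration;
* quasi-periodic breathing; trials aligned to inhalation onset.

The stimulus panel mirrors the standard design: six odorants at a nominal
concentration, two of which are additionally presented across four
concentrations in 0.5 log10 steps, giving 12 stimuli plus a mineral-oil
blank, each presented ``n_trials_per_stimulus`` times.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io import BLANK_ODORANT, Dataset

# default late-component means (s) per region and concentration (v/v).
# endpoints are the reported values; the two intermediate concentrations
# are interpolated linearly in log10 concentration (assumption, not a
# measured fact).
DEFAULT_LATE_PHASE_MEANS: Mapping[str, Mapping[float, float]] = {
    "PCx": {0.0003: 0.206, 0.001: 0.183, 0.003: 0.159, 0.01: 0.136},
    "OB": {0.0003: 0.192, 0.001: 0.178, 0.003: 0.165, 0.01: 0.151},
}

ODORANT_NAMES = ("ethyl_butyrate", "hexanal", "ethyl_acetate",
                 "2-hexanone", "isoamyl_acetate", "ethyl_tiglate")


@dataclasses.dataclass
class SyntheticConfig:
    """Generative parameters; defaults reproduce the reference conditions.

    Rates are Hz, times seconds, concentrations v/v fractions.
    """

    n_cells_pcx: int = 459
    n_cells_ob: int = 126
    n_odorants: int = 6
    concentrations: tuple = (0.0003, 0.001, 0.003, 0.01)
    nominal_concentration: float = 0.003
    n_series_odorants: int = 2
    n_trials_per_stimulus: int = 10
    n_blank_trials: int = 10
    #: (log-mean, log-sd); arithmetic mean exp(mu + sd^2/2) ~ 3.09 Hz
    spontaneous_rate_lognormal: tuple = (0.52, 1.10)
    frac_activated_per_odor: float = 0.067
    frac_suppressed_per_odor: float = 0.133
    frac_mixed_cells: float = 0.04
    #: cell-class fractions (activated-only, suppressed-only)
    frac_activated_cells: float = 0.19
    frac_suppressed_cells: float = 0.29
    #: early latency component (mean s, sd s), concentration-invariant
    early_phase: tuple = (0.07, 0.018)
    #: concentration -> late-component mean (s), per region
    late_phase_means: Mapping[str, Mapping[float, float]] = dataclasses.field(
        default_factory=lambda: {r: dict(v)
                                 for r, v in DEFAULT_LATE_PHASE_MEANS.items()})
    #: cell-to-cell sd (s) around the late-component mean
    late_phase_sd: float = 0.030
    #: (mean s, sd s, weight) of the slow tail component
    late_tail: tuple = (0.35, 0.06, 0.15)
    #: probability an activated pair belongs to the early / late component
    #: (tail weight comes from late_tail[2])
    early_weight: float = 0.40
    #: sd (s) of the Gaussian rate transient; FWHM = 2.355 * sd ~ 43 ms
    response_duration_sd: float = 0.0183
    #: mean extra spikes per trial in an activated response (conc-invariant)
    response_spikes_per_trial: float = 5.0
    #: lognormal sd of the per-pair response amplitude (conc-invariant)
    amplitude_sd: float = 0.6
    #: probability an activated pair is actually recruited at any given
    #: concentration; the activated fraction stays flat across
    #: concentration while the specific ensemble churns
    frac_active_per_conc: float = 0.75
    #: latent correlation of membership between adjacent concentrations
    #: (0.5 log10 apart): nearby concentrations recruit overlapping but
    #: distinct ensembles
    membership_corr: float = 0.95
    #: per-trial latency jitter sd (s)
    latency_jitter_sd: float = 0.010
    #: multiplicative rate factor for suppressed pairs at the lowest conc
    suppression_base: float = 0.05
    #: additional suppression per log10 unit of concentration
    suppression_gain_per_logconc: float = 0.0333
    #: suppression starts after the early population peak (s)
    suppression_onset: float = 0.04
    #: fraction of each odor's suppressed-pair pool recruited at each
    #: concentration (non-decreasing): more cells are suppressed at
    #: higher concentrations
    suppression_recruitment: tuple = (0.80, 0.87, 0.94, 1.0)
    #: minimum spontaneous rate (Hz) for cells that express suppression;
    #: a rate decrease is unobservable in nearly silent cells
    suppressible_min_rate: float = 2.0
    #: depth of the (weak) sniff-phase modulation of spontaneous rate
    phase_modulation_depth: float = 0.10
    #: population-wide temporal envelope of within-sniff spiking on odor
    #: trials: weights of (early bump, late bump, flat floor).  The odor
    #: sniff redistributes spike times across the whole population — an
    #: early concentration-invariant wave and a later wave that moves
    #: earlier at higher concentrations — without changing spike counts.
    envelope_weights: tuple = (0.30, 0.45, 0.25)
    envelope_early_sd: float = 0.030
    envelope_late_sd: float = 0.050
    breath_period: float = 0.40
    breath_period_sd: float = 0.03
    inhalation_fraction: float = 0.40
    trial_interval: float = 10.0
    #: optional broadly tuned inhibitory-like subpopulation
    include_vgat: bool = False
    n_cells_vgat: int = 35
    vgat_peak_latency: Mapping[float, float] = dataclasses.field(
        default_factory=lambda: {0.0003: 0.091, 0.001: 0.082,
                                 0.003: 0.073, 0.01: 0.065})
    vgat_fwhm: Mapping[float, float] = dataclasses.field(
        default_factory=lambda: {0.0003: 0.089, 0.001: 0.076,
                                 0.003: 0.063, 0.01: 0.050})
    vgat_spikes_per_trial: float = 5.0
    require_monotone_late_phase: bool = False
    seed: int = 0

    def validate(self) -> None:
        fr = (self.frac_activated_per_odor, self.frac_suppressed_per_odor,
              self.frac_mixed_cells, self.frac_activated_cells,
              self.frac_suppressed_cells)
        if any(not 0 <= f <= 1 for f in fr):
            raise ValueError("all fractions must lie in [0, 1]")
        if (self.frac_activated_cells + self.frac_suppressed_cells
                + self.frac_mixed_cells) > 1 + 1e-12:
            raise ValueError("cell-class fractions must sum to <= 1")
        conc = np.asarray(self.concentrations, float)
        if not np.all(np.diff(conc) > 0):
            raise ValueError("concentrations must be strictly increasing")
        for region, means in self.late_phase_means.items():
            vals = [means[c] for c in self.concentrations if c in means]
            if any(not 0 < v < 0.5 for v in vals):
                raise ValueError("latency means must lie in (0, 0.5) s")
            if self.require_monotone_late_phase and not all(
                    a > b for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"late-phase means must decrease with concentration "
                    f"({region})")
        if self.spontaneous_rate_lognormal[1] < 0:
            raise ValueError("log-sd must be non-negative")
        if self.response_spikes_per_trial < 0:
            raise ValueError("negative response rate")
        rec = np.asarray(self.suppression_recruitment, float)
        if len(rec) != len(self.concentrations):
            raise ValueError(
                "suppression_recruitment needs one entry per concentration")
        if np.any(np.diff(rec) < 0) or np.any(rec <= 0) or np.any(rec > 1):
            raise ValueError(
                "suppression_recruitment must be non-decreasing in (0, 1]")
        if self.breath_period <= 0 or self.trial_interval <= 0:
            raise ValueError("periods must be positive")


def stimulus_panel(config: SyntheticConfig) -> pd.DataFrame:
    """The (odorant, concentration) panel: series odorants at every
    concentration, the rest at the nominal concentration only."""
    rows = []
    for i, od in enumerate(_odorant_names(config.n_odorants)):
        if i < config.n_series_odorants:
            for c in config.concentrations:
                rows.append((od, float(c)))
        else:
            rows.append((od, float(config.nominal_concentration)))
    return pd.DataFrame(rows, columns=["odorant", "concentration"])


def _odorant_names(n: int) -> list[str]:
    if n <= len(ODORANT_NAMES):
        return list(ODORANT_NAMES[:n])
    return list(ODORANT_NAMES) + [f"odorant_{i}" for i in
                                  range(len(ODORANT_NAMES), n)]


def _breath_onsets(rng: np.random.Generator, config: SyntheticConfig,
                   duration: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(np.ceil(duration / max(config.breath_period
                                   - 3 * config.breath_period_sd, 0.05))) + 2
    periods = rng.normal(config.breath_period, config.breath_period_sd, n)
    periods = np.clip(periods, 0.25 * config.breath_period,
                      2.0 * config.breath_period)
    inh = np.concatenate([[0.0], np.cumsum(periods)])
    exh = inh[:-1] + config.inhalation_fraction * periods
    keep = inh <= duration
    return inh[keep], exh[exh <= duration]


def _interp_phase(t: np.ndarray, inh: np.ndarray,
                  exh: np.ndarray) -> np.ndarray:
    """Unwrapped sniff phase at times ``t`` (0 at inhalation, pi at
    exhalation onset, 2*pi at the next inhalation)."""
    # interleave (inh_k, exh_k) pairs; exh_k lies between inh_k and inh_{k+1}
    n_pairs = min(len(inh), len(exh))
    knots = np.empty(2 * n_pairs)
    knots[0::2] = inh[:n_pairs]
    knots[1::2] = exh[:n_pairs]
    phases = np.empty_like(knots)
    phases[0::2] = 2 * np.pi * np.arange(n_pairs)
    phases[1::2] = 2 * np.pi * np.arange(n_pairs) + np.pi
    return np.interp(t, knots, phases)


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Simulate a full recording session for PCx and OB populations.

    Spontaneous spiking is an inhomogeneous Poisson process at each cell's
    log-normal rate with a weak sinusoidal sniff-phase preference.  On odor
    trials, activated cell-odor pairs add a Gaussian-in-time rate transient
    centred on a latency drawn from the pair's assigned component;
    suppressed pairs have their spontaneous spikes thinned by a factor that
    shrinks with concentration.  Returns a :class:`~odorcode.io.Dataset`
    with ground-truth labels and assigned latencies attached.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- trial table -------------------------------------------------------
    panel = stimulus_panel(config)
    stim = panel.loc[panel.index.repeat(config.n_trials_per_stimulus)]
    blanks = pd.DataFrame({
        "odorant": [BLANK_ODORANT] * config.n_blank_trials,
        "concentration": 0.0,
    })
    stim = pd.concat([stim, blanks], ignore_index=True)
    order = rng.permutation(len(stim))
    stim = stim.iloc[order].reset_index(drop=True)

    duration = 5.0 + len(stim) * config.trial_interval
    inh_all, exh_all = _breath_onsets(rng, config, duration)

    odor_onsets = 5.0 + config.trial_interval * np.arange(len(stim))
    # trial time zero: first inhalation onset at/after odor onset
    idx = np.searchsorted(inh_all, odor_onsets, side="left")
    idx = np.minimum(idx, len(inh_all) - 1)
    inh_onsets = inh_all[idx]
    nxt = np.minimum(idx + 1, len(inh_all) - 1)
    sniff_dur = inh_all[nxt] - inh_onsets

    trials = pd.DataFrame({
        "trial_id": [f"t{i:04d}" for i in range(len(stim))],
        "odorant": stim["odorant"],
        "concentration": stim["concentration"],
        "odor_onset_s": odor_onsets,
        "inhalation_onset_s": inh_onsets,
        "is_blank": (stim["odorant"] == BLANK_ODORANT).astype(int),
    })
    trials["sniff_duration_s"] = sniff_dur

    # --- per-region populations -------------------------------------------
    populations = [("PCx", "pcx", config.n_cells_pcx),
                   ("OB", "ob", config.n_cells_ob)]
    if config.include_vgat:
        populations.append(("VGAT", "vgat", config.n_cells_vgat))

    unit_rows, spike_chunks, gt_rows, gtl_rows = [], [], [], []
    odorants = _odorant_names(config.n_odorants)
    conc_arr = np.asarray(config.concentrations)
    logc = np.log10(conc_arr)

    for region, prefix, n_cells in populations:
        rates = rng.lognormal(*config.spontaneous_rate_lognormal, n_cells)
        rates = np.clip(rates, 1e-3, None)
        uids = [f"{prefix}{i:04d}" for i in range(n_cells)]
        for u, r in zip(uids, rates):
            unit_rows.append((u, region, r))

        if region == "VGAT":
            labels = np.full(n_cells, "activated")
            cls = {u: {od: "activated" for od in odorants} for u in uids}
        else:
            cls = _assign_classes(rng, config, uids, odorants, rates)

        # latency component / per-pair latency means / amplitude profiles
        lat_means = {}  # (unit, odor) -> array over concentrations
        amp_profiles = {}
        comp_of = {}
        sup_from = {}   # (unit, odor) -> lowest concentration suppressed
        rec = np.asarray(config.suppression_recruitment, float)
        for u in uids:
            for od in odorants:
                if cls[u].get(od) == "suppressed":
                    urec = rng.random()
                    idx = np.flatnonzero(rec >= urec)
                    if len(idx):
                        sup_from[(u, od)] = float(conc_arr[idx[0]])
                    continue
                if cls[u].get(od) != "activated":
                    continue
                if region == "VGAT":
                    comp, means = "vgat", np.array(
                        [config.vgat_peak_latency[c] for c in conc_arr])
                else:
                    comp, means = _draw_component(rng, config, region,
                                                  conc_arr)
                comp_of[(u, od)] = comp
                lat_means[(u, od)] = means
                amp, active = _amplitude_profile(rng, config, len(conc_arr))
                if region == "VGAT":
                    amp, active = np.ones(len(conc_arr)), active | True
                amp_profiles[(u, od)] = amp
                for c, m, a in zip(conc_arr, means, active):
                    gtl_rows.append((u, od, float(c), float(m), bool(a)))

        # ground-truth table
        for u in uids:
            sig = cls[u]
            pos = [od for od, lab in sig.items() if lab == "activated"]
            neg = [od for od, lab in sig.items() if lab == "suppressed"]
            if pos and neg:
                cell_class = "mixed"
            elif pos:
                cell_class = "activated"
            elif neg:
                cell_class = "suppressed"
            else:
                cell_class = "unresponsive"
            for od in odorants:
                lab = sig.get(od, "unresponsive")
                gt_rows.append((u, od, lab, comp_of.get((u, od), ""),
                                region, cell_class,
                                sup_from.get((u, od), np.nan)))

        spike_chunks.append(_simulate_spikes(
            rng, config, region, uids, rates, cls, lat_means, amp_profiles,
            sup_from, trials, inh_all, exh_all, duration))

    units = pd.DataFrame(unit_rows,
                         columns=["unit_id", "region", "spontaneous_rate_hz"])
    spikes = pd.concat(spike_chunks, ignore_index=True)
    ground_truth = pd.DataFrame(
        gt_rows, columns=["unit_id", "odorant", "label", "component",
                          "region", "cell_class", "suppressed_from"])
    gt_latencies = pd.DataFrame(
        gtl_rows, columns=["unit_id", "odorant", "concentration",
                           "latency_mean_s", "active"])
    ds = Dataset(units, spikes, trials, ground_truth, gt_latencies,
                 inh_all, exh_all)
    ds.meta["config"] = dataclasses.asdict(config)
    return ds


def _assign_classes(rng, config, uids, odorants, rates):
    """Cell classes and per-odor polarities.

    Cells split into disjoint activated-only / suppressed-only / mixed /
    unresponsive classes; per-odor membership probabilities are solved so
    the expected per-odor activated and suppressed fractions match the
    configured targets.  Classes that express suppression (suppressed-only
    and mixed) are sampled with probability proportional to spontaneous
    rate: a rate decrease is only observable — and only meaningfully
    defined — in cells with appreciable baseline spiking.
    """
    n = len(uids)
    n_mix = int(round(config.frac_mixed_cells * n))
    n_act = int(round(config.frac_activated_cells * n))
    n_sup = int(round(config.frac_suppressed_cells * n))
    rates = np.asarray(rates, float)
    groups = {u: "U" for u in uids}
    avail = np.arange(n)
    if n_sup + n_mix > 0:
        n_pick = min(n_sup + n_mix, n)
        eligible = avail[rates[avail] >= config.suppressible_min_rate]
        if len(eligible) < n_pick:
            eligible = avail[np.argsort(rates[avail])[-n_pick:]]
        p = rates[eligible] / rates[eligible].sum()
        chosen = rng.choice(eligible, n_pick, replace=False, p=p)
        for i in chosen[:n_sup]:
            groups[uids[i]] = "S"
        for i in chosen[n_sup:]:
            groups[uids[i]] = "M"
        avail = np.setdiff1d(avail, chosen)
    if n_act > 0 and len(avail):
        chosen = rng.choice(avail, min(n_act, len(avail)), replace=False)
        for i in chosen:
            groups[uids[i]] = "A"

    n_od = len(odorants)
    # mixed cells: one guaranteed activated + one suppressed odor, the rest
    # independent at 0.25/0.25
    p_mix_act = (1.0 + 0.25 * (n_od - 2)) / n_od if n_od >= 2 else 0.5
    f_mix = n_mix / n if n else 0.0
    # frac_activated_per_odor is the observed per-concentration fraction;
    # the underlying pool is larger by 1/frac_active_per_conc
    p_act = 0.0
    if config.frac_activated_cells > 0:
        p_act = (config.frac_activated_per_odor - f_mix * p_mix_act) \
            / (config.frac_activated_cells * config.frac_active_per_conc)
    # likewise the suppressed pool: the configured fraction is observed at
    # the nominal concentration, where only part of the pool is recruited
    rec = np.asarray(config.suppression_recruitment, float)
    conc = np.asarray(config.concentrations, float)
    i_nom = int(np.argmin(np.abs(conc - config.nominal_concentration)))
    p_sup = 0.0
    if config.frac_suppressed_cells > 0:
        p_sup = (config.frac_suppressed_per_odor - f_mix * p_mix_act) \
            / (config.frac_suppressed_cells * rec[i_nom])
    p_act, p_sup = np.clip([p_act, p_sup], 0.0, 1.0)

    cls: dict[str, dict[str, str]] = {}
    for u in uids:
        g = groups[u]
        sig: dict[str, str] = {}
        if g == "A":
            for od in odorants:
                if rng.random() < p_act:
                    sig[od] = "activated"
        elif g == "S":
            for od in odorants:
                if rng.random() < p_sup:
                    sig[od] = "suppressed"
        elif g == "M" and len(odorants) >= 2:
            i, j = rng.choice(len(odorants), 2, replace=False)
            sig[odorants[i]] = "activated"
            sig[odorants[j]] = "suppressed"
            for k, od in enumerate(odorants):
                if k in (i, j):
                    continue
                r = rng.random()
                if r < 0.25:
                    sig[od] = "activated"
                elif r < 0.5:
                    sig[od] = "suppressed"
        cls[u] = sig
    return cls


def _draw_component(rng, config, region, conc_arr):
    """Latency component for one activated cell-odor pair."""
    w_tail = config.late_tail[2]
    w_early = config.early_weight
    r = rng.random()
    if r < w_early:
        mu = rng.normal(*config.early_phase)
        means = np.full(len(conc_arr), np.clip(mu, 0.02, 0.48))
        return "early", means
    if r < w_early + w_tail:
        mu = rng.normal(config.late_tail[0], config.late_tail[1])
        means = np.full(len(conc_arr), np.clip(mu, 0.02, 0.48))
        return "tail", means
    base = np.array([config.late_phase_means[region][c] for c in conc_arr])
    delta = rng.normal(0.0, config.late_phase_sd)
    return "late", np.clip(base + delta, 0.02, 0.48)


def _amplitude_profile(rng, config, n_conc):
    """Per-concentration response amplitudes for one activated pair.

    Membership is all-or-none per concentration: a stationary latent
    AR(1) Gaussian thresholded at the stationary activity probability
    (Gaussian copula), so each concentration recruits the configured
    fraction of the activated pool while nearby concentrations recruit
    overlapping — but distinct — ensembles.  When recruited, the pair
    responds with a concentration-invariant lognormal amplitude (mean 1).

    Returns ``(amplitudes, active_mask)``.
    """
    from scipy.special import ndtri
    g = config.amplitude_sd
    rho = config.membership_corr
    z = np.empty(n_conc)
    z[0] = rng.normal()
    for i in range(1, n_conc):
        z[i] = rho * z[i - 1] + np.sqrt(max(1 - rho * rho, 0)) * rng.normal()
    active = z < ndtri(config.frac_active_per_conc)
    amp = np.exp(rng.normal(-0.5 * g * g, g)) * active
    return amp, active


def _envelope_sample(rng, config, region, conc, n, dur):
    """Spike times (s, relative to inhalation onset) drawn from the
    population temporal envelope of the odor sniff: an early
    concentration-invariant bump, a late bump at the region's
    concentration-dependent latency, and a flat floor, all confined to
    the sniff window [0, dur) so within-sniff counts are conserved."""
    w = np.asarray(config.envelope_weights, float)
    w = w / w.sum()
    comp = rng.choice(3, n, p=w)
    out = np.empty(n)
    n_e = int((comp == 0).sum())
    n_l = int((comp == 1).sum())
    n_f = n - n_e - n_l
    late_means = config.late_phase_means.get(
        region, config.late_phase_means.get("PCx", {}))
    late_mu = late_means.get(conc, 0.17)
    out[comp == 0] = rng.normal(config.early_phase[0],
                                config.envelope_early_sd, n_e)
    out[comp == 1] = rng.normal(late_mu, config.envelope_late_sd, n_l)
    out[comp == 2] = rng.uniform(0, dur, n_f)
    return np.clip(out, 0.0, dur - 1e-4)


def _suppression_factor(config, conc):
    lo = np.log10(min(config.concentrations))
    f = config.suppression_base - config.suppression_gain_per_logconc * (
        np.log10(conc) - lo)
    return float(np.clip(f, 0.0, 1.0))


def _simulate_spikes(rng, config, region, uids, rates, cls, lat_means,
                     amp_profiles, sup_from, trials, inh_all, exh_all,
                     duration):
    """Superpose baseline Poisson spiking, suppression thinning, and
    activated-response transients for one population."""
    m = config.phase_modulation_depth
    pref = rng.uniform(0, 2 * np.pi, len(uids))
    conc_arr = np.asarray(config.concentrations)
    conc_index = {float(c): k for k, c in enumerate(conc_arr)}

    stim_trials = trials[trials["is_blank"] == 0]
    all_u, all_t = [], []
    for ui, (u, lam) in enumerate(zip(uids, rates)):
        # baseline via thinning of a homogeneous process at lam*(1+m)
        n_base = rng.poisson(lam * (1 + m) * duration)
        t = rng.uniform(0, duration, n_base)
        if n_base and m > 0:
            phase = _interp_phase(t, inh_all, exh_all)
            acc = (1 + m * np.cos(phase - pref[ui])) / (1 + m)
            t = t[rng.random(n_base) < acc]
        t.sort()

        # odor-sniff processing: suppression thinning (suppressed pairs)
        # and the count-preserving temporal envelope (all cells)
        sig = cls[u]
        if len(t):
            drop = np.zeros(len(t), bool)
            new_times = []
            for t0, dur, c, od in zip(stim_trials["inhalation_onset_s"],
                                      stim_trials["sniff_duration_s"],
                                      stim_trials["concentration"],
                                      stim_trials["odorant"]):
                i0, i1 = np.searchsorted(t, [t0, t0 + dur])
                if i1 <= i0:
                    continue
                drop[i0:i1] = True
                seg = _envelope_sample(rng, config, region, float(c),
                                       i1 - i0, dur)
                recruited = (sig.get(od) == "suppressed"
                             and float(c) >= sup_from.get((u, od), np.inf)
                             - 1e-12)
                if recruited:
                    # sustained suppression after the early population
                    # peak; more pairs are recruited, and suppression
                    # deepens, at higher concentrations
                    keep_p = _suppression_factor(config, c)
                    keep = ~((seg >= config.suppression_onset)
                             & (seg < dur)
                             & (rng.random(i1 - i0) >= keep_p))
                    seg = seg[keep]
                if len(seg):
                    new_times.append(t0 + seg)
            if new_times:
                t = np.concatenate([t[~drop]] + new_times)
            else:
                t = t[~drop]
            t.sort()

        # activated transients
        resp_times = []
        act_odors = [od for od, lab in sig.items() if lab == "activated"]
        for od in act_odors:
            means = lat_means[(u, od)]
            sel = stim_trials[stim_trials["odorant"] == od]
            for t0, c in zip(sel["inhalation_onset_s"],
                             sel["concentration"]):
                ci = conc_index[float(c)]
                mu = means[ci]
                amp = (config.response_spikes_per_trial
                       * amp_profiles[(u, od)][ci])
                if region == "VGAT":
                    amp = config.vgat_spikes_per_trial * (
                        1 + 0.1 * (np.log10(c) - np.log10(conc_arr[0])))
                n_sp = rng.poisson(amp)
                if not n_sp:
                    continue
                lat = mu + rng.normal(0, config.latency_jitter_sd)
                sd = config.response_duration_sd
                if region == "VGAT":
                    sd = config.vgat_fwhm[float(c)] / 2.3548
                sp = t0 + rng.normal(lat, sd, n_sp)
                sp = sp[(sp >= t0) & (sp < t0 + 0.5)]
                resp_times.append(sp)
        if resp_times:
            t = np.sort(np.concatenate([t] + resp_times))
        all_u.append(np.full(len(t), u, dtype=object))
        all_t.append(t)

    return pd.DataFrame({
        "unit_id": np.concatenate(all_u) if all_u else [],
        "time_s": np.concatenate(all_t) if all_t else [],
    })


def generate_respiration_trace(breath_period: float, duration: float,
                               sampling_rate: float = 2000.0,
                               period_sd: float = 0.0,
                               amplitude: float = 1.0,
                               noise_sd: float = 0.0,
                               drift_per_s: float = 0.0,
                               inhalation_fraction: float = 0.5,
                               seed: int | None = None):
    """Quasi-periodic airflow trace whose negative lobes are inhalations.

    Returns ``(trace, inhalation_onsets, exhalation_onsets)``; the onset
    arrays are the generator's ground truth.  With ``period_sd = 0``,
    ``noise_sd = 0`` and ``inhalation_fraction = 0.5`` the trace is exactly
    ``-amplitude * sin(2*pi*t/breath_period)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if breath_period <= 0 or sampling_rate <= 0:
        raise ValueError("breath_period and sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate

    onsets = [0.0]
    while onsets[-1] < duration:
        p = breath_period if period_sd == 0 else max(
            rng.normal(breath_period, period_sd), 0.25 * breath_period)
        onsets.append(onsets[-1] + p)
    inh = np.asarray(onsets)

    # piecewise sinusoid: negative half-lobe over the inhalation fraction of
    # each cycle, positive half-lobe over the remainder
    cyc = np.searchsorted(inh, t, side="right") - 1
    cyc = np.clip(cyc, 0, len(inh) - 2)
    start = inh[cyc]
    period = inh[cyc + 1] - inh[cyc]
    frac = (t - start) / period
    exh_frac = inhalation_fraction
    trace = np.where(
        frac < exh_frac,
        -np.sin(np.pi * frac / exh_frac),
        np.sin(np.pi * (frac - exh_frac) / (1 - exh_frac)),
    ) * amplitude
    if noise_sd > 0:
        trace = trace + rng.normal(0, noise_sd, len(trace))
    if drift_per_s:
        trace = trace + drift_per_s * t
    exh = inh[:-1] + exh_frac * np.diff(inh)
    inh = inh[inh <= duration]
    exh = exh[exh <= duration]
    return trace, inh, exh
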