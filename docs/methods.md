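# Methods

`odorcode` analyzes population spike trains recorded from olfactory bulb
(OB) and piriform cortex (PCx) during odor presentations, and ships a
synthetic-data generator that reproduces the statistical structure of such
recordings so that every stage of the analysis can be validated against
ground truth. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic data do and do not show.

## The scientific question

A population code must represent which odor is present (identity) in a way
that survives changes in how much of it is present (intensity), while still
representing intensity itself. The analyses here dissociate the two: odor
identity is carried by *which* neurons respond (ensemble membership), while
intensity is carried by *when* the later part of the population response
occurs (a latency code). The package implements the full chain needed to
make that argument quantitatively: respiration alignment, per cell-odor
response statistics, population-vector geometry, decoding under membership
/ rate / temporal encodings, truncated-Gaussian mixture modeling of
peak-latency distributions, and latency-versus-concentration regression.

## Data model

All analyses consume a `Dataset`: continuous per-unit spike times, a trial
table (odorant, v/v concentration, odor onset, inhalation onset), unit
metadata (region), and optionally full-session breath events. Analysis
time zero is the first inhalation onset at or after odor onset. Counting
windows are half-open `[start, end)`; the "first sniff" is the trial's
first full respiration cycle when breath events are available and a fixed
480 ms otherwise. Peak latencies live on the closed window `[0, 0.5]` s.

## Synthetic data generator

The generator simulates a head-fixed recording session: trials every 10 s,
six odorants at a nominal 0.3% v/v, two of them additionally at 0.03, 0.1,
0.3 and 1% (0.5-log10 steps; 12 panel stimuli) plus a mineral-oil blank,
10 trials each. Quasi-periodic breathing (period 0.40 ± 0.03 s) provides
inhalation onsets; odor onsets are aligned to the respiratory cycle.

**Spontaneous activity.** Each cell's rate is log-normal
(log-mean 0.52, log-sd 1.10; arithmetic mean ≈ 3.09 Hz, median ≈ 1.7 Hz),
realized as a Poisson process with a weak sinusoidal sniff-phase preference
(10% modulation, preferred phases uniform) so that population spiking is
effectively decoupled from respiration.

**Cell classes.** Cells split into disjoint activated-only (19%),
suppressed-only (29%), mixed (4%) and unresponsive classes. Per odor, the
expected activated and suppressed fractions are 6.7% and 13.3% of cells;
membership probabilities are solved from the class fractions so those
targets hold at the nominal concentration. Two modeling choices shape the
suppressed class:

* *Rate eligibility.* Suppression-expressing classes are drawn with
  probability proportional to spontaneous rate among cells above 2 Hz. A
  rate decrease is unobservable — and arguably undefined — in a cell that
  hardly fires within one sniff; without this choice no one-sniff rank-sum
  test can detect most suppressed pairs at these firing rates.
* *Concentration recruitment.* Each suppressed pair has a threshold
  concentration; the recruited fraction of the pool grows
  (0.80/0.87/0.94/1.00 across the four concentrations), so the suppressed
  percentage rises with concentration while the activated percentage stays
  flat. Recruited suppression is multiplicative (factor 0.05 at the lowest
  concentration, shrinking by 0.033 per log10 unit, floored at 0) and
  starts 40 ms after inhalation, after the early population peak.

**Activated responses.** An activated pair emits a Gaussian-in-time rate
transient with SD 18.3 ms (FWHM ≈ 43 ms), mean 5 extra spikes per trial,
per-trial latency jitter 10 ms. Amplitude does not depend on
concentration. Each pair belongs to one latency component:

* *early* (40%): mean 70 ± 18 ms, concentration-invariant;
* *late* (45%): mean shifts with concentration — PCx 206/183/159/136 ms,
  OB 192/178/165/151 ms at 0.03/0.1/0.3/1% (endpoints are the reference
  values; intermediates interpolate linearly in log10 concentration);
  cell-to-cell spread 30 ms;
* *tail* (15%): mean 350 ± 60 ms, concentration-invariant.

Membership across concentration churns: a pair is actually recruited at
each concentration with probability 0.75, governed by a latent AR(1)
Gaussian (correlation 0.95 between adjacent concentrations) thresholded at
that probability. Nearby concentrations therefore activate overlapping but
distinct ensembles while the per-concentration activated fraction and the
expected spike count stay flat — this is what lets a membership code carry
some intensity information without creating a systematic rate code.

**Population temporal envelope.** On odor trials, the within-sniff spike
times of *all* cells are redrawn from a mixture of an early bump (70 ms,
weight 0.30), a late bump at the region's concentration-dependent latency
(weight 0.45) and a flat floor (weight 0.25), confined to the sniff window
so per-trial counts are conserved exactly. This emulates the
concentration-dependent redistribution of population spike timing without
touching any rate statistic; it is what gives every cell's first-spike and
single-trial-peak latencies their concentration dependence, and what makes
the cortical latency compression steeper than the bulb's.

**Inhibitory-like subpopulation (optional).** A broadly tuned population
(35 cells) activated by every odor, with peak latency 91→65 ms and
response FWHM 89→50 ms across the concentration range, analyzed only
through the ordinary response metrics.

**Determinism.** Everything derives from one `numpy` `Generator`; a fixed
config and seed reproduce the dataset bit for bit.

**What the generator does not emulate.** Trial-order effects, adaptation,
correlated (non-Poisson) variability, spike sorting artifacts, waveforms,
LFPs, true bulb→cortex circuit dynamics, and behavioral state. Passing
tests show the *analyses* behave correctly on data with the reported
response statistics, not that real cortex works this way. One consequence
worth flagging: under a Poisson baseline, far more cell-odor pairs have a
well-defined KDF peak at every concentration (~88%) than in real
recordings (~45%), so mixture fits to pipeline-extracted latency samples
contain a larger noise-peak background than fits to real data; the
mixture-model validation therefore draws latencies directly from the
generator's three-component model.

## Respiration

Airflow traces (2 kHz; negative = inhalation) are smoothed with a
second-order Savitzky-Golay filter in 200 ms frames and locally detrended
with linear fits in 1.5 s windows with 1 s overlap (triangular blending
across overlaps avoids trend discontinuities; the regression order is a
knob). Inhalation/exhalation onsets are the linearly interpolated zero
crossings before and after negative peaks whose prominence exceeds half
the median trough depth (the amplitude criterion for a "large" peak is not
standardized; this default is configurable). Note that a line fitted to a
sinusoid over a finite window is not identically zero, so detrending
shifts pure-tone zero crossings by a few milliseconds; on breath-like
traces onsets are recovered within 10 ms. Spike phases interpolate 0 → π
across inhalation and π → 2π to the next inhalation; phase histograms use
10° bins.

## Response metrics

Firing rates are kernel density estimates: 10 ms Gaussian kernel on a 1 ms
grid, truncated at the window bounds without renormalization (so a peak at
a window edge is flagged undefined rather than smeared inward). Peak
latency is the KDF maximum; response duration is the width of that peak at
25% or 50% of its height, clipped at the window bounds.

The response index is 2·auROC − 1, where auROC is the probability that an
odor-trial first-sniff count exceeds a blank-trial count (ties count one
half), computed from the Mann-Whitney U statistic; significance is the
two-sided rank-sum test (exact for small tie-free samples, tie-corrected
normal approximation otherwise), uncorrected at α = 0.05 — no
multiple-testing correction is applied, deliberately, so the null
false-positive rate is itself a calibration check (rank-sum on discrete
counts is mildly conservative, so the empirical rate runs slightly below
α). Cells are classed activated / suppressed / mixed / unresponsive from
the signs of their significant per-odor indices; the tuning null shuffles
cell identities within each odor column 100 times, preserving per-odor
response counts.

Sparseness uses the standard normalized-peakedness formula
S = (1 − (Σr/n)²/(Σr²/n)) / (1 − 1/n) on trial-averaged first-sniff
counts; negative (suppressed) responses are rectified to zero before the
formula since it assumes non-negative rates (a documented knob), and an
all-zero profile is undefined. Blank subtraction is not applied.

The population PSTH is the across-cell average of per-cell trial-averaged
KDFs; the peak/average ratio over the first sniff is the synchrony index.
Total spiking output sums first-sniff counts over cells and is normalized,
per concentration-series odorant, by its mean across concentrations (the
normalization baseline is a package choice).

## Population vectors and correlations

Response vectors are per-cell spike counts in the trial's first sniff.
Trial-pair similarity uses Spearman's rank correlation (mid-rank ties);
within-stimulus averages use all unordered distinct trial pairs (45 pairs
for 10 trials), never self-pairs, while between-condition averages use the
full cross product. Pairs are grouped by relation: same stimulus, same
odorant at Δlog10 concentration 0.5/1.0/1.5, different odorant. Vectors
with zero variance are skipped with a log notice.

## Decoding

Three feature encodings of the 0-480 ms response: binary membership
(count strictly greater than the cell's blank mean + 1 SD; sample SD, and
a zero-SD blank falls back to the mean), summed counts, and 16
concatenated 30 ms bins. The classifier is leave-one-out nearest class
mean under Euclidean distance, with macro-averaged per-class accuracy;
distance ties break deterministically to the lowest class index (a
seeded-random alternative exists), and a linear SVM is available behind
the same interface as a robustness check.

Tasks: 6-way odorant identification at the nominal concentration; 4-way
concentration identification per series odorant, averaged over the two
odorants (trained and tested separately per odorant); and identity
generalization — hold out one concentration of one series odorant, train
an 11-way stimulus classifier on the rest, score a held-out trial correct
whenever the predicted stimulus has the held-out odorant's identity,
averaged over all 8 holdouts. Chance is 1/6, 1/4 and 3/11 respectively
(3 of the 11 training stimuli share the held-out identity). Blank
statistics for the binary threshold are pooled across all blank trials.

Pseudopopulations sample cells without replacement within a permutation
and with replacement across permutations; the draws depend only on the
seed, so runs with different encodings are paired permutation-by-
permutation and encoding comparisons use paired differences with a
2.5-97.5 percentile band. Temporal decoding uses either an expanding
window of 30 ms bins or a sliding 30 ms bin across 0-480 ms, on the full
population. Note that leave-one-out with label shuffling has a small
negative finite-sample bias (the held-out trial depletes its own class
mean), visible at 10 trials per class and shrinking with trial count.

## Truncated-Gaussian latency mixtures

Peak-latency distributions on [0, 0.5] s are fit with mixtures of
truncated normal densities by EM. The E-step uses responsibilities under
the truncated densities; the M-step maximizes each component's weighted
truncated-normal log-likelihood, which reduces to a two-parameter function
of three sufficient statistics and is solved by L-BFGS with analytic
gradients, warm-started at the current parameters and falling back to them
if no improvement is found — so the observed log-likelihood never
decreases (a property the tests check). Initialization is k-means cluster
assignment; five restarts by default; convergence at |ΔlogL| < 1e-7 per
observation or 8000 iterations; σ is floored at 1 ms and restarts that
collapse onto the floor count as non-converged. Non-converged fits carry
no parameters and are excluded downstream.

BIC is −2·logL + q·ln n with q = 3k − 1 free parameters for an
unconstrained fit (whether the reference analysis counted 3k or 3k − 1 is
not documented; q always equals the number of *unfrozen* parameters, so
constrained refits are penalized consistently). Bootstrap CIs refit
with-replacement resamples of the same size and take 2.5-97.5 percentiles
per parameter; resample fits warm-start at the point estimate with no
fresh restarts (verified to give the same intervals as restarted fits,
at a fraction of the cost). Components are matched across resamples and
concentrations by increasing mean — a known limitation when components
overlap, and the reason the constrained protocol exists: freezing the
mixing proportions and the slowest component at their across-concentration
means leaves only the timing of the two principal phases free, which
substantially narrows the bootstrap intervals.

## Concentration-latency slopes

Per cell and concentration, response latency is measured trial-by-trial —
first spike after inhalation, or the single-trial KDF peak — and averaged
over trials; a cell contributes only when more than one trial yields a
measurement. Cell latencies are averaged per concentration and an
ordinary (unweighted) least-squares line is fit against log10
concentration (the stimulus design is logarithmic; a linear-axis option
exists). Populations with no measurable latencies are dropped with a
notice. Region comparison is an unpaired two-sided t-test on the slope
distributions.

## Problem sizes used in validation

The test-suite and acceptance-script runs use populations of 80-459
cortical cells, 8-15 trials per stimulus, mixture samples of n ≈ 400 with
120-200 bootstrap resamples, 200 decoder permutations, and 6-10 simulated
sessions for the region-slope comparison. These sizes were chosen so each
check has adequate statistical resolution for the effect it probes;
estimates tighten in the obvious ways when they are raised.

## Known limitations

* The leave-one-out chance bias and the conservative rank-sum on discrete
  counts, both noted above, are properties of the referenced procedures,
  reproduced faithfully rather than "fixed".
* Mixture component identity is by mean order only; heavily overlapping
  components can swap identities across bootstrap resamples.
* The generator's envelope model couples all cells' timing to two global
  waves; real populations are heterogeneous in ways this ignores.
* Pipeline-extracted latency mixtures on fully synthetic data carry a
  uniform noise-peak background (see above); interpret their absolute
  component weights with care.
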