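# odorcode

Analysis pipeline for population spike-train recordings from olfactory
bulb (OB) and piriform cortex (PCx), built to dissociate how a cortical
population encodes **odor identity** from how it encodes **odor
intensity**. It is aimed at systems neuroscientists working with
extracellular recordings aligned to respiration: the inputs are per-unit
spike times, a trial table (odorant, v/v concentration, inhalation onset),
and optionally a raw airflow trace.

The core analyses:

* **Respiration alignment** — Savitzky-Golay smoothing, local detrending,
  inhalation/exhalation onsets from zero crossings around airflow troughs,
  and sniff-phase assignment of spikes.
* **Response characterization** — per cell-odor kernel density rates
  (10 ms Gaussian kernel), peak latency and duration, the auROC response
  index `RI = 2·auROC − 1` against mineral-oil blanks with rank-sum
  significance, polarity classes, tuning-shuffle nulls, and lifetime /
  population sparseness
  `S = (1 − (Σrᵢ/n)²/Σ(rᵢ²/n)) / (1 − 1/n)`.
* **Population geometry** — first-sniff spike-count vectors and Spearman
  trial-pair correlations by stimulus relation and Δlog₁₀ concentration.
* **Decoding** — leave-one-out nearest-class-mean classification under
  three encodings (binary membership, summed counts, 16 × 30 ms bins) and
  three tasks (6-way odorant, 4-way concentration, identity
  generalization with chance 3/11), with pseudopopulation permutation
  statistics and expanding/sliding-window temporal decoding.
* **Latency mixture modeling** — maximum-likelihood mixtures of Gaussians
  truncated to [0, 0.5] s fit to peak-latency distributions by EM, BIC
  component selection, percentile bootstrap CIs, and constrained refits
  that freeze the slow component.
* **Concentration-latency slopes** — per-population OLS slopes of mean
  response latency against log₁₀ concentration, compared between regions.

Because such datasets are rarely shareable, the package includes a
first-class synthetic-data generator (`odorcode.synth`) that reproduces
the reported response structure — log-normal spontaneous rates (mean
≈ 3.09 Hz), ~6.7% activated / ~13.3% suppressed cells per odor with
disjoint polarity classes, brief (~43 ms FWHM) responses, a trimodal
latency structure whose late component shifts from 206 to 136 ms (PCx)
and 192 to 151 ms (OB) across a 0.03–1% v/v concentration series — so
every stage can be validated against ground truth. See
`docs/methods.md` for the generative model and all analysis conventions.

## Worked example

```python
import odorcode as oc
from odorcode import decode

# a synthetic session: 459 cortical cells, 12-stimulus panel + blanks
ds = oc.generate_dataset(oc.SyntheticConfig(n_cells_ob=0, seed=17))

# per cell-odor response statistics at the nominal concentration
stats = oc.response_stats_table(ds)
classes = oc.classify_polarity(stats, concentration=0.003)
print(classes["cell_class"].value_counts().to_dict())

# decode odor concentration from three encodings of the same trials
feats = {s: decode.encode(ds, decode.EncodingConfig(scheme=s), region="PCx")
         for s in decode.SCHEMES}
for scheme, f in feats.items():
    r = decode.run_task(f, "concentration", [50, 200, 459],
                        n_permutations=200, seed=3, with_shuffled=False)
    print(scheme, [round(a, 3) for a in r.mean_accuracy])
```

Output:

```
{'unresponsive': 203, 'suppressed': 149, 'activated': 85, 'mixed': 22}
binary [0.342, 0.442, 0.525]
summed [0.398, 0.595, 0.75]
binned [0.598, 0.828, 0.925]
```

The class counts show the expected mix of activated, suppressed and
mixed-polarity cells. The decoding table is the central dissociation:
keeping coarse spike *timing* (binned) markedly improves concentration
decoding over spike *counts* (summed) or bare ensemble *membership*
(binary) — intensity is carried by when cells fire, not how much. Running
the same comparison for the odorant task gives near-identical accuracies
across encodings: identity is fully available from membership alone.

A command-line interface mirrors the library
(`odorcode simulate | breaths | metrics | correlate | decode |
latency-fit | slopes | run-all`); `odorcode run-all --seed 0 --out out/`
executes the whole pipeline on synthetic data and writes CSV/JSON
artifacts plus a content-hash manifest.

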